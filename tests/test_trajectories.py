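"""Candidate ranking, trajectory shapes, fixation, overlap and decay."""

import numpy as np
import pandas as pd
import pytest

from erps.snp_calling import SnpTable
from erps.trajectories import (
    CandidateSet,
    candidate_overlap,
    classify_trajectories,
    compare_trajectory_classes,
    fixation_fraction,
    flanking_decay,
    interval_afc,
    orient_selected_allele,
    top_candidates,
    trajectory_table,
)


def scan_frame(pvals, chrom="2L"):
    return pd.DataFrame({
        "chrom": chrom, "pos": np.arange(1, len(pvals) + 1) * 10,
        "contrast": "B-E", "statistic": 1.0, "p_value": pvals, "k_used": 3,
    })


class TestTopCandidates:
    def test_selects_smallest(self):
        cand = top_candidates(scan_frame([0.5, 0.001, 0.01, 0.2]), 3)
        assert cand.table["p_value"].tolist() == [0.001, 0.01, 0.2]

    def test_tie_broken_by_position(self):
        frame = scan_frame([0.01, 0.01, 0.5])
        cand = top_candidates(frame, 1)
        assert cand.table.loc[0, "pos"] == 10

    def test_nan_pvalues_ignored_and_shortage_raises(self):
        frame = scan_frame([0.1, np.nan, 0.2])
        assert top_candidates(frame, 2).n == 2
        with pytest.raises(ValueError):
            top_candidates(frame, 3)


def make_table(design, freq_by_tp_rep):
    """freq_by_tp_rep: {(timepoint, replicate): minor frequency}."""
    npop = design.n_populations
    cov = np.full((1, npop), 100)
    mc = np.zeros((1, npop), dtype=int)
    for i, pop in enumerate(design.populations):
        f = freq_by_tp_rep.get((pop.timepoint, pop.replicate),
                               freq_by_tp_rep.get(pop.timepoint, 0.0))
        mc[0, i] = round(f * 100)
    return SnpTable(np.array(["2L"], dtype=object), np.array([100]),
                    np.array(["A"], dtype=object), np.array(["T"], dtype=object),
                    mc, cov, design.population_names)


class TestOrientation:
    def test_rising_minor_selected(self, design):
        t = make_table(design, {"B": 0.2, "M": 0.4, "E": 0.5, "F27": 0.45})
        is_minor, flag = orient_selected_allele(t, design, ("B", "E"))
        assert is_minor[0] and not flag[0]

    def test_falling_minor_selects_major(self, design):
        t = make_table(design, {"B": 0.5, "M": 0.3, "E": 0.2, "F27": 0.25})
        is_minor, _ = orient_selected_allele(t, design, ("B", "E"))
        assert not is_minor[0]

    def test_mixed_signs_flagged(self, design):
        t = make_table(design, {("B", 1): 0.3, ("B", 2): 0.3, ("B", 3): 0.3,
                                ("E", 1): 0.6, ("E", 2): 0.1, ("E", 3): 0.35,
                                "M": 0.3, "F27": 0.3})
        is_minor, flag = orient_selected_allele(t, design, ("B", "E"))
        assert is_minor[0]  # mean change +0.05
        assert flag[0]


class TestIntervalAfc:
    def test_direct_change(self, design):
        t = make_table(design, {"B": 0.1, "M": 0.4, "E": 0.4, "F27": 0.4})
        per_snp, med = interval_afc(t, design, np.array([True]), "B", "M")
        assert per_snp[0] == pytest.approx(0.3)
        assert med == pytest.approx(0.3)

    def test_telescoping_identity_exact(self, design, neutral_experiment):
        snps = neutral_experiment.snps
        is_minor = np.ones(len(snps), dtype=bool)
        bm, _ = interval_afc(snps, design, is_minor, "B", "M")
        me, _ = interval_afc(snps, design, is_minor, "M", "E")
        be, _ = interval_afc(snps, design, is_minor, "B", "E")
        np.testing.assert_allclose(bm + me, be, atol=1e-12)


class TestClassification:
    def test_plateau_and_continuous_examples(self):
        # trajectories B=0.1 -> M -> E
        rise = np.array([0.4, 0.2])
        late = np.array([0.0, 0.3])
        labels = classify_trajectories(rise, late, rise_min=0.2, flat_max=0.05)
        assert labels.tolist() == ["plateau", "continuous"]

    def test_labels_partition(self, rng):
        rise = rng.normal(0.15, 0.1, 500)
        late = rng.normal(0.05, 0.1, 500)
        labels = classify_trajectories(rise, late, 0.2, 0.05)
        counts = pd.Series(labels).value_counts()
        assert counts.sum() == 500
        assert set(counts.index) <= {"plateau", "continuous", "other"}

    def test_bad_thresholds(self):
        with pytest.raises(ValueError):
            classify_trajectories([0.1], [0.1], rise_min=0.0, flat_max=0.05)


class TestFixation:
    def test_all_fixed(self):
        assert fixation_fraction(np.ones(5)) == 1.0

    def test_hand_fraction(self):
        assert fixation_fraction([0.995, 0.5, 0.7, 0.2], 0.99) == pytest.approx(0.25)

    def test_strict_mode(self):
        f = [0.90, 0.95]
        assert fixation_fraction(f, 0.90) == 1.0
        assert fixation_fraction(f, 0.90, strict=True) == 0.5

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            fixation_fraction([0.5], threshold=0.0)


class TestOverlap:
    def _set(self, positions):
        return {("2L", p) for p in positions}

    def test_partial_overlap_fraction(self):
        a = self._set(range(2000))
        b = self._set(range(1553, 3553))  # 447 shared
        count, frac = candidate_overlap(a, b)
        assert count == 447
        assert round(100 * frac) == 22

    def test_identical_and_disjoint(self):
        a = self._set(range(10))
        assert candidate_overlap(a, a) == (10, 1.0)
        assert candidate_overlap(a, self._set(range(100, 110)))[0] == 0


class TestFlankingDecay:
    def _setup(self):
        cand = CandidateSet("B-E", pd.DataFrame({
            "chrom": ["2L"], "pos": [10_000], "p_value": [1e-9]}))
        pos = np.concatenate([[10_000], 10_000 + np.arange(-1000, 1001, 37)])
        allpos = pd.DataFrame({"chrom": "2L", "pos": pos})
        afc = np.full(len(pos), 0.05)
        afc[0] = 0.9  # the candidate itself: must be excluded
        return cand, allpos, afc

    def test_candidate_excluded_and_flat_curve(self):
        cand, allpos, afc = self._setup()
        out = flanking_decay(cand, allpos, afc, bin_width=100, span=1000)
        filled = out.dropna(subset=["median_afc"])
        np.testing.assert_allclose(filled["median_afc"], 0.05)

    def test_bin_assignment_floor_rule(self):
        cand = CandidateSet("B-E", pd.DataFrame({
            "chrom": ["2L"], "pos": [1000], "p_value": [1e-9]}))
        allpos = pd.DataFrame({"chrom": ["2L"], "pos": [1130]})  # 130 bp away
        out = flanking_decay(cand, allpos, np.array([0.3]), bin_width=100, span=1000)
        assert out.loc[1, "n_snps"] == 1
        assert out["n_snps"].sum() == 1

    def test_bin_width_consistency(self):
        cand, allpos, afc = self._setup()
        wide = flanking_decay(cand, allpos, afc, bin_width=100, span=1000)
        narrow = flanking_decay(cand, allpos, afc, bin_width=50, span=1000)
        assert narrow["n_snps"].sum() == wide["n_snps"].sum()

    def test_span_smaller_than_bin_rejected(self):
        cand, allpos, afc = self._setup()
        with pytest.raises(ValueError):
            flanking_decay(cand, allpos, afc, bin_width=100, span=50)


def test_trajectory_table_long_format(design, neutral_experiment):
    snps = neutral_experiment.snps.subset(np.arange(5))
    out = trajectory_table(snps, design, np.ones(5, dtype=bool))
    assert len(out) == 5 * design.n_populations
    assert set(out.columns) == {"chrom", "pos", "replicate", "timepoint",
                                "generation", "freq"}


def test_class_comparison_detects_shift(rng):
    a = rng.normal(0.02, 0.05, 300)   # plateau-like late changes
    b = rng.normal(0.20, 0.05, 300)   # continuous-like
    _, p = compare_trajectory_classes(a, b)
    assert p < 1e-10
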