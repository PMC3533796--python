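"""SNP-calling filters, frequencies, and diversity summaries."""

import itertools

import numpy as np
import pytest

from erps.design import default_design
from erps.snp_calling import (
    SnpRecord,
    call_snp_table,
    site_frequencies,
    snp_filter_mask,
    heterozygosity_change,
    window_pi,
)
from erps.sync_io import SyncRecord

POPS6 = [f"p{i}" for i in range(6)]


def site(pos, per_pop, chrom="2L", ref="A"):
    """per_pop: list of 6 sextuples [A,T,C,G,N,del]."""
    return SyncRecord(chrom, pos, ref, per_pop)


def biallelic(pos, major_counts, minor_counts, major="A", minor="T"):
    idx = {"A": 0, "T": 1, "C": 2, "G": 3}
    rows = []
    for ma, mi in zip(major_counts, minor_counts):
        row = [0] * 6
        row[idx[major]] += ma
        row[idx[minor]] += mi
        rows.append(row)
    return site(pos, rows)


class TestCallFilters:
    def test_minimum_minor_total_and_spread(self):
        recs = [
            biallelic(100, [20] * 6, [3, 3, 4, 0, 0, 0]),   # total 10, 3 pops -> pass
            biallelic(200, [20] * 6, [9, 0, 0, 0, 0, 0]),   # total 9 -> fail
            biallelic(300, [20] * 6, [10, 0, 0, 0, 0, 0]),  # 1 pop -> fail
        ]
        out = call_snp_table(recs, POPS6)
        assert out.pos.tolist() == [100]

    def test_max_coverage_per_population(self):
        ok = biallelic(100, [40] * 6, [2] * 6)
        too_deep = biallelic(200, [499, 40, 40, 40, 40, 40], [2] * 6)  # pop0 cov 501
        out = call_snp_table([ok, too_deep], POPS6)
        assert out.pos.tolist() == [100]

    def test_triallelic_noise_zeroed_but_strong_third_drops(self):
        noisy = site(100, [[20, 4, 1, 0, 0, 0], [20, 4, 1, 0, 0, 0],
                           [20, 4, 0, 0, 0, 0], [20, 0, 0, 0, 0, 0],
                           [20, 0, 0, 0, 0, 0], [20, 0, 0, 0, 0, 0]])
        strong = site(200, [[20, 4, 3, 0, 0, 0], [20, 4, 0, 0, 0, 0],
                            [20, 4, 0, 0, 0, 0], [20, 0, 0, 0, 0, 0],
                            [20, 0, 0, 0, 0, 0], [20, 0, 0, 0, 0, 0]])
        out = call_snp_table([noisy, strong], POPS6)
        assert out.pos.tolist() == [100]
        # coverage excludes the zeroed noise allele
        assert out.coverages[0].tolist() == [24, 24, 24, 20, 20, 20]

    def test_monomorphic_never_called(self):
        out = call_snp_table([biallelic(100, [30] * 6, [0] * 6)], POPS6)
        assert len(out) == 0

    def test_permissive_filters_emit_every_polymorphic_site(self):
        recs = [biallelic(p, [20] * 6, m) for p, m in
                [(1, [1, 0, 0, 0, 0, 0]), (2, [0, 2, 0, 0, 0, 0]), (3, [1] * 6)]]
        out = call_snp_table(recs, POPS6, min_minor_total=1, max_coverage=10**9,
                             min_populations_detected=1)
        assert len(out) == 3

    def test_filters_commute(self):
        rng = np.random.default_rng(3)
        mc = rng.integers(0, 8, size=(200, 6))
        cov = mc + rng.integers(5, 600, size=(200, 6))
        full = snp_filter_mask(mc, cov)
        # apply the three filters one at a time in every order
        singles = {
            "total": snp_filter_mask(mc, cov, 10, 10**9, 1),
            "spread": snp_filter_mask(mc, cov, 1, 10**9, 2),
            "cov": snp_filter_mask(mc, cov, 1, 500, 1),
        }
        for order in itertools.permutations(singles):
            acc = np.ones(len(mc), bool)
            for key in order:
                acc &= singles[key]
            np.testing.assert_array_equal(acc, full)

    def test_tie_breaks_alphabetical(self):
        rec = biallelic(100, [5] * 6, [5] * 6, major="T", minor="A")
        out = call_snp_table([rec], POPS6, min_minor_total=10)
        assert out.major[0] == "A" and out.minor[0] == "T"

    def test_bad_parameter(self):
        with pytest.raises(ValueError):
            call_snp_table([], POPS6, min_minor_total=0)


class TestFrequencies:
    def make(self):
        return SnpRecord("2L", 5, "A", "T", [5, 0], [50, 0])

    def test_minor_fraction_and_missing(self):
        snp = self.make()
        f = site_frequencies(snp, "T")
        assert f[0] == pytest.approx(0.10)
        assert np.isnan(f[1])

    def test_major_minor_complementarity(self):
        snp = SnpRecord("2L", 5, "A", "T", [5, 20], [50, 40])
        total = site_frequencies(snp, "A") + site_frequencies(snp, "T")
        np.testing.assert_allclose(total, 1.0)

    def test_unknown_allele_rejected(self):
        with pytest.raises(ValueError):
            site_frequencies(self.make(), "G")


class TestWindowPi:
    def test_single_site_unbiased_heterozygosity(self):
        rec = site(50, [[5, 5, 0, 0, 0, 0]] + [[0] * 6] * 5)
        (w,) = window_pi([rec], window=10_000)
        assert w.pi == pytest.approx((10 / 9) * 0.5)
        assert w.n_sites == 1

    def test_monomorphic_window_zero(self):
        rec = site(50, [[9, 0, 0, 0, 0, 0]] + [[0] * 6] * 5)
        (w,) = window_pi([rec], window=1000)
        assert w.pi == 0.0

    def test_doubling_counts_shrinks_correction_only(self):
        r1 = site(50, [[5, 5, 0, 0, 0, 0]])
        r2 = site(50, [[10, 10, 0, 0, 0, 0]])
        (w1,) = window_pi([r1])
        (w2,) = window_pi([r2])
        assert w2.pi < w1.pi
        assert w2.pi == pytest.approx((20 / 19) * 0.5)

    def test_windows_tile_and_order_invariance(self):
        recs = [site(p, [[5, 5, 0, 0, 0, 0]]) for p in (100, 15_000, 25_000)]
        ws = list(window_pi(recs, window=10_000))
        assert [(w.window_start, w.window_end) for w in ws] == \
            [(0, 10_000), (10_000, 20_000), (20_000, 30_000)]
        ws_rev = list(window_pi(recs[::-1], window=10_000))
        assert [w.pi for w in ws] == [w.pi for w in ws_rev]


class TestHeterozygosityChange:
    def test_no_change_is_zero(self, design):
        from erps.snp_calling import SnpTable
        mc = np.full((4, design.n_populations), 10)
        cov = np.full_like(mc, 50)
        t = SnpTable(np.array(["2L", "2L", "3R", "3R"], dtype=object),
                     np.array([1, 2, 3, 4]), np.array(["A"] * 4, dtype=object),
                     np.array(["T"] * 4, dtype=object), mc, cov,
                     design.population_names)
        delta = heterozygosity_change(t, design, "B", "E")
        assert all(abs(v) < 1e-12 for v in delta.values())

    def test_hand_computed_drop(self, design):
        from erps.snp_calling import SnpTable
        npop = design.n_populations
        cov = np.full((1, npop), 100)
        mc = np.full((1, npop), 50)
        for i, _ in design.pops_at("E"):
            mc[0, i] = 10  # p drops 0.5 -> 0.1 in every E pool
        t = SnpTable(np.array(["2L"], dtype=object), np.array([1]),
                     np.array(["A"], dtype=object), np.array(["T"], dtype=object),
                     mc, cov, design.population_names)
        delta = heterozygosity_change(t, design, "B", "E")
        assert delta["2L"] == pytest.approx(2 * 0.1 * 0.9 - 2 * 0.5 * 0.5)
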