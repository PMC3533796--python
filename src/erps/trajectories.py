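"""Candidate SNP trajectories: shape classification, fixation, overlap, decay.

Once a scan has ranked SNPs, the selected allele at each candidate is
followed through every sequenced time point.  Two qualitative shapes are
distinguished: a *plateau* (rapid early rise, then little change — the
signature expected under balancing mechanisms such as overdominance) and a
*continuous* rise (the classic additive sweep-in-progress).  The default
thresholds are data-driven: the rise requirement from the candidates
themselves, the flatness tolerance from the drift envelope of a neutral
simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign
from .snp_calling import SnpTable

__all__ = [
    "CandidateSet",
    "top_candidates",
    "orient_selected_allele",
    "selected_freq_matrix",
    "trajectory_table",
    "interval_afc",
    "auto_thresholds",
    "classify_trajectories",
    "fixation_fraction",
    "candidate_overlap",
    "flanking_decay",
    "compare_trajectory_classes",
]


@dataclass
class CandidateSet:
    """Top-n SNPs of one contrast, ranked by ascending p-value."""

    contrast: str
    table: pd.DataFrame  # columns chrom, pos, statistic, p_value (sorted)

    @property
    def n(self) -> int:
        return len(self.table)

    def keys(self) -> set[tuple[str, int]]:
        return set(zip(self.table["chrom"], self.table["pos"]))


def top_candidates(scan: pd.DataFrame, n: int = 2000) -> CandidateSet:
    """The n most significant SNPs; ties broken by (chrom, pos)."""
    defined = scan.dropna(subset=["p_value"])
    if len(defined) < n:
        raise ValueError(f"scan has only {len(defined)} defined p-values, need {n}")
    ranked = defined.sort_values(["p_value", "chrom", "pos"], kind="mergesort").head(n)
    contrast = str(scan["contrast"].iloc[0]) if "contrast" in scan and len(scan) else ""
    return CandidateSet(contrast=contrast, table=ranked.reset_index(drop=True))


def orient_selected_allele(
    snps: SnpTable,
    design: ExperimentDesign,
    contrast: tuple[str, str],
) -> tuple[np.ndarray, np.ndarray]:
    """Which allele rose over the identification contrast, per SNP.

    Returns ``(is_minor, inconsistent)``: ``is_minor[i]`` is True when the
    minor allele's mean frequency change across replicates is positive
    (zero mean change also maps to the minor allele, flagged);
    ``inconsistent[i]`` marks SNPs whose replicates disagree in sign.
    """
    freqs = snps.minor_freqs()
    changes = []
    for i0, i1, _rep, _t in design.contrast_pairs(*contrast):
        changes.append(freqs[:, i1] - freqs[:, i0])
    delta = np.column_stack(changes)
    mean = np.nanmean(delta, axis=1)
    is_minor = mean >= 0
    signs = np.sign(np.where(np.isnan(delta), 0.0, delta))
    inconsistent = (signs.max(axis=1) > 0) & (signs.min(axis=1) < 0)
    inconsistent |= mean == 0
    return is_minor, inconsistent


def selected_freq_matrix(snps: SnpTable, is_minor: np.ndarray) -> np.ndarray:
    """Per-population frequency of the selected allele, shape (n, n_pops)."""
    f = snps.minor_freqs()
    return np.where(is_minor[:, None], f, 1.0 - f)


def trajectory_table(
    snps: SnpTable,
    design: ExperimentDesign,
    is_minor: np.ndarray,
) -> pd.DataFrame:
    """Long-format selected-allele trajectories.

    One row per (SNP, population): chrom, pos, replicate, timepoint,
    generation, freq.
    """
    sel = selected_freq_matrix(snps, is_minor)
    frames = []
    for j, pop in enumerate(design.populations):
        frames.append(pd.DataFrame({
            "chrom": snps.chrom, "pos": snps.pos,
            "replicate": pop.replicate, "timepoint": pop.timepoint,
            "generation": pop.generation, "freq": sel[:, j],
        }))
    return pd.concat(frames, ignore_index=True)


def _mean_freq_at(snps: SnpTable, design: ExperimentDesign, is_minor: np.ndarray,
                  timepoint: str) -> np.ndarray:
    sel = selected_freq_matrix(snps, is_minor)
    cols = [i for i, _ in design.pops_at(timepoint)]
    return np.nanmean(sel[:, cols], axis=1)


def interval_afc(
    snps: SnpTable,
    design: ExperimentDesign,
    is_minor: np.ndarray,
    t_a: str,
    t_b: str,
) -> tuple[np.ndarray, float]:
    """Selected-allele frequency change between two time points.

    Per SNP the replicate-wise changes are averaged (replicates covering
    both time points only); returns the per-SNP array and the median over
    SNPs.  The telescoping identity AFC(a->b) + AFC(b->c) = AFC(a->c)
    holds exactly per replicate and therefore for the replicate means.
    """
    sel = selected_freq_matrix(snps, is_minor)
    changes = []
    for i0, i1, _rep, _t in design.contrast_pairs(t_a, t_b):
        changes.append(sel[:, i1] - sel[:, i0])
    per_snp = np.nanmean(np.column_stack(changes), axis=1)
    return per_snp, float(np.nanmedian(per_snp))


def auto_thresholds(candidate_afc_rise: np.ndarray, null_afc_flat: np.ndarray) -> tuple[float, float]:
    """Data-driven classification thresholds.

    rise_min = median early-phase AFC among candidates; flat_max = 95th
    percentile of |late-phase AFC| among neutral-simulation SNPs (the
    drift envelope).
    """
    rise_min = float(np.nanpercentile(candidate_afc_rise, 50))
    flat_max = float(np.nanpercentile(np.abs(null_afc_flat), 95))
    return rise_min, flat_max


def classify_trajectories(
    afc_rise: np.ndarray,
    afc_late: np.ndarray,
    rise_min: float,
    flat_max: float,
) -> np.ndarray:
    """Label each trajectory plateau / continuous / other.

    plateau:    AFC(B->M) >= rise_min  and |AFC(M->E)| <= flat_max
    continuous: AFC(B->M) >= rise_min/2 and AFC(M->E) >= flat_max
    other:      anything else (including undefined AFCs)

    The labels partition the input: every SNP gets exactly one.
    """
    if rise_min <= 0 or flat_max <= 0:
        raise ValueError("thresholds must be positive")
    afc_rise = np.asarray(afc_rise, dtype=np.float64)
    afc_late = np.asarray(afc_late, dtype=np.float64)
    labels = np.full(afc_rise.shape, "other", dtype=object)
    plateau = (afc_rise >= rise_min) & (np.abs(afc_late) <= flat_max)
    continuous = ~plateau & (afc_rise >= rise_min / 2) & (afc_late >= flat_max)
    labels[continuous] = "continuous"
    labels[plateau] = "plateau"
    return labels


def fixation_fraction(
    freqs_at_t: np.ndarray,
    threshold: float = 0.99,
    strict: bool = False,
) -> float:
    """Fraction of candidates whose selected allele reached the threshold.

    ``freqs_at_t`` are replicate-mean selected-allele frequencies at the
    queried time point (pass per-replicate columns and reduce yourself for
    the per-replicate variant).  ``strict=True`` tests > threshold instead
    of >= (the ">0.90" style of report).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    f = np.asarray(freqs_at_t, dtype=np.float64)
    f = f[~np.isnan(f)]
    if f.size == 0:
        return float("nan")
    hit = f > threshold if strict else f >= threshold
    return float(hit.mean())


def candidate_overlap(set_a: CandidateSet | set, set_b: CandidateSet | set) -> tuple[int, float]:
    """Shared (chrom, pos) keys: count and fraction of the first set."""
    ka = set_a.keys() if isinstance(set_a, CandidateSet) else set(set_a)
    kb = set_b.keys() if isinstance(set_b, CandidateSet) else set(set_b)
    shared = len(ka & kb)
    return shared, shared / len(ka) if ka else 0.0


def flanking_decay(
    candidates: CandidateSet,
    all_positions: pd.DataFrame,
    afc: np.ndarray,
    bin_width: int = 100,
    span: int = 1000,
    control_offset: int = 500_000,
) -> pd.DataFrame:
    """Median AFC of non-candidate SNPs by distance from candidates.

    ``all_positions`` has columns chrom/pos aligned with ``afc`` (selected-
    or rising-allele frequency change, base to final generation).  SNPs
    within ``span`` of a candidate are stacked into ``bin_width`` distance
    bins (bin index floor(|distance| / width); candidates themselves are
    excluded).  A parallel curve uses position-adjusted control loci
    ``control_offset`` bp upstream of each candidate, so chromosome-scale
    heterogeneity in drift cancels.
    """
    if span < bin_width:
        raise ValueError("span must be >= bin_width")
    cand_keys = candidates.keys()
    n_bins = span // bin_width
    rows = []
    afc = np.asarray(afc, dtype=np.float64)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    chroms = all_positions["chrom"].to_numpy()
    poss = all_positions["pos"].to_numpy()
    for chrom in np.unique(chroms):
        sel = chroms == chrom
        order = np.argsort(poss[sel])
        by_chrom[str(chrom)] = (poss[sel][order], afc[sel][order])

    def collect(centers: list[tuple[str, int]]) -> list[list[float]]:
        bins: list[list[float]] = [[] for _ in range(n_bins)]
        for chrom, cpos in centers:
            if chrom not in by_chrom:
                continue
            pos_arr, afc_arr = by_chrom[chrom]
            lo = np.searchsorted(pos_arr, cpos - span)
            hi = np.searchsorted(pos_arr, cpos + span, side="right")
            for p, v in zip(pos_arr[lo:hi], afc_arr[lo:hi]):
                if (chrom, int(p)) in cand_keys or np.isnan(v):
                    continue
                d = abs(int(p) - cpos)
                if 0 < d <= span:
                    bins[min(d // bin_width, n_bins - 1)].append(v)
        return bins

    centers = [(c, int(p)) for c, p in zip(candidates.table["chrom"], candidates.table["pos"])]
    control_centers = [(c, p - control_offset) for c, p in centers if p - control_offset > 0]
    main = collect(centers)
    ctrl = collect(control_centers)
    for b in range(n_bins):
        rows.append({
            "bin_start": b * bin_width,
            "bin_end": (b + 1) * bin_width,
            "median_afc": float(np.median(main[b])) if main[b] else float("nan"),
            "n_snps": len(main[b]),
            "median_afc_control": float(np.median(ctrl[b])) if ctrl[b] else float("nan"),
            "n_control": len(ctrl[b]),
        })
    return pd.DataFrame(rows)


def compare_trajectory_classes(afc_late_a: np.ndarray, afc_late_b: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney comparison of late-phase AFC between two candidate sets.

    Stands in for a distribution-level test that the two candidate groups
    follow different dynamics; returns (U, p).
    """
    a = np.asarray(afc_late_a, dtype=np.float64)
    b = np.asarray(afc_late_b, dtype=np.float64)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(u), float(p)
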