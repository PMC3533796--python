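"""Temporal (moment-based) effective population size estimation.

Drift makes allele frequencies wander; the standardised variance of the
change between two samples t generations apart,

    F = sum_i (x_i - y_i)^2 / sum_i z_i (1 - z_i),   z = (x + y) / 2,

grows like t / (2 Ne) for a diploid population, plus a contribution from
the two sampling events.  Pool-Seq samples twice — first a pool of
individuals from the population, then reads from the pool — so the
effective allele-sample size per SNP is the harmonic composition
S = (n_pool * cov) / (n_pool + cov) of pool chromosomes and coverage.
The estimator (sampling plan II, written with S in allele units) is

    Ne = t / (2 * [F - 1/S0 - 1/S1]),

equivalent to the classic t / (2 * [F - 1/(2*S0') - 1/(2*S1')]) with S'
counted in diploid individuals.  An infinity sentinel is returned when the
sampling terms absorb all of F (no detectable drift).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ExperimentDesign
from .snp_calling import SnpTable

__all__ = [
    "NeEstimate",
    "subsample_snps",
    "temporal_f",
    "effective_sample_size",
    "estimate_ne",
    "estimate_ne_from_table",
]


@dataclass
class NeEstimate:
    f_mean: float
    ne: float            # math.inf when drift is below the sampling floor
    ci_low: float
    ci_high: float
    n_snps: int
    t: int


def subsample_snps(snps: SnpTable, n: int = 1000, rng: np.random.Generator | None = None) -> SnpTable:
    """Random SNP subset, stratified by chromosome proportionally to SNP counts.

    Largest-remainder allocation keeps every stratum within one SNP of its
    proportional share.
    """
    if rng is None:
        rng = np.random.default_rng()
    total = len(snps)
    if n > total:
        raise ValueError(f"requested {n} SNPs but only {total} available")
    chroms, counts = np.unique(snps.chrom.astype(str), return_counts=True)
    quotas = n * counts / total
    base = np.floor(quotas).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quotas - base))
    base[order[:rem]] += 1
    picked = []
    for chrom, take in zip(chroms, base):
        idx = np.nonzero(snps.chrom.astype(str) == chrom)[0]
        picked.append(rng.choice(idx, size=take, replace=False))
    return snps.subset(np.sort(np.concatenate(picked)))


def temporal_f(x, y) -> tuple[np.ndarray, float]:
    """Per-SNP Fc and the ratio-of-means mean F.

    Only SNPs polymorphic at the first time point (0 < x < 1) enter; the
    mean uses the ratio-of-means form sum (x-y)^2 / sum z(1-z), which is
    more stable at extreme frequencies than averaging per-SNP ratios.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    ok = (x > 0) & (x < 1) & ~np.isnan(y)
    if not ok.any():
        raise ValueError("no SNP polymorphic at the first time point")
    x, y = x[ok], y[ok]
    z = (x + y) / 2.0
    num = (x - y) ** 2
    den = z * (1.0 - z)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(den > 0, num / den, np.nan)
    return fc, float(num.sum() / den.sum())


def effective_sample_size(pool_chromosomes, coverage, mode: str = "two_stage"):
    """Effective allele-sample size of one Pool-Seq sampling event."""
    npool = np.asarray(pool_chromosomes, dtype=np.float64)
    cov = np.asarray(coverage, dtype=np.float64)
    if mode == "two_stage":
        return npool * cov / (npool + cov)
    if mode == "reads_only":
        return cov + np.zeros_like(npool)
    if mode == "pool_only":
        return npool + np.zeros_like(cov)
    raise ValueError(f"unknown sample-size mode {mode!r}")


def _point_ne(x, y, t, s0, s1):
    z = (x + y) / 2.0
    num = (x - y) ** 2
    den = z * (1.0 - z)
    f = num.sum() / den.sum()
    # one sampling event at effective allele-sample size S adds pq/S of
    # variance, i.e. 1/S to F (== the classic 1/(2S) with S in individuals)
    corr = np.mean(1.0 / s0) + np.mean(1.0 / s1)
    bracket = f - corr
    ne = t / (2.0 * bracket) if bracket > 0 else math.inf
    return f, ne


def estimate_ne(
    x,
    y,
    t: int,
    s0,
    s1,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci: float = 0.95,
) -> NeEstimate:
    """Sampling-corrected temporal Ne from paired frequencies.

    Parameters
    ----------
    x, y
        Allele frequencies at the two time points (per SNP).
    t
        Generations elapsed.
    s0, s1
        Effective allele-sample sizes per SNP (scalars broadcast).
    n_boot
        Bootstrap resamples over SNPs for the percentile interval.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    s0 = np.broadcast_to(np.asarray(s0, dtype=np.float64), x.shape).copy()
    s1 = np.broadcast_to(np.asarray(s1, dtype=np.float64), x.shape).copy()
    if (s0 < 1).any() or (s1 < 1).any():
        raise ValueError("sample sizes must be >= 1")
    ok = (x > 0) & (x < 1) & ~np.isnan(y)
    if not ok.any():
        raise ValueError("no SNP polymorphic at the first time point")
    x, y, s0, s1 = x[ok], y[ok], s0[ok], s1[ok]
    f, ne = _point_ne(x, y, t, s0, s1)

    lo = hi = ne
    if n_boot > 0:
        if rng is None:
            rng = np.random.default_rng()
        boots = np.empty(n_boot)
        m = x.size
        for b in range(n_boot):
            idx = rng.integers(0, m, size=m)
            _, boots[b] = _point_ne(x[idx], y[idx], t, s0[idx], s1[idx])
        alpha = (1.0 - ci) / 2.0
        lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return NeEstimate(f_mean=f, ne=ne, ci_low=float(lo), ci_high=float(hi),
                      n_snps=int(x.size), t=t)


def estimate_ne_from_table(
    snps: SnpTable,
    design: ExperimentDesign,
    pair: tuple[str, str] = ("B", "E"),
    n_snps: int | None = 1000,
    sample_size_mode: str = "two_stage",
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-replicate temporal Ne for one time-point pair.

    Frequencies come from the SNP table's read counts; the per-SNP
    effective sample sizes combine the pool (2 * pool_size chromosomes)
    with the observed coverages.  Returns one row per replicate plus the
    estimate pooled over replicates (all SNP-replicate pairs share one
    ratio-of-means F; only defined when all replicates share t).
    """
    if rng is None:
        rng = np.random.default_rng()
    table = subsample_snps(snps, n_snps, rng) if n_snps and n_snps < len(snps) else snps
    freqs = table.minor_freqs()
    npool = 2 * design.pool_size
    rows = []
    pooled_x, pooled_y, pooled_s0, pooled_s1, ts = [], [], [], [], []
    for i0, i1, rep, t in design.contrast_pairs(*pair):
        x, y = freqs[:, i0], freqs[:, i1]
        s0 = effective_sample_size(npool, table.coverages[:, i0], sample_size_mode)
        s1 = effective_sample_size(npool, table.coverages[:, i1], sample_size_mode)
        est = estimate_ne(x, y, t, s0, s1, n_boot=n_boot, rng=rng)
        rows.append({"replicate": rep, "t": t, "f": est.f_mean, "ne": est.ne,
                     "ci_low": est.ci_low, "ci_high": est.ci_high, "n_snps": est.n_snps})
        pooled_x.append(x); pooled_y.append(y); pooled_s0.append(s0); pooled_s1.append(s1)
        ts.append(t)
    if len(set(ts)) == 1 and len(ts) > 1:
        est = estimate_ne(np.concatenate(pooled_x), np.concatenate(pooled_y), ts[0],
                          np.concatenate(pooled_s0), np.concatenate(pooled_s1),
                          n_boot=n_boot, rng=rng)
        rows.append({"replicate": "pooled", "t": ts[0], "f": est.f_mean, "ne": est.ne,
                     "ci_low": est.ci_low, "ci_high": est.ci_high, "n_snps": est.n_snps})
    return pd.DataFrame(rows)
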