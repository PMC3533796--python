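"""Cochran-Mantel-Haenszel test for replicated allele-frequency change.

Each SNP contributes one 2 x 2 x k contingency stack: strata are the k
replicate populations, rows the two alleles (minor, major), columns the two
time points.  Under the null hypothesis that allele frequencies are equal
at both time points, the per-replicate odds ratios are 1 and the statistic
follows a chi-square distribution with one degree of freedom.  Note this
treats reads as the sampling unit: genetic drift between the time points is
real extra variance not captured by the table, which is why significance is
ultimately calibrated against the simulated drift null, not this asymptotic
distribution alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import ExperimentDesign
from .snp_calling import SnpTable

__all__ = ["cmh_statistic", "cmh_statistic_bulk", "cmh_scan"]


def cmh_statistic(tables, continuity_correction: bool = False) -> tuple[float, float]:
    """CMH statistic and p-value for one 2 x 2 x k stack.

    ``tables`` is array-like of shape ``(k, 2, 2)`` with rows (minor, major)
    and columns (time 0, time 1).  Strata with a zero row or column margin
    carry no information and are skipped; if all strata are degenerate the
    result is ``(nan, nan)``.
    """
    t = np.asarray(tables, dtype=np.float64)
    if t.ndim == 2:
        t = t[None]
    if t.ndim != 3 or t.shape[1:] != (2, 2):
        raise ValueError(f"expected (k, 2, 2) tables, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative cell count")
    stat, p = cmh_statistic_bulk(
        t[None, :, 0, 0], t[None, :, 0, 1], t[None, :, 1, 0], t[None, :, 1, 1],
        continuity_correction=continuity_correction,
    )
    return float(stat[0]), float(p[0])


def cmh_statistic_bulk(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    d: np.ndarray,
    continuity_correction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised CMH over many SNPs.

    Cell arrays have shape ``(n_snps, k)``: per stratum the table is
    ``[[a, b], [c, d]]`` = [[minor_t0, minor_t1], [major_t0, major_t1]].
    With row1 = a+b, row2 = c+d, col1 = a+c, col2 = b+d and n their total:

        statistic = (|sum_k (a_k - E_k)| - corr)^2 / sum_k V_k
        E_k = row1_k * col1_k / n_k
        V_k = row1_k * row2_k * col1_k * col2_k / (n_k^2 * (n_k - 1))

    Degenerate strata (any zero margin, or n < 2) are excluded per SNP;
    SNPs with no informative stratum get NaN statistic and p-value.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    c = np.asarray(c, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = row1 + row2
    valid = (row1 > 0) & (row2 > 0) & (col1 > 0) & (col2 > 0) & (n > 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        e = row1 * col1 / n
        v = row1 * row2 * col1 * col2 / (n * n * (n - 1.0))
    e = np.where(valid, e, 0.0)
    v = np.where(valid, v, 0.0)
    num = np.where(valid, a - e, 0.0).sum(axis=-1)
    den = v.sum(axis=-1)
    corr = 0.5 if continuity_correction else 0.0
    shifted = np.maximum(np.abs(num) - corr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = shifted * shifted / den
    stat = np.where(den > 0, stat, np.nan)
    p = np.where(np.isnan(stat), np.nan, stats.chi2.sf(stat, df=1))
    return stat, p


def cmh_scan(
    snps: SnpTable,
    design: ExperimentDesign,
    contrast: tuple[str, str],
    continuity_correction: bool = False,
) -> pd.DataFrame:
    """Run the CMH test at every SNP for one two-time-point contrast.

    Replicates with zero coverage at either time point are dropped from
    that SNP's stack; ``k_used`` records how many remained.  SNPs whose
    remaining strata are all degenerate (e.g. monomorphic everywhere)
    report NaN statistic/p.

    Returns a DataFrame with columns chrom, pos, contrast, statistic,
    p_value, k_used.
    """
    t0, t1 = contrast
    pairs = design.contrast_pairs(t0, t1)
    k = len(pairs)
    nsnp = len(snps)
    a = np.zeros((nsnp, k))
    b = np.zeros((nsnp, k))
    c = np.zeros((nsnp, k))
    d = np.zeros((nsnp, k))
    covered = np.zeros((nsnp, k), dtype=bool)
    for j, (i0, i1, _rep, _t) in enumerate(pairs):
        m0, m1 = snps.minor_counts[:, i0], snps.minor_counts[:, i1]
        c0, c1 = snps.coverages[:, i0], snps.coverages[:, i1]
        cov_ok = (c0 > 0) & (c1 > 0)
        covered[:, j] = cov_ok
        a[:, j] = np.where(cov_ok, m0, 0)
        b[:, j] = np.where(cov_ok, m1, 0)
        c[:, j] = np.where(cov_ok, c0 - m0, 0)
        d[:, j] = np.where(cov_ok, c1 - m1, 0)
    stat, p = cmh_statistic_bulk(a, b, c, d, continuity_correction)
    return pd.DataFrame(
        {
            "chrom": snps.chrom,
            "pos": snps.pos,
            "contrast": f"{t0}-{t1}",
            "statistic": stat,
            "p_value": p,
            "k_used": covered.sum(axis=1),
        }
    )
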