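"""Coverage-matched neutral Wright-Fisher null and empirical FDR machinery.

The null model: an idealised haploid population of constant size N evolves
by pure drift — each generation the allele count is a binomial draw with
parameters N and the current frequency.  A whole experiment is simulated by
drifting every base-population SNP independently through each replicate's
generations, then re-sampling reads binomially at the real (or modelled)
coverages, re-applying the SNP-calling filters, and running the same CMH
scan as on the real data.  Significance thresholds and false discovery
rates are then defined empirically from the simulated p-value distribution.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cmh import cmh_scan
from .design import ExperimentDesign
from .snp_calling import SnpTable, snp_filter_mask

__all__ = [
    "SimulationConfig",
    "FdrResult",
    "wf_trajectory",
    "sample_reads",
    "simulate_null_experiment",
    "empirical_threshold",
    "empirical_fdr",
    "fdr_top_n",
]


@dataclass
class SimulationConfig:
    """Parameters of a neutral whole-experiment simulation.

    ``ne`` is the haploid Wright-Fisher size N (the number of surviving
    offspring per generation).  By default N = Ne as estimated from the
    data; set ``diploid_scaling=True`` to use N = 2*Ne chromosomes instead.
    ``coverage_model`` is either ``("matched",)`` — reuse the observed
    per-SNP, per-population coverages — or ``("poisson", mean)`` /
    ``("uniform", lo, hi)``.
    ``resample_base=True`` bootstraps base SNPs jointly with their coverage
    rows, preserving the coverage-frequency correlation.
    """

    ne: float = 200.0
    seed: int = 0
    coverage_model: tuple = ("matched",)
    diploid_scaling: bool = False
    resample_base: bool = True
    min_minor_total: int = 10
    max_coverage: int = 500
    min_populations_detected: int = 2

    @property
    def n_haploid(self) -> int:
        n = int(round(2 * self.ne if self.diploid_scaling else self.ne))
        if n < 2:
            raise ValueError("haploid population size must be >= 2")
        return n

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FdrResult:
    """Empirical FDR at one p-value threshold.

    fdr = (n_sim_below * scale) / max(n_exp_below, 1) where scale is the
    ratio of experimental to simulated SNP counts; with no experimental
    SNP below the threshold the result is flagged.
    """

    threshold: float
    n_sim_below: int
    n_exp_below: int
    scale: float
    fdr: float
    flagged: bool = False


# ---------------------------------------------------------------------------
# elementary draws


def wf_trajectory(p0, N: int, t: int, rng: np.random.Generator):
    """Frequency after ``t`` binomial Wright-Fisher generations.

    ``p0`` may be a scalar or an array (loci evolve independently).
    Frequencies 0 and 1 are absorbing.  Scalar in, scalar out.
    """
    if N < 2:
        raise ValueError("N must be >= 2")
    if t < 0:
        raise ValueError("t must be >= 0")
    p = np.atleast_1d(np.asarray(p0, dtype=np.float64)).copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p0 must lie in [0, 1]")
    for _ in range(t):
        p = rng.binomial(N, p) / N
    return float(p[0]) if np.isscalar(p0) or np.ndim(p0) == 0 else p


def sample_reads(p, coverage, rng: np.random.Generator):
    """Binomial read draw(s): reads carrying the allele at frequency ``p``."""
    return rng.binomial(np.asarray(coverage), np.asarray(p, dtype=np.float64))


# ---------------------------------------------------------------------------
# whole-experiment simulation


def _draw_coverages(config: SimulationConfig, base: SnpTable, shape, rng) -> np.ndarray:
    model = config.coverage_model
    if model[0] == "matched":
        if base.coverages.shape != shape:
            raise ValueError("matched coverage model requires base coverages of matching shape")
        return base.coverages.copy()
    if model[0] == "poisson":
        return rng.poisson(float(model[1]), size=shape)
    if model[0] == "uniform":
        lo, hi = int(model[1]), int(model[2])
        if lo < 0:
            raise ValueError("coverage model yields negative coverage")
        return rng.integers(lo, hi + 1, size=shape)
    raise ValueError(f"unknown coverage model {model!r}")


def simulate_reads(
    p0: np.ndarray,
    design: ExperimentDesign,
    n_haploid: int,
    coverages: np.ndarray,
    rng: np.random.Generator,
    selection_update=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Drift + read sampling for every population of a design.

    Each replicate's lineage starts at ``p0`` (the base frequencies) and is
    advanced one binomial generation at a time; whenever a sequenced
    generation of that replicate is reached, reads are drawn at the given
    coverages.  Populations at the base time point sample reads directly
    from ``p0``.  An optional per-generation ``selection_update(p)`` hook
    (used by the synthetic-experiment generator) is applied before each
    drift draw.

    Returns ``(read_counts, true_freqs)`` with shape ``(n_loci, n_pops)``.
    """
    n_loci = len(p0)
    npop = design.n_populations
    reads = np.zeros((n_loci, npop), dtype=np.int64)
    truth = np.zeros((n_loci, npop), dtype=np.float64)
    for rep in design.replicates:
        cols = [(i, p) for i, p in enumerate(design.populations) if p.replicate == rep]
        cols.sort(key=lambda ip: ip[1].generation)
        p = p0.copy()
        gen = 0
        for i, pop in cols:
            while gen < pop.generation:
                if selection_update is not None:
                    p = selection_update(p)
                p = rng.binomial(n_haploid, p) / n_haploid
                gen += 1
            truth[:, i] = p
            reads[:, i] = rng.binomial(coverages[:, i], p)
    return reads, truth


def simulate_null_experiment(
    base_snps: SnpTable,
    design: ExperimentDesign,
    config: SimulationConfig,
    contrasts: Sequence[tuple[str, str]] = (("B", "M"),),
    rng: np.random.Generator | None = None,
) -> tuple[SnpTable, dict[str, pd.DataFrame]]:
    """Simulate the whole experiment under neutrality and scan it.

    Starting frequencies are the observed base-population minor-allele
    frequencies of ``base_snps`` (coverage-weighted across base pools),
    optionally bootstrapped SNP-wise together with their coverage rows.
    The simulated reads pass through the same quality filters and the same
    CMH scan as the experimental data.

    Returns the simulated SNP table and one scan DataFrame per contrast
    (keyed "B-M" etc.); every frame carries the seed and config digest in
    ``frame.attrs``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base_cols = [i for i, _ in design.pops_at("B")]
    mc = base_snps.minor_counts[:, base_cols].sum(axis=1)
    cov = base_snps.coverages[:, base_cols].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p0 = np.where(cov > 0, mc / cov, 0.0)

    table = base_snps
    if config.resample_base:
        idx = rng.integers(0, len(base_snps), size=len(base_snps))
        table = base_snps.subset(idx)
        p0 = p0[idx]

    shape = (len(table), design.n_populations)
    coverages = _draw_coverages(config, table, shape, rng)
    reads, _truth = simulate_reads(p0, design, config.n_haploid, coverages, rng)

    keep = snp_filter_mask(
        reads, coverages,
        min_minor_total=config.min_minor_total,
        max_coverage=config.max_coverage,
        min_populations_detected=config.min_populations_detected,
    )
    sim = SnpTable(table.chrom[keep], table.pos[keep], table.major[keep],
                   table.minor[keep], reads[keep], coverages[keep],
                   design.population_names)
    scans: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        frame = cmh_scan(sim, design, contrast)
        frame.attrs["seed"] = config.seed
        frame.attrs["config_digest"] = config.digest()
        scans[f"{contrast[0]}-{contrast[1]}"] = frame
    return sim, scans


# ---------------------------------------------------------------------------
# empirical thresholds and FDR


def empirical_threshold(sim_pvalues, top_fraction: float = 1e-5) -> float:
    """P-value at the top ``top_fraction`` of the simulated distribution.

    The threshold is the ceil(top_fraction * n)-th smallest simulated
    p-value, clamped to at least the 1st order statistic.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    p = np.asarray(sim_pvalues, dtype=np.float64)
    p = p[~np.isnan(p)]
    if p.size == 0:
        raise ValueError("no simulated p-values")
    k = max(1, int(np.ceil(top_fraction * p.size)))
    return float(np.partition(p, k - 1)[k - 1])


def empirical_fdr(exp_pvalues, sim_pvalues, threshold: float) -> FdrResult:
    """Drift-explained fraction of discoveries at a p-value cutoff.

    Counts p <= threshold (ties inclusive — conservative) in both sets;
    the simulated count is rescaled by |exp| / |sim| before division.
    """
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must lie in [0, 1]")
    e = np.asarray(exp_pvalues, dtype=np.float64)
    s = np.asarray(sim_pvalues, dtype=np.float64)
    e = e[~np.isnan(e)]
    s = s[~np.isnan(s)]
    if e.size == 0:
        return FdrResult(threshold, 0, 0, 0.0, float("nan"), flagged=True)
    n_sim = int((s <= threshold).sum())
    n_exp = int((e <= threshold).sum())
    scale = e.size / s.size
    fdr = (n_sim * scale) / max(n_exp, 1)
    return FdrResult(threshold, n_sim, n_exp, scale, fdr, flagged=(n_exp == 0))


def fdr_top_n(exp_pvalues, sim_pvalues, n: int = 2000) -> FdrResult:
    """Empirical FDR of the top-n experimental candidates.

    The threshold is the n-th smallest experimental p-value (the worst
    p among the candidates), then the FDR is computed as usual.
    """
    e = np.asarray(exp_pvalues, dtype=np.float64)
    e = e[~np.isnan(e)]
    if e.size < n:
        raise ValueError(f"need at least n={n} experimental p-values, have {e.size}")
    threshold = float(np.partition(e, n - 1)[n - 1])
    return empirical_fdr(e, sim_pvalues, threshold)
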