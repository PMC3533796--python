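"""Synthetic evolve-and-resequence experiments with known truth.

Generates a base population of unlinked biallelic SNPs with a neutral-like
site-frequency spectrum, evolves replicate populations by Wright-Fisher
drift with optional planted selection (additive or overdominant), samples
Pool-Seq reads at each sequenced time point, and emits sync files plus a
truth table for recovery tests.  With no planted loci and matching seeds
the output is exactly the neutral null of :mod:`erps.drift` — the two
share one simulation core.

The defaults mirror the fly experiment the pipeline targets: three
replicates, time points at generations 0 / 15 (or 23) / 37, drift at
Ne = 200, and per-SNP per-population coverage uniform in {30..64}.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .design import ExperimentDesign, default_design
from .drift import simulate_reads
from .snp_calling import SnpTable
from .sync_io import SyncRecord, write_sync

__all__ = [
    "SelectionModel",
    "SyntheticExperiment",
    "generate_base_frequencies",
    "selection_update",
    "generate_experiment",
]

_CHROMS = ("2L", "2R", "3L", "3R", "X")
_CHROM_WEIGHTS = (0.21, 0.19, 0.22, 0.25, 0.13)  # rough arm-size proportions
_SPACING = 100  # bp between simulated loci (unlinked regardless)


@dataclass
class SelectionModel:
    """Per-locus fitness scheme.

    additive:     w_AA = 1+s, w_Aa = 1+h*s, w_aa = 1   (A = tracked allele)
    overdominant: w_AA = 1-s1, w_Aa = 1, w_aa = 1-s2; the deterministic
                  equilibrium is p_hat = s2 / (s1 + s2).
    neutral:      identity.
    """

    mode: str = "neutral"
    s: float = 0.0
    h: float = 0.5
    s1: float = 0.0
    s2: float = 0.0
    p0: float | None = None  # fixed starting frequency (None: drawn from the SFS)

    def __post_init__(self) -> None:
        if self.mode not in ("neutral", "additive", "overdominant"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.mode == "neutral" and self.s != 0:
            raise ValueError("neutral mode forces s = 0")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not (0 <= self.h <= 1):
            raise ValueError("dominance h must lie in [0, 1]")
        if self.mode == "overdominant":
            if self.s1 >= 1 or self.s2 >= 1 or self.s1 < 0 or self.s2 < 0:
                raise ValueError("homozygote disadvantages must lie in [0, 1)")
            if self.s1 + self.s2 <= 0:
                raise ValueError("overdominant model needs s1 + s2 > 0")

    @property
    def equilibrium(self) -> float | None:
        if self.mode == "overdominant":
            return self.s2 / (self.s1 + self.s2)
        return None

    def fitnesses(self) -> tuple[float, float, float]:
        if self.mode == "additive":
            return 1.0 + self.s, 1.0 + self.h * self.s, 1.0
        if self.mode == "overdominant":
            return 1.0 - self.s1, 1.0, 1.0 - self.s2
        return 1.0, 1.0, 1.0


def selection_update(p, model: SelectionModel):
    """One deterministic generation of selection (diploid approximation).

    p' = p * (w_AA * p + w_Aa * q) / w_bar with q = 1-p and
    w_bar = w_AA p^2 + 2 w_Aa p q + w_aa q^2.  Applied before the
    stochastic drift draw; vectorises over arrays of p.
    """
    w_aa_, w_het, w_bb = model.fitnesses()
    if min(w_aa_, w_het, w_bb) <= 0:
        raise ValueError("fitnesses must be positive")
    if model.mode == "neutral":
        return p
    p = np.asarray(p, dtype=np.float64)
    q = 1.0 - p
    wbar = w_aa_ * p * p + 2.0 * w_het * p * q + w_bb * q * q
    out = p * (w_aa_ * p + w_het * q) / wbar
    return float(out) if out.ndim == 0 else out


def generate_base_frequencies(
    n_snps: int,
    sfs: str = "neutral",
    rng: np.random.Generator | None = None,
    sample_size: int = 200,
    beta_params: tuple[float, float] = (0.5, 0.5),
) -> np.ndarray:
    """Minor-allele frequencies with a realistic site-frequency spectrum.

    ``"neutral"`` draws allele counts i in 1..sample_size-1 with weight
    proportional to 1/i (the standing neutral spectrum in a sample), then
    folds i/sample_size into (0, 0.5].  ``"beta"`` draws from
    Beta(*beta_params*) folded the same way.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if sfs == "neutral":
        i = np.arange(1, sample_size)
        w = 1.0 / i
        counts = rng.choice(i, size=n_snps, p=w / w.sum())
        f = counts / sample_size
    elif sfs == "beta":
        f = rng.beta(*beta_params, size=n_snps)
        f = np.clip(f, 1.0 / (2 * sample_size), 1 - 1.0 / (2 * sample_size))
    else:
        raise ValueError(f"unknown sfs {sfs!r}")
    return np.minimum(f, 1.0 - f)


def standard_planting(
    n_additive: int = 100,
    n_overdominant: int = 50,
    s: float = 0.1,
    h: float = 0.5,
    p0_additive: tuple[float, float] = (0.05, 0.2),
    overdominant: tuple[float, float, float] = (0.45, 0.55, 0.3),
) -> list[tuple[int, SelectionModel]]:
    """The canonical planting scheme for recovery studies.

    Additive loci get s = 0.1 with starting frequencies spread evenly over
    ``p0_additive``; overdominant loci get (s1, s2, p0) = ``overdominant``
    — strong heterozygote advantage with equilibrium p_hat = s2/(s1+s2)
    = 0.55 reached just before generation 15, i.e. a rapid rise of ~0.25
    followed by a plateau.  Loci occupy the first indices of the base.
    """
    lo, hi = p0_additive
    planted = [(i, SelectionModel("additive", s=s, h=h,
                                  p0=lo + (hi - lo) * (i / max(n_additive - 1, 1))))
               for i in range(n_additive)]
    s1, s2, p0 = overdominant
    planted += [(n_additive + j, SelectionModel("overdominant", s1=s1, s2=s2, p0=p0))
                for j in range(n_overdominant)]
    return planted


@dataclass
class SyntheticExperiment:
    """A complete generated experiment: reads, truth, and provenance."""

    snps: SnpTable
    truth: pd.DataFrame          # one row per locus, incl. realised trajectories
    true_freqs: np.ndarray       # (n_loci, n_pops) tracked-allele frequencies
    design: ExperimentDesign
    seed: int

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.snps.write_tsv(outdir / "snps.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        self.design.to_yaml(outdir / "design.yaml")
        write_sync(self.to_sync_records(), outdir / "experiment.sync")

    def to_sync_records(self):
        """Render read counts as sync records (tracked allele = minor letter)."""
        base_j = {"A": 0, "T": 1, "C": 2, "G": 3}
        for i in range(len(self.snps)):
            counts = np.zeros((self.snps.n_populations, 6), dtype=np.int64)
            mi = base_j[self.snps.minor[i]]
            ma = base_j[self.snps.major[i]]
            counts[:, mi] = self.snps.minor_counts[i]
            counts[:, ma] = self.snps.coverages[i] - self.snps.minor_counts[i]
            yield SyncRecord(self.snps.chrom[i], int(self.snps.pos[i]),
                             self.snps.major[i], counts)


def _assign_positions(n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    arms = rng.choice(len(_CHROMS), size=n, p=np.asarray(_CHROM_WEIGHTS))
    chrom = np.array([_CHROMS[a] for a in arms], dtype=object)
    pos = np.zeros(n, dtype=np.int64)
    for a in range(len(_CHROMS)):
        sel = arms == a
        pos[sel] = (np.arange(sel.sum()) + 1) * _SPACING
    return chrom, pos


def generate_experiment(
    design: ExperimentDesign | None = None,
    n_snps: int = 10_000,
    ne: float = 200.0,
    planted: Sequence[tuple[int, SelectionModel]] = (),
    coverage: tuple = ("uniform", 30, 64),
    seed: int = 0,
    sfs: str = "neutral",
    diploid_scaling: bool = True,
) -> SyntheticExperiment:
    """Generate one full synthetic experiment.

    ``planted`` maps locus indices (into the generated base) to selection
    models; all other loci are neutral.  Selection acts deterministically
    on the tracked (initially minor) allele before each binomial drift
    draw.  Because the generator models a diploid population (its fitness
    schemes are diploid), drift defaults to 2*ne chromosomes for an
    effective size of ``ne`` individuals; ``diploid_scaling=False`` drifts
    ``ne`` haploid genomes instead, matching the null simulator's default.
    Coverages default to Uniform{30..64} per population and SNP.
    """
    if design is None:
        design = default_design()
    rng = np.random.default_rng(seed)
    p0 = generate_base_frequencies(n_snps, sfs=sfs, rng=rng)
    chrom, pos = _assign_positions(n_snps, rng)

    models: dict[int, SelectionModel] = {}
    for idx, model in planted:
        if not (0 <= idx < n_snps):
            raise ValueError(f"planted locus index {idx} outside 0..{n_snps - 1}")
        models[int(idx)] = model
        if model.p0 is not None:
            p0[int(idx)] = model.p0

    # group planted loci by identical model so the update stays vectorised
    groups: dict[tuple, list[int]] = {}
    for idx, model in models.items():
        key = (model.mode, model.s, model.h, model.s1, model.s2)
        groups.setdefault(key, []).append(idx)
    group_updates = []
    for key, idxs in groups.items():
        model = models[idxs[0]]
        if model.mode != "neutral":
            group_updates.append((np.array(sorted(idxs)), model))

    def update(p: np.ndarray) -> np.ndarray:
        if not group_updates:
            return p
        p = p.copy()
        for idxs, model in group_updates:
            p[idxs] = selection_update(p[idxs], model)
        return p

    npop = design.n_populations
    n_haploid = int(round(2 * ne if diploid_scaling else ne))
    if coverage[0] == "uniform":
        cov = rng.integers(int(coverage[1]), int(coverage[2]) + 1, size=(n_snps, npop))
    elif coverage[0] == "poisson":
        cov = rng.poisson(float(coverage[1]), size=(n_snps, npop))
    else:
        raise ValueError(f"unknown coverage model {coverage!r}")
    if (cov < 0).any():
        raise ValueError("coverage model yielded negative coverage")

    reads, truth_f = simulate_reads(p0, design, n_haploid, cov, rng,
                                    selection_update=update if group_updates else None)

    # allele letters: tracked allele is the site's minor letter at the base
    pair_choices = np.array([("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"),
                             ("C", "T"), ("G", "T")], dtype=object)
    pick = rng.integers(0, len(pair_choices), size=n_snps)
    flip = rng.integers(0, 2, size=n_snps).astype(bool)
    major = np.where(flip, pair_choices[pick, 1], pair_choices[pick, 0])
    minor = np.where(flip, pair_choices[pick, 0], pair_choices[pick, 1])

    snps = SnpTable(chrom, pos, major, minor, reads, cov, design.population_names)

    truth = pd.DataFrame({
        "chrom": chrom, "pos": pos,
        "mode": [models[i].mode if i in models else "neutral" for i in range(n_snps)],
        "s": [models[i].s if i in models else 0.0 for i in range(n_snps)],
        "h": [models[i].h if i in models else 0.5 for i in range(n_snps)],
        "s1": [models[i].s1 if i in models else 0.0 for i in range(n_snps)],
        "s2": [models[i].s2 if i in models else 0.0 for i in range(n_snps)],
        "p_hat": [models[i].equilibrium if i in models and models[i].mode == "overdominant"
                  else np.nan for i in range(n_snps)],
        "p0": p0,
    })
    for j, popn in enumerate(design.populations):
        truth[f"freq_{popn.name}"] = truth_f[:, j]
    return SyntheticExperiment(snps=snps, truth=truth, true_freqs=truth_f,
                               design=design, seed=seed)
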