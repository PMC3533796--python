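"""Biallelic SNP calling from pooled allele counts, plus diversity summaries.

A site becomes a SNP when it passes three quality filters: the minor allele
is seen in at least two populations, it is covered by at least 10 reads
summed over all populations, and no population's coverage exceeds 500.
These thresholds are exposed as parameters; coverage counts only the four
nucleotides (N and deletions are never part of a SNP's coverage).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .design import DesignError, ExperimentDesign
from .sync_io import SyncRecord

__all__ = [
    "SnpRecord",
    "SnpTable",
    "WindowDiversity",
    "call_snps",
    "call_snp_table",
    "snp_filter_mask",
    "site_frequencies",
    "window_pi",
    "heterozygosity_change",
]

_ACGT = np.array([0, 1, 2, 3])  # indices of A,T,C,G in the sync sextuple
_BASES = np.array(["A", "T", "C", "G"])


@dataclass
class SnpRecord:
    """A called biallelic SNP with per-population minor counts and coverages."""

    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    minor_counts: np.ndarray
    coverages: np.ndarray

    def __post_init__(self) -> None:
        self.minor_counts = np.asarray(self.minor_counts, dtype=np.int64)
        self.coverages = np.asarray(self.coverages, dtype=np.int64)
        if (self.minor_counts > self.coverages).any():
            raise ValueError(f"minor count exceeds coverage at {self.chrom}:{self.pos}")

    @property
    def minor_freqs(self) -> np.ndarray:
        """Per-population minor-allele frequency; NaN where coverage is 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.minor_counts / self.coverages
        return np.where(self.coverages > 0, f, np.nan)


def site_frequencies(snp: SnpRecord, allele: str) -> np.ndarray:
    """Per-population frequency of the major or minor allele (NaN = no coverage)."""
    if allele == snp.minor_allele:
        return snp.minor_freqs
    if allele == snp.major_allele:
        return 1.0 - snp.minor_freqs
    raise ValueError(f"allele {allele!r} is neither major nor minor at {snp.chrom}:{snp.pos}")


class SnpTable:
    """Column-oriented container for a set of called SNPs.

    Arrays: ``chrom``/``pos``/``major``/``minor`` of length ``n`` and
    integer matrices ``minor_counts``/``coverages`` of shape
    ``(n, n_populations)`` in the design's population order.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        pos: np.ndarray,
        major: np.ndarray,
        minor: np.ndarray,
        minor_counts: np.ndarray,
        coverages: np.ndarray,
        populations: Sequence[str],
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.major = np.asarray(major, dtype=object)
        self.minor = np.asarray(minor, dtype=object)
        self.minor_counts = np.asarray(minor_counts, dtype=np.int64)
        self.coverages = np.asarray(coverages, dtype=np.int64)
        self.populations = list(populations)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.major) == len(self.minor) == n):
            raise ValueError("column length mismatch")
        if self.minor_counts.shape != (n, len(self.populations)):
            raise ValueError("minor_counts shape mismatch")
        if self.coverages.shape != self.minor_counts.shape:
            raise ValueError("coverages shape mismatch")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def minor_freqs(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = self.minor_counts / self.coverages
        return np.where(self.coverages > 0, f, np.nan)

    def keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chrom.tolist(), self.pos.tolist()))

    def subset(self, mask_or_idx) -> "SnpTable":
        return SnpTable(
            self.chrom[mask_or_idx],
            self.pos[mask_or_idx],
            self.major[mask_or_idx],
            self.minor[mask_or_idx],
            self.minor_counts[mask_or_idx],
            self.coverages[mask_or_idx],
            self.populations,
        )

    def records(self) -> Iterator[SnpRecord]:
        for i in range(len(self)):
            yield SnpRecord(
                self.chrom[i], int(self.pos[i]), self.major[i], self.minor[i],
                self.minor_counts[i], self.coverages[i],
            )

    @classmethod
    def from_records(cls, records: Iterable[SnpRecord], populations: Sequence[str]) -> "SnpTable":
        recs = list(records)
        if not recs:
            npop = len(populations)
            z = np.zeros((0, npop), dtype=np.int64)
            return cls(np.array([]), np.array([], dtype=np.int64), np.array([]),
                       np.array([]), z, z.copy(), populations)
        return cls(
            np.array([r.chrom for r in recs], dtype=object),
            np.array([r.pos for r in recs], dtype=np.int64),
            np.array([r.major_allele for r in recs], dtype=object),
            np.array([r.minor_allele for r in recs], dtype=object),
            np.vstack([r.minor_counts for r in recs]),
            np.vstack([r.coverages for r in recs]),
            populations,
        )

    # -- TSV round trip ----------------------------------------------------

    def write_tsv(self, path: str | Path) -> None:
        cols = {"chrom": self.chrom, "pos": self.pos, "major": self.major, "minor": self.minor}
        for j, name in enumerate(self.populations):
            cols[name] = [f"{c}:{v}" for c, v in zip(self.minor_counts[:, j], self.coverages[:, j])]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SnpTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        pops = [c for c in df.columns if c not in ("chrom", "pos", "major", "minor")]
        n = len(df)
        mc = np.zeros((n, len(pops)), dtype=np.int64)
        cov = np.zeros_like(mc)
        for j, p in enumerate(pops):
            parts = df[p].str.split(":", expand=True).astype(np.int64)
            mc[:, j] = parts[0]
            cov[:, j] = parts[1]
        return cls(df["chrom"].to_numpy(dtype=object), df["pos"].to_numpy(),
                   df["major"].to_numpy(dtype=object), df["minor"].to_numpy(dtype=object),
                   mc, cov, pops)


# ---------------------------------------------------------------------------
# calling


def snp_filter_mask(
    minor_counts: np.ndarray,
    coverages: np.ndarray,
    min_minor_total: int = 10,
    max_coverage: int = 500,
    min_populations_detected: int = 2,
    coverage_mode: str = "per_population",
) -> np.ndarray:
    """Boolean mask of sites passing the three quality filters.

    The minor allele is re-identified from the summed counts (the lesser of
    the two allele totals), so the same function calibrates simulated reads
    exactly as it does real ones.
    """
    if min_minor_total < 1:
        raise ValueError("min_minor_total must be >= 1")
    minor_counts = np.asarray(minor_counts)
    coverages = np.asarray(coverages)
    other = coverages - minor_counts
    tracked_total = minor_counts.sum(axis=1)
    other_total = other.sum(axis=1)
    swap = tracked_total > other_total
    eff_minor = np.where(swap[:, None], other, minor_counts)
    minor_total = np.minimum(tracked_total, other_total)
    detected = (eff_minor > 0).sum(axis=1)
    ok = minor_total >= min_minor_total
    ok &= detected >= min_populations_detected
    if coverage_mode == "per_population":
        ok &= (coverages <= max_coverage).all(axis=1)
    elif coverage_mode == "total":
        ok &= coverages.sum(axis=1) <= max_coverage
    else:
        raise ValueError(f"unknown coverage_mode {coverage_mode!r}")
    return ok


def call_snp_table(
    records: Iterable[SyncRecord],
    populations: Sequence[str],
    min_minor_total: int = 10,
    max_coverage: int = 500,
    min_populations_detected: int = 2,
    noise_max: int = 2,
    coverage_mode: str = "per_population",
) -> SnpTable:
    """Call biallelic SNPs from sync records into a :class:`SnpTable`.

    Allele identity: counts are summed over all populations; the two
    top-ranked nucleotides define the site, with alphabetical tie-breaking
    (major = alphabetically first on a tie).  Alleles beyond the top two
    totalling at most ``noise_max`` reads are zeroed as sequencing noise;
    anything stronger disqualifies the site.
    """
    if min_minor_total < 1:
        raise ValueError("min_minor_total must be >= 1")
    recs = list(records)
    npop = len(populations)
    if not recs:
        return SnpTable.from_records([], populations)
    counts = np.stack([r.counts for r in recs])  # (n, npop, 6)
    if counts.shape[1] != npop:
        raise ValueError("record population count does not match design")
    acgt = counts[:, :, _ACGT]                    # (n, npop, 4)
    totals = acgt.sum(axis=1)                     # (n, 4)

    # rank alleles by summed count; stable alphabetical order among ties
    # (A,T,C,G sextuple order is not alphabetical, so sort explicitly)
    alpha = np.argsort(_BASES)                    # alphabetical index into ATCG order
    tot_alpha = totals[:, alpha]
    order = np.argsort(-tot_alpha, axis=1, kind="stable")  # per-site allele ranking
    ranked_idx = alpha[order]                     # back to sextuple ATCG indices
    ranked_tot = np.take_along_axis(totals, ranked_idx, axis=1)

    biallelic = ranked_tot[:, 1] > 0
    extra = ranked_tot[:, 2] + ranked_tot[:, 3]
    keep = biallelic & (extra <= noise_max)

    idx = np.nonzero(keep)[0]
    maj_i = ranked_idx[idx, 0]
    min_i = ranked_idx[idx, 1]
    ar = np.arange(len(idx))
    major_counts = acgt[idx][ar, :, maj_i]        # (m, npop)
    minor_counts = acgt[idx][ar, :, min_i]
    coverages = major_counts + minor_counts       # noise alleles zeroed

    ok = snp_filter_mask(minor_counts, coverages, min_minor_total, max_coverage,
                         min_populations_detected, coverage_mode)
    idx = idx[ok]
    return SnpTable(
        np.array([recs[i].chrom for i in idx], dtype=object),
        np.array([recs[i].pos for i in idx], dtype=np.int64),
        _BASES[maj_i[ok]].astype(object),
        _BASES[min_i[ok]].astype(object),
        minor_counts[ok],
        coverages[ok],
        populations,
    )


def call_snps(
    records: Iterable[SyncRecord],
    min_minor_total: int = 10,
    max_coverage: int = 500,
    min_populations_detected: int = 2,
    populations: Sequence[str] | None = None,
    **kw,
) -> Iterator[SnpRecord]:
    """Streaming wrapper around :func:`call_snp_table`."""
    recs = list(records)
    if populations is None:
        populations = [f"pop{i + 1}" for i in range(recs[0].n_populations)] if recs else []
    table = call_snp_table(recs, populations, min_minor_total, max_coverage,
                           min_populations_detected, **kw)
    yield from table.records()


# ---------------------------------------------------------------------------
# diversity summaries


@dataclass
class WindowDiversity:
    chrom: str
    window_start: int  # 0-based half-open, BED-like
    window_end: int
    pi: float
    n_sites: int


def window_pi(
    records: Iterable[SyncRecord],
    window: int = 10_000,
    population: int | None = None,
) -> Iterator[WindowDiversity]:
    """Nucleotide diversity per non-overlapping window.

    Per covered site the unbiased heterozygosity n/(n-1) * (1 - sum f_a^2)
    is computed from the nucleotide counts (summed over populations unless
    a single ``population`` index is given); a window's pi is the mean over
    its genotyped sites.  Windows with no covered site report pi = 0.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    per_chrom: dict[str, dict[int, list[float]]] = {}
    maxpos: dict[str, int] = {}
    for rec in records:
        acgt = rec.counts[:, _ACGT]
        cnt = acgt[population] if population is not None else acgt.sum(axis=0)
        n = int(cnt.sum())
        maxpos[rec.chrom] = max(maxpos.get(rec.chrom, 0), rec.pos)
        if n < 2:
            continue
        f = cnt / n
        h = (n / (n - 1)) * (1.0 - float((f * f).sum()))
        w = (rec.pos - 1) // window
        per_chrom.setdefault(rec.chrom, {}).setdefault(w, []).append(h)
    for chrom in sorted(maxpos):
        windows = per_chrom.get(chrom, {})
        n_windows = (maxpos[chrom] - 1) // window + 1
        for w in range(n_windows):
            hs = windows.get(w, [])
            pi = float(np.mean(hs)) if hs else 0.0
            yield WindowDiversity(chrom, w * window, (w + 1) * window, pi, len(hs))


def heterozygosity_change(
    snps: SnpTable,
    design: ExperimentDesign,
    t0: str,
    t1: str,
) -> dict[str, float]:
    """Per-chromosome mean change in expected heterozygosity 2p(1-p).

    Averages over SNPs and over the replicates sequenced at both time
    points; a negative value is a loss of heterozygosity between ``t0``
    and ``t1``.
    """
    pairs = design.contrast_pairs(t0, t1)
    freqs = snps.minor_freqs()
    deltas = []
    for i0, i1, _rep, _t in pairs:
        p0, p1 = freqs[:, i0], freqs[:, i1]
        deltas.append(2 * p1 * (1 - p1) - 2 * p0 * (1 - p0))
    delta = np.nanmean(np.column_stack(deltas), axis=1)
    out: dict[str, float] = {}
    for chrom in sorted(set(snps.chrom.tolist())):
        sel = snps.chrom == chrom
        out[chrom] = float(np.nanmean(delta[sel]))
    return out
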