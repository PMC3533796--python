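"""Allele-count I/O (sync format, pileup conversion) and positional masking.

The sync format is the tab-separated per-site count table used by Pool-Seq
toolkits: ``chrom  pos  ref  A:T:C:G:N:del`` with one colon-sextuple column
per sequenced population.  Coordinates are 1-based inclusive on disk; mask
intervals are kept 0-based half-open internally (BED convention), and the
two conversions happen only in this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

__all__ = [
    "SyncRecord",
    "SyncFormatError",
    "MaskSet",
    "read_sync",
    "write_sync",
    "pileup_to_counts",
    "build_indel_mask",
    "apply_masks",
]

#: column order of a sync count sextuple
ALLELE_ORDER = ("A", "T", "C", "G", "N", "del")
_BASE_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4, "*": 5}


class SyncFormatError(ValueError):
    """Malformed sync or pileup input; the message names the offending line."""


@dataclass
class SyncRecord:
    """One genomic site: per-population A/T/C/G/N/deletion counts.

    ``counts`` has shape ``(n_populations, 6)`` in :data:`ALLELE_ORDER`.
    """

    chrom: str
    pos: int
    ref: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 6:
            raise SyncFormatError(f"counts must be (n_pops, 6), got {self.counts.shape}")
        if self.pos < 1:
            raise SyncFormatError(f"position must be >= 1, got {self.pos}")
        if (self.counts < 0).any():
            raise SyncFormatError(f"negative count at {self.chrom}:{self.pos}")

    @property
    def n_populations(self) -> int:
        return self.counts.shape[0]

    def to_line(self) -> str:
        cols = [":".join(str(c) for c in row) for row in self.counts]
        return "\t".join([self.chrom, str(self.pos), self.ref] + cols)


# ---------------------------------------------------------------------------
# sync reading / writing


def _parse_sextuple(field: str, lineno: int) -> list[int]:
    parts = field.split(":")
    if len(parts) != 6:
        raise SyncFormatError(f"line {lineno}: expected A:T:C:G:N:del sextuple, got {field!r}")
    try:
        vals = [int(p) for p in parts]
    except ValueError:
        raise SyncFormatError(f"line {lineno}: non-integer count in {field!r}") from None
    if any(v < 0 for v in vals):
        raise SyncFormatError(f"line {lineno}: negative count in {field!r}")
    return vals


def read_sync(path: str | Path, n_populations: int) -> Iterator[SyncRecord]:
    """Stream :class:`SyncRecord` objects from a sync file.

    Raises :class:`SyncFormatError` (with the 1-based line number) on a
    wrong column count or a malformed count field.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_populations:
                raise SyncFormatError(
                    f"line {lineno}: expected {3 + n_populations} columns "
                    f"({n_populations} populations), found {len(fields)}"
                )
            try:
                pos = int(fields[1])
            except ValueError:
                raise SyncFormatError(f"line {lineno}: non-integer position {fields[1]!r}") from None
            counts = [_parse_sextuple(f, lineno) for f in fields[3:]]
            yield SyncRecord(chrom=fields[0], pos=pos, ref=fields[2], counts=np.array(counts))


def write_sync(records: Iterable[SyncRecord], path: str | Path) -> int:
    """Write records in sync format; returns the number of lines written."""
    n = 0
    with open(path, "w") as fh:
        for rec in records:
            fh.write(rec.to_line() + "\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# pileup conversion


def pileup_to_counts(pileup_line: str, min_base_quality: int = 20, quality_offset: int = 33) -> SyncRecord:
    """Convert one samtools text-pileup line into a :class:`SyncRecord`.

    Handles the pileup subset relevant to Pool-Seq counting: ``.``/``,``
    (reference match), explicit bases, ``^X`` read starts (the mapping
    quality character is consumed, nothing counted), ``$`` read ends,
    ``+N.../‑N...`` indel descriptors (skipped — indels are masked, not
    counted) and ``*`` deletion placeholders.  Bases whose phred quality is
    below ``min_base_quality`` are dropped.  Multiple populations (extra
    depth/base/quality column triplets) are supported.
    """
    fields = pileup_line.rstrip("\n").split("\t")
    if len(fields) < 6 or (len(fields) - 3) % 3 != 0:
        raise SyncFormatError("pileup line must have 3 + 3*n_populations columns")
    chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
    counts = []
    for i in range(3, len(fields), 3):
        bases, quals = fields[i + 1], fields[i + 2]
        counts.append(_count_bases(ref, bases, quals, min_base_quality, quality_offset))
    return SyncRecord(chrom=chrom, pos=int(pos_s), ref=ref, counts=np.array(counts))


def _count_bases(ref: str, bases: str, quals: str, min_bq: int, offset: int) -> list[int]:
    counts = [0] * 6
    qi = 0  # index into the quality string: one char per counted-or-dropped base
    ci = 0
    n = len(bases)
    while ci < n:
        ch = bases[ci]
        if ch == "^":
            ci += 2  # '^' plus mapping-quality char: a read start, no base
            continue
        if ch == "$":
            ci += 1
            continue
        if ch in "+-":
            ci += 1
            num = ""
            while ci < n and bases[ci].isdigit():
                num += bases[ci]
                ci += 1
            if not num:
                raise SyncFormatError("indel descriptor without a length")
            ci += int(num)  # the inserted/deleted bases carry no qualities
            continue
        # a quality-consuming symbol
        if qi >= len(quals):
            raise SyncFormatError("more bases than quality characters in pileup line")
        q = ord(quals[qi]) - offset
        qi += 1
        ci += 1
        if q < min_bq:
            continue
        if ch in ".,":
            base = ref
        else:
            base = ch.upper()
        idx = _BASE_INDEX.get(base if base != "*" else "*")
        if ch == "*":
            idx = 5
        if idx is None:
            continue  # symbols outside the supported subset are ignored
        counts[idx] += 1
    if qi != len(quals):
        raise SyncFormatError(
            f"base/quality length mismatch: consumed {qi} qualities of {len(quals)}"
        )
    return counts


# ---------------------------------------------------------------------------
# masking


class MaskSet:
    """Labelled genomic intervals (repeat / indel / excluded_region).

    Intervals are 0-based half-open and merged per (chromosome, label);
    membership queries are logarithmic via an interval tree.
    """

    LABELS = ("repeat", "indel", "excluded_region")

    def __init__(self) -> None:
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    def add(self, chrom: str, start: int, end: int, label: str) -> None:
        """Add a 0-based half-open interval."""
        if end <= start:
            return
        key = (chrom, label)
        tree = self._trees.setdefault(key, IntervalTree())
        tree[max(0, start):end] = label
        tree.merge_overlaps(strict=False)

    def add_positions(self, chrom: str, first: int, last: int, label: str) -> None:
        """Add a 1-based inclusive position range (sync/pileup convention)."""
        self.add(chrom, first - 1, last, label)

    def labels_at(self, chrom: str, pos: int) -> set[str]:
        """Labels covering a 1-based position."""
        point = pos - 1
        out = set()
        for (c, label), tree in self._trees.items():
            if c == chrom and tree.overlaps_point(point):
                out.add(label)
        return out

    def contains(self, chrom: str, pos: int) -> bool:
        return bool(self.labels_at(chrom, pos))

    def intervals(self, label: str | None = None) -> list[tuple[str, int, int, str]]:
        out = []
        for (chrom, lab), tree in sorted(self._trees.items()):
            if label is not None and lab != label:
                continue
            for iv in sorted(tree):
                out.append((chrom, iv.begin, iv.end, lab))
        return out

    def chromosomes(self) -> set[str]:
        return {c for c, _ in self._trees}

    def update(self, other: "MaskSet") -> "MaskSet":
        for chrom, start, end, label in other.intervals():
            self.add(chrom, start, end, label)
        return self

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    # -- constructors from standard formats --------------------------------

    @classmethod
    def from_bed(cls, path: str | Path, label: str = "excluded_region") -> "MaskSet":
        """BED is already 0-based half-open; no coordinate shift."""
        ms = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                ms.add(f[0], int(f[1]), int(f[2]), label)
        return ms

    @classmethod
    def from_gff(cls, path: str | Path, label: str = "repeat") -> "MaskSet":
        """GFF3 features (1-based inclusive) as mask intervals."""
        ms = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 5:
                    continue
                ms.add_positions(f[0], int(f[3]), int(f[4]), label)
        return ms


def build_indel_mask(
    indel_calls: Iterable[tuple[str, int, str | int, int]],
    flank: int = 5,
    min_reads: int = 2,
) -> MaskSet:
    """Mask indels plus ``flank`` nucleotides on both sides.

    ``indel_calls`` are ``(chrom, pos, population, supporting_reads)``
    tuples with 1-based positions.  An indel is masked if it is supported
    by at least ``min_reads`` reads in at least one population; the masked
    range is the closed positional range ``[pos - flank, pos + flank]``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    ms = MaskSet()
    for chrom, pos, _pop, reads in indel_calls:
        if reads >= min_reads:
            ms.add_positions(chrom, max(1, pos - flank), pos + flank, "indel")
    return ms


def apply_masks(
    records: Iterable[SyncRecord],
    masks: MaskSet,
    dropped: dict[str, int] | None = None,
) -> Iterator[SyncRecord]:
    """Drop records whose position falls inside any mask interval.

    Order is preserved.  Per-label drop counts are accumulated into
    ``dropped`` (if given) and logged when the stream is exhausted.
    Mask chromosomes absent from the data are simply never queried.
    """
    tally: dict[str, int] = dropped if dropped is not None else {}
    for rec in records:
        labels = masks.labels_at(rec.chrom, rec.pos)
        if labels:
            for lab in labels:
                tally[lab] = tally.get(lab, 0) + 1
            continue
        yield rec
    if tally:
        log.info("apply_masks dropped records: %s", dict(sorted(tally.items())))
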