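"""Experimental design: which sequenced pool belongs to which replicate and time point.

An evolve-and-resequence experiment maintains ``k`` replicate populations
founded from one base population and sequences pooled individuals at a few
time points.  Everything downstream (contingency-table pairing for the CMH
scan, generation counts for the drift null, trajectory assembly) is driven
by this mapping, so it lives in one validated object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["Population", "ExperimentDesign", "DesignError", "default_design"]


class DesignError(ValueError):
    """Raised when a design file or a contrast request is inconsistent."""


@dataclass(frozen=True)
class Population:
    """One sequenced pool: a (replicate, time point) cell of the design."""

    name: str
    replicate: int
    timepoint: str
    generation: int


@dataclass
class ExperimentDesign:
    """Replicated time-series design of a Pool-Seq selection experiment.

    Parameters
    ----------
    populations
        Ordered list of sequenced pools; the order defines the column order
        of every sync file and SNP table in the analysis.
    census_size
        Number of adults maintained per replicate each generation.
    pool_size
        Individuals pooled for sequencing (diploid, so ``2 * pool_size``
        chromosomes enter the pool).
    ne
        Effective population size used by the drift null (estimated from the
        data or supplied).
    """

    populations: list[Population]
    census_size: int = 1000
    pool_size: int = 500
    ne: float = 200.0

    def __post_init__(self) -> None:
        problems = self.validate()
        if problems:
            raise DesignError("; ".join(problems))

    # -- basic views -------------------------------------------------------

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    @property
    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    @property
    def replicates(self) -> list[int]:
        return sorted({p.replicate for p in self.populations})

    @property
    def timepoints(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p.timepoint not in seen:
                seen.append(p.timepoint)
        return seen

    def index(self, name: str) -> int:
        for i, p in enumerate(self.populations):
            if p.name == name:
                return i
        raise DesignError(f"unknown population {name!r}")

    def pops_at(self, timepoint: str) -> list[tuple[int, Population]]:
        """(column index, population) pairs at a time point, replicate order."""
        if timepoint not in self.timepoints:
            raise DesignError(f"unknown time point {timepoint!r}")
        hits = [(i, p) for i, p in enumerate(self.populations) if p.timepoint == timepoint]
        return sorted(hits, key=lambda ip: ip[1].replicate)

    def contrast_pairs(self, t0: str, t1: str) -> list[tuple[int, int, int, int]]:
        """Replicate-wise column pairing for a two-time-point contrast.

        Returns tuples ``(col_t0, col_t1, replicate, generations_elapsed)``
        for every replicate sequenced at both time points.
        """
        at0 = {p.replicate: (i, p) for i, p in self.pops_at(t0)}
        at1 = {p.replicate: (i, p) for i, p in self.pops_at(t1)}
        pairs = []
        for rep in sorted(set(at0) & set(at1)):
            i0, p0 = at0[rep]
            i1, p1 = at1[rep]
            pairs.append((i0, i1, rep, p1.generation - p0.generation))
        if not pairs:
            raise DesignError(f"no replicate sequenced at both {t0!r} and {t1!r}")
        return pairs

    # -- validation --------------------------------------------------------

    def validate(self) -> list[str]:
        """Return a list of violated invariants (empty when valid)."""
        problems: list[str] = []
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            problems.append("duplicate population names")
        for p in self.populations:
            if p.generation < 0:
                problems.append(f"negative generation for {p.name}")
        # within a replicate, listing order must not go back in time
        for rep in {p.replicate for p in self.populations}:
            gens = [p.generation for p in self.populations if p.replicate == rep]
            if any(b < a for a, b in zip(gens, gens[1:])):
                problems.append(f"decreasing generations within replicate {rep}")
        if self.census_size < 2:
            problems.append("census_size must be >= 2")
        if self.pool_size < 1:
            problems.append("pool_size must be >= 1")
        if self.ne <= 0:
            problems.append("ne must be positive")
        return problems

    def describe(self) -> str:
        """Human-readable report of the class structure (B/M/E and generations)."""
        lines = [
            f"{self.n_populations} populations, {len(self.replicates)} replicates, "
            f"census {self.census_size}, pool {self.pool_size}, Ne {self.ne:g}"
        ]
        for tp in self.timepoints:
            gens = {p.replicate: p.generation for _, p in self.pops_at(tp)}
            lines.append(f"  {tp}: generations {gens}")
        return "\n".join(lines)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "census_size": self.census_size,
            "pool_size": self.pool_size,
            "ne": self.ne,
            "populations": [
                {
                    "name": p.name,
                    "replicate": p.replicate,
                    "timepoint": p.timepoint,
                    "generation": p.generation,
                }
                for p in self.populations
            ],
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentDesign":
        try:
            pops = [
                Population(
                    name=str(e["name"]),
                    replicate=int(e["replicate"]),
                    timepoint=str(e["timepoint"]),
                    generation=int(e["generation"]),
                )
                for e in d["populations"]
            ]
        except (KeyError, TypeError, ValueError) as exc:
            raise DesignError(f"malformed design: {exc}") from exc
        return cls(
            populations=pops,
            census_size=int(d.get("census_size", 1000)),
            pool_size=int(d.get("pool_size", 500)),
            ne=float(d.get("ne", 200.0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentDesign":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def default_design(include_f27: bool = True) -> ExperimentDesign:
    """The canonical 3-replicate fly design.

    Three base pools (generation 0), the middle samples at generations
    15/15/23, the end samples at generation 37, and optionally one extra
    pool of replicate 1 at generation 27.
    """
    pops = [
        Population("B1", 1, "B", 0),
        Population("B2", 2, "B", 0),
        Population("B3", 3, "B", 0),
        Population("M1", 1, "M", 15),
        Population("M2", 2, "M", 15),
        Population("M3", 3, "M", 23),
    ]
    if include_f27:
        pops.append(Population("F27_1", 1, "F27", 27))
    pops += [
        Population("E1", 1, "E", 37),
        Population("E2", 2, "E", 37),
        Population("E3", 3, "E", 37),
    ]
    return ExperimentDesign(populations=pops)
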