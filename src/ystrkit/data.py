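"""Haplotype and population data model.

A :class:`YHaplotype` is one male donor's allele vector over a panel;
:class:`PopulationSample` groups donors sharing a population label;
:class:`Dataset` is a panel plus populations. The duplicated locus DYS385
is always stored as an ascending-sorted pair, so two donors match iff
their 17 reported values match regardless of input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import ValidationError
from .panel import LocusDef, format_allele, reported_columns

__all__ = ["YHaplotype", "PopulationSample", "Dataset", "haplotype_key"]

AlleleValue = float | tuple[float, float]


@dataclass
class YHaplotype:
    """One donor: sample ID, population label, locus -> allele value(s).

    Single-copy loci map to a float; DYS385 maps to an ascending pair.
    Loci absent from ``alleles`` are missing calls.
    """

    sample_id: str
    population_id: str
    alleles: dict[str, AlleleValue]

    def __post_init__(self) -> None:
        for name, val in self.alleles.items():
            if isinstance(val, tuple):
                if len(val) != 2:
                    raise ValidationError(f"{self.sample_id}/{name}: pair expected")
                self.alleles[name] = (min(val), max(val))

    def is_complete(self, panel: Sequence[LocusDef]) -> bool:
        """True iff every panel locus has a call of the right copy number."""
        for loc in panel:
            val = self.alleles.get(loc.name)
            if val is None:
                return False
            if loc.copies == 2 and not isinstance(val, tuple):
                return False
        return True

    def values_for(self, locus: LocusDef) -> tuple[float, ...]:
        """Allele value(s) at a locus as a tuple; () if missing."""
        val = self.alleles.get(locus.name)
        if val is None:
            return ()
        return val if isinstance(val, tuple) else (val,)

    def column_values(self, panel: Sequence[LocusDef]) -> list[float | None]:
        """Values aligned to ``reported_columns(panel)``; None for missing."""
        out: list[float | None] = []
        for loc in panel:
            vals = self.values_for(loc)
            if not vals:
                out.extend([None] * loc.copies)
            else:
                out.extend(vals)
        return out

    def out_of_range(self, panel: Sequence[LocusDef]) -> list[str]:
        """Names of loci with a call outside the panel's allele bounds."""
        bad = []
        for loc in panel:
            if any(not loc.in_range(v) for v in self.values_for(loc)):
                bad.append(loc.name)
        return bad


@dataclass
class PopulationSample:
    """All donors sharing one population label, plus free-form metadata."""

    population_id: str
    members: list[YHaplotype]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"population {self.population_id!r} is empty")
        for h in self.members:
            if h.population_id != self.population_id:
                raise ValidationError(
                    f"{h.sample_id}: population {h.population_id!r} does not "
                    f"match sample {self.population_id!r}"
                )

    @property
    def n(self) -> int:
        return len(self.members)


@dataclass
class Dataset:
    """A locus panel plus one or more population samples."""

    panel: tuple[LocusDef, ...]
    populations: list[PopulationSample]

    def __post_init__(self) -> None:
        self.panel = tuple(self.panel)
        ids = [p.population_id for p in self.populations]
        if len(set(ids)) != len(ids):
            raise ValidationError("population_ids must be unique")
        seen: set[str] = set()
        for h in self.all_members():
            if h.sample_id in seen:
                raise ValidationError(f"duplicate sample_id {h.sample_id!r}")
            seen.add(h.sample_id)

    @property
    def N(self) -> int:
        return sum(p.n for p in self.populations)

    @property
    def population_ids(self) -> list[str]:
        return [p.population_id for p in self.populations]

    def all_members(self):
        for pop in self.populations:
            yield from pop.members

    def population(self, population_id: str) -> PopulationSample:
        for pop in self.populations:
            if pop.population_id == population_id:
                return pop
        raise KeyError(population_id)

    def subset(self, population_ids: Sequence[str]) -> "Dataset":
        return Dataset(self.panel, [self.population(p) for p in population_ids])


def haplotype_key(h: YHaplotype, panel: Sequence[LocusDef]) -> str:
    """Canonical string identity of a complete haplotype.

    Fixed panel order, DYS385 ascending, microvariants rendered exactly;
    two haplotypes share a key iff all 17 reported values are equal.
    """
    if not h.is_complete(panel):
        raise ValidationError(f"{h.sample_id}: incomplete haplotype has no key")
    parts = []
    for loc in panel:
        parts.extend(format_allele(v) for v in h.values_for(loc))
    return "|".join(parts)


def haplotype_counts(
    members: Sequence[YHaplotype], panel: Sequence[LocusDef]
) -> Mapping[str, int]:
    """Key -> multiplicity over the complete haplotypes in ``members``."""
    counts: dict[str, int] = {}
    for h in members:
        if h.is_complete(panel):
            k = haplotype_key(h, panel)
            counts[k] = counts.get(k, 0) + 1
    return counts
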