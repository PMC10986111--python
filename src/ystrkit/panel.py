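"""Y-STR locus panel definitions.

A panel is an ordered tuple of :class:`LocusDef`. The built-in default is
the 17-column Yfiler panel (16 loci; the duplicated locus DYS385 reports
two unordered allele calls per donor, conventionally split into DYS385a
and DYS385b after ascending sort). Allele values are repeat counts;
microvariant alleles carry exact decimal fractional parts (e.g. 13.2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import yaml

from .errors import ConfigError, ValidationError

__all__ = [
    "LocusDef",
    "YFILER_PANEL",
    "reported_columns",
    "locus_for_column",
    "format_allele",
    "parse_allele",
    "load_panel",
    "save_panel",
]


@dataclass(frozen=True)
class LocusDef:
    """One Y-STR locus: name, admissible repeat-count range, copy number.

    ``copies`` is the number of allele calls reported per donor: 2 for the
    duplicated DYS385, 1 for every other Yfiler locus.
    """

    name: str
    allele_min: float
    allele_max: float
    copies: int = 1

    def __post_init__(self) -> None:
        if not self.allele_min < self.allele_max:
            raise ValidationError(
                f"{self.name}: allele_min must be < allele_max "
                f"({self.allele_min} vs {self.allele_max})"
            )
        if self.copies not in (1, 2):
            raise ValidationError(f"{self.name}: copies must be 1 or 2")

    def in_range(self, allele: float) -> bool:
        return self.allele_min <= allele <= self.allele_max

    @property
    def columns(self) -> tuple[str, ...]:
        """Reported column name(s): 'DYS385' -> ('DYS385a', 'DYS385b')."""
        if self.copies == 2:
            return (self.name + "a", self.name + "b")
        return (self.name,)


# Yfiler kit panel: 16 loci, 17 reported columns. Repeat-count ranges follow
# the kit's certified allele ladders. (The kit's own documentation lists
# DYS456 both first and last; it is of course a single locus.)
YFILER_PANEL: tuple[LocusDef, ...] = (
    LocusDef("DYS456", 13, 18),
    LocusDef("DYS389I", 9, 17),
    LocusDef("DYS390", 17, 28),
    LocusDef("DYS389II", 23, 34),
    LocusDef("DYS458", 14, 20),
    LocusDef("DYS19", 10, 19),
    LocusDef("DYS385", 7, 25, copies=2),
    LocusDef("DYS393", 8, 16),
    LocusDef("DYS391", 6, 14),
    LocusDef("DYS439", 8, 15),
    LocusDef("DYS635", 20, 26),
    LocusDef("DYS392", 7, 18),
    LocusDef("YGATAH4", 8, 13),
    LocusDef("DYS437", 13, 17),
    LocusDef("DYS438", 8, 13),
    LocusDef("DYS448", 17, 27),
)


def _validate_panel(panel: Sequence[LocusDef]) -> None:
    names = [loc.name for loc in panel]
    if len(set(names)) != len(names):
        raise ValidationError("panel locus names must be unique")


def reported_columns(panel: Sequence[LocusDef]) -> list[str]:
    """Flat ordered list of reported allele columns (DYS385 -> a, b)."""
    cols: list[str] = []
    for loc in panel:
        cols.extend(loc.columns)
    return cols


def locus_for_column(panel: Sequence[LocusDef], column: str) -> LocusDef:
    for loc in panel:
        if column in loc.columns:
            return loc
    raise KeyError(column)


def format_allele(value: float) -> str:
    """Canonical text form: integers bare, microvariants with one decimal."""
    if value == int(value):
        return str(int(value))
    return f"{value:.1f}"


def parse_allele(text: str) -> float:
    """Parse a repeat-count allele; raises ValueError on garbage."""
    value = float(text)
    if value < 0:
        raise ValueError(f"negative allele {text!r}")
    return value


def load_panel(path) -> tuple[LocusDef, ...]:
    """Read a panel from a small YAML file.

    Format: an ordered mapping ``name: {min: .., max: .., copies: ..}``
    (``copies`` optional, default 1).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or not raw:
        raise ConfigError(f"panel file {path}: expected a non-empty mapping")
    panel = []
    for name, spec in raw.items():
        try:
            panel.append(
                LocusDef(
                    str(name),
                    float(spec["min"]),
                    float(spec["max"]),
                    int(spec.get("copies", 1)),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"panel file {path}: bad entry {name!r}: {exc}") from exc
    _validate_panel(panel)
    return tuple(panel)


def save_panel(panel: Iterable[LocusDef], path) -> None:
    data = {
        loc.name: {"min": loc.allele_min, "max": loc.allele_max, "copies": loc.copies}
        for loc in panel
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
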