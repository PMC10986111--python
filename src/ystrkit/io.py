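"""Reading and writing tabular haplotype data.

Accepted layout: delimited text (TSV or CSV, auto-detected by extension,
UTF-8) with a header row naming ``SampleID``, ``Population`` and the
panel's allele columns. DYS385 may arrive either as one combined column
``DYS385`` holding a comma pair (``"14,11"``) or as the split columns
``DYS385a``/``DYS385b``; output always uses the split form, pair sorted
ascending. Microvariant alleles round-trip exactly (13.2 stays 13.2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .data import Dataset, PopulationSample, YHaplotype
from .errors import FormatError, ValidationError
from .panel import LocusDef, YFILER_PANEL, format_allele, parse_allele

__all__ = ["read_haplotype_table", "write_haplotype_table", "ReadReport"]

log = logging.getLogger(__name__)

SAMPLE_COL = "SampleID"
POP_COL = "Population"


@dataclass
class ReadReport:
    """Bookkeeping from one read: every input row is accounted for."""

    n_rows: int = 0
    n_valid: int = 0
    skipped: list[tuple[str, str]] = field(default_factory=list)  # (sample, why)
    incomplete: list[str] = field(default_factory=list)
    out_of_range: list[tuple[str, str]] = field(default_factory=list)  # (sample, locus)


def _sep_for(path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


def _cell(row, col) -> str:
    val = row.get(col)
    if val is None or (isinstance(val, float) and pd.isna(val)):
        return ""
    return str(val).strip()


def _parse_row(
    row: dict, panel: Sequence[LocusDef], combined_385: bool
) -> tuple[dict, list[str]]:
    """Return (alleles mapping, list of unparseable column names)."""
    alleles: dict = {}
    bad: list[str] = []
    for loc in panel:
        if loc.copies == 2:
            if combined_385:
                raw = _cell(row, loc.name)
                if not raw:
                    continue
                parts = [p for p in raw.replace(";", ",").split(",") if p.strip()]
                if len(parts) != 2:
                    bad.append(loc.name)
                    continue
                try:
                    pair = (parse_allele(parts[0]), parse_allele(parts[1]))
                except ValueError:
                    bad.append(loc.name)
                    continue
            else:
                a, b = (_cell(row, c) for c in loc.columns)
                if not a and not b:
                    continue
                if not a or not b:
                    bad.append(loc.name)
                    continue
                try:
                    pair = (parse_allele(a), parse_allele(b))
                except ValueError:
                    bad.append(loc.name)
                    continue
            alleles[loc.name] = (min(pair), max(pair))
        else:
            raw = _cell(row, loc.name)
            if not raw:
                continue
            try:
                alleles[loc.name] = parse_allele(raw)
            except ValueError:
                bad.append(loc.name)
    return alleles, bad


def read_haplotype_table(
    path,
    panel: Sequence[LocusDef] = YFILER_PANEL,
    *,
    strict: bool = False,
) -> tuple[Dataset, ReadReport]:
    """Read a haplotype table into a validated :class:`Dataset`.

    Rows with unparseable allele cells are skipped (or, under
    ``strict=True``, abort the read); rows with missing calls are kept as
    incomplete. Out-of-range alleles are kept but flagged in the report —
    they never pass silently.
    """
    sep = _sep_for(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if df.empty and df.columns.empty:
        raise FormatError(f"{path}: empty file")

    cols = set(df.columns)
    for required in (SAMPLE_COL, POP_COL):
        if required not in cols:
            raise FormatError(f"{path}: missing required column {required!r}")
    combined_385 = False
    for loc in panel:
        if loc.copies == 2:
            if loc.name in cols:
                combined_385 = True
            elif not all(c in cols for c in loc.columns):
                raise FormatError(
                    f"{path}: missing required column {loc.columns[0]!r} "
                    f"(or combined {loc.name!r})"
                )
        elif loc.name not in cols:
            raise FormatError(f"{path}: missing required column {loc.name!r}")

    report = ReadReport(n_rows=len(df))
    by_pop: dict[str, list[YHaplotype]] = {}
    order: list[str] = []
    for _, row in df.iterrows():
        rec = row.to_dict()
        sample = _cell(rec, SAMPLE_COL)
        popid = _cell(rec, POP_COL)
        if not sample or not popid:
            if strict:
                raise FormatError(f"{path}: row with empty SampleID/Population")
            report.skipped.append((sample or "<blank>", "empty SampleID/Population"))
            continue
        alleles, bad = _parse_row(rec, panel, combined_385)
        if bad:
            msg = f"unparseable allele(s) at {', '.join(bad)}"
            if strict:
                raise FormatError(f"{path}: sample {sample!r}: {msg}")
            report.skipped.append((sample, msg))
            log.warning("skipping %s: %s", sample, msg)
            continue
        h = YHaplotype(sample, popid, alleles)
        if not h.is_complete(panel):
            report.incomplete.append(sample)
        for locus in h.out_of_range(panel):
            report.out_of_range.append((sample, locus))
            log.warning("%s: allele out of panel range at %s", sample, locus)
        if popid not in by_pop:
            by_pop[popid] = []
            order.append(popid)
        by_pop[popid].append(h)
        report.n_valid += 1

    if not by_pop:
        raise FormatError(f"{path}: no usable haplotype rows")
    try:
        ds = Dataset(
            tuple(panel),
            [PopulationSample(p, by_pop[p]) for p in order],
        )
    except ValidationError:
        raise
    return ds, report


def write_haplotype_table(ds: Dataset, path) -> None:
    """Write a Dataset back to TSV/CSV (split DYS385a/DYS385b columns).

    Guarantees ``read(write(ds))`` equality field-for-field, including
    microvariant decimals.
    """
    if not ds.populations:
        raise ValidationError("refusing to write a dataset with no populations")
    from .panel import reported_columns

    cols = reported_columns(ds.panel)
    rows = []
    for h in ds.all_members():
        vals = h.column_values(ds.panel)
        rows.append(
            [h.sample_id, h.population_id]
            + ["" if v is None else format_allele(v) for v in vals]
        )
    df = pd.DataFrame(rows, columns=[SAMPLE_COL, POP_COL] + cols)
    df.to_csv(path, sep=_sep_for(path), index=False)


def read_matrix_tsv(path) -> pd.DataFrame:
    """Read a square labelled matrix (e.g. an FST matrix) from TSV."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: matrix row and column labels differ")
    return df


def write_matrix_tsv(df: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep=_sep_for(path), float_format=float_format)
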