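"""Diversity statistics for Y-STR haplotype data.

All estimators are Nei's unbiased gene diversity

    GD = n/(n-1) * (1 - sum_i p_i^2)

applied either per reported allele column (gene diversity, GD) or to
whole-haplotype frequencies (haplotype diversity, HD). Derived forensic
quantities: discrimination capacity DC = h/n (distinct haplotypes over
sample size) and haplotype match probability HMP = 1 - HD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import Dataset, PopulationSample, YHaplotype, haplotype_counts
from .errors import DiversityError, ValidationError
from .panel import LocusDef, locus_for_column, reported_columns

__all__ = [
    "gene_diversity",
    "haplotype_diversity",
    "discrimination_capacity",
    "match_probability",
    "allele_frequencies",
    "summarize",
    "gd_matrix",
    "DiversitySummary",
    "POOLED_SCOPE",
]

log = logging.getLogger(__name__)

POOLED_SCOPE = "ALL"

# Printed precision used by report tables; full precision kept internally.
ROUND_HD = 5
ROUND_DC = 3
ROUND_GD = 3
ROUND_HMP = 4


def gene_diversity(allele_counts: Mapping) -> float:
    """Nei's unbiased gene diversity from an allele -> count mapping.

    Requires n = sum(counts) >= 2; returns a value in [0, 1], zero iff
    monomorphic.
    """
    counts = np.asarray(list(allele_counts.values()), dtype=float)
    if np.any(counts < 0):
        raise ValidationError("negative allele count")
    n = counts.sum()
    if n < 2:
        raise DiversityError(f"gene diversity undefined for n={int(n)} < 2")
    # (n/(n-1))(1 - sum p^2) rearranged to (n^2 - sum c^2)/(n(n-1)): with
    # integer counts both numerator and denominator are exact in floats, so
    # the all-distinct case yields exactly 1.0 and monomorphic exactly 0.0.
    gd = (n * n - float(np.sum(counts * counts))) / (n * (n - 1.0))
    return min(max(gd, 0.0), 1.0)


def _complete_members(members: Sequence[YHaplotype], panel) -> list[YHaplotype]:
    return [h for h in members if h.is_complete(panel)]


def _members_of(data: Dataset | PopulationSample) -> Sequence[YHaplotype]:
    if isinstance(data, Dataset):
        return list(data.all_members())
    return data.members


def haplotype_diversity(data: Dataset | PopulationSample, panel=None) -> float:
    """Nei diversity of whole-haplotype frequencies (complete donors only).

    Equals exactly 1 when every haplotype is distinct, for any n, since
    (n/(n-1)) * (1 - n * (1/n)^2) = 1.
    """
    panel = panel if panel is not None else _panel_of(data)
    counts = haplotype_counts(_members_of(data), panel)
    n = sum(counts.values())
    if n < 2:
        raise DiversityError(f"haplotype diversity undefined for n={n} < 2")
    return gene_diversity(counts)


def discrimination_capacity(data: Dataset | PopulationSample, panel=None) -> float:
    """Distinct haplotypes / complete sample size, in (0, 1]."""
    panel = panel if panel is not None else _panel_of(data)
    counts = haplotype_counts(_members_of(data), panel)
    n = sum(counts.values())
    if n < 1:
        raise DiversityError("discrimination capacity undefined: no complete haplotypes")
    return len(counts) / n


def match_probability(hd: float) -> float:
    """HMP = 1 - HD; the chance two random males share a haplotype."""
    if not 0.0 <= hd <= 1.0:
        raise ValidationError(f"HD must lie in [0, 1], got {hd}")
    return 1.0 - hd


def _panel_of(data: Dataset | PopulationSample):
    if isinstance(data, Dataset):
        return data.panel
    raise ValidationError("panel required when summarising a bare PopulationSample")


def allele_frequencies(
    members: Sequence[YHaplotype],
    panel: Sequence[LocusDef],
    *,
    combine_dys385: bool = False,
) -> dict[str, dict[float, float]]:
    """Per reported column, allele -> relative frequency over non-missing calls.

    By default the DYS385 pair is split into two columns, 'a' the smaller
    allele after ascending sort. With ``combine_dys385=True`` the two gene
    copies are pooled into one 2n-copy frequency spectrum per donor pair.
    """
    counts = allele_count_table(members, panel, combine_dys385=combine_dys385)
    freqs: dict[str, dict[float, float]] = {}
    for col, cnt in counts.items():
        tot = sum(cnt.values())
        freqs[col] = {a: c / tot for a, c in cnt.items()} if tot else {}
    return freqs


def allele_count_table(
    members: Sequence[YHaplotype],
    panel: Sequence[LocusDef],
    *,
    combine_dys385: bool = False,
) -> dict[str, dict[float, int]]:
    """Per reported column, allele -> count over non-missing calls."""
    counts: dict[str, dict[float, int]] = {}
    for loc in panel:
        cols = (loc.name,) if (loc.copies == 2 and combine_dys385) else loc.columns
        for c in cols:
            counts[c] = {}
    for h in members:
        for loc in panel:
            vals = h.values_for(loc)
            if not vals:
                continue
            if loc.copies == 2 and combine_dys385:
                tgt_cols = (loc.name,) * len(vals)
            else:
                tgt_cols = loc.columns
            for col, v in zip(tgt_cols, vals):
                counts[col][v] = counts[col].get(v, 0) + 1
    return counts


@dataclass
class DiversitySummary:
    """Diversity report for one scope (a population or the pooled sample)."""

    scope: str
    n: int
    h: int
    per_locus_gd: dict[str, float]
    HD: float
    DC: float
    HMP: float
    allele_freqs: dict[str, dict[float, float]] = field(default_factory=dict)

    def rounded(self) -> dict:
        """The summary at report precision (HD 5 d.p., DC/GD 3, HMP 4)."""
        return {
            "scope": self.scope,
            "n": self.n,
            "h": self.h,
            "HD": round(self.HD, ROUND_HD),
            "DC": round(self.DC, ROUND_DC),
            "HMP": round(self.HMP, ROUND_HMP),
            "per_locus_gd": {c: round(g, ROUND_GD) for c, g in self.per_locus_gd.items()},
        }


def summarize(
    data: Dataset | PopulationSample,
    panel=None,
    *,
    scope: str | None = None,
    combine_dys385: bool = False,
) -> DiversitySummary:
    """Full diversity summary: per-column GD, HD, DC, HMP, allele spectra."""
    panel = panel if panel is not None else _panel_of(data)
    members = list(_members_of(data))
    if scope is None:
        scope = (
            POOLED_SCOPE if isinstance(data, Dataset) else data.population_id
        )
    counts = haplotype_counts(members, panel)
    n = sum(counts.values())
    if n < 2:
        raise DiversityError(f"scope {scope!r}: fewer than 2 complete haplotypes")
    hd = gene_diversity(counts)
    per_locus = {}
    for col, cnt in allele_count_table(
        members, panel, combine_dys385=combine_dys385
    ).items():
        if sum(cnt.values()) >= 2:
            per_locus[col] = gene_diversity(cnt)
        else:
            log.warning("scope %s: column %s has <2 calls; GD omitted", scope, col)
    return DiversitySummary(
        scope=scope,
        n=n,
        h=len(counts),
        per_locus_gd=per_locus,
        HD=hd,
        DC=len(counts) / n,
        HMP=match_probability(hd),
        allele_freqs=allele_frequencies(members, panel, combine_dys385=combine_dys385),
    )


def gd_matrix(
    ds: Dataset, *, combine_dys385: bool = False, include_pooled: bool = True
) -> pd.DataFrame:
    """Per-population x per-column gene diversity table.

    Rows are populations (plus a pooled 'ALL' row when requested), columns
    the panel's reported columns. Populations with fewer than two calls at
    a column get NaN there, with a logged warning. The pooled row's mean
    across columns is the national mean gene diversity.
    """
    if combine_dys385:
        cols = [loc.name for loc in ds.panel]
    else:
        cols = reported_columns(ds.panel)
    rows = {}
    for pop in ds.populations:
        row = {}
        table = allele_count_table(pop.members, ds.panel, combine_dys385=combine_dys385)
        for col in cols:
            cnt = table.get(col, {})
            if sum(cnt.values()) >= 2:
                row[col] = gene_diversity(cnt)
            else:
                log.warning(
                    "population %s, column %s: <2 calls, GD excluded",
                    pop.population_id, col,
                )
                row[col] = np.nan
        rows[pop.population_id] = row
    if include_pooled:
        table = allele_count_table(
            list(ds.all_members()), ds.panel, combine_dys385=combine_dys385
        )
        rows[POOLED_SCOPE] = {
            col: gene_diversity(table[col]) if sum(table.get(col, {}).values()) >= 2
            else np.nan
            for col in cols
        }
    return pd.DataFrame.from_dict(rows, orient="index").reindex(columns=cols)


def gd_extremes(gd: pd.DataFrame) -> dict:
    """Argmin/argmax cells of a per-population GD matrix (pooled row excluded)."""
    body = gd.drop(index=POOLED_SCOPE, errors="ignore")
    stacked = body.stack()
    if stacked.empty:
        raise DiversityError("GD matrix has no finite entries")
    (pop_min, col_min) = stacked.idxmin()
    (pop_max, col_max) = stacked.idxmax()
    return {
        "min": {"population": pop_min, "column": col_min, "gd": float(stacked.min())},
        "max": {"population": pop_max, "column": col_max, "gd": float(stacked.max())},
    }
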