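"""Pairwise population differentiation.

Two-level analysis of molecular variance (AMOVA) on squared haplotype
distances, following the standard Excoffier decomposition:

    SS_total  = (1/N) * sum_{i<j} d_ij^2            (all donors pooled)
    SS_within = sum_pops (1/n_p) * sum_{i<j in p} d_ij^2
    SS_among  = SS_total - SS_within
    sigma2_w  = SS_within / (N - k)
    sigma2_a  = (SS_among/(k-1) - sigma2_w) / n_bar,
                n_bar = (N - sum n_p^2 / N) / (k - 1)
    Phi_ST    = sigma2_a / (sigma2_a + sigma2_w)

With identity distances (d = 0 iff haplotype keys equal, else 1) Phi_ST
is a haplotype-frequency FST, the convention used by YHRD; with stepwise
distances (sum of absolute repeat differences, minimum assignment over
the unordered DYS385 pair) it is an RST-like Phi_ST. Pairwise matrices
carry permutation p-values from random reassignment of donors to the two
population labels, sizes held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Dataset, PopulationSample, YHaplotype, haplotype_key
from .errors import ConfigError, ValidationError
from .panel import LocusDef

__all__ = [
    "DistanceModel",
    "haplotype_distance",
    "distance_matrix",
    "AmovaResult",
    "amova_two_level",
    "FstMatrix",
    "pairwise_fst_matrix",
]


class DistanceModel(str, Enum):
    """How two haplotypes differ: categorical identity or repeat steps."""

    identity = "identity"
    stepwise = "stepwise"


def _check_same_panel(h1: YHaplotype, h2: YHaplotype, panel) -> None:
    for h in (h1, h2):
        if not h.is_complete(panel):
            raise ValidationError(f"{h.sample_id}: incomplete haplotype")


def haplotype_distance(
    h1: YHaplotype,
    h2: YHaplotype,
    panel: Sequence[LocusDef],
    model: DistanceModel = DistanceModel.identity,
) -> float:
    """Distance between two complete haplotypes under the chosen model.

    identity: 0 if all reported values equal else 1. stepwise: sum of
    |a1 - a2| over single-copy loci plus the minimum-assignment repeat
    difference for the unordered DYS385 pair.
    """
    _check_same_panel(h1, h2, panel)
    model = DistanceModel(model)
    if model is DistanceModel.identity:
        return 0.0 if haplotype_key(h1, panel) == haplotype_key(h2, panel) else 1.0
    total = 0.0
    for loc in panel:
        v1, v2 = h1.values_for(loc), h2.values_for(loc)
        if loc.copies == 2:
            (a1, a2), (b1, b2) = v1, v2
            total += min(
                abs(a1 - b1) + abs(a2 - b2),
                abs(a1 - b2) + abs(a2 - b1),
            )
        else:
            total += abs(v1[0] - v2[0])
    return total


def _encode(members: Sequence[YHaplotype], panel) -> np.ndarray:
    """Complete haplotypes -> (n, n_columns) float array in panel order."""
    rows = []
    for h in members:
        if not h.is_complete(panel):
            raise ValidationError(f"{h.sample_id}: incomplete haplotype")
        rows.append(h.column_values(panel))
    return np.asarray(rows, dtype=float)


def distance_matrix(
    members: Sequence[YHaplotype],
    panel: Sequence[LocusDef],
    model: DistanceModel = DistanceModel.identity,
) -> np.ndarray:
    """Dense pairwise distance matrix over complete haplotypes.

    For the stepwise model the ascending-sorted DYS385 pair realises the
    minimum assignment automatically (sorted vectors minimise the L1
    matching), so a plain column-wise |difference| sum is exact.
    """
    model = DistanceModel(model)
    if model is DistanceModel.identity:
        keys = [haplotype_key(h, panel) for h in members]
        codes = pd.factorize(np.asarray(keys, dtype=object))[0]
        return (codes[:, None] != codes[None, :]).astype(float)
    X = _encode(members, panel)
    return np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)


@dataclass
class AmovaResult:
    """Two-level AMOVA decomposition and its Phi statistic."""

    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_a: float
    sigma2_w: float
    phi: float
    n_bar: float
    degenerate: bool = False  # total variance was zero; phi defined as 0

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def as_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source": ["among populations", "within populations", "total"],
                "df": [self.df_among, self.df_within, self.df_among + self.df_within],
                "SS": [self.ss_among, self.ss_within, self.ss_total],
                "variance": [self.sigma2_a, self.sigma2_w, self.sigma2_a + self.sigma2_w],
                "phi_ST": [self.phi, np.nan, np.nan],
            }
        )


def _group_ss(D2: np.ndarray, idx: np.ndarray) -> float:
    sub = D2[np.ix_(idx, idx)]
    return float(sub.sum()) / (2.0 * len(idx))


def _amova_from_d2(D2: np.ndarray, sizes: Sequence[int]) -> AmovaResult:
    sizes = np.asarray(sizes, dtype=int)
    N = int(sizes.sum())
    k = len(sizes)
    ss_total = float(D2.sum()) / (2.0 * N)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    ss_within = sum(
        _group_ss(D2, np.arange(bounds[i], bounds[i + 1])) for i in range(k)
    )
    ss_among = ss_total - ss_within
    df_among, df_within = k - 1, N - k
    sigma2_w = ss_within / df_within
    n_bar = (N - float(np.sum(sizes**2)) / N) / (k - 1)
    sigma2_a = (ss_among / df_among - sigma2_w) / n_bar
    denom = sigma2_a + sigma2_w
    if ss_total <= 1e-12:
        return AmovaResult(
            ss_among, ss_within, df_among, df_within, 0.0, sigma2_w, 0.0, n_bar,
            degenerate=True,
        )
    phi = sigma2_a / denom
    return AmovaResult(
        ss_among, ss_within, df_among, df_within, sigma2_a, sigma2_w, phi, n_bar
    )


def amova_two_level(
    pops: Sequence[PopulationSample],
    panel: Sequence[LocusDef],
    model: DistanceModel = DistanceModel.identity,
) -> AmovaResult:
    """Two-level AMOVA across >= 2 populations of complete haplotypes."""
    if len(pops) < 2:
        raise ConfigError("AMOVA needs at least two populations")
    for p in pops:
        if p.n < 2:
            raise ValidationError(f"population {p.population_id!r} has n < 2")
    members = [h for p in pops for h in p.members]
    D = distance_matrix(members, panel, model)
    D2 = D * D
    return _amova_from_d2(D2, [p.n for p in pops])


@dataclass
class FstMatrix:
    """Symmetric pairwise Phi/FST matrix with permutation p-values."""

    population_ids: list[str]
    values: pd.DataFrame
    pvalues: pd.DataFrame
    B: int
    seed: int
    model: DistanceModel = DistanceModel.identity

    def clamped(self) -> pd.DataFrame:
        """Non-negative copy of the matrix (negative estimates -> 0)."""
        return self.values.clip(lower=0.0)

    def bonferroni(self) -> pd.DataFrame:
        """p-values multiplied by the number of off-diagonal tests, capped at 1."""
        k = len(self.population_ids)
        m = k * (k - 1) // 2
        out = (self.pvalues * m).clip(upper=1.0)
        np.fill_diagonal(out.values, np.nan)
        return out


def _pair_phi_and_p(
    D2: np.ndarray, n1: int, n2: int, B: int, rng: np.random.Generator
) -> tuple[float, float]:
    """Observed Phi for a pooled pair plus its permutation p-value.

    Under label permutation SS_total is fixed, so Phi is a monotone
    decreasing function of SS_within; counting permuted SS_within <=
    observed SS_within is equivalent to counting permuted Phi >= observed.
    """
    N = n1 + n2
    res = _amova_from_d2(D2, [n1, n2])
    if B < 1:
        raise ConfigError("permutation count B must be >= 1")
    ssw_obs = res.ss_within
    rowsum = D2.sum(axis=0)
    tot = float(D2.sum())
    # membership matrix for group 1 across permutations
    M = np.zeros((B, N))
    for b in range(B):
        M[b, rng.permutation(N)[:n1]] = 1.0
    q1 = np.einsum("bi,ij,bj->b", M, D2, M, optimize=True)
    # group 2 quadratic form from complement: (1-m)'S(1-m) = tot - 2 r.m + q1
    q2 = tot - 2.0 * (M @ rowsum) + q1
    ssw_perm = q1 / (2.0 * n1) + q2 / (2.0 * n2)
    n_extreme = int(np.sum(ssw_perm <= ssw_obs + 1e-12))
    p = (1.0 + n_extreme) / (B + 1.0)
    return res.phi, p


def pairwise_fst_matrix(
    ds: Dataset,
    model: DistanceModel = DistanceModel.identity,
    B: int = 10_000,
    seed: int | None = None,
) -> FstMatrix:
    """All pairwise Phi/FST values with permutation significance.

    Entry (i, j) is the two-population AMOVA Phi; its p-value is
    (1 + #{permuted Phi >= observed}) / (B + 1) under random reassignment
    of donors to the two labels with sizes held fixed. ``seed`` is
    mandatory for reproducible permutation streams.
    """
    if len(ds.populations) < 2:
        raise ConfigError("need at least two populations")
    if B < 1:
        raise ConfigError("permutation count B must be >= 1")
    if seed is None:
        raise ConfigError("seed is required for the permutation test")
    for p in ds.populations:
        if p.n < 2:
            raise ValidationError(f"population {p.population_id!r} has n < 2")
    ids = ds.population_ids
    k = len(ids)
    vals = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    rng = np.random.default_rng(seed)
    for i in range(k):
        for j in range(i + 1, k):
            pi, pj = ds.populations[i], ds.populations[j]
            members = list(pi.members) + list(pj.members)
            D = distance_matrix(members, ds.panel, model)
            D2 = D * D
            phi, p = _pair_phi_and_p(D2, pi.n, pj.n, B, rng)
            vals[i, j] = vals[j, i] = phi
            pvals[i, j] = pvals[j, i] = p
    values = pd.DataFrame(vals, index=ids, columns=ids)
    pvalues = pd.DataFrame(pvals, index=ids, columns=ids)
    return FstMatrix(ids, values, pvalues, B=B, seed=seed, model=DistanceModel(model))
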