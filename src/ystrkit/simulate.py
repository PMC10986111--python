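"""Synthetic Y-STR data: forward-time patrilineal Wright-Fisher simulation.

Each population holds ``Ne`` patrilines (the Y chromosome is haploid and
strictly paternally inherited, so the relevant effective size is the
number of breeding male lineages). Every generation each patriline picks
a father uniformly at random (multinomial offspring numbers), optionally
from another deme under a symmetric island migration model, and every
locus copy mutates with per-generation probability ``mu`` by one repeat
unit up or down (stepwise mutation model), reflecting at the panel's
allele bounds. The duplicated locus DYS385 is simulated as two
independently mutating copies and sorted ascending only on output.

``expansion_generations`` appends a star-like terminal phase: after the
final sample is drawn, every sampled lineage accrues that many
generations of private mutation with no shared ancestry. This is the
coalescent limit of rapid recent population growth and is what lets a
desk-scale simulation reproduce the hallmark of real national Y-STR
surveys — nearly every 17-locus haplotype unique while per-locus gene
diversity stays moderate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .data import Dataset, PopulationSample, YHaplotype, haplotype_counts
from .errors import ConfigError
from .panel import LocusDef, YFILER_PANEL, reported_columns

__all__ = [
    "SimConfig",
    "mutate_haplotype",
    "simulate_dataset",
    "make_fixture",
    "expected_fst_island",
    "IRAN_PROVINCE_SIZES",
    "FIXTURE_PROFILES",
]

DEFAULT_MU = 2e-3  # per locus per generation, typical Y-STR order of magnitude

# Per-province sample sizes of a 16-population national survey (N = 1353),
# used by the "iran-like" fixture profile.
IRAN_PROVINCE_SIZES: dict[str, int] = {
    "Tehran": 236,
    "Isfahan": 153,
    "Golestan": 82,
    "Mazandaran": 102,
    "Gilan": 77,
    "Tabriz": 41,
    "Urmia": 53,
    "Kermanshah": 75,
    "Kurdistan": 50,
    "Ilam": 55,
    "Hamedan": 34,
    "Fars": 105,
    "Khuzestan": 34,
    "KhorasanRazavi": 127,
    "SouthKhorasan": 27,
    "SistanBaluchestan": 102,
}


@dataclass
class SimConfig:
    """Demographic and mutational parameters for one simulation run."""

    k: int
    n_sample: int | Sequence[int]
    Ne: int
    generations: int
    seed: int
    migration_rate: float = 0.0
    topology: str = "island"
    split_generations: int = 0
    mu: float | Mapping[str, float] = DEFAULT_MU
    panel: tuple[LocusDef, ...] = YFILER_PANEL
    founder: Mapping[str, float] | None = None
    init_spread: float | Mapping[str, float] = 0.0
    expansion_generations: int = 0
    population_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is required")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ConfigError("migration_rate must lie in [0, 1]")
        if self.topology not in ("island", "split"):
            raise ConfigError(f"unknown topology {self.topology!r}")
        if self.topology == "split" and self.split_generations < 0:
            raise ConfigError("split_generations must be >= 0")
        sizes = self.sample_sizes
        if len(sizes) != self.k:
            raise ConfigError("n_sample list length must equal k")
        if any(s < 1 for s in sizes):
            raise ConfigError("n_sample must be >= 1")
        if max(sizes) > self.Ne:
            raise ConfigError("n_sample cannot exceed Ne")
        for m in self._col_mu():
            if m < 0:
                raise ConfigError("mu must be >= 0")
        if self.population_ids is not None and len(self.population_ids) != self.k:
            raise ConfigError("population_ids length must equal k")

    @property
    def sample_sizes(self) -> list[int]:
        if isinstance(self.n_sample, int):
            return [self.n_sample] * self.k
        return list(self.n_sample)

    def _per_locus(self, value, default) -> list[float]:
        if isinstance(value, Mapping):
            return [float(value.get(loc.name, default)) for loc in self.panel]
        return [float(value)] * len(self.panel)

    def _col_mu(self) -> np.ndarray:
        per_locus = self._per_locus(self.mu, DEFAULT_MU)
        return np.asarray(
            [mu for loc, mu in zip(self.panel, per_locus) for _ in range(loc.copies)]
        )

    def _col_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = [loc.allele_min for loc in self.panel for _ in range(loc.copies)]
        hi = [loc.allele_max for loc in self.panel for _ in range(loc.copies)]
        return np.asarray(lo, dtype=float), np.asarray(hi, dtype=float)

    def _founder_columns(self) -> np.ndarray:
        vals = []
        for loc in self.panel:
            if self.founder is not None and loc.name in self.founder:
                v = float(self.founder[loc.name])
            else:
                v = float(round((loc.allele_min + loc.allele_max) / 2.0))
            vals.extend([v] * loc.copies)
        return np.asarray(vals, dtype=float)


def _smm_step(
    A: np.ndarray, col_mu: np.ndarray, lo: np.ndarray, hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """One generation of stepwise mutation on an (..., C) allele array.

    A mutating copy moves +-1 repeat with equal probability; a step that
    would leave [lo, hi] reflects to the opposite direction, so the
    fractional part of microvariant alleles is always preserved.
    """
    mask = rng.random(A.shape) < col_mu
    steps = np.where(rng.random(A.shape) < 0.5, -1.0, 1.0)
    steps = np.where(mask, steps, 0.0)
    cand = A + steps
    bad = (cand < lo) | (cand > hi)
    return np.where(bad, A - steps, cand)


def mutate_haplotype(
    h: YHaplotype,
    mu: float | Mapping[str, float],
    rng: np.random.Generator,
    panel: Sequence[LocusDef] = YFILER_PANEL,
) -> YHaplotype:
    """Apply one generation of stepwise mutation to a complete haplotype."""
    if not h.is_complete(panel):
        raise ConfigError(f"{h.sample_id}: incomplete haplotype cannot mutate")
    cfg_mu = mu if isinstance(mu, Mapping) else {loc.name: mu for loc in panel}
    col_mu = np.asarray(
        [float(cfg_mu.get(loc.name, DEFAULT_MU)) for loc in panel
         for _ in range(loc.copies)]
    )
    lo = np.asarray([loc.allele_min for loc in panel for _ in range(loc.copies)])
    hi = np.asarray([loc.allele_max for loc in panel for _ in range(loc.copies)])
    row = np.asarray(h.column_values(panel), dtype=float)
    new = _smm_step(row, col_mu, lo, hi, rng)
    return _row_to_haplotype(h.sample_id, h.population_id, new, panel)


def _row_to_haplotype(
    sample_id: str, population_id: str, row: np.ndarray, panel
) -> YHaplotype:
    alleles: dict = {}
    i = 0
    for loc in panel:
        if loc.copies == 2:
            pair = (float(row[i]), float(row[i + 1]))
            alleles[loc.name] = (min(pair), max(pair))
            i += 2
        else:
            alleles[loc.name] = float(row[i])
            i += 1
    return YHaplotype(sample_id, population_id, alleles)


def simulate_dataset(cfg: SimConfig) -> tuple[Dataset, dict]:
    """Run the forward simulation; returns (Dataset, truth log).

    Fully reproducible from ``cfg.seed``. The truth log records the
    realized per-column allele frequencies of each sampled population,
    the number of distinct founder patrilines surviving in each deme, and
    the configuration actually used.
    """
    rng = np.random.default_rng(cfg.seed)
    k, Ne = cfg.k, cfg.Ne
    col_mu = cfg._col_mu()
    lo, hi = cfg._col_bounds()
    C = len(col_mu)

    A = np.tile(cfg._founder_columns(), (k, Ne, 1))
    spread = cfg._per_locus(cfg.init_spread, 0.0)
    col_spread = np.asarray(
        [s for loc, s in zip(cfg.panel, spread) for _ in range(loc.copies)]
    )
    if np.any(col_spread > 0):
        # spread >= 1: uniform integer offset in [-s, s];
        # spread in (0, 1): +-1 offset with that total probability.
        wide = np.ceil(np.where(col_spread >= 1, col_spread, 0)).astype(int)
        offs = rng.integers(-wide, wide + 1, size=(k, Ne, C)).astype(float)
        frac = np.where(col_spread < 1, col_spread, 0.0)
        hit = rng.random((k, Ne, C)) < frac
        sign = np.where(rng.random((k, Ne, C)) < 0.5, -1.0, 1.0)
        offs = np.where(hit, sign, offs)
        A = np.clip(A + offs, lo, hi)
    founder_id = np.tile(np.arange(Ne), (k, 1))

    if cfg.topology == "island":
        phases = [(cfg.generations, cfg.migration_rate)]
    else:  # split: shared ancestry (full mixing), then isolated divergence
        phases = [(cfg.generations, 1.0 - 1.0 / k if k > 1 else 0.0),
                  (cfg.split_generations, 0.0)]

    own = np.arange(k)[:, None]
    for gens, m in phases:
        for _ in range(gens):
            deme = np.broadcast_to(own, (k, Ne)).copy()
            if m > 0 and k > 1:
                mig = rng.random((k, Ne)) < m
                offsets = rng.integers(1, k, size=(k, Ne))
                deme = np.where(mig, (deme + offsets) % k, deme)
            parent = rng.integers(0, Ne, size=(k, Ne))
            A = A[deme, parent]
            founder_id = founder_id[deme, parent]
            A = _smm_step(A, col_mu, lo, hi, rng)

    pop_ids = (
        list(cfg.population_ids)
        if cfg.population_ids is not None
        else [f"pop{i + 1:02d}" for i in range(k)]
    )
    sizes = cfg.sample_sizes
    cols = reported_columns(cfg.panel)
    populations = []
    truth_pops = {}
    for i, (pid, n) in enumerate(zip(pop_ids, sizes)):
        take = rng.choice(Ne, size=n, replace=False)
        S = A[i, take].copy()
        for _ in range(cfg.expansion_generations):
            S = _smm_step(S, col_mu, lo, hi, rng)
        # canonical ascending order for multi-copy loci (matches output)
        c0 = 0
        for loc in cfg.panel:
            if loc.copies == 2:
                S[:, c0:c0 + 2] = np.sort(S[:, c0:c0 + 2], axis=1)
            c0 += loc.copies
        members = [
            _row_to_haplotype(f"{pid}-{j + 1:04d}", pid, S[j], cfg.panel)
            for j in range(n)
        ]
        populations.append(PopulationSample(pid, members))
        freqs = {}
        for c_idx, col in enumerate(cols):
            vals, counts = np.unique(S[:, c_idx], return_counts=True)
            freqs[col] = {float(v): int(cn) for v, cn in zip(vals, counts)}
        truth_pops[pid] = {
            "n": n,
            "allele_counts": freqs,
            "surviving_founder_lineages": int(len(np.unique(founder_id[i]))),
            "sample_founder_lineages": int(len(np.unique(founder_id[i, take]))),
        }
    ds = Dataset(cfg.panel, populations)
    n_distinct = len(haplotype_counts(list(ds.all_members()), cfg.panel))
    truth = {
        "config": {
            "k": k, "Ne": Ne, "generations": cfg.generations,
            "migration_rate": cfg.migration_rate, "topology": cfg.topology,
            "split_generations": cfg.split_generations,
            "expansion_generations": cfg.expansion_generations,
            "seed": cfg.seed,
            "mu_per_column": {c: float(m) for c, m in zip(cols, col_mu)},
        },
        "populations": truth_pops,
        "distinct_haplotypes_total": n_distinct,
        "N": ds.N,
    }
    return ds, truth


def expected_fst_island(Ne: int, m: float, d: int) -> float:
    """Quasi-equilibrium FST of the haploid finite island model.

    Solves the exact one-generation identity-by-descent recursion for the
    stationary ratio F = (Q0 - Q1)/(1 - Q1) in a system of ``d`` demes of
    ``Ne`` patrilines with symmetric migration rate ``m`` (migrant source
    uniform over the other d-1 demes), no mutation:

        F = (a + b*F) * (F*(1 - 1/Ne) + 1/Ne)

    with a = alpha - beta, where alpha (beta) is the probability that the
    parents of two genes sampled in the same (different) deme(s) lived in
    the same deme. To first order in m this is the familiar
    F = 1 / (1 + 2*Ne*m*d/(d-1)); the diploid-convention counterpart of
    the composite parameter 2*Ne*m*d/(d-1) is "4Nm".
    """
    if d < 2:
        raise ConfigError("island model needs d >= 2 demes")
    if m <= 0:
        return 1.0
    alpha = (1 - m) ** 2 + m**2 / (d - 1)
    beta = 2 * m * (1 - m) / (d - 1) + (d - 2) * m**2 / (d - 1) ** 2
    a = alpha - beta

    def g(F: float) -> float:
        return (a + beta * F) * (F * (1 - 1 / Ne) + 1 / Ne) - F

    return float(brentq(g, 0.0, 1.0, xtol=1e-12))


def all_distinct_dataset(
    sizes: Mapping[str, int] | None = None,
    panel: Sequence[LocusDef] = YFILER_PANEL,
    seed: int | None = None,
) -> Dataset:
    """Deterministic dataset in which every haplotype is distinct.

    Reproduces the headline structure of a national survey where no two
    donors share a 17-locus haplotype: donor i gets the panel-midpoint
    haplotype with a unique mixed-radix offset pattern encoded, within
    the panel's allele bounds, across the three widest single-copy loci.
    ``sizes`` defaults to the 16-province structure (N = 1353). ``seed``
    only shuffles donor order; the haplotype set is unchanged.
    """
    sizes = dict(IRAN_PROVINCE_SIZES) if sizes is None else dict(sizes)
    N = sum(sizes.values())
    single = sorted(
        (loc for loc in panel if loc.copies == 1),
        key=lambda loc: loc.allele_max - loc.allele_min,
        reverse=True,
    )[:3]
    radices = [int(loc.allele_max - loc.allele_min) + 1 for loc in single]
    capacity = int(np.prod(radices))
    if N > capacity:
        raise ConfigError(f"cannot encode {N} distinct haplotypes (max {capacity})")
    base = {loc.name: float(round((loc.allele_min + loc.allele_max) / 2.0))
            for loc in panel}

    rows = []
    for i in range(N):
        alleles: dict = {}
        for loc in panel:
            if loc.copies == 2:
                alleles[loc.name] = (base[loc.name], base[loc.name])
            else:
                alleles[loc.name] = base[loc.name]
        rem = i
        for loc, radix in zip(single, radices):
            rem, digit = divmod(rem, radix)
            alleles[loc.name] = loc.allele_min + digit
        rows.append(alleles)
    if seed is not None:
        rng = np.random.default_rng(seed)
        rng.shuffle(rows)

    populations = []
    it = iter(rows)
    for pid, n in sizes.items():
        members = [
            YHaplotype(f"{pid}-{j + 1:04d}", pid, next(it)) for j in range(n)
        ]
        populations.append(PopulationSample(pid, members))
    return Dataset(tuple(panel), populations)


FIXTURE_PROFILES: dict[str, dict] = {
    # Three small populations for oracle-scale tests.
    "tiny": dict(
        k=3,
        n_sample=10,
        Ne=60,
        generations=150,
        migration_rate=0.05,
        mu=0.005,
        init_spread=2.0,
        seed=20240,
    ),
    # A 16-population national survey with the study-design sample sizes
    # (N = 1353). Mutation rates per locus are tuning choices spread over
    # an order of magnitude so per-locus gene diversity lands in roughly
    # [0.3, 0.9] (DYS385 most, DYS391 least polymorphic), and the
    # star-like expansion phase makes >= 99% of haplotypes unique. These
    # are properties of the generator, not inferences about any real
    # population; realized values are recorded in the truth log.
    "iran-like": dict(
        k=16,
        n_sample=list(IRAN_PROVINCE_SIZES.values()),
        population_ids=list(IRAN_PROVINCE_SIZES.keys()),
        Ne=300,
        generations=800,
        migration_rate=0.04,
        mu={
            "DYS391": 2e-4, "DYS437": 2.5e-4, "YGATAH4": 3e-4, "DYS393": 3e-4,
            "DYS392": 3.5e-4, "DYS389I": 3.5e-4, "DYS438": 4e-4, "DYS635": 4e-4,
            "DYS456": 4.5e-4, "DYS19": 5e-4, "DYS390": 5e-4, "DYS439": 6e-4,
            "DYS389II": 7e-4, "DYS458": 8e-4, "DYS448": 1.0e-3, "DYS385": 2.6e-3,
        },
        init_spread={
            "DYS391": 0.3, "DYS437": 0.4, "YGATAH4": 0.45, "DYS393": 0.5,
            "DYS392": 0.5, "DYS389I": 0.6, "DYS438": 0.6, "DYS635": 0.65,
            "DYS456": 0.65, "DYS19": 0.7, "DYS390": 0.7, "DYS439": 0.8,
            "DYS389II": 1, "DYS458": 1, "DYS448": 2, "DYS385": 3,
        },
        expansion_generations=450,
        seed=999,
    ),
}


def make_fixture(profile: str, seed: int | None = None) -> tuple[Dataset, dict]:
    """Generate a named preset dataset (deterministic given seed)."""
    if profile not in FIXTURE_PROFILES:
        raise ConfigError(
            f"unknown fixture profile {profile!r}; "
            f"available: {sorted(FIXTURE_PROFILES)}"
        )
    params = dict(FIXTURE_PROFILES[profile])
    if seed is not None:
        params["seed"] = seed
    return simulate_dataset(SimConfig(**params))
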