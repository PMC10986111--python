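"""Haplotype distances, AMOVA decomposition, pairwise FST, permutations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ystrkit import (
    ConfigError,
    Dataset,
    DistanceModel,
    PopulationSample,
    ValidationError,
    YFILER_PANEL,
    YHaplotype,
    amova_two_level,
    distance_matrix,
    haplotype_distance,
    haplotype_key,
    pairwise_fst_matrix,
)

from conftest import dataset_from_haps, hap, midpoint_alleles


def anova_oracle_identity(pops, panel):
    """AMOVA variance components via an independent route.

    Haplotype classes are one-hot embedded as vectors x/sqrt(2), so the
    squared Euclidean distance between two donors is exactly the identity
    distance (0 or 1). The sums of squares are then computed as ordinary
    ANOVA deviations from group/grand centroids (never from pairwise
    distances); Gower's identity guarantees agreement with the
    distance-based decomposition.
    """
    members = [h for p in pops for h in p.members]
    keys = sorted({haplotype_key(h, panel) for h in members})
    index = {k: i for i, k in enumerate(keys)}
    X = np.zeros((len(members), len(keys)))
    for r, h in enumerate(members):
        X[r, index[haplotype_key(h, panel)]] = 1.0 / np.sqrt(2.0)
    sizes = [p.n for p in pops]
    N, k = sum(sizes), len(sizes)
    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_within = 0.0
    start = 0
    for n in sizes:
        G = X[start:start + n]
        ss_within += float(((G - G.mean(axis=0)) ** 2).sum())
        start += n
    ss_among = ss_total - ss_within
    sigma2_w = ss_within / (N - k)
    n_bar = (N - sum(n * n for n in sizes) / N) / (k - 1)
    sigma2_a = (ss_among / (k - 1) - sigma2_w) / n_bar
    phi = sigma2_a / (sigma2_a + sigma2_w) if ss_total > 0 else 0.0
    return ss_among, ss_within, phi


def stepwise_oracle(h1, h2, panel):
    """Naive per-locus distance with explicit DYS385 pairing enumeration."""
    total = 0.0
    for loc in panel:
        v1, v2 = h1.values_for(loc), h2.values_for(loc)
        if loc.copies == 2:
            total += min(
                abs(v1[0] - v2[0]) + abs(v1[1] - v2[1]),
                abs(v1[0] - v2[1]) + abs(v1[1] - v2[0]),
            )
        else:
            total += abs(v1[0] - v2[0])
    return total


def random_dataset(rng, k=3, n_range=(2, 8)):
    """Small random multi-population dataset with repeat-scale alleles."""
    pops = []
    for p in range(k):
        n = int(rng.integers(*n_range))
        members = []
        for j in range(n):
            over = {
                "DYS391": float(rng.integers(8, 12)),
                "DYS439": float(rng.integers(9, 13)),
                "DYS385": (float(rng.integers(11, 15)), float(rng.integers(11, 15))),
            }
            members.append(
                YHaplotype(f"p{p}s{j}", f"pop{p}", midpoint_alleles(**over))
            )
        pops.append(PopulationSample(f"pop{p}", members))
    return Dataset(YFILER_PANEL, pops)


class TestHaplotypeDistance:
    @pytest.mark.parametrize("model", list(DistanceModel))
    def test_identical_haplotypes_distance_zero(self, model):
        assert haplotype_distance(hap("a", "p"), hap("b", "p"), YFILER_PANEL,
                                  model) == 0.0

    def test_one_step_difference_stepwise(self):
        d = haplotype_distance(
            hap("a", "p", DYS391=10), hap("b", "p", DYS391=11),
            YFILER_PANEL, DistanceModel.stepwise,
        )
        assert d == 1.0

    def test_dys385_minimum_assignment(self):
        d = haplotype_distance(
            hap("a", "p", DYS385=(11, 14)), hap("b", "p", DYS385=(12, 14)),
            YFILER_PANEL, DistanceModel.stepwise,
        )
        assert d == 1.0

    def test_identity_mode_is_binary(self):
        d = haplotype_distance(
            hap("a", "p", DYS391=8), hap("b", "p", DYS391=12),
            YFILER_PANEL, DistanceModel.identity,
        )
        assert d == 1.0

    def test_incomplete_rejected(self):
        alleles = midpoint_alleles()
        del alleles["DYS19"]
        with pytest.raises(ValidationError):
            haplotype_distance(YHaplotype("a", "p", alleles), hap("b", "p"),
                               YFILER_PANEL, DistanceModel.stepwise)

    @given(
        a1=st.integers(7, 25), a2=st.integers(7, 25),
        b1=st.integers(7, 25), b2=st.integers(7, 25),
    )
    @settings(max_examples=60, deadline=None)
    def test_sorted_pair_realises_minimum_assignment(self, a1, a2, b1, b2):
        h1 = hap("a", "p", DYS385=(float(a1), float(a2)))
        h2 = hap("b", "p", DYS385=(float(b1), float(b2)))
        got = haplotype_distance(h1, h2, YFILER_PANEL, DistanceModel.stepwise)
        assert got == stepwise_oracle(h1, h2, YFILER_PANEL)
        # symmetry
        assert got == haplotype_distance(h2, h1, YFILER_PANEL,
                                         DistanceModel.stepwise)

    @pytest.mark.parametrize("model", list(DistanceModel))
    def test_matrix_agrees_with_scalar_distance(self, model):
        rng = np.random.default_rng(7)
        ds = random_dataset(rng)
        members = list(ds.all_members())
        D = distance_matrix(members, ds.panel, model)
        for i in range(len(members)):
            for j in range(len(members)):
                assert D[i, j] == haplotype_distance(
                    members[i], members[j], ds.panel, model
                )


class TestAmova:
    def test_identical_composition_phi_near_zero(self):
        shared = [hap(f"a{i}", "p", DYS391=6 + i % 2) for i in range(6)]
        mirror = [
            YHaplotype(f"b{i}", "q", dict(h.alleles)) for i, h in enumerate(shared)
        ]
        res = amova_two_level(
            [PopulationSample("p", shared), PopulationSample("q", mirror)],
            YFILER_PANEL,
        )
        assert res.phi <= 1e-9  # <= 0 before clamping is acceptable

    def test_fully_differentiated_phi_is_one(self):
        ds = dataset_from_haps(
            [hap(f"a{i}", "p", DYS391=7) for i in range(5)],
            [hap(f"b{i}", "q", DYS391=12) for i in range(5)],
        )
        res = amova_two_level(ds.populations, ds.panel)
        assert res.phi == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_all_identical(self):
        ds = dataset_from_haps(
            [hap(f"a{i}", "p") for i in range(3)],
            [hap(f"b{i}", "q") for i in range(3)],
        )
        res = amova_two_level(ds.populations, ds.panel)
        assert res.degenerate and res.phi == 0.0

    def test_small_population_rejected(self):
        ds = dataset_from_haps([hap("a", "p")], [hap("b", "q"), hap("c", "q")])
        with pytest.raises(ValidationError):
            amova_two_level(ds.populations, ds.panel)

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_centroid_oracle_on_random_instances(self, seed):
        """Distance-based decomposition equals the one-hot ANOVA route."""
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, k=int(rng.integers(2, 5)))
        res = amova_two_level(ds.populations, ds.panel, DistanceModel.identity)
        ssa, ssw, phi = anova_oracle_identity(ds.populations, ds.panel)
        assert res.ss_among == pytest.approx(ssa, abs=1e-9)
        assert res.ss_within == pytest.approx(ssw, abs=1e-9)
        if not res.degenerate:
            assert res.phi == pytest.approx(phi, abs=1e-9)

    @pytest.mark.parametrize("model", list(DistanceModel))
    def test_ss_decomposition_identity(self, model):
        rng = np.random.default_rng(123)
        for _ in range(5):
            ds = random_dataset(rng, k=3)
            res = amova_two_level(ds.populations, ds.panel, model)
            members = list(ds.all_members())
            D2 = distance_matrix(members, ds.panel, model) ** 2
            ss_total = D2.sum() / (2 * ds.N)
            assert res.ss_among + res.ss_within == pytest.approx(
                ss_total, abs=1e-9
            )

    def test_label_invariance(self):
        rng = np.random.default_rng(42)
        ds = random_dataset(rng, k=3)
        res1 = amova_two_level(ds.populations, ds.panel)
        renamed = [
            PopulationSample(
                f"renamed{i}",
                [YHaplotype(h.sample_id, f"renamed{i}", dict(h.alleles))
                 for h in p.members],
            )
            for i, p in enumerate(ds.populations)
        ]
        res2 = amova_two_level(renamed[::-1], ds.panel)
        assert res1.phi == pytest.approx(res2.phi, abs=1e-12)
        assert res1.ss_total == pytest.approx(res2.ss_total, abs=1e-12)


class TestPairwiseFst:
    def test_duplicated_population_low_fst_high_p(self, tiny_ds):
        pop = tiny_ds.populations[0]
        clone = PopulationSample(
            "clone",
            [YHaplotype(h.sample_id + "_c", "clone", dict(h.alleles))
             for h in pop.members],
        )
        ds = Dataset(tiny_ds.panel, [pop, clone])
        fst = pairwise_fst_matrix(ds, B=199, seed=5)
        assert fst.values.iloc[0, 1] <= 1e-9
        assert fst.pvalues.iloc[0, 1] > 0.5

    def test_full_differentiation_minimal_p(self):
        ds = dataset_from_haps(
            [hap(f"a{i}", "p", DYS391=7) for i in range(8)],
            [hap(f"b{i}", "q", DYS391=12) for i in range(8)],
        )
        B = 199
        fst = pairwise_fst_matrix(ds, B=B, seed=11)
        assert fst.values.iloc[0, 1] == pytest.approx(1.0)
        assert fst.pvalues.iloc[0, 1] == pytest.approx(1 / (B + 1))

    def test_matrix_structure(self, tiny_ds):
        B = 99
        fst = pairwise_fst_matrix(tiny_ds, B=B, seed=3)
        V, P = fst.values.to_numpy(), fst.pvalues.to_numpy()
        assert np.allclose(V, V.T) and np.all(np.diag(V) == 0.0)
        off = ~np.eye(len(V), dtype=bool)
        assert np.all(P[off] >= 1 / (B + 1)) and np.all(P[off] <= 1.0)

    def test_same_seed_reproduces(self, tiny_ds):
        f1 = pairwise_fst_matrix(tiny_ds, B=99, seed=21)
        f2 = pairwise_fst_matrix(tiny_ds, B=99, seed=21)
        assert f1.values.equals(f2.values) and f1.pvalues.equals(f2.pvalues)

    def test_config_errors(self, tiny_ds):
        with pytest.raises(ConfigError):
            pairwise_fst_matrix(tiny_ds, B=0, seed=1)
        with pytest.raises(ConfigError):
            pairwise_fst_matrix(tiny_ds, B=99, seed=None)

    def test_clamped_and_bonferroni(self, tiny_ds):
        fst = pairwise_fst_matrix(tiny_ds, B=99, seed=9)
        assert (fst.clamped().to_numpy() >= 0).all()
        bonf = fst.bonferroni().to_numpy()
        off = ~np.eye(len(bonf), dtype=bool)
        assert np.all(bonf[off] >= fst.pvalues.to_numpy()[off] - 1e-15)
        assert np.nanmax(bonf) <= 1.0
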