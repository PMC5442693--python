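"""Diversity statistics, Nei identity, AMOVA, Mantel, PCA, proportion tests."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mtphylogeo.mtdna_io import Haplotype
from mtphylogeo.phylogeography import GeoPoint
from mtphylogeo.popstats import (
    amova_two_level,
    exclusive_haplotypes,
    frequency_pca,
    haplotype_diversity,
    haplotypic_richness,
    mantel,
    nei_distance,
    nei_identity,
    pairwise_mutation_distances,
    pearson_with_coordinates,
    two_proportion_test,
)


class TestSpectrumStatistics:
    def test_single_haplotype_diversity_zero(self):
        assert haplotype_diversity({"a": 5}) == 0.0

    def test_two_by_two_unbiased(self):
        assert haplotype_diversity({"a": 2, "b": 2}) == pytest.approx(2 / 3)

    def test_unbiased_at_least_biased(self, rng):
        for _ in range(20):
            counts = {f"h{i}": int(c) for i, c in
                      enumerate(rng.integers(1, 6, size=rng.integers(2, 8)))}
            assert haplotype_diversity(counts, True) >= haplotype_diversity(counts, False)

    @given(st.lists(st.integers(1, 9), min_size=2, max_size=10))
    def test_diversity_in_unit_interval(self, counts):
        h = haplotype_diversity({f"h{i}": c for i, c in enumerate(counts)})
        assert 0.0 <= h <= 1.0 + 1e-12

    def test_richness_all_distinct_and_all_identical(self):
        assert haplotypic_richness({f"h{i}": 1 for i in range(7)}) == 100.0
        assert haplotypic_richness({"h": 10}) == 10.0

    def test_richness_arabia_style_ratio(self):
        counts = {f"h{i}": 1 for i in range(21)} | {"major": 13}  # 22 of 34
        assert haplotypic_richness(counts) == pytest.approx(64.7, abs=0.05)

    def test_exclusive_shares(self):
        spectra = {"r1": {"A": 1, "B": 2}, "r2": {"B": 1, "C": 3}}
        assert exclusive_haplotypes(spectra) == {"r1": 50.0, "r2": 50.0}
        all_shared = {"r1": {"A": 1}, "r2": {"A": 2}}
        assert exclusive_haplotypes(all_shared) == {"r1": 0.0, "r2": 0.0}


class TestNei:
    def test_identity_bounds_and_symmetry(self):
        p, q = [0.5, 0.5, 0.0], [0.5, 0.0, 0.5]
        assert nei_identity(p, q) == pytest.approx(0.5)
        assert nei_distance(p, q) == pytest.approx(math.log(2))
        assert nei_distance(p, q) == nei_distance(q, p)

    def test_self_distance_zero(self):
        assert nei_distance([0.2, 0.8], [0.2, 0.8]) == 0.0

    def test_disjoint_profiles_infinite_distance(self):
        assert nei_distance([1, 0], [0, 1]) == math.inf


def naive_amova_components(sq, labels):
    """Sums of squares from first principles (independent of the package)."""
    n = len(sq)
    groups = sorted(set(labels))
    ss_total = sum(sq[i][j] for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            sq[i][j] for i in idx for j in idx if i < j
        ) / len(idx)
    ss_among = ss_total - ss_within
    ms_within = ss_within / (n - len(groups))
    counts = [labels.count(g) for g in groups]
    n0 = (n - sum(c * c for c in counts) / n) / (len(groups) - 1)
    var_among = (ss_among / (len(groups) - 1) - ms_within) / n0
    return var_among, ms_within


class TestAmova:
    def haps(self, tokens_by_pop):
        out, pops = [], []
        i = 0
        for pop, toks in tokens_by_pop:
            out.append(Haplotype.from_tokens(toks, f"s{i}", population=pop))
            pops.append(pop)
            i += 1
        return out, pops

    def test_all_identical_is_degenerate_convention(self):
        d = np.zeros((6, 6))
        res = amova_two_level(
            d, ["p1"] * 3 + ["p2"] * 3, {"p1": "R1", "p2": "R2"}, 99, seed=1
        )
        assert (res.pct_among, res.pct_within, res.p_value) == (0.0, 100.0, 1.0)

    def test_fixed_regional_difference_is_fully_among(self):
        haps, pops = self.haps(
            [("p1", "73 146"), ("p1", "73 146"), ("p2", "73 146"), ("p2", "73 146"),
             ("p3", "10398 12705"), ("p3", "10398 12705"),
             ("p4", "10398 12705"), ("p4", "10398 12705")]
        )
        d = pairwise_mutation_distances(haps)
        res = amova_two_level(
            d, pops, {"p1": "R1", "p2": "R1", "p3": "R2", "p4": "R2"}, 999, seed=2
        )
        assert res.pct_among == pytest.approx(100.0)
        assert res.phi_rt == pytest.approx(1.0)

    def test_components_match_naive_oracle(self, rng):
        for _ in range(10):
            n = 12
            muts = [
                " ".join(str(int(p)) for p in rng.choice(
                    np.arange(100, 200), size=rng.integers(0, 6), replace=False))
                for _ in range(n)
            ]
            haps = [Haplotype.from_tokens(m, f"s{i}") for i, m in enumerate(muts)]
            d = pairwise_mutation_distances(haps)
            pops = [f"p{i // 3}" for i in range(n)]
            regions = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
            res = amova_two_level(d, pops, regions, permutations=99, seed=0)
            labels = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
            va, vw = naive_amova_components(d.tolist(), labels)
            assert res.var_among == pytest.approx(va, abs=1e-9)
            assert res.var_within == pytest.approx(vw, abs=1e-9)

    def test_bit_reproducible_for_fixed_seed(self, rng):
        d = pairwise_mutation_distances(
            [Haplotype.from_tokens(" ".join(
                str(int(p)) for p in rng.choice(np.arange(100, 150), 3, replace=False)),
                f"s{i}") for i in range(8)]
        )
        pops = [f"p{i // 2}" for i in range(8)]
        regions = {"p0": "A", "p1": "A", "p2": "B", "p3": "B"}
        r1 = amova_two_level(d, pops, regions, 999, seed=42)
        r2 = amova_two_level(d, pops, regions, 999, seed=42)
        assert r1 == r2


class TestMantel:
    def randdist(self, rng, n):
        x = rng.random((n, 2))
        return np.sqrt(((x[:, None] - x[None, :]) ** 2).sum(-1))

    def test_self_correlation_is_one(self, rng):
        a = self.randdist(rng, 7)
        assert mantel(a, a, 99, 0).r == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        a = self.randdist(rng, 7)
        assert mantel(a, 3 * a + 1, 99, 0).r == pytest.approx(1.0)

    def test_matches_skbio_statistic(self, rng):
        import skbio

        a, b = self.randdist(rng, 9), self.randdist(rng, 9)
        mine = mantel(a, b, 999, 0)
        r_ref, _, _ = skbio.stats.distance.mantel(
            a, b, permutations=0, alternative="two-sided"
        )
        assert mine.r == pytest.approx(r_ref)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            mantel(np.ones((4, 4)) - np.eye(4), np.ones((4, 4)) - np.eye(4), 99, 0)

    def test_bit_reproducible(self, rng):
        a, b = self.randdist(rng, 8), self.randdist(rng, 8)
        assert mantel(a, b, 999, 7) == mantel(a, b, 999, 7)


class TestPearsonWithCoordinates:
    COORDS = [GeoPoint(10, 0), GeoPoint(20, 10), GeoPoint(35, 5), GeoPoint(50, 20)]

    def test_values_equal_latitude(self):
        out = pearson_with_coordinates([c.lat for c in self.COORDS], self.COORDS)
        assert out["latitude"][0] == pytest.approx(1.0)

    def test_sign_flip_negates_r(self):
        vals = [1.0, 3.0, 2.0, 5.0]
        r_pos = pearson_with_coordinates(vals, self.COORDS)["latitude"][0]
        r_neg = pearson_with_coordinates([-v for v in vals], self.COORDS)["latitude"][0]
        assert r_neg == pytest.approx(-r_pos)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_coordinates([1, 1, 1, 1], self.COORDS)


class TestFrequencyPca:
    def test_mirror_populations_single_component(self):
        x = pd.DataFrame([[0.8, 0.2], [0.2, 0.8]])
        res = frequency_pca(x)
        assert res.explained_pct[0] == pytest.approx(100.0)

    def test_explained_variance_sums_to_100(self, rng):
        x = pd.DataFrame(rng.random((6, 5)))
        assert frequency_pca(x).explained_pct.sum() == pytest.approx(100.0)

    def test_matches_svd_oracle_on_fixture(self):
        x = pd.DataFrame(
            [[0.1, 0.5, 0.2, 0.2], [0.3, 0.3, 0.2, 0.2], [0.6, 0.1, 0.1, 0.2],
             [0.2, 0.2, 0.5, 0.1], [0.1, 0.1, 0.1, 0.7]]
        )
        res = frequency_pca(x)
        centered = x.values - x.values.mean(0)
        sv = np.linalg.svd(centered, compute_uv=False)
        ref = 100 * sv**2 / (sv**2).sum()
        assert res.explained_pct[: len(ref)] == pytest.approx(ref, abs=1e-9)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            frequency_pca(pd.DataFrame(np.ones((3, 3))))


class TestTwoProportions:
    def test_equal_large_proportions_near_one(self):
        assert two_proportion_test(50, 100, 50, 100) == pytest.approx(1.0)

    def test_extreme_table(self):
        assert two_proportion_test(0, 50, 50, 50) < 1e-10

    def test_matches_hypergeometric_enumeration(self):
        from scipy.stats import hypergeom

        k1, n1, k2, n2 = 3, 12, 9, 14
        # exhaustive two-sided Fisher: sum probabilities of tables as or less
        # likely than the observed one, margins fixed
        K, N = k1 + k2, n1 + n2
        obs = hypergeom.pmf(k1, N, K, n1)
        p_ref = sum(
            hypergeom.pmf(x, N, K, n1)
            for x in range(max(0, K - n2), min(K, n1) + 1)
            if hypergeom.pmf(x, N, K, n1) <= obs * (1 + 1e-9)
        )
        assert two_proportion_test(k1, n1, k2, n2) == pytest.approx(p_ref)

    def test_z_method_close_to_fisher_for_large_n(self):
        pf = two_proportion_test(60, 200, 40, 200)
        pz = two_proportion_test(60, 200, 40, 200, method="z")
        assert pz == pytest.approx(pf, rel=0.4)
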