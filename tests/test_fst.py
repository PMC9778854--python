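"""Pool-seq FST estimator against independent variance-components
oracles, matrix assembly, and the Mantel IBD test."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from driftmeta.errors import UndefinedStatisticError
from driftmeta.fst import (
    FstMatrix,
    distance_matrix_from_coords,
    fst_from_frequencies,
    fst_matrix,
    mantel_ibd,
    pairwise_fst,
    population_specific_fst,
)
from driftmeta.pool_diversity import PoolSample

from conftest import make_table


def wc_oracle(p1, p2, n1, n2) -> float:
    """Independent brute-force variance-components FST (ratio of averages
    of the classic a / (a + within) decomposition, per locus)."""
    num = den = 0.0
    for i in range(len(p1)):
        nt = n1[i] + n2[i]
        nc = nt - (n1[i] ** 2 + n2[i] ** 2) / nt
        pbar = (n1[i] * p1[i] + n2[i] * p2[i]) / nt
        msp = n1[i] * (p1[i] - pbar) ** 2 + n2[i] * (p2[i] - pbar) ** 2
        msg = (n1[i] * p1[i] * (1 - p1[i]) + n2[i] * p2[i] * (1 - p2[i])) \
            / (nt - 2)
        a = (msp - msg) / nc
        num += a
        den += a + msg
    return num / den


class TestPairwiseFst:
    def test_identical_pools_near_zero(self):
        """Identical depth tables give FST <= 0.01 (the small negative
        bias of the unbiased estimator)."""
        rng = np.random.default_rng(0)
        depth = 50
        alt = rng.binomial(depth, 0.3, size=10_000)
        ad = np.column_stack([depth - alt, alt])
        f, n = pairwise_fst(ad, ad, PoolSample("a", 50), PoolSample("b", 50))
        assert n == 10_000
        assert f <= 0.01  # signed bound: the bias is a small negative value
        assert abs(f) < 0.06

    def test_fixed_opposite_alleles_near_one(self):
        n_sites = 500
        ad_a = np.column_stack([np.full(n_sites, 1000), np.zeros(n_sites)])
        ad_b = np.column_stack([np.zeros(n_sites), np.full(n_sites, 1000)])
        f, _ = pairwise_fst(ad_a, ad_b, PoolSample("a", 50), PoolSample("b", 50))
        assert f > 0.98

    def test_three_site_toy_matches_oracle(self):
        """Frozen 3-site example, h=10, D=20: value equals the
        independent variance-components computation."""
        ad_a = np.array([[15, 5], [10, 10], [20, 0]], float)
        ad_b = np.array([[5, 15], [10, 10], [18, 2]], float)
        f, n = pairwise_fst(ad_a, ad_b, PoolSample("a", 5), PoolSample("b", 5))
        assert n == 3
        d = ad_a.sum(1)
        ne = 10 * d / (10 + d - 1)
        expected = wc_oracle(ad_a[:, 1] / d, ad_b[:, 1] / d, ne, ne)
        assert f == pytest.approx(expected, abs=1e-12)
        assert f == pytest.approx(0.07864900346103353, abs=1e-12)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(1)
        depth = rng.integers(15, 60, size=200)
        a1 = rng.binomial(depth, 0.4)
        a2 = rng.binomial(depth, 0.6)
        ad_a = np.column_stack([depth - a1, a1]).astype(float)
        ad_b = np.column_stack([depth - a2, a2]).astype(float)
        f, _ = pairwise_fst(ad_a, ad_b, PoolSample("a", 20), PoolSample("b", 30))
        ne1 = 40 * depth / (40 + depth - 1)
        ne2 = 60 * depth / (60 + depth - 1)
        expected = wc_oracle(a1 / depth, a2 / depth, ne1, ne2)
        assert f == pytest.approx(expected, abs=1e-12)

    def test_infinite_depth_limit_matches_genotype_estimator(self):
        """At depth 1e4 the read-count estimator agrees with the
        allele-count (individual-genotype) Weir-Cockerham estimator
        within 1e-3."""
        rng = np.random.default_rng(2)
        n_sites, h = 20_000, 100
        anc = rng.uniform(0.15, 0.85, n_sites)
        fst_true = 0.10
        a = anc * (1 - fst_true) / fst_true
        b = (1 - anc) * (1 - fst_true) / fst_true
        c1 = rng.binomial(h, rng.beta(a, b))
        c2 = rng.binomial(h, rng.beta(a, b))
        genotype_based = wc_oracle(
            c1 / h, c2 / h, np.full(n_sites, float(h)),
            np.full(n_sites, float(h)))
        depth = 10_000
        r1 = rng.binomial(depth, c1 / h)
        r2 = rng.binomial(depth, c2 / h)
        pool_based, _ = pairwise_fst(
            np.column_stack([depth - r1, r1]),
            np.column_stack([depth - r2, r2]),
            PoolSample("a", 50), PoolSample("b", 50))
        assert pool_based == pytest.approx(genotype_based, abs=1e-3)

    def test_no_usable_sites_errors(self):
        ad = np.zeros((5, 2))
        with pytest.raises(UndefinedStatisticError):
            pairwise_fst(ad, ad, PoolSample("a", 10), PoolSample("b", 10))


class TestFstMatrix:
    def _table(self, seed=0, n_sites=400):
        rng = np.random.default_rng(seed)
        depth = 40
        p = {"x": 0.3, "y": 0.3, "z": 0.8}
        ad = {s: [(depth - a, a) for a in rng.binomial(depth, p[s], n_sites)]
              for s in p}
        return make_table(ad, pos=np.arange(1, n_sites + 1))

    def test_identical_samples_near_zero(self):
        rng = np.random.default_rng(3)
        alt = rng.binomial(40, 0.4, 2000)
        ads = [(40 - a, a) for a in alt]
        table = make_table({"a": ads, "b": ads, "c": ads},
                           pos=np.arange(1, 2001))
        pools = [PoolSample(s, 25) for s in "abc"]
        m = fst_matrix(table, pools)
        off = m.condensed()
        # identical tables: small negative bias of order -1/n_eff
        assert np.all(off <= 0.01)
        assert np.all(np.abs(off) < 0.06)

    def test_outlier_sample_detected(self):
        table = self._table()
        pools = [PoolSample(s, 25) for s in "xyz"]
        m = fst_matrix(table, pools)
        scores = population_specific_fst(m)
        assert scores.idxmax() == "z"

    def test_sample_order_permutation_consistency(self):
        table = self._table(seed=4)
        pools = [PoolSample(s, 25) for s in "xyz"]
        m1 = fst_matrix(table, pools).values
        m2 = fst_matrix(table, list(reversed(pools))).values
        assert m1.loc["x", "z"] == pytest.approx(m2.loc["x", "z"])
        assert list(m2.index) == ["z", "y", "x"]

    def test_masked_sites_excluded_per_pair(self):
        table = self._table(seed=5, n_sites=100)
        table.mask[:50, 0] = True  # half the sites masked in sample x
        pools = [PoolSample(s, 25) for s in "xyz"]
        m = fst_matrix(table, pools)
        assert m.n_sites.loc["x", "y"] == 50
        assert m.n_sites.loc["y", "z"] == 100

    def test_matrix_invariants_asserted(self):
        bad = pd.DataFrame([[0.0, 0.1], [0.2, 0.0]], index=["a", "b"],
                           columns=["a", "b"])
        with pytest.raises(AssertionError):
            FstMatrix(values=bad, n_sites=bad)


class TestPopulationSpecificFst:
    def test_constant_matrix(self):
        v = pd.DataFrame(0.2 * (1 - np.eye(4)),
                         index=list("abcd"), columns=list("abcd"))
        m = FstMatrix(values=v, n_sites=v * 0 + 1)
        assert np.allclose(population_specific_fst(m), 0.2)

    def test_requires_three_samples(self):
        v = pd.DataFrame(np.zeros((2, 2)), index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError):
            population_specific_fst(FstMatrix(values=v, n_sites=v))


class TestFounderDemesThroughReads:
    def test_single_founder_demes_read_level_fst_half(self):
        """Age-0 single-founder demes (frequencies in {0, 1/2, 1} drawn
        from a p=0.5 source) re-estimated from pool-seq read counts give
        mean FST near the propagule-model expectation 0.5."""
        rng = np.random.default_rng(6)
        n_demes, n_loci, pool, depth = 40, 800, 50, 100
        dosage = rng.binomial(2, 0.5, size=(n_demes, n_loci))
        freqs = dosage / 2.0
        # true frequency-level FST
        assert fst_from_frequencies(freqs) == pytest.approx(0.5, abs=0.03)
        pools = [PoolSample(f"d{i}", pool) for i in range(n_demes)]
        counts = rng.binomial(2 * pool, freqs)  # pool sampling
        alt = rng.binomial(depth, counts / (2 * pool))
        ad = {f"d{i}": [(depth - alt[i, l], alt[i, l])
                        for l in range(n_loci)] for i in range(n_demes)}
        table = make_table(ad, pos=np.arange(1, n_loci + 1))
        m = fst_matrix(table, pools)
        assert np.nanmean(m.condensed()) == pytest.approx(0.5, abs=0.03)


class TestMantel:
    def _coords(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return np.column_stack([59.8 + rng.random(n) * 0.01,
                                23.2 + rng.random(n) * 0.02])

    def test_monotone_relation_detected(self):
        coords = self._coords(20)
        dist = distance_matrix_from_coords(coords)
        fst = np.log10(dist.values + 1) * 0.02
        np.fill_diagonal(fst, 0)
        r, p = mantel_ibd(pd.DataFrame(fst), dist, n_perm=999, seed=1)
        assert r > 0.9
        assert p <= 0.01

    def test_identical_matrices_perfect_correlation(self):
        coords = self._coords(12, seed=1)
        dist = distance_matrix_from_coords(coords)
        logd = np.log10(dist.values + (dist.values == 0))
        np.fill_diagonal(logd, 0)
        r, _ = mantel_ibd(pd.DataFrame(logd), dist, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_constant_matrix_undefined(self):
        coords = self._coords(8, seed=2)
        dist = distance_matrix_from_coords(coords)
        const = pd.DataFrame(np.full((8, 8), 0.1) - 0.1 * np.eye(8))
        with pytest.raises(UndefinedStatisticError):
            mantel_ibd(const, dist, n_perm=99)

    def test_type_one_error_calibrated(self):
        """Independent matrices: rejection rate at alpha = 0.05 is close
        to nominal over 200 simulated draws."""
        rng = np.random.default_rng(7)
        n = 12
        coords = self._coords(n, seed=3)
        dist = distance_matrix_from_coords(coords)
        rejections = 0
        n_draws = 200
        for k in range(n_draws):
            y = rng.random((n, n)) * 0.2
            y = (y + y.T) / 2
            np.fill_diagonal(y, 0)
            _, p = mantel_ibd(pd.DataFrame(y), dist, n_perm=99, seed=k)
            rejections += p <= 0.05
        rate = rejections / n_draws
        assert 0.01 <= rate <= 0.10

    def test_requires_matching_shapes_and_perms(self):
        coords = self._coords(5, seed=4)
        dist = distance_matrix_from_coords(coords)
        with pytest.raises(ValueError):
            mantel_ibd(pd.DataFrame(np.zeros((4, 4))), dist)
        with pytest.raises(ValueError):
            mantel_ibd(pd.DataFrame(np.zeros((5, 5))), dist, n_perm=10)


def test_fst_from_frequencies_founder_theory():
    """Among-deme variance pq/(2k) over total pq: k founders give
    FST = 1/(2k)."""
    rng = np.random.default_rng(8)
    for k in (1, 2, 4):
        dosage = rng.binomial(2 * k, 0.5, size=(400, 1500))
        f = fst_from_frequencies(dosage / (2 * k))
        assert f == pytest.approx(1 / (2 * k), abs=0.02)
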