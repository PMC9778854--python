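"""Propagule-model metapopulation dynamics and pool-seq emission."""

from __future__ import annotations

import numpy as np
import pytest

from driftmeta.errors import ConfigurationError
from driftmeta.fst import fst_from_frequencies
from driftmeta.metapop import (
    MetapopConfig,
    PoolseqEmission,
    default_coords,
    emit_poolseq,
    founder_fst_experiment,
    initial_state,
    run_metapop,
    step_year,
)


def small_config(**kw) -> MetapopConfig:
    base = dict(n_patches=40, n_loci=100, years=10, seed=1)
    base.update(kw)
    return MetapopConfig(**base)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"extinction_rate": 1.5}, {"colonization_rate": -0.1},
        {"single_founder_prob": 2.0}, {"n_loci": 0}, {"deme_size": 0},
    ])
    def test_rejects(self, kwargs):
        with pytest.raises(ConfigurationError):
            MetapopConfig(**kwargs)

    def test_coords_shape_checked(self):
        with pytest.raises(ConfigurationError):
            MetapopConfig(n_patches=5, coords=np.zeros((4, 2)))


class TestStepYear:
    def test_frozen_system_keeps_frequencies_and_ages_increase(self):
        """No extinction, no migration, near-infinite deme size: occupied
        frequencies stay (almost) constant and ages strictly increase."""
        cfg = small_config(extinction_rate=0.0, colonization_rate=0.0,
                           migration_rate=0.0, deme_size=10_000_000)
        rng = np.random.default_rng(0)
        state = initial_state(cfg, rng)
        occ = np.arange(10)
        state.occupied[occ] = True
        state.freqs[occ] = rng.random((10, cfg.n_loci))
        state.age[occ] = 3
        before = state.freqs[occ].copy()
        for _ in range(4):
            state = step_year(state, cfg, rng)
        np.testing.assert_allclose(state.freqs[occ], before, atol=2e-3)
        assert np.all(state.age[occ] == 7)

    def test_pure_extinction_empties_the_system(self):
        cfg = small_config(extinction_rate=0.5, colonization_rate=0.0)
        rng = np.random.default_rng(2)
        state = initial_state(cfg, rng)
        state.occupied[:] = True
        state.freqs[:] = 0.5
        counts = [state.occupied.sum()]
        for _ in range(40):
            state = step_year(state, cfg, rng)
            counts.append(state.occupied.sum())
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        assert counts[-1] == 0

    def test_quasi_equilibrium_occupancy(self):
        """At the stated turnover rates the system persists near the
        two-state Markov equilibrium c/(c+e) = 20% occupancy, and the
        whole system survives 100 years in >= 90% of runs."""
        survived = 0
        finals = []
        for s in range(30):
            cfg = MetapopConfig(n_patches=100, n_loci=20, years=100, seed=s)
            state = run_metapop(cfg)
            finals.append(state.occupancy_fraction)
            survived += state.occupied.any()
        assert survived >= 27
        assert 0.10 < np.mean(finals) < 0.35

    def test_new_colonists_have_age_zero_and_valid_freqs(self):
        cfg = small_config(colonization_rate=1.0, extinction_rate=0.0)
        rng = np.random.default_rng(3)
        state = initial_state(cfg, rng)
        state = step_year(state, cfg, rng)  # Beta fallback founding
        assert state.occupied.all()
        assert np.all(state.age == 0)
        assert not np.isnan(state.freqs).any()
        # single diploid founders: frequencies exactly in {0, 1/2, 1}
        vals = np.unique(state.freqs[state.founder_counts == 1])
        assert set(np.round(vals, 6)).issubset({0.0, 0.5, 1.0})

    def test_seed_determinism(self):
        cfg = small_config(seed=11)
        s1 = run_metapop(cfg)
        s2 = run_metapop(cfg)
        np.testing.assert_array_equal(s1.occupied, s2.occupied)
        np.testing.assert_array_equal(s1.age, s2.age)
        np.testing.assert_allclose(
            s1.freqs[s1.occupied], s2.freqs[s2.occupied])


class TestFounderFst:
    def test_single_founder_half(self):
        """Propagule colonization by one diploid founder: FST = 0.5."""
        cfg = MetapopConfig(n_patches=10, n_loci=1000)
        f = founder_fst_experiment(cfg, 500, np.random.default_rng(0),
                                   source_freq=0.5)
        assert f == pytest.approx(0.5, abs=0.02)

    def test_two_founders_quarter(self):
        cfg = MetapopConfig(n_patches=10, n_loci=1000)
        f = founder_fst_experiment(cfg, 500, np.random.default_rng(1),
                                   source_freq=0.5, n_founders=2)
        assert f == pytest.approx(0.25, abs=0.02)

    def test_no_bottleneck_no_differentiation(self):
        """Founding by (effectively) the whole source population leaves
        demes undifferentiated."""
        cfg = MetapopConfig(n_patches=10, n_loci=1000)
        f = founder_fst_experiment(cfg, 200, np.random.default_rng(2),
                                   source_freq=0.5, n_founders=500)
        assert abs(f) < 0.01

    def test_monotone_in_founder_number(self):
        """FST ~ 1/(2k): strictly decreasing over k = 1, 2, 4, 8."""
        cfg = MetapopConfig(n_patches=10, n_loci=2000)
        vals = [
            founder_fst_experiment(cfg, 300, np.random.default_rng(3 + k),
                                   source_freq=0.5, n_founders=k)
            for k in (1, 2, 4, 8)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        for k, v in zip((1, 2, 4, 8), vals):
            assert v == pytest.approx(1 / (2 * k), abs=0.02)

    def test_requires_two_demes(self):
        cfg = MetapopConfig(n_patches=10, n_loci=10)
        with pytest.raises(ValueError):
            founder_fst_experiment(cfg, 1, np.random.default_rng(0))


class TestHeterozygosityBottleneck:
    def test_new_deme_heterozygosity_halved(self):
        """A single diploid founder halves expected heterozygosity
        relative to its source pool."""
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, 2000)
        source_h = 2 * p * (1 - p)
        dosages = rng.binomial(2, p, size=(500, 2000))
        deme_h = 2 * (dosages / 2) * (1 - dosages / 2)
        assert deme_h.mean() == pytest.approx(source_h.mean() / 2, rel=0.02)


class TestEmission:
    def _founded_state(self, freqs, cfg, rng):
        state = initial_state(cfg, rng)
        k = freqs.shape[0]
        state.occupied[:k] = True
        state.freqs[:k] = freqs
        state.founder_counts[:k] = 1
        return state

    def test_read_frequency_converges_with_depth(self):
        """With no miscalls, mean |read freq - pool freq| shrinks as
        depth grows (law of large numbers)."""
        cfg = small_config(n_patches=5, n_loci=400)
        rng = np.random.default_rng(5)
        freqs = rng.uniform(0.2, 0.8, (3, cfg.n_loci))
        errs = {}
        for depth in (20, 2000):
            state = self._founded_state(freqs, cfg, np.random.default_rng(6))
            table, _ = emit_poolseq(
                state, PoolseqEmission(pool_size=2000, depth_mean=depth,
                                       error_rate=0.0),
                np.random.default_rng(7))
            dp = table.ad_ref + table.ad_alt
            with np.errstate(invalid="ignore"):
                rf = np.where(dp > 0, table.ad_alt / dp, np.nan)
            errs[depth] = np.nanmean(np.abs(rf.T - freqs))
        assert errs[2000] < errs[20]
        assert errs[2000] < 0.02

    def test_single_founder_pond_read_frequencies_trimodal(self):
        """Pooling one diploid individual: read frequencies concentrate
        near {0, 1/2, 1}."""
        cfg = small_config(n_patches=4, n_loci=300)
        rng = np.random.default_rng(8)
        founder_freqs = rng.choice([0.0, 0.5, 1.0], size=(1, cfg.n_loci))
        state = self._founded_state(founder_freqs, cfg, rng)
        table, _ = emit_poolseq(
            state, PoolseqEmission(pool_size=1, depth_mean=200,
                                   error_rate=0.0),
            np.random.default_rng(9))
        dp = (table.ad_ref + table.ad_alt)[:, 0]
        rf = table.ad_alt[:, 0][dp > 0] / dp[dp > 0]
        nearest = np.min(np.abs(rf[:, None] - np.array([0, 0.5, 1.0])), axis=1)
        assert np.quantile(nearest, 0.95) < 0.12

    def test_emission_determinism_and_covariates(self):
        cfg = small_config(seed=12, years=15)
        state = run_metapop(cfg)
        t1, c1 = emit_poolseq(state, PoolseqEmission(), np.random.default_rng(1))
        t2, c2 = emit_poolseq(state, PoolseqEmission(), np.random.default_rng(1))
        np.testing.assert_array_equal(t1.ad_alt, t2.ad_alt)
        assert (c1 == c2).all().all()
        assert {"pond", "lat", "lon", "age", "nn2", "infection"} <= set(c1.columns)
        assert (c1["age"] >= 0).all()

    def test_empty_system_raises(self):
        cfg = small_config()
        state = initial_state(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            emit_poolseq(state, PoolseqEmission(), np.random.default_rng(0))


def test_young_demes_more_differentiated_than_old():
    """Newly founded demes carry the full founder-bottleneck signal;
    immigration erodes it with age (young FST > old FST)."""
    cfg = MetapopConfig(seed=42)
    state = run_metapop(cfg)
    occ = np.flatnonzero(state.occupied)
    young = occ[state.age[occ] <= 2]
    old = occ[state.age[occ] > 2]
    assert young.size >= 2 and old.size >= 2

    def mean_pairwise(idx):
        vals = []
        for i in range(idx.size):
            for j in range(i + 1, idx.size):
                vals.append(fst_from_frequencies(
                    state.freqs[[idx[i], idx[j]]]))
        return np.mean(vals)

    assert mean_pairwise(young) > mean_pairwise(old)


def test_migration_conserves_mean_frequency():
    """Closed system (no extinction/colonization), huge demes: migration
    only redistributes alleles, so the mean frequency over demes stays a
    convex combination of the initial values (within sampling noise)."""
    cfg = small_config(extinction_rate=0.0, colonization_rate=0.0,
                       migration_rate=20.0, deme_size=1_000_000,
                       n_loci=500)
    rng = np.random.default_rng(13)
    state = initial_state(cfg, rng)
    occ = np.arange(12)
    state.occupied[occ] = True
    state.freqs[occ] = rng.uniform(0.2, 0.8, (12, cfg.n_loci))
    before = state.freqs[occ].mean()
    lo, hi = state.freqs[occ].min(), state.freqs[occ].max()
    for _ in range(10):
        state = step_year(state, cfg, rng)
    after = state.freqs[occ]
    # immigrant genotype sampling adds binomial noise of order 1/(2m),
    # so the hull is respected only up to that noise
    assert lo - 0.02 <= after.min() and after.max() <= hi + 0.02
    assert abs(after.mean() - before) < 0.01


def test_default_coords_archipelago_structure():
    coords = default_coords(300, np.random.default_rng(0))
    assert coords.shape == (300, 2)
    assert np.ptp(coords[:, 0]) < 0.05 and np.ptp(coords[:, 1]) < 0.08
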