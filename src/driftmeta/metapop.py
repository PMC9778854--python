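"""Propagule-model metapopulation simulator and pool-seq data generator.

Habitat patches (rock pools) on a map undergo yearly extinction,
colonization, migration and drift:

* each occupied patch goes extinct with probability ``extinction_rate``
  (default 0.20/year);
* each empty patch is colonized with probability ``colonization_rate``
  (default 0.05/year), usually (``single_founder_prob``, default 0.90) by a
  single diploid founder that then expands clonally — the propagule model,
  under which newly founded demes are expected to show FST near 0.5;
* occupied patches receive immigrants at a rate that scales with their
  kernel-weighted connectivity (exponential distance decay), so isolated
  patches both receive fewer immigrants and stay differentiated longer;
* allele frequencies drift by binomial resampling at 2 x ``deme_size``.

Colonists and immigrants are individuals sampled from a source patch
chosen with probability proportional to the dispersal kernel, with
genotypes drawn at Hardy-Weinberg proportions from the source patch's
allele frequencies. When no occupied source patch exists, founder
genotypes fall back to the metapopulation-wide Beta(alpha, beta) frequency
distribution.

:func:`emit_poolseq` converts a state into pool-seq style data: pooled
individuals, overdispersed read depths, and read counts with optional
miscalls, emitted as a :class:`~driftmeta.pool_diversity.VariantTable`
plus a pond-covariate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError
from .fst import fst_from_frequencies
from .geo import haversine_matrix
from .pool_diversity import PoolSample, VariantTable

__all__ = [
    "MetapopConfig",
    "MetapopState",
    "PoolseqEmission",
    "initial_state",
    "step_year",
    "run_metapop",
    "founder_fst_experiment",
    "emit_poolseq",
    "default_coords",
]


def default_coords(n_patches: int, rng: np.random.Generator) -> np.ndarray:
    """Random patch coordinates on a ~3 x 3 km archipelago-like map.

    Centered on 59.82 N, 23.25 E; patches are clustered onto many small
    island-like groups (roughly a dozen patches each, tens of meters
    apart within an island, hundreds of meters between islands), so the
    dispersal kernel produces both well-connected and genuinely isolated
    ponds.
    """
    n_islands = max(4, n_patches // 12)
    centers_lat = 59.82 + rng.uniform(-0.013, 0.013, n_islands)
    centers_lon = 23.25 + rng.uniform(-0.026, 0.026, n_islands)
    which = rng.integers(n_islands, size=n_patches)
    lat = centers_lat[which] + rng.normal(0, 0.0003, n_patches)
    lon = centers_lon[which] + rng.normal(0, 0.0006, n_patches)
    # ~20% of patches sit on scattered skerries rather than the main
    # islands, giving a continuum from well-connected to isolated ponds
    lone = rng.random(n_patches) < 0.2
    lat[lone] = 59.82 + rng.uniform(-0.013, 0.013, int(lone.sum()))
    lon[lone] = 23.25 + rng.uniform(-0.026, 0.026, int(lone.sum()))
    return np.column_stack([lat, lon])


@dataclass
class MetapopConfig:
    """Metapopulation simulation parameters.

    Defaults follow the focal rock-pool system: ~20% of occupied ponds go
    extinct per year, ~5% of empty ponds are colonized per year, ~90% of
    colonizations are by a single diploid founder. ``n_patches`` defaults
    to 300 so that the quasi-equilibrium occupancy (~c/(c+e) = 20%) yields
    on the order of 60 occupied ponds, the size of a realistic survey.
    ``migration_rate`` and ``deme_size`` are free parameters; the defaults
    (15 effective immigrants/pond/year into demes of 100) put the system
    in the empirically observed regime where founder differentiation
    (FST ~0.5-0.6) erodes to ~0.35-0.4 over one to two decades.
    """

    n_patches: int = 300
    coords: np.ndarray | None = None
    extinction_rate: float = 0.20
    colonization_rate: float = 0.05
    single_founder_prob: float = 0.90
    migration_rate: float = 15.0
    migration_decay: float = 1.0 / 200.0  # per meter
    n_loci: int = 1000
    source_freq_alpha: float = 1.0
    source_freq_beta: float = 1.0
    deme_size: int = 100
    years: int = 30
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("extinction_rate", "colonization_rate", "single_founder_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.n_loci < 1:
            raise ConfigurationError("n_loci must be >= 1")
        if self.deme_size < 1:
            raise ConfigurationError("deme_size must be >= 1")
        if self.migration_rate < 0 or self.migration_decay < 0:
            raise ConfigurationError("migration parameters must be >= 0")
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (self.n_patches, 2):
                raise ConfigurationError("coords must be (n_patches, 2) lat/lon")


@dataclass
class MetapopState:
    """Patch occupancy, ages, coordinates and allele frequencies.

    ``freqs[i]`` is undefined (NaN) for empty patches. ``age`` is 0 in the
    founding year. ``founder_counts`` records the number of diploid
    founders of the current occupancy spell (0 for empty patches).
    """

    occupied: np.ndarray
    age: np.ndarray
    coords: np.ndarray
    freqs: np.ndarray
    founder_counts: np.ndarray
    founder_events: list[dict] = field(default_factory=list)
    year: int = 0

    @property
    def n_patches(self) -> int:
        return self.occupied.size

    @property
    def occupancy_fraction(self) -> float:
        return float(self.occupied.mean())


def initial_state(config: MetapopConfig, rng: np.random.Generator) -> MetapopState:
    """All patches empty; colonization bootstraps from the Beta source."""
    coords = (config.coords if config.coords is not None
              else default_coords(config.n_patches, rng))
    n = config.n_patches
    return MetapopState(
        occupied=np.zeros(n, dtype=bool),
        age=np.zeros(n, dtype=np.int64),
        coords=np.asarray(coords, dtype=float),
        freqs=np.full((n, config.n_loci), np.nan),
        founder_counts=np.zeros(n, dtype=np.int64),
    )


def _kernel(dist_row: np.ndarray, decay: float) -> np.ndarray:
    return np.exp(-decay * dist_row)


def _sample_founder_freq(
    target: int,
    n_founders: int,
    occupied_idx: np.ndarray,
    freqs: np.ndarray,
    dist: np.ndarray,
    config: MetapopConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Frequency vector of a newly founded deme (founder dosages / 2k).

    Under the propagule model all founders of one colonization event
    derive from a single source patch, chosen with probability
    proportional to the dispersal kernel; founder genotypes are sampled
    at Hardy-Weinberg proportions from that patch's frequencies (or from
    the Beta source distribution when no occupied patch exists).
    """
    if occupied_idx.size:
        w = _kernel(dist[target, occupied_idx], config.migration_decay)
        tot = w.sum()
        if tot > 0:
            src = occupied_idx[rng.choice(occupied_idx.size, p=w / tot)]
        else:  # all sources beyond kernel reach: uniform choice
            src = occupied_idx[rng.integers(occupied_idx.size)]
        p = freqs[src]
    else:  # documented fallback: Beta-distributed source pool
        p = rng.beta(config.source_freq_alpha, config.source_freq_beta,
                     config.n_loci)
    dosage_sum = rng.binomial(2 * n_founders, p)
    return dosage_sum / (2.0 * n_founders)


def step_year(
    state: MetapopState, config: MetapopConfig, rng: np.random.Generator
) -> MetapopState:
    """Advance the metapopulation by one year.

    Order of events: extinction -> colonization -> migration -> drift ->
    age increment. Patches founded this year keep age 0 and skip migration
    and drift (the founding year is pure clonal expansion of the
    founders).
    """
    n = state.n_patches
    occ = state.occupied.copy()
    age = state.age.copy()
    freqs = state.freqs.copy()
    founders = state.founder_counts.copy()
    dist = haversine_matrix(state.coords)
    year = state.year + 1
    events = list(state.founder_events)

    # (1) extinction
    dies = occ & (rng.random(n) < config.extinction_rate)
    occ[dies] = False
    freqs[dies] = np.nan
    age[dies] = 0
    founders[dies] = 0

    # (2) colonization of empty patches from the survivors
    survivors = np.flatnonzero(occ)
    empty = np.flatnonzero(~occ)
    colonized = empty[rng.random(empty.size) < config.colonization_rate]
    for i in colonized:
        k = 1 if rng.random() < config.single_founder_prob else 2
        freqs[i] = _sample_founder_freq(i, k, survivors, freqs, dist, config, rng)
        founders[i] = k
        age[i] = 0
        events.append({"year": year, "patch": int(i), "n_founders": k})
    occ[colonized] = True
    is_new = np.zeros(n, dtype=bool)
    is_new[colonized] = True

    # (3) migration into established patches, intensity ~ connectivity
    established = np.flatnonzero(occ & ~is_new)
    if established.size >= 2 and config.migration_rate > 0:
        kern = np.exp(-config.migration_decay * dist[np.ix_(established, established)])
        np.fill_diagonal(kern, 0.0)
        conn = kern.sum(axis=1)
        mean_conn = conn.mean()
        lam = (config.migration_rate * conn / mean_conn if mean_conn > 0
               else np.zeros_like(conn))
        n_imm = np.minimum(rng.poisson(lam), config.deme_size)
        for a, i in enumerate(established):
            m = int(n_imm[a])
            if m == 0:
                continue
            w = kern[a]
            if w.sum() == 0:
                continue
            # immigrant genotypes from the kernel-weighted migrant pool
            p_mix = np.clip(w @ freqs[established] / w.sum(), 0.0, 1.0)
            dosages = rng.binomial(2 * m, p_mix)
            freqs[i] = ((config.deme_size - m) * freqs[i] + dosages / 2.0) \
                / config.deme_size

    # (4) binomial drift in established patches
    if established.size:
        two_k = 2 * config.deme_size
        freqs[established] = rng.binomial(
            two_k, freqs[established]
        ) / float(two_k)

    # (5) ages increment (newly founded stay 0)
    age[occ & ~is_new] += 1

    return MetapopState(
        occupied=occ, age=age, coords=state.coords, freqs=freqs,
        founder_counts=founders, founder_events=events, year=year,
    )


def run_metapop(
    config: MetapopConfig, rng: np.random.Generator | None = None
) -> MetapopState:
    """Run from an all-empty map for ``config.years`` years."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    state = initial_state(config, rng)
    for _ in range(config.years):
        state = step_year(state, config, rng)
    return state


def founder_fst_experiment(
    config: MetapopConfig,
    n_founded: int,
    rng: np.random.Generator,
    source_freq: float | np.ndarray | None = None,
    n_founders: int = 1,
) -> float:
    """Mean multi-locus FST among newly founded demes.

    Each deme is founded by ``n_founders`` diploid colonizers drawn at
    Hardy-Weinberg proportions from a common source pool; the deme
    frequency is the founder allele dosage over ``2 * n_founders``
    (clonal expansion copies the founders faithfully). FST is the
    ratio-of-averages estimator over loci treating each deme's frequency
    as exactly known. Under the propagule model with k founders the
    expectation is ``1/(2k)`` — 0.5 for single-founder colonization.

    ``source_freq`` fixes the source allele frequencies (scalar or
    per-locus array); by default they are drawn from the configured
    Beta distribution.
    """
    if n_founded < 2:
        raise ValueError("need at least 2 founded demes")
    if source_freq is None:
        p = rng.beta(config.source_freq_alpha, config.source_freq_beta,
                     config.n_loci)
    else:
        p = np.broadcast_to(np.asarray(source_freq, dtype=float),
                            (config.n_loci,))
    dosages = rng.binomial(2 * n_founders, p,
                           size=(n_founded, config.n_loci))
    freqs = dosages / (2.0 * n_founders)
    return fst_from_frequencies(freqs)


@dataclass
class PoolseqEmission:
    """Pool-seq sampling model: individuals pooled, then reads sampled."""

    pool_size: int = 50
    depth_mean: float = 30.0
    depth_dispersion: float = 10.0
    error_rate: float = 0.001

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ConfigurationError("pool_size must be >= 1")
        if self.depth_mean <= 0:
            raise ConfigurationError("depth_mean must be > 0")
        if self.depth_dispersion <= 0:
            raise ConfigurationError("depth_dispersion must be > 0")
        if not 0.0 <= self.error_rate < 0.5:
            raise ConfigurationError("error_rate must lie in [0, 0.5)")


_BASES = np.array(list("ACGT"))


def emit_poolseq(
    state: MetapopState,
    emission: PoolseqEmission,
    rng: np.random.Generator,
) -> tuple[VariantTable, pd.DataFrame]:
    """Emit pool-seq read counts and a covariate table for occupied ponds.

    For each occupied patch and locus: pool allele count ~
    Binomial(2 * pool_size, p); read depth ~ NegBinomial(mean,
    dispersion); alt reads ~ Binomial(depth, pool frequency) with
    symmetric miscalls at ``error_rate``. Covariates: coordinates, age,
    NN2-ready coordinates, plus simulated pond depth / surface area and a
    random infection flag (pure noise by design — only age and isolation
    carry built-in effects).
    """
    occ = np.flatnonzero(state.occupied)
    if occ.size == 0:
        raise ValueError("no occupied patches to sample")
    if np.isnan(state.freqs[occ]).any():
        raise DataIntegrityError("occupied patch with undefined frequencies")
    n_pond = occ.size
    n_loci = state.freqs.shape[1]
    names = [f"pond_{int(i):03d}" for i in occ]

    two_n = 2 * emission.pool_size
    pool_counts = rng.binomial(two_n, state.freqs[occ])
    pool_freq = pool_counts / float(two_n)
    k = emission.depth_dispersion
    m = emission.depth_mean
    depth = rng.negative_binomial(k, k / (k + m), size=(n_pond, n_loci))
    e = emission.error_rate
    read_p = pool_freq * (1 - e) + (1 - pool_freq) * e
    alt = rng.binomial(depth, read_p)
    ref = depth - alt

    ref_idx = rng.integers(4, size=n_loci)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_loci)) % 4
    ref_base = _BASES[ref_idx]
    alt_base = _BASES[alt_idx]

    table = VariantTable.from_arrays(
        chrom=np.array(["sim_1"] * n_loci, dtype=object),
        pos=np.arange(1, n_loci + 1) * 100,
        ref=ref_base.astype(object),
        alt=alt_base.astype(object),
        samples=names,
        ad_ref=ref.T,
        ad_alt=alt.T,
    )

    dist = haversine_matrix(state.coords[occ])
    np.fill_diagonal(dist, np.inf)
    nn2 = np.sort(dist, axis=1)[:, :2].mean(axis=1) if n_pond >= 3 \
        else np.full(n_pond, np.nan)
    covariates = pd.DataFrame({
        "pond": names,
        "lat": state.coords[occ, 0],
        "lon": state.coords[occ, 1],
        "age": state.age[occ],
        "nn2": nn2,
        "depth_m": np.round(rng.lognormal(-1.2, 0.5, n_pond), 3),
        "surface_area_m2": np.round(rng.lognormal(0.7, 0.8, n_pond), 3),
        "infection": rng.integers(2, size=n_pond),
        "n_founders": state.founder_counts[occ],
    })
    return table, covariates


def pools_for_emission(names: list[str], emission: PoolseqEmission) -> list[PoolSample]:
    return [PoolSample(n, emission.pool_size) for n in names]
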