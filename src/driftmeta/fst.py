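"""Pairwise and population-specific FST from pooled read counts, and
isolation-by-distance testing.

The pairwise estimator is a pool-seq method-of-moments (ANOVA) estimator:
read-count allele frequencies enter Weir-Cockerham-style mean squares with
an effective sample size per pool of

    n_eff = h * D / (h + D - 1)

where ``h`` is the haploid pool size (2 x individuals) and ``D`` the read
depth at the site — the double-binomial correction for sampling
individuals into the pool and then reads from the pool. The multi-locus
value is a ratio of averages (sum of among-population components over sum
of totals), so weakly informative sites cannot dominate; negative per-site
components are kept as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError
from .geo import haversine_matrix
from .pool_diversity import PoolSample, VariantTable

__all__ = [
    "FstMatrix",
    "pairwise_fst",
    "fst_matrix",
    "population_specific_fst",
    "mantel_ibd",
]


@dataclass
class FstMatrix:
    """Symmetric pairwise FST matrix with per-pair site counts."""

    values: pd.DataFrame
    n_sites: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        assert np.allclose(np.diag(v), 0.0), "diagonal must be 0"
        assert np.allclose(v, v.T, equal_nan=True), "matrix must be symmetric"

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values in pair order."""
        v = self.values.to_numpy(dtype=float)
        iu = np.triu_indices_from(v, k=1)
        return v[iu]


def _n_eff(h: float, depth: np.ndarray) -> np.ndarray:
    return h * depth / (h + depth - 1.0)


def _components(p1, p2, n1, n2):
    """Per-site Weir-Cockerham variance components for two populations:
    among-population component ``a`` and total ``a + within``; these are
    summed over loci before the final division (ratio of averages)."""
    n_tot = n1 + n2
    p_bar = (n1 * p1 + n2 * p2) / n_tot
    msa = n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2  # r - 1 = 1
    msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (n_tot - 2.0)
    n_c = n_tot - (n1**2 + n2**2) / n_tot  # / (r - 1)
    a = (msa - msw) / n_c
    return a, a + msw


def pairwise_fst(
    ad_a: np.ndarray,
    ad_b: np.ndarray,
    pool_a: PoolSample,
    pool_b: PoolSample,
    min_depth: int = 2,
) -> tuple[float, int]:
    """Multi-locus FST between two pools from per-site [ref, alt] depths.

    ``ad_a``/``ad_b`` are (n_sites, 2) arrays over the *same* sites.
    Returns (FST, number of sites used). Sites with depth < ``min_depth``
    (>= 2, so the mean squares are defined) in either pool are dropped;
    zero usable sites is an error.
    """
    ad_a = np.asarray(ad_a, dtype=float)
    ad_b = np.asarray(ad_b, dtype=float)
    if ad_a.shape != ad_b.shape or ad_a.ndim != 2 or ad_a.shape[1] != 2:
        raise ValueError("allele-depth arrays must both be (n_sites, 2)")
    d1 = ad_a.sum(axis=1)
    d2 = ad_b.sum(axis=1)
    ok = (d1 >= max(min_depth, 2)) & (d2 >= max(min_depth, 2))
    if not ok.any():
        raise UndefinedStatisticError("no shared sites with read support")
    p1 = ad_a[ok, 1] / d1[ok]
    p2 = ad_b[ok, 1] / d2[ok]
    n1 = _n_eff(pool_a.haploid_size, d1[ok])
    n2 = _n_eff(pool_b.haploid_size, d2[ok])
    num, den = _components(p1, p2, n1, n2)
    total = den.sum()
    if total == 0:
        raise UndefinedStatisticError("all sites monomorphic in both pools")
    return float(num.sum() / total), int(ok.sum())


def fst_matrix(table: VariantTable, pools: list[PoolSample]) -> FstMatrix:
    """All pairwise FSTs on the intersection of unmasked sites per pair."""
    if len(pools) < 2:
        raise ValueError("need at least 2 samples")
    names = [p.sample for p in pools]
    idx = {p.sample: table.sample_index(p.sample) for p in pools}
    n = len(pools)
    vals = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    for (i, pa), (k, pb) in combinations(enumerate(pools), 2):
        ja, jb = idx[pa.sample], idx[pb.sample]
        shared = ~table.mask[:, ja] & ~table.mask[:, jb]
        ad_a = np.column_stack([table.ad_ref[shared, ja], table.ad_alt[shared, ja]])
        ad_b = np.column_stack([table.ad_ref[shared, jb], table.ad_alt[shared, jb]])
        try:
            f, ns = pairwise_fst(ad_a, ad_b, pa, pb)
        except UndefinedStatisticError:
            f, ns = np.nan, 0
        vals[i, k] = vals[k, i] = f
        sites[i, k] = sites[k, i] = ns
    return FstMatrix(
        values=pd.DataFrame(vals, index=names, columns=names),
        n_sites=pd.DataFrame(sites, index=names, columns=names),
    )


def population_specific_fst(matrix: FstMatrix) -> pd.Series:
    """Per-sample differentiation score: mean of its pairwise FSTs.

    A moment-based proxy for deme-specific FST from hierarchical F-models.
    Requires >= 3 samples.
    """
    v = matrix.values.to_numpy(dtype=float)
    if v.shape[0] < 3:
        raise ValueError("population-specific FST needs >= 3 samples")
    off = v.copy()
    np.fill_diagonal(off, np.nan)
    return pd.Series(np.nanmean(off, axis=1), index=matrix.samples,
                     name="fst_specific")


def fst_from_frequencies(freqs: np.ndarray) -> float:
    """Ratio-of-averages FST from exact deme allele frequencies.

    ``freqs`` is (n_demes, n_loci). Demes are treated as fully measured
    populations (e.g. clonal expansions of known founders): the
    among-deme component is the unbiased sample variance of frequencies
    across demes, the total is ``p_bar * (1 - p_bar)``, summed over loci
    before the division.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 2 or freqs.shape[0] < 2:
        raise ValueError("need an (n_demes >= 2, n_loci) frequency array")
    var_among = freqs.var(axis=0, ddof=1)
    p_bar = freqs.mean(axis=0)
    total = p_bar * (1.0 - p_bar)
    denom = total.sum()
    if denom == 0:
        raise UndefinedStatisticError("all loci fixed across demes")
    return float(var_among.sum() / denom)


def mantel_ibd(
    fst: FstMatrix | pd.DataFrame,
    dist: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    log10_distance: bool = True,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel test of isolation by distance.

    Pearson correlation between the off-diagonal FST and geographic
    distance vectors; the p-value comes from ``n_perm`` random joint
    row/column permutations of the distance matrix (one-sided, upper).
    Distances are log10-transformed by default.
    """
    fvals = fst.values.to_numpy(dtype=float) if isinstance(fst, FstMatrix) \
        else np.asarray(fst, dtype=float)
    dvals = np.asarray(dist.values if isinstance(dist, pd.DataFrame) else dist,
                       dtype=float)
    if fvals.shape != dvals.shape:
        raise ValueError("FST and distance matrices must match")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    n = fvals.shape[0]
    iu = np.triu_indices(n, k=1)
    x = dvals[iu]
    if log10_distance:
        if np.any(x <= 0):
            raise ValueError("distances must be positive for log10 transform")
        x = np.log10(x)
    y = fvals[iu]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant matrix: correlation undefined")
    r_obs = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    if log10_distance:
        with np.errstate(divide="ignore"):  # diagonal zeros are never used
            d_full = np.log10(dvals)
    else:
        d_full = dvals
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        xp = d_full[np.ix_(perm, perm)][iu]
        if stats.pearsonr(xp, y)[0] >= r_obs:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return r_obs, p


def distance_matrix_from_coords(coords, names=None) -> pd.DataFrame:
    """Pairwise haversine distances (m) as a labeled DataFrame."""
    d = haversine_matrix(coords)
    names = list(names) if names is not None else list(range(d.shape[0]))
    return pd.DataFrame(d, index=names, columns=names)
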