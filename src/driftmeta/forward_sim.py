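"""Forward-in-time simulation of a partially clonal diploid population.

Simulates a single panmictic population of cyclically parthenogenetic
diploids (clonal reproduction with a sexual episode every ``sex_interval``
generations, the *Daphnia*-style life cycle) carrying a stretch of coding
DNA. New mutations are synonymous (always neutral) or nonsynonymous, with
nonsynonymous selection coefficients drawn from a configurable distribution
of fitness effects (DFE). Two run modes mirror two standard experimental
designs:

* :func:`run_equilibrium` — run to mutation–drift equilibrium and report
  per-site nonsynonymous and synonymous diversity (pi_N, pi_S);
* :func:`run_substitutions` — long runs with substitution tracking,
  reporting polymorphism and fixation counts (P_n, P_s, D_n, D_s) and
  per-site substitution rates (d_N, d_S) for downstream alpha / omega_A
  statistics.

The population is regulated softly: every generation exactly ``N`` offspring
are produced by fitness-proportional parent sampling (non-overlapping
generations). Mutations are stored sparsely as rows of a boolean
genotype matrix over the 2N haplotypes; at realistic parameters only a
handful of sites segregate at any time, so the per-generation cost is
dominated by small vectorised array operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "DfeSpec",
    "SimulationConfig",
    "DiversityResult",
    "SubstitutionResult",
    "draw_selection_coefficient",
    "run_equilibrium",
    "run_substitutions",
    "class_pi_from_haplotypes",
]

DFE_KINDS = ("fixed_zero", "gamma_deleterious", "gamma_plus_beneficial")


@dataclass(frozen=True)
class DfeSpec:
    """Distribution of fitness effects for new nonsynonymous mutations.

    Parameters
    ----------
    kind
        ``"fixed_zero"`` (every draw exactly 0), ``"gamma_deleterious"``
        (s = -g, g ~ Gamma(shape, scale=|mean|/shape)), or
        ``"gamma_plus_beneficial"`` (as gamma_deleterious, but with
        probability ``beneficial_fraction`` the draw is ``+beneficial_s``).
    gamma_mean
        Mean selection coefficient of the deleterious gamma part
        (negative, dimensionless).
    gamma_shape
        Shape of the gamma distribution (> 0).
    beneficial_fraction
        Probability that a nonsynonymous mutation is beneficial.
    beneficial_s
        Selection coefficient of beneficial mutations (>= 0).
    """

    kind: str = "fixed_zero"
    gamma_mean: float = -0.03
    gamma_shape: float = 0.2
    beneficial_fraction: float = 0.0
    beneficial_s: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in DFE_KINDS:
            raise ConfigurationError(f"unknown DFE kind {self.kind!r}")
        if self.kind != "fixed_zero":
            if not self.gamma_mean < 0:
                raise ConfigurationError("gamma_mean must be negative")
            if not self.gamma_shape > 0:
                raise ConfigurationError("gamma_shape must be positive")
        if not 0.0 <= self.beneficial_fraction <= 1.0:
            raise ConfigurationError("beneficial_fraction must lie in [0, 1]")
        if self.beneficial_s < 0:
            raise ConfigurationError("beneficial_s must be >= 0")


def draw_selection_coefficient(
    dfe: DfeSpec, rng: np.random.Generator, size: int | None = None
):
    """Draw selection coefficient(s) for new nonsynonymous mutations.

    Returns a scalar when ``size`` is None, else an array of length ``size``.
    """
    n = 1 if size is None else int(size)
    if dfe.kind == "fixed_zero":
        out = np.zeros(n)
    else:
        scale = abs(dfe.gamma_mean) / dfe.gamma_shape
        out = -rng.gamma(dfe.gamma_shape, scale, size=n)
        if dfe.kind == "gamma_plus_beneficial" and dfe.beneficial_fraction > 0:
            hit = rng.random(n) < dfe.beneficial_fraction
            out[hit] = dfe.beneficial_s
    return float(out[0]) if size is None else out


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of a forward run.

    Defaults follow the focal study design: a 100 kb coding stretch,
    mutation and recombination rates of 1e-8 per site per generation,
    sex every eighth generation, burn-in of ten times the population size.
    """

    N: int = 100
    L: int = 100_000
    mu: float = 1e-8
    rec: float = 1e-8
    sex_interval: int = 8
    nonsyn_fraction: float = 0.70
    dfe: DfeSpec = field(default_factory=DfeSpec)
    dominance_h: float = 0.5
    burnin_multiplier: float = 10.0
    n_generations_total: int = 100_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ConfigurationError("N must be >= 2")
        if self.L < 1:
            raise ConfigurationError("L must be >= 1")
        if self.mu < 0 or self.rec < 0:
            raise ConfigurationError("mu and rec must be >= 0")
        if self.sex_interval < 1:
            raise ConfigurationError("sex_interval must be >= 1")
        if not 0.0 < self.nonsyn_fraction < 1.0:
            raise ConfigurationError("nonsyn_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class DiversityResult:
    """Class-wise nucleotide diversity from one equilibrium run."""

    pi_n: float
    pi_s: float
    n_seg_n: int
    n_seg_s: int


@dataclass(frozen=True)
class SubstitutionResult:
    """Polymorphism and substitution counts from one tracking run."""

    P_n: int
    P_s: int
    D_n: int
    D_s: int
    d_n: float
    d_s: float


def _kernel_seed(seed: int | None) -> int:
    if seed is None:
        return int(np.random.SeedSequence().generate_state(1)[0])
    return int(np.random.SeedSequence(seed).generate_state(1)[0])


def _run(config: SimulationConfig, n_generations: int, sample_start: int = -1):
    """Run the compiled kernel, growing mutation capacity on overflow."""
    from ._engine import (
        DFE_FIXED_ZERO,
        DFE_GAMMA,
        DFE_GAMMA_BENEFICIAL,
        run_kernel,
    )

    dfe = config.dfe
    kind = {
        "fixed_zero": DFE_FIXED_ZERO,
        "gamma_deleterious": DFE_GAMMA,
        "gamma_plus_beneficial": DFE_GAMMA_BENEFICIAL,
    }[dfe.kind]
    scale = abs(dfe.gamma_mean) / dfe.gamma_shape if kind != DFE_FIXED_ZERO else 1.0
    shape = dfe.gamma_shape if kind != DFE_FIXED_ZERO else 1.0
    theta = 4.0 * config.N * config.mu * config.L
    cap = max(128, int(6.0 * theta * (np.log(2 * config.N) + 1.0)) + 128)
    seed = _kernel_seed(config.seed)
    while True:
        out = run_kernel(
            seed,
            n_generations,
            config.N,
            config.L,
            config.mu,
            config.rec,
            config.sex_interval,
            config.nonsyn_fraction,
            config.dominance_h,
            kind,
            shape,
            scale,
            dfe.beneficial_fraction,
            dfe.beneficial_s,
            cap,
            sample_start,
        )
        if not out[6]:
            return out
        cap *= 2  # overflow: retry the same seed with more room


def run_equilibrium(
    config: SimulationConfig, tail_multiplier: float = 0.0
) -> DiversityResult:
    """Run to mutation-drift equilibrium and report pi_N and pi_S.

    Starts from a monomorphic population and runs
    ``burnin_multiplier * N`` generations. With ``tail_multiplier`` > 0
    the run is extended by ``tail_multiplier * N`` generations and pi is
    the time-average over that tail rather than the endpoint value — an
    ergodic-averaging variance reduction with the same expectation,
    useful when many replicate means must be estimated precisely.
    ``n_seg_n``/``n_seg_s`` always report endpoint segregating counts.
    """
    n_burn = int(round(config.burnin_multiplier * config.N))
    if tail_multiplier > 0:
        n_gen = n_burn + int(round(tail_multiplier * config.N))
        sample_start = n_burn
    else:
        n_gen = n_burn
        sample_start = -1
    pi_n_sum, pi_s_sum, n_seg_n, n_seg_s, _, _, _ = _run(
        config, n_gen, sample_start)
    return DiversityResult(
        pi_n=pi_n_sum / (config.L * config.nonsyn_fraction),
        pi_s=pi_s_sum / (config.L * (1.0 - config.nonsyn_fraction)),
        n_seg_n=n_seg_n,
        n_seg_s=n_seg_s,
    )


def run_substitutions(config: SimulationConfig) -> SubstitutionResult:
    """Long run with substitution tracking.

    A mutation reaching frequency 1 across all 2N haplotypes is removed
    from the segregating set and counted as a fixation of its class.
    Runs ``n_generations_total`` generations.
    """
    _, _, n_seg_n, n_seg_s, d_n_count, d_s_count, _ = _run(
        config, int(config.n_generations_total)
    )
    return SubstitutionResult(
        P_n=n_seg_n,
        P_s=n_seg_s,
        D_n=d_n_count,
        D_s=d_s_count,
        d_n=d_n_count / (config.L * config.nonsyn_fraction),
        d_s=d_s_count / (config.L * (1.0 - config.nonsyn_fraction)),
    )


def class_pi_from_haplotypes(haplotypes, site_classes) -> DiversityResult:
    """Class-wise pi from an explicit haplotype alignment.

    Parameters
    ----------
    haplotypes
        Array-like of shape (n_haplotypes, L); entries are arbitrary
        hashable site states (integers or characters).
    site_classes
        Length-L array-like; truthy / ``"N"`` marks a nonsynonymous site,
        falsy / ``"S"`` a synonymous site.

    Returns per-class diversity using the unbiased per-site heterozygosity
    ``(1 - sum_a p_a^2) * n/(n-1)`` (equal to ``2p(1-p) * n/(n-1)`` at
    biallelic sites), divided by the number of sites of each class.
    """
    hap = np.asarray(haplotypes)
    if hap.ndim != 2 or hap.shape[0] < 2:
        raise ValueError("need a 2-D alignment with at least 2 haplotypes")
    classes = np.asarray(
        [c == "N" if isinstance(c, str) else bool(c) for c in site_classes]
    )
    if classes.size != hap.shape[1]:
        raise ValueError("site_classes length must match alignment width")
    n = hap.shape[0]
    het = np.empty(hap.shape[1])
    nseg = np.zeros(hap.shape[1], dtype=bool)
    for j in range(hap.shape[1]):
        _, counts = np.unique(hap[:, j], return_counts=True)
        p = counts / n
        het[j] = (1.0 - np.sum(p**2)) * n / (n - 1)
        nseg[j] = counts.size > 1
    l_n = int(classes.sum())
    l_s = int((~classes).sum())
    pi_n = het[classes].sum() / l_n if l_n else 0.0
    pi_s = het[~classes].sum() / l_s if l_s else 0.0
    return DiversityResult(
        pi_n=float(pi_n),
        pi_s=float(pi_s),
        n_seg_n=int(nseg[classes].sum()),
        n_seg_s=int(nseg[~classes].sum()),
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Return a copy of ``config`` with a different seed (replicate helper)."""
    return replace(config, seed=seed)
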