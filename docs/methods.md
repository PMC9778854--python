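# Methods

`driftmeta` models and measures evolution in a *Daphnia*-style rock-pool
metapopulation: many small habitat patches, frequent extinction and
recolonization, cyclical parthenogenesis (clonal growth punctuated by
episodic sex), and pool-sequencing as the observation layer. This note
records the models, the parameter choices and their rationale, the
numerical decisions, and what the synthetic-data tests do and do not
establish.

## Forward simulation (`driftmeta.forward_sim`)

A single panmictic diploid population of constant census size `N` carries
`L` base pairs of coding DNA. Generations are discrete and
non-overlapping; regulation is soft: each generation exactly `N`
offspring are produced, each choosing its parent(s) with probability
proportional to fitness (fitness-proportional *reproduction*; whether the
original non-Wright-Fisher implementations regulated through fecundity or
survival is not recoverable, so this choice is an explicit assumption).

* **Life cycle.** Clonal generations copy both parental haplotypes to the
  offspring. Every `sex_interval`-th generation (default 8, matching a
  summer season of asexual reproduction between sexual episodes) each
  offspring instead draws two distinct parents and receives one
  recombinant gamete from each; crossover counts are Poisson with mean
  `rec * (L-1)` and breakpoints uniform.
* **Mutation.** New mutations arrive as Poisson(`2 N L mu`) per
  generation on random haplotypes at random sites. A fraction
  `nonsyn_fraction` (default 0.70, the ~2.3:1 nonsynonymous:synonymous
  opportunity of coding DNA) is nonsynonymous and draws a selection
  coefficient from the configured DFE; synonymous mutations are always
  neutral. The DFE is either fixed at zero, a negated gamma
  (defaults mean -0.03, shape 0.2; the alternative regime is mean -0.05,
  shape 0.5), or the gamma plus a beneficial class (fraction 0.015 at
  s = +1e-4).
* **Fitness.** Multiplicative across sites, additive within a site
  (dominance `h = 0.5`); factors are floored at zero (a homozygous s <= -1
  is lethal). Both `h` and multiplicativity are conventional defaults,
  not sourced values.
* **Outputs.** `run_equilibrium` runs `burnin_multiplier * N` generations
  (default 10N, the standard equilibration heuristic for these designs)
  from a monomorphic start and reports pi_N and pi_S, computed as
  `sum over segregating sites of 2p(1-p) * 2N/(2N-1)` divided by the
  number of sites in the class. `run_substitutions` additionally counts a
  mutation as a substitution of its class the moment it reaches frequency
  1 across all 2N haplotypes, and reports P/D counts and per-site rates
  d_N = D_n/(L*f), d_S = D_s/(L*(1-f)).
* **Engine.** Mutations are stored sparsely (one row of a 2N-wide boolean
  matrix per segregating site) inside a numba-compiled kernel; a given
  (seed, configuration) pair is bit-reproducible. Capacity overflows
  retry the same seed with a larger buffer, so results do not depend on
  the initial capacity guess.
* **Tail averaging.** `run_equilibrium(..., tail_multiplier=k)` extends
  the run by `k*N` generations and reports pi as the time-average over
  that tail instead of the endpoint value. The expectation is unchanged
  (the chain is stationary after burn-in); the variance drops by roughly
  the number of effectively independent samples in the tail (the
  autocorrelation time of pi is of order 2N generations). Empirically
  this is ~6x more CPU-efficient than extra replicates. Replicate-mean
  experiments (the neutral slope check) use it; the default remains
  endpoint sampling.

**Desk scaling.** Tests run the paper-regime products, not the paper
sizes: L = 20 kb with mu = rec = 5e-8 keeps mu*L = 1e-3 (the study's
1e-8 * 100 kb); substitution-tracking tests raise mu to 1e-6 and shorten
runs while keeping the divergence-to-polymorphism balance sensible.
Hundreds rather than 1,000 replicates are used. Full-scale runs are a
configuration choice away but take hours.

**Known limitation.** The count-based MK alpha (below) applied to these
simulations is dominated by its segregating-deleterious bias: at desk
scale, omega_A is flat to weakly decreasing in N rather than increasing,
because the bias grows with N as fast as the true adaptive signal (the
beneficial class at 4Ns <= 0.2 is nearly neutral). Tests therefore assert
the robust qualitative facts (omega_NA > 0, negative omega_A under
segregating weak deleterious variation, neutral d_N = d_S, d_N/d_S < 1
under a deleterious DFE, pi_N/pi_S decreasing in N) and not an
omega_A-vs-N trend.

## Metapopulation generator (`driftmeta.metapop`)

Patches live on a map (default: an archipelago-like arrangement of
island clusters of ~12 patches tens of meters across, plus ~20%
scattered lone skerries, spanning ~3 km) and evolve in yearly steps:

1. each occupied patch goes extinct with probability 0.20;
2. each empty patch is colonized with probability 0.05 — with
   probability 0.90 by a single diploid founder, else two. All founders
   of one event come from a *single* source patch chosen with
   probability proportional to the dispersal kernel
   `exp(-distance/200 m)` (the propagule model); founder genotypes are
   Hardy-Weinberg draws from the source frequencies, and the new patch
   frequency is the founder dosage over 2k. With no occupied source the
   founder draws from a Beta(1, 1) metapopulation-wide frequency
   distribution (bootstrap fallback, used only at the start);
3. established patches receive Poisson immigrants with mean
   `migration_rate * connectivity / mean connectivity` (connectivity =
   kernel sum over other occupied patches), so isolated ponds receive
   proportionally fewer immigrants while the metapopulation-wide mean
   rate stays `migration_rate`. Immigrant genotypes are drawn from the
   kernel-weighted frequency mixture and admixed in proportion
   `immigrants / deme_size`;
4. binomial drift at `2 * deme_size`;
5. ages increment; patches founded this year stay at age 0 and skip
   migration and drift (their year is the clonal expansion itself).

**Parameter rationale.** Extinction 0.20/yr, colonization 0.05/yr and
the 90% single-founder share are the study system's reported rates. The
remaining parameters are free and were fixed once: `n_patches = 300`
(at the ~20% quasi-equilibrium occupancy this yields ~60 occupied ponds,
matching the survey; the study area has roughly ninefold more habitat
patches than occupied ponds), `deme_size = 100` (small effective sizes in
small rock pools), `migration_rate = 15` effective immigrants per pond
per year. The migration default is deliberately at the high end of
plausible passive dispersal: it places the system in the empirically
reported regime where founder differentiation (pairwise FST ~0.5-0.6
among newly founded ponds) erodes to ~0.35-0.4 over one to two decades.
Runs start from an empty map and 30 simulated years.

**Pool-seq emission.** For each occupied pond: pool allele counts ~
Binomial(2 * 50, p); depths ~ negative binomial (mean 30, dispersion 10);
alt reads ~ Binomial(depth, pool frequency) with symmetric miscalls at
rate 1e-3. Emitted records carry passing QUAL/MQ/QD/FS values; the
filtering stage is exercised separately with hand-built tables.
Covariates: coordinates, age, NN2, plus pond depth, surface area and an
infection flag generated as pure noise — by construction only age and
isolation carry real effects, so regression calibration on the noise
covariates is meaningful.

**What a green test establishes.** The generator encodes founder
bottlenecks, age-dependent diversity recovery, and isolation-dependent
immigration — the structure the analysis stack is meant to detect. It
does not emulate resting-egg banks, within-pond genealogy or linkage,
parasite dynamics, hybrid-vigor-boosted introgression, or reference-bias
artifacts of real pool-seq. Sign recovery on this generator validates
the statistical machinery, not the biology of any particular pond
system.

## Site classes (`driftmeta.site_classes`)

Classic Nei-Gojobori counting on the standard genetic code (via
Biopython's table): each codon's nine single-base changes are classified
by amino-acid identity, with equal weights (no transition/transversion
weighting). Changes that create a stop count as nonsynonymous by
default (`stop_policy="exclude"` drops them from the opportunity
instead). Reference stop codons and codons with ambiguous bases are
skipped and tallied. Coordinates are GFF3 1-based inclusive externally,
0-based half-open internally; minus-strand CDS are handled by
complementation, and the `phase` of the 5'-most CDS feature is honored.
Overlapping transcripts are counted per transcript.

## Pool diversity (`driftmeta.pool_diversity`)

Hard filters reproduce a standard pool-seq stack, all strict
inequalities: QUAL > 30, MQ > 40, QD > 2.0, FS < 60, biallelic SNVs
only; per-sample masks for DP < 10 and minor-allele AD == 1 (depth-aware
error guard). DP is always recomputed as the sum of allelic depths.
Removed-record counts are attributed to the first failing rule in the
order QUAL, MQ, QD, FS, biallelic.

Per-site diversity is `(D/(D-1)) * 2 p (1-p)` with `p` the alt-read
fraction — the read-sampling-unbiased heterozygosity. The
individuals-then-reads double-binomial variance is *not* further
corrected here (it enters the FST estimator's effective sample size
instead); this is a stated simplification. Region pi divides by assayed
sites of each class: monomorphic sites count in denominators, and
variant sites skipped for masking or depth are removed from them.
pi_N/pi_S is flagged undefined when pi_S = 0.

## Divergence statistics (`driftmeta.divergence`)

Per sample: a filtered site is polymorphic (P_n/P_s) if both alleles
retain read support after masking, and a substitution (D_n/D_s) only if
the sample is monomorphic post-masking and its allele differs from the
outgroup base — a site never counts in both. An optional fixation
threshold (< 1) relaxes strict monomorphism; it is off by default.
Sites absent from the variant table are not assayed (the original
outgroup-remapping workflow is out of scope), so D counts are relative
to the callable variant set. Then

    alpha    = 1 - (D_s P_n) / (D_n P_s)
    d_N      = D_n / S_nonsyn,  d_S = D_s / S_syn
    omega_A  = alpha * d_N/d_S,  omega_NA = (1 - alpha) * d_N/d_S

with zero denominators raised as explicit undefined-statistic errors
(table builders catch them and record flags). The identity
omega_A + omega_NA = d_N/d_S holds to machine precision by construction.

## FST (`driftmeta.fst`)

The pairwise estimator is the two-population Weir-Cockerham ANOVA on
read-count allele frequencies with a double-binomial effective sample
size per pool and site, `n_eff = h D / (h + D - 1)` (h = haploid pool
size, D = depth). Per-site variance components
`a = (MSA - MSW)/n_c` and `a + MSW` are summed over loci before the
division (ratio of averages); negative per-site components are kept.
Sites with depth < 2 in either pool are dropped; identical pools give
the expected small negative bias of order -1/n_eff. The exact published
pool FST variant is not recoverable from the text, so this form is fixed
and documented rather than claimed equivalent.

`fst_from_frequencies` treats demes as fully measured (clonal expansions
of known founders): among-deme sample variance over `p(1-p)` of the
pooled frequency, summed over loci — the form under which single-diploid
propagule founding gives exactly 1/2 and k founders give 1/(2k).

Population-specific differentiation is the mean of a sample's pairwise
FSTs — a moment-based stand-in for F-model deme-specific estimates
(the Bayesian machinery is out of scope). Isolation by distance is a
Mantel test: Pearson correlation of off-diagonal FST against
log10-distance with seeded joint row/column permutations (the
eigenvector-map/RDA analysis is likewise replaced, as a documented
simplification).

## Ecology (`driftmeta.ecology`)

Pond volume is the pyramid `area * depth / 3`. NN2 is the mean haversine
distance (spherical Earth, R = 6,371 km) to the two nearest occupied
neighbor ponds. Survey-based age scans an ordered biannual
presence/absence series: a founding event is a detection after >= 3
consecutive misses (or series start); age is years from the latest
founding to the reference date; "newly founded" means age <= 2 years
(age classes at 2 and 15 years). With per-visit detection probability
0.74, the chance an extant pond is misclassified as newly founded is
0.26^3 = 1.76% < 2%. Covariate PCA standardizes columns (correlation
PCA) after log10-transforming designated area/length measures, drops
constant columns with a warning, and orients each loading vector so its
largest-magnitude entry is positive. The diversity regression is OLS
with type-II (marginal) tests via `statsmodels.anova_lm(typ=2)` — each
term tested after all others — with log10(age+1) built internally and an
optional island factor; rank-deficient designs are rejected with the
aliased terms named. Spearman correlations are rank-based Pearson with
average ranks.

## Numerical and testing conventions

* All randomness flows through seeds; identical seeds give identical
  results (simulators are bit-reproducible per seed and configuration).
* Undefined statistics raise typed errors rather than returning silent
  NaNs; batch wrappers convert them to flag strings.
* Stochastic tests assert within 3 SE, or sign recovery across >= 20
  seeds, at the desk scales stated above; oracles (codon enumeration,
  variance-components FST, neutral-theory expectations) are implemented
  independently in the test suite.
* The acceptance script (`scripts/acceptance.py`) recomputes the
  founder-FST expectation from scratch with the propagule experiment at
  500 demes x 1,000 loci.
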