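# Methods

`coexar` reconstructs, bottom-up, how species–area relationships (SARs)
emerge from local coexistence in an annual plant community: neighborhood
fecundity observations → interaction networks → structural feasibility →
persistence categories → coexistence–area relationships (CARs) → null
models. This note records the models, the defaults and why, and the
numerical and design choices a maintainer would want to know.

## The fecundity model

Per focal individual of species *i*, viable seed production is Ricker:

    F_i = lambda_i * exp(-sum_j alpha_ij * N_j)

where `lambda_i` is seed production free of neighbors, `N_j` the number of
neighbors of species *j* within 7.5 cm, and `alpha_ij` the per-capita
effect of *j* on *i* (positive = competition, negative = facilitation).
Observed counts are negative-binomial (NB2) around this mean; NB2 handles
the strong overdispersion of individual seed set while keeping predictions
on the count scale. In regression form this is a log-link NB model:
intercept `log lambda_i`, slope `-alpha_ij` on each neighbor-count column.

Two parameterizations are fitted per year:

- **homogeneous** — plots pooled, one study-wide `(lambda_i, alpha_i.)`
  per species per year; one NB2 maximum-likelihood fit per focal species
  (statsmodels), with asymptotic standard errors and per-species
  dispersion. If the dispersion estimate hits the Poisson boundary
  (`1/k -> 0`, typical for sparse low-fecundity species) the mean
  structure is refitted at a fixed near-Poisson dispersion with
  expected-information standard errors.
- **heterogeneous** — per-plot coefficients by penalized maximum
  likelihood: each plot's coefficient vector maximizes that plot's NB
  log-likelihood plus a Gaussian penalty on its deviation from the pooled
  estimates. This is a deterministic partial-pooling stand-in for a
  crossed plot random effect on intercept and all slopes. The penalty is
  elementwise: scale `shrinkage_sd` (default 0.5) on the intercept and
  `shrinkage_sd × 0.04` on slopes. The scale separation matters: log
  fecundities (≈ 3) and interaction coefficients (≈ 0.05) differ by two
  orders of magnitude, and a shared scale lets the optimizer absorb a
  fecundity deviation into many tiny slope deviations at a fraction of
  the penalty cost, silently flattening the plot-level fecundity
  estimates. `shrinkage_sd = 0` is the infinite-penalty limit and returns
  the pooled estimates exactly.

Coefficients for neighbor species never observed next to a focal species
are unidentifiable; they are fixed at 0 and flagged
`fixed_zero_unobserved`. Parameter uncertainty is propagated by Gaussian
sampling-distribution draws around the estimates (`draw_parameter_replicates`,
default 100 draws), the frequentist analog of re-running the downstream
analysis on posterior draws.

## From fecundity to Lotka–Volterra

Feasibility analysis needs the linear Lotka–Volterra (LV) frame
`dN_i/dt = N_i (r_i - sum_j alpha_ij N_j)` with the fitted `alpha`
unchanged. With a seed bank (germination `g_i`, seed survival `s_i`), a
rare species' seed count grows by `g_i lambda_i + (1 - g_i) s_i` per
season, so invasion requires `lambda_i > (1 - (1-g_i) s_i) / g_i`. The
transform used is the invasion-consistent

    r_i = log(lambda_i) - log((1 - (1-g_i) s_i) / g_i),

which is zero exactly at that boundary and reduces to `ln lambda` when
`g = 1`. An alternative published form adds the bank term to `lambda` on
the natural scale; taken literally it is dimensionally inconsistent and
contradicts the invasion condition, but it is available via
`convention="printed"` for comparison.

## Feasibility, Omega, and persistence categories

A species subset coexists (structuralist sense) when `A' N* = r'`
restricted to the subset has a componentwise-positive solution.
Numerics: positivity tolerance 1e-10; subsets whose matrix has condition
number above 1e12 are flagged singular and infeasible. Local stability
(all eigenvalues of `-diag(N*) A'` in the left half-plane) is computed on
request but deliberately not used by the classifier: feasibility is the
coexistence proxy, and in strongly seasonal systems feasible-but-locally-
unstable configurations are still ecologically meaningful.

The feasibility-domain volume Omega is the fraction of the unit sphere
occupied by the cone `{r : A^{-1} r > 0}` (the cone positively spanned by
the columns of `A`): closed form in dimensions 1–2 (half-line share 1/2;
column angle / 2π), Monte-Carlo over uniform random directions otherwise
(default 1e5 samples, mandatory seed). Omega is reported but not used by
the classifier.

Each species in a plot-year community gets the *simplest* configuration
under which it persists:

- `pair` — member of a feasible 2-species subset;
- `multispecies` — otherwise member of a feasible subset of ≥ 3 species;
- `dominant` — persists alone (`r_i > 0`, `alpha_ii > 0`) but in no
  feasible multi-species subset;
- `transient` — no feasible configuration at all.

Precedence is `pair > multispecies > dominant` (configurable): a species
that could persist alone but also coexists in a pair is recorded as
coexisting through that pair; dominance is reserved for species that
persist only by excluding everyone else. The singleton rule (`r_i > 0`
and positive self-limitation) is the natural monoculture-equilibrium
criterion.

Enumeration is exhaustive up to a hard cap of 20 species (override
explicitly above that). The production classifier is exactly equivalent
to the exhaustive definition but uses three shortcuts, each exact:
batched linear solves per subset size; beyond pairs, only subsets
containing a not-yet-classified species are visited; and a species with
`r_i ≤ 0` whose interaction row is entirely non-negative is transient
without enumeration, because its equilibrium condition would sum
non-negative terms to a non-positive total. Equivalence to the exhaustive
path is property-tested on random sign-mixed communities.

## Curves and summary statistics

SARs are combination-averaged ("Type B"): for each k = 1..9, the union
richness of every one of the C(9, k) plot combinations, reported as mean
± SE (sample SD / √#combinations; SE = 0 where only one combination
exists). CARs are built identically from per-plot *persistent* sets
(non-transient species); a species coexists in an area if it persists in
at least one constituent plot. Plot area is carried exactly (8.5² =
72.25 m²). Curves are fitted to `S = c A^z` by nonlinear least squares on
untransformed values, initialized from the log–log regression; zero-mean
rows are dropped before fitting.

Two summary statistics: the **heterogeneity contribution**,
`100 × mean over (year, k) of (CAR_het − CAR_hom) / CAR_het` (rows with
zero heterogeneous CAR excluded; the heterogeneous curve is the
denominator by default, configurable), and the **transient fraction**,
the mean over all (year, k, combination) of the share of the
combination's species pool classified transient in every constituent
plot where present (heterogeneous-parameterization records by default).

## Null models

Two reshufflings of each plot-year interaction matrix: `shuffle_all`
permutes the full entry multiset (diagonal included); `shuffle_offdiag`
fixes the self-limitation diagonal and permutes only interspecific
entries. Each null replicate reshuffles every plot's matrix (restricted
to the species observed there, baseline = homogeneous parameterization),
re-runs the classification and rebuilds the CAR; 100 replicates per model
and year by default. Replicate seeds are spawned from the master seed via
`numpy.random.SeedSequence` in a fixed (replicate, plot) grid, so
ensembles are bit-reproducible and replicates independent. No
significance test is attached: the comparison is the ensemble mean ± SE
against the baseline curve.

## The synthetic community

The generator emulates the study design the analysis assumes: 5 years ×
9 plots (8.5 m side, 36 subplots) × 19 species, with all parameters
known. Defaults, chosen once for realism:

- **Fecundity** `log lambda ~ N(3.0, 0.4)` (λ ≈ 20 seeds): typical for
  Mediterranean annuals after neighborhood suppression.
- **Quasi-neutral interactions**: `alpha_ij ~ N(0.055, 0.018)` off the
  diagonal with an 8% chance of weak facilitation (−|N(0, 0.02)|),
  `alpha_ii ~ N(0.045, 0.008)` on it. Intra- and interspecific strengths
  are similar, with intraspecific exceeding interspecific in roughly a
  third of interactions — weak, mostly competitive networks in which
  most pairs are feasible.
- **Sink-prone species**: a fixed 15% of the pool (3 of 19) has
  `log lambda ~ N(−1.2, 0.4)`, decisively below the seed-bank invasion
  boundary: observed, but predicted transient. They receive no
  facilitation (they sit at a physiological limit), so their transience
  is structural rather than an artifact of one coefficient.
- **Occupancy** is gradient-structured: each species' per-plot occurrence
  probability is a logistic response to a 1-D plot covariate (three
  blocks of three plots, standing in for a salinity gradient). A realism
  device only; nothing downstream fits it.
- **Neighborhoods**: independent Poisson counts per focal with
  per-species mean density `~ LogNormal(log 1.5, 0.4)` for species
  present in the plot-year; only counts enter the model, so no explicit
  spatial point process is simulated.
- **Noise**: NB2 dispersion `k ~ U(1.5, 4)` per species.
- **Sampling effort**: 34 focals per species and plot (~300 per species
  and year, within the one-per-subplot cap of 324). The fits here are
  per-year; this effort gives each yearly fit roughly the information a
  multilevel model would borrow by pooling a sparser sample across years.
- **Heterogeneity scenario**: per-plot deviations `N(0, sd)` on
  `log lambda` and `N(0, sd × 0.04)` on `alpha` entries — the 0.04 factor
  puts an `sd = 0.5` perturbation on the natural scale of the
  coefficients themselves. Sink-prone species additionally respond to the
  gradient (`±3 sd` per unit covariate), emulating salinity specialists
  whose fecundity peaks at one end. `sd = 0` recovers the exactly
  homogeneous world.

What the generator does **not** emulate: spatially explicit positions and
dispersal, temporal seed-bank dynamics, year-to-year parameter drift, and
observation-level covariates. Passing tests therefore validate the
*machinery* — inference recovers known parameters, classification matches
independent dynamical oracles, curves satisfy their combinatorial
identities — not that the synthetic world reproduces every field pattern.

Two known behaviors of the synthetic system deserve note. First,
feasibility classification of *marginal* species is rescue-prone: a
species with slightly negative fitted `r` is counted persistent if any
fitted interaction toward it is even slightly negative, so sampling noise
in weakly-identified coefficients biases against transience. Transients
here are therefore those whose fitted growth rates are decisively
negative, and the synthetic transient fraction (a few percent, varying by
year) is smaller than in field systems where hierarchical priors shrink
noisy coefficients. Second, because quasi-neutral interactions make most
subsets feasible, predicted coexistence is nearly saturated and the
heterogeneity-contribution statistic is structurally near zero in
synthetic runs; the statistic's correctness is instead verified on
constructed curve tables and by its vanishing under exactly homogeneous
truth.

## Problem sizes and determinism

Default end-to-end runs (acceptance script and heavier tests) use the
full design — 5 years × 9 plots × 19 species, ~29,000 focal rows, 100
null replicates per model-year — and complete in a few minutes on one
core; unit tests use reduced designs (2 years, 4–6 plots, 6–10 species).
Every stochastic operation takes an explicit seed; stage seeds are
derived from the master seed by CRC-labeled `SeedSequence` spawning, so a
pipeline run is a pure function of (config, seed).
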