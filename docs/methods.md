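# Methods

This note documents the statistical models, their default priors and
numerical conventions, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## Sampling machinery

All posteriors are drawn with affine-invariant ensemble MCMC (`emcee`
stretch moves). The sampler contract (`MCMCConfig`) defaults to 4 chains of
3000 iterations with a 1000-iteration warm-up. A "chain" is one independent
ensemble of walkers (at least `2·ndim + 2`, minimum 10) started from
jittered initial points with its own seed; after warm-up the walkers are
flattened into the draw axis, so convergence diagnostics (rank-normalised
split R-hat, bulk ESS, via `arviz`) compare genuinely independent runs.
Any parameter with R-hat > 1.01 triggers a warning. Stretch moves have no
divergence concept; the divergence count is reported as 0 for interface
compatibility. Pointwise log-likelihoods for PSIS-LOO model comparison are
evaluated on a thinned subset of draws (500 per chain by default).

Fits are deterministic for a given `MCMCConfig.seed`. Initial points come
from a cheap moment-style center per model; non-finite log densities at
initialisation are re-jittered, and a persistent non-finite density raises
with a report of the offending parameter values.

### Highest-posterior-density intervals

`hpdi(draws, mass)` returns the narrowest contiguous window of the sorted
draws containing `ceil(mass·n)` draws. Ties between equally narrow windows
are broken toward the smallest lower bound. This rule is exact and is
verified in the tests against a brute-force scan over all windows.
Summaries report the median plus 75% and 95% HPDIs.

### Default priors

Priors are weakly informative and scale-aware, all overridable per fit:

- regression engine (all families): intercept ~ Student-t(3, median(y),
  2.5·mad(y)); treatment and covariate coefficients ~ Normal(0,
  2.5·sd(y)/sd(x)); residual and atoll SDs ~ half-Student-t(3, 0,
  2.5·mad(y)); atoll intercepts are non-centered (sd × standard-normal
  deviates).
- VBGF: L∞ ~ Normal(1.1·max L, 0.3·max L) truncated below at the *median*
  observed length; L₀ ~ Normal(8, 5) truncated at 0; k ~ half-Normal(0.5);
  k_b ~ Normal(0, 0.25); σ_L ~ half-Normal(5). Truncating L∞ at the median
  rather than the maximum observed length matters: residual scatter
  routinely places individual fish above the true asymptote, and a bound
  at the sample maximum squashes the posterior against it, biasing k and
  k_b low and over-narrowing their intervals. With the median bound the
  simulation-based calibration checks recover the generating k_b at
  nominal coverage.
- three-age model: mean lengths at each reference age ~ Normal(empirical
  mean length within ±1 yr of that age, 10); a shared σ_L as above. The
  ordering l_phi < l_chi < l_psi and deceleration (0 < r < 1) are enforced
  through the likelihood support.

## Growth models

The treatment-offset VBGF is

    L_t = L∞ − (L∞ − L₀)·exp(−(k + k_b·1[rat-free])·t)

with homoscedastic Gaussian residuals on length-at-age (the mean function
fixes only the curve; an additive Gaussian residual is the conventional
likelihood for length-at-age data and is what the synthetic generator
emits). Three variants are provided: `no_offset`, `offset_k` (the primary
model) and `offset_k_and_Linf` (adds an L∞ offset); they are ranked by
PSIS-LOO. Atoll intercepts are *not* placed on the growth mean by default
— the growth equation is a two-group contrast — and fish of all stages
enter the fit (a stage filter is available).

Derived quantities are computed per posterior draw and then summarised:
percent-faster growth is the median of `100·k_b/k` (propagating the joint
posterior rather than taking a ratio of medians), and length-at-age
contrasts are per-draw differences of the mean curves.

### Three-age reparameterisation

With reference ages τ_phi < τ_chi < τ_psi where τ_chi is the midpoint, the
distances to the asymptote form a geometric sequence, giving the closed
bijection

    r  = (l_psi − l_chi)/(l_chi − l_phi),  0 < r < 1
    L∞ = l_phi + (l_psi − l_phi)/(1 − r²)
    k  = −2·ln(r)/(τ_psi − τ_phi)
    L₀ = L∞ − (L∞ − l_phi)·exp(k·τ_phi)

The mapping is verified by a round-trip property (inverts to ≤1e-9) and by
the equivalence of maximum-likelihood mean curves fitted in either
coordinate system (≤1e-6 cm). Mean lengths at (2, 4, 6) yr are estimated
separately per treatment with a shared residual SD.

### Upper-quartile extremes

Because the collections are initial-phase females of a protogynous
species, "maximum" age and length proxy age- and size-at-sex-change. Per
island, the metric is the mean of observations at or above the island's
75th percentile (linear-interpolation quantile, inclusive rule — the
convention had to be fixed somewhere and is documented here). Islands with
fewer than 4 fish fall back to their full-sample mean and are logged. The
island values then enter a Gaussian treatment model with atoll intercepts.

## Reproductive investment

GSI = 100 · gonad mass (g) / body mass (g); wet weight is stored in kg as
measured and converted inside the ratio. The GSI model is Gaussian on the
raw percent scale (treatment differences are reported additively), with
the covariate (length or age; optionally collection day) centred at its
sample mean so the treatment effect is the difference in adjusted GSI at
the mean covariate. The percent difference is per-draw
`100·effect/intercept` (intercept = rat-infested adjusted GSI).

The growth–GSI correlation is computed from individual deviates: growth
deviate = observed length − posterior-median VBGF mean at the fish's age
and treatment; GSI deviate = observed GSI − posterior-median fitted GSI at
its length and treatment (including the median atoll offset). The Pearson
correlation of the deviates gets a 95% percentile interval from 2000
nonparametric bootstrap resamples. This construction is a declared choice:
an individual-level correlation can be assembled in several ways, and this
one is simple, deterministic given the fits, and recovers the generating
latent correlation in simulation.

## Population structure

Per-transect density and biomass are zero-inflated; both use a hurdle
gamma: P(zero) on the logit scale (intercept-only by default, optional
treatment term) and a log-linked gamma mean with treatment effect and
atoll intercepts for the positive part. Counts are reported both per
transect (150 m² default) and per m²; the treatment ratio is invariant to
that choice. `exp(treatment effect)` back-transforms to the rat-free :
rat-infested fold ratio.

Pooled survey lengths follow an ex-Gaussian: y = Normal(μ, σ) + Exp(τ).
The exponential component τ governs right-skew and is what the field
reports as the "skew parameter"; it carries a log-linked treatment effect,
μ an identity-linked one. The distribution mean is μ + τ per draw (an
identity, asserted in the tests), so the mean-size contrast propagates
both effects. Lengths are modelled per fish pooled across transects (the
survey design gives no within-transect size dependence structure worth a
grouping level at these sample sizes). The likelihood uses the erfc-based
closed form via `log_ndtr` for numerical stability at small τ.

Size-frequency histograms use left-closed right-open 2.5 cm bins aligned
at the 8 cm survey cutoff.

## Drivers

Strictly positive island covariates (seabird density) use a lognormal
family so the treatment effect is a log fold-ratio; a configurable offset
of half the smallest positive observed value is available for zeros and is
logged prominently when applied. Muscle %N and δ¹⁵N use the Gaussian
family on individual fish. All reuse the same engine and atoll-intercept
structure.

## Functional rates

Annual grazing area and bioerosion mass scale allometrically with length,
`rate = c·L^d`. The coefficients are published, species-specific, external
inputs; the package ships **no numeric defaults** so users cannot silently
propagate fabricated values. Per draw, the VBGF mean length at a reference
age (default 4 yr) per treatment is pushed through the relationship.

Reproductive potential is a declared interpretation: every surveyed fish
is treated as a spawning-capable female, body mass comes from the
length–weight curve, predicted GSI comes from the fitted GSI–length model
(floored at 0), gonad mass = GSI/100 × body mass, summed per transect and
averaged per treatment. The assumptions string travels with the result.

## Synthetic data generator

The generator emulates the study design: paired rat-free / rat-infested
islands in atolls (default 3 atolls × 1 island per treatment × 15 fish);
ages uniform on 1–8 yr (the real catch's age distribution is unknown, so
uniform is an explicit, configurable stand-in); lengths on the
treatment-specific VBGF with additive Gaussian noise (σ = 1 cm) plus an
atoll offset, rounded to 0.1 cm; weights from the length–weight curve with
5% lognormal noise; GSI linear in centred length with a treatment shift,
floored at 0 (floored rows are counted and logged), with the growth and
GSI residuals drawn from a bivariate standard normal with correlation
ρ = −0.26 injected at the latent-deviate level; %N and δ¹⁵N normal per
treatment; transects from an occupancy × gamma process (the hurdle owns
all zeros: occupied transects hold at least one fish) with truncated
ex-Gaussian lengths rounded to 1 cm (visual-census precision); island
seabird densities lognormal with a configured treatment ratio, other
covariates shared across treatments.

Default parameter values are the study-scale quantities: growth
(L∞ = 25 cm, L₀ = 8 cm, k = 0.27/yr, k_b = 0.11/yr), GSI (baseline 1.20,
shift −0.25, ρ = −0.26), roughly half the transects empty with positive
densities averaging 3.5–5 fish per transect and a density ratio near 0.7,
ex-Gaussian sizes whose means differ by ≈2.3 cm and τ by ≈0.46 cm, a
seabird ratio of 788.5, %N shift 0.23 and δ¹⁵N shift 0.02. Where the
magnitudes were not dictated by the design (isotope means, gamma shape,
length–weight coefficients a = 0.0136, b = 3.05, atoll SDs) values typical
for a small Indo-Pacific parrotfish were fixed once.

Each island and transect block draws from its own seeded child generator,
so output is byte-deterministic under a seed and changing one parameter
block perturbs only the affected columns.

**What the generator does not emulate** — and hence what passing recovery
tests do and do not show: measurement error in otolith ages; non-uniform,
mortality-shaped age distributions; sex change and stage mixtures (all
generated fish are spawning-capable females); spatial autocorrelation
among transects; within-transect size clustering; seasonal growth; any
relationship between island covariates and fish demography beyond the
treatment dichotomy. Recovery results demonstrate that the estimators are
calibrated under the assumed generative structure, not that the structure
matches any particular reef.

## Problem sizes and runtime conventions

Recovery checks run at study scale — 8 islands × 15 fish (growth), 96
females (GSI), 48–192 transects, 500 lengths per treatment (size
structure) — with the reduced sampler setting of 2 chains × 1500
iterations (500 warm-up), which the calibration experiments show is
sufficient for these low-dimensional posteriors. The acceptance script
uses the full 4 × 3000 contract. Bootstrap intervals use 2000 resamples;
posterior predictive checks use 200 replicated datasets.

## Known limitations

- The ensemble sampler is gradient-free; models with many more group
  levels or strong funnels than occur here would mix poorly and should be
  re-expressed (the atoll intercepts are already non-centered).
- The hurdle zero-probability is intercept-only by default; a treatment
  effect on occupancy is available but not part of the headline contrasts.
- The growth–GSI correlation conditions on posterior-median fits rather
  than propagating fit uncertainty into the deviates; its bootstrap
  interval reflects sampling of fish, not of model parameters.
- Percent metrics (percent-faster growth, percent GSI difference) are
  ratios of posterior draws and can be heavy-tailed when the denominator
  approaches zero; medians and HPDIs are reported for that reason.
- The ex-Gaussian size model ignores the 8 cm survey truncation in the
  likelihood; at the observed size ranges (means well above the cutoff)
  the truncated mass is small, but treatment contrasts in τ absorb a
  slight attenuation.
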