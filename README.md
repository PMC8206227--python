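# reefdemo

Bayesian demographic analysis of reef fish across seabird nutrient-subsidy
gradients.

On islands where invasive rats have extirpated breeding seabirds, the flow
of guano-derived nutrients onto adjacent reefs collapses. `reefdemo`
implements the statistical machinery to ask what that loss does to the
demography of a reef fish — individual growth, reproductive investment,
population density, biomass and size structure — by contrasting *rat-free*
(seabird-rich) with *rat-infested* (seabird-poor) islands, with islands
nested in atolls. The motivating system is the bullethead parrotfish
*Chlorurus sordidus*, a protogynous excavating herbivore whose body size
drives reef grazing and bioerosion rates.

## Models

**Growth.** Length-at-age from otolith-aged fish follows a von Bertalanffy
growth function with an additive treatment offset on the growth
coefficient:

    L_t = L∞ − (L∞ − L₀) · exp(−(k + k_b·1[rat-free]) · t)

so `k_b` is directly the difference in growth rate between treatments
(`k_b = 0`: no difference; `k_b > 0`: faster growth around rat-free
islands). Alternative parameterisations (offset on both `k` and `L∞`, or
no offset) are compared by PSIS-LOO, and a Francis-style reparameterisation
estimates mean lengths at three reference ages (2, 4, 6 yr) per treatment.
Island-level means of the upper quartile of ages and lengths proxy
age- and size-at-sex-change.

**Reproductive investment.** Gonadosomatic index
(GSI = gonad mass / body mass × 100) of spawning-capable females is
modelled as Gaussian in treatment + centred length (or age, optionally
collection day) with atoll varying intercepts; an individual-level
growth–GSI deviate correlation quantifies the growth–fecundity trade-off.

**Population structure.** Per-transect density and biomass from underwater
visual censuses are zero-inflated and use hurdle-gamma models with log
links; pooled survey lengths follow an exponentially modified normal
(ex-Gaussian) whose exponential component τ carries the right-skew, with
treatment effects on both location and skew.

**Drivers and functional rates.** The same treatment + atoll-intercept
engine fits seabird density (lognormal — effects back-transform to fold
ratios), muscle %N and δ¹⁵N, and other covariates. Growth posteriors
propagate through user-supplied allometric scaling `rate = c·L^d` into
annual grazing (m²/yr) and bioerosion (kg/yr) posteriors per treatment.

All models are sampled with affine-invariant ensemble MCMC (`emcee`)
behind a common contract (4 chains × 3000 iterations, 1000 warm-up, by
default), with rank-normalised split R-hat, effective sample size,
narrowest-window highest-posterior-density intervals, posterior predictive
checks and PSIS-LOO comparison via `arviz`.

A fully parameterised synthetic-data generator reproduces the generative
structure of every model (treatment-offset VBGF lengths, GSI with a latent
growth–fecundity correlation, occupancy × gamma transect counts,
truncated ex-Gaussian sizes, lognormal seabird densities), so every stage
supports parameter-recovery testing without any field data.

## Worked example

```python
import numpy as np
from reefdemo import (MCMCConfig, SyntheticConfig, fit_vbgf, fit_gsi_model,
                      percent_growth_difference, simulate_fish)

fish = simulate_fish(SyntheticConfig(n_atolls=4, seed=1))   # 8 islands x 15 fish
mcmc = MCMCConfig(chains=4, iterations=3000, warmup=1000, seed=1)

growth = fit_vbgf(fish, variant="offset_k", mcmc=mcmc)
k = np.median(growth.get("k")); kb = np.median(growth.get("k_b"))
print(f"k (rat-infested) = {k:.3f} /yr, k + k_b (rat-free) = {k + kb:.3f} /yr")
_, pct = percent_growth_difference(growth)
print(f"rat-free fish grow {pct.median:.1f}% faster "
      f"(95% HPDI {pct.hpdi95[0]:.1f} to {pct.hpdi95[1]:.1f})")

gsi = fit_gsi_model(fish, covariate="length", mcmc=mcmc)
d = gsi.difference
print(f"GSI difference at mean length = {d.median:.2f} "
      f"(95% HPDI {d.hpdi95[0]:.2f} to {d.hpdi95[1]:.2f})")
```

prints

```
k (rat-infested) = 0.273 /yr, k + k_b (rat-free) = 0.372 /yr
rat-free fish grow 36.1% faster (95% HPDI 25.0 to 47.5)
GSI difference at mean length = -0.23 (95% HPDI -0.39 to -0.07)
```

The synthetic fish were generated with `k = 0.27`, `k_b = 0.11` and a GSI
treatment shift of `−0.25`, so the fits recover the generating values: fish
around rat-free islands grow about a third faster but invest relatively
less in gonads at a given length — the individual-level growth–fecundity
trade-off the package is built to detect.

The same analysis runs from the shell: `reefdemo simulate` writes synthetic
CSVs, `reefdemo fit-growth fish.csv` fits the growth model, and
`reefdemo run config.yaml` executes the full suite (growth, GSI,
population, drivers, rates) and writes per-model posterior summaries, a
consolidated `results.json` and a `report.md`.

## Layout

- `src/reefdemo/data_model.py` — domain records, CSV I/O, validation, GSI
  and length–weight conversions, transect summaries
- `src/reefdemo/synthetic_data.py` — the generative model and its defaults
- `src/reefdemo/inference_core.py` — sampler contract, priors, HPDI,
  R-hat/ESS, LOO comparison, posterior predictive checks
- `src/reefdemo/growth_models.py` — VBGF variants, three-age
  reparameterisation, upper-quartile extremes
- `src/reefdemo/treatment_effects.py` — the response-family engine
  (gaussian / lognormal / hurdle-gamma / ex-Gaussian), GSI models,
  correlation, ratios, size structure
- `src/reefdemo/functional_rates.py` — allometric propagation and
  reproductive potential
- `src/reefdemo/pipeline.py`, `src/reefdemo/cli.py` — orchestration and
  the `reefdemo` command

See `docs/methods.md` for the statistical details, default priors,
numerical choices and known limitations.
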