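"""Generic treatment-effect models: response ~ rat status (+ covariates)
with an atoll varying intercept.

One engine, four response families:

``gaussian``
    identity link; used for %N, d15N, GSI, island-level extremes and mean
    sizes.
``lognormal``
    Gaussian on log(response); treatment effect is a log-ratio, so
    ``exp(effect)`` is the fold difference (used for strictly positive
    island covariates such as seabird density).
``hurdle_gamma``
    two-part model for zero-inflated per-transect density/biomass: a
    probability of a structural zero plus a log-linked gamma for positive
    values.
``exgaussian``
    exponentially-modified normal for size distributions; the exponential
    component ``tau`` (the field's "skew parameter") carries a
    log-linked treatment effect, so rat status can shift both the location
    and the right tail.

Atoll varying intercepts are non-centered (sd times a standard-normal
deviate per atoll).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, log_ndtr

from .data_model import FishRecord, Stage, Treatment
from .inference_core import (
    BayesModel,
    HalfNormal,
    HalfStudentT,
    IntervalSummary,
    MCMCConfig,
    Normal,
    PosteriorSamples,
    Prior,
    StudentT,
    fit,
    interval_summary,
)

logger = logging.getLogger("reefdemo")

__all__ = [
    "TreatmentEffectSpec",
    "TreatmentEffectPosterior",
    "GSIResult",
    "CorrelationResult",
    "SizeStructureResult",
    "fit_treatment_effect",
    "fit_gsi_model",
    "growth_gsi_correlation",
    "back_transform_ratio",
    "fit_size_structure",
    "size_frequency",
]

FAMILIES = ("gaussian", "lognormal", "hurdle_gamma", "exgaussian")

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass(frozen=True)
class TreatmentEffectSpec:
    """What to fit: response column, family, covariates, grouping, baseline."""

    response: str
    family: str = "gaussian"
    covariates: tuple[str, ...] = ()
    group_atoll: bool = True
    baseline: str = Treatment.RAT_INFESTED.value
    hurdle_treatment: bool = False  # treatment effect on the zero probability

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family '{self.family}'; expected one of {FAMILIES}")


def _robust_scale(y: np.ndarray) -> float:
    mad = float(np.median(np.abs(y - np.median(y)))) * 1.4826
    if mad == 0.0:
        mad = float(np.std(y))
    return max(mad, 1e-3)


class _LinearPredictorMixin:
    """Shared linear-predictor machinery: treatment flag, centered covariates,
    non-centered atoll intercepts."""

    def _init_design(
        self,
        is_free: np.ndarray,
        X: np.ndarray,
        cov_names: Sequence[str],
        atoll_idx: np.ndarray | None,
        n_atolls: int,
    ) -> None:
        self.is_free = np.asarray(is_free, float)
        self.X = np.asarray(X, float)
        self.cov_names = list(cov_names)
        self.atoll_idx = atoll_idx
        self.n_atolls = n_atolls

    def _linpred_names(self) -> list[str]:
        names = ["intercept", "b_treatment"] + [f"b_{c}" for c in self.cov_names]
        if self.atoll_idx is not None:
            names += ["atoll_sd"] + [f"z_atoll_{j}" for j in range(self.n_atolls)]
        return names

    def _linpred(self, p: Mapping[str, np.ndarray]) -> np.ndarray:
        eta = p["intercept"][:, None] + p["b_treatment"][:, None] * self.is_free[None, :]
        for j, c in enumerate(self.cov_names):
            eta = eta + p[f"b_{c}"][:, None] * self.X[:, j][None, :]
        if self.atoll_idx is not None:
            z = np.stack([p[f"z_atoll_{j}"] for j in range(self.n_atolls)], axis=1)
            eta = eta + p["atoll_sd"][:, None] * z[:, self.atoll_idx]
        return eta

    def _unpack(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        theta = np.atleast_2d(theta)
        return {n: theta[:, j] for j, n in enumerate(self.param_names)}


class GaussianModel(_LinearPredictorMixin, BayesModel):
    def __init__(self, y, is_free, X, cov_names, atoll_idx, n_atolls,
                 priors: Mapping[str, Prior] | None = None, log_response: bool = False):
        self.y = np.log(np.asarray(y, float)) if log_response else np.asarray(y, float)
        self.log_response = log_response
        self._init_design(is_free, X, cov_names, atoll_idx, n_atolls)
        self.n_obs = self.y.size
        self.param_names = self._linpred_names() + ["sigma"]
        scale = _robust_scale(self.y)
        defaults: dict[str, Prior] = {
            "intercept": StudentT(3.0, float(np.median(self.y)), 2.5 * scale),
            "b_treatment": Normal(0.0, 2.5 * max(float(np.std(self.y)), scale)),
            "sigma": HalfStudentT(3.0, 2.5 * scale),
            "atoll_sd": HalfStudentT(3.0, 2.5 * scale),
        }
        for j, c in enumerate(self.cov_names):
            sx = max(float(np.std(self.X[:, j])), 1e-6)
            defaults[f"b_{c}"] = Normal(0.0, 2.5 * max(float(np.std(self.y)), scale) / sx)
        for j in range(self.n_atolls):
            defaults[f"z_atoll_{j}"] = Normal(0.0, 1.0)
        if priors:
            defaults.update(priors)
        self.priors = {n: defaults[n] for n in self.param_names}

    def pointwise_log_likelihood(self, theta):
        p = self._unpack(theta)
        mu = self._linpred(p)
        sigma = p["sigma"][:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (self.y[None, :] - mu) / sigma
            out = -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI
        out[~np.isfinite(out)] = -np.inf
        return out

    def initial_center(self):
        guess = {
            "intercept": float(np.median(self.y)),
            "b_treatment": 0.0,
            "sigma": max(float(np.std(self.y)), 1e-2),
            "atoll_sd": 0.1 * max(float(np.std(self.y)), 1e-2),
        }
        for c in self.cov_names:
            guess[f"b_{c}"] = 0.0
        for j in range(self.n_atolls):
            guess[f"z_atoll_{j}"] = 0.0
        return np.array([guess[n] for n in self.param_names])

    def simulate(self, theta, rng):
        p = self._unpack(np.atleast_2d(theta))
        mu = self._linpred(p)[0]
        y = mu + rng.normal(0.0, float(p["sigma"][0]), mu.size)
        return np.exp(y) if self.log_response else y


class HurdleGammaModel(_LinearPredictorMixin, BayesModel):
    """P(zero) = inv_logit(hurdle terms); positive part Gamma with log-linked mean."""

    def __init__(self, y, is_free, X, cov_names, atoll_idx, n_atolls,
                 priors: Mapping[str, Prior] | None = None, hurdle_treatment: bool = False):
        self.y = np.asarray(y, float)
        if np.any(self.y < 0):
            raise ValueError("hurdle-gamma responses must be >= 0")
        self._init_design(is_free, X, cov_names, atoll_idx, n_atolls)
        self.n_obs = self.y.size
        self.is_zero = self.y == 0.0
        self.hurdle_treatment = hurdle_treatment
        self.param_names = self._linpred_names() + ["hurdle_logit", "shape"]
        if hurdle_treatment:
            self.param_names.append("hurdle_b_treatment")
        pos = self.y[~self.is_zero]
        log_mean = float(np.log(pos.mean())) if pos.size else 0.0
        defaults: dict[str, Prior] = {
            "intercept": StudentT(3.0, log_mean, 2.5),
            "b_treatment": Normal(0.0, 2.5),
            "atoll_sd": HalfStudentT(3.0, 2.5),
            "hurdle_logit": Normal(0.0, 2.5),
            "hurdle_b_treatment": Normal(0.0, 2.5),
            "shape": HalfNormal(10.0),
        }
        for c in self.cov_names:
            defaults[f"b_{c}"] = Normal(0.0, 2.5)
        for j in range(self.n_atolls):
            defaults[f"z_atoll_{j}"] = Normal(0.0, 1.0)
        if priors:
            defaults.update(priors)
        self.priors = {n: defaults[n] for n in self.param_names}

    def pointwise_log_likelihood(self, theta):
        p = self._unpack(theta)
        eta = self._linpred(p)  # log mean of positive part
        logit = p["hurdle_logit"][:, None]
        if self.hurdle_treatment:
            logit = logit + p["hurdle_b_treatment"][:, None] * self.is_free[None, :]
        # log p0 and log(1-p0) via stable softplus
        log_p0 = -np.logaddexp(0.0, -logit)
        log_1mp0 = -np.logaddexp(0.0, logit)
        shape = p["shape"][:, None]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            mu = np.exp(eta)
            rate = shape / mu
            ylog = np.where(self.is_zero, 1.0, self.y)[None, :]
            yval = self.y[None, :]
            gamma_ll = (
                shape * np.log(rate)
                - gammaln(shape)
                + (shape - 1.0) * np.log(ylog)
                - rate * yval
            )
            out = np.where(self.is_zero[None, :], log_p0, log_1mp0 + gamma_ll)
        out[~np.isfinite(out)] = -np.inf
        return out

    def initial_center(self):
        pos = self.y[~self.is_zero]
        zfrac = float(np.clip(self.is_zero.mean(), 0.02, 0.98))
        guess = {
            "intercept": float(np.log(pos.mean())) if pos.size else 0.0,
            "b_treatment": 0.0,
            "atoll_sd": 0.1,
            "hurdle_logit": float(np.log(zfrac / (1 - zfrac))),
            "hurdle_b_treatment": 0.0,
            "shape": 2.0,
        }
        for c in self.cov_names:
            guess[f"b_{c}"] = 0.0
        for j in range(self.n_atolls):
            guess[f"z_atoll_{j}"] = 0.0
        return np.array([guess[n] for n in self.param_names])

    def zero_probability_draws(self, flat: np.ndarray, rat_free: bool = False) -> np.ndarray:
        p = {n: flat[:, j] for j, n in enumerate(self.param_names)}
        logit = p["hurdle_logit"]
        if self.hurdle_treatment and rat_free:
            logit = logit + p["hurdle_b_treatment"]
        return 1.0 / (1.0 + np.exp(-logit))

    def simulate(self, theta, rng):
        p = self._unpack(np.atleast_2d(theta))
        eta = self._linpred(p)[0]
        logit = float(p["hurdle_logit"][0]) + (
            p["hurdle_b_treatment"][0] * self.is_free if self.hurdle_treatment else 0.0
        )
        p0 = 1.0 / (1.0 + np.exp(-logit))
        shape = float(p["shape"][0])
        mu = np.exp(eta)
        pos = rng.gamma(shape, mu / shape)
        zero = rng.random(mu.size) < p0
        return np.where(zero, 0.0, pos)


class ExGaussianModel(_LinearPredictorMixin, BayesModel):
    """Exponentially-modified normal: y = Normal(mu, sigma) + Exp(tau), with
    treatment effects on mu (identity link) and tau (log link)."""

    def __init__(self, y, is_free, X, cov_names, atoll_idx, n_atolls,
                 priors: Mapping[str, Prior] | None = None):
        self.y = np.asarray(y, float)
        self._init_design(is_free, X, cov_names, atoll_idx, n_atolls)
        self.n_obs = self.y.size
        self.param_names = self._linpred_names() + ["sigma", "log_tau", "log_tau_treatment"]
        scale = _robust_scale(self.y)
        defaults: dict[str, Prior] = {
            "intercept": StudentT(3.0, float(np.median(self.y)) - scale, 2.5 * scale),
            "b_treatment": Normal(0.0, 2.5 * max(float(np.std(self.y)), scale)),
            "sigma": HalfStudentT(3.0, 2.5 * scale),
            "atoll_sd": HalfStudentT(3.0, 2.5 * scale),
            "log_tau": Normal(float(np.log(scale)), 1.5),
            "log_tau_treatment": Normal(0.0, 1.0),
        }
        for c in self.cov_names:
            defaults[f"b_{c}"] = Normal(0.0, 2.5 * max(float(np.std(self.y)), scale))
        for j in range(self.n_atolls):
            defaults[f"z_atoll_{j}"] = Normal(0.0, 1.0)
        if priors:
            defaults.update(priors)
        self.priors = {n: defaults[n] for n in self.param_names}

    def _tau(self, p: Mapping[str, np.ndarray]) -> np.ndarray:
        return np.exp(
            p["log_tau"][:, None] + p["log_tau_treatment"][:, None] * self.is_free[None, :]
        )

    def pointwise_log_likelihood(self, theta):
        p = self._unpack(theta)
        mu = self._linpred(p)
        sigma = p["sigma"][:, None]
        tau = self._tau(p)
        y = self.y[None, :]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            z = (y - mu) / sigma - sigma / tau
            out = -np.log(tau) + (mu - y) / tau + sigma * sigma / (2.0 * tau * tau) + log_ndtr(z)
        out[~np.isfinite(out)] = -np.inf
        return out

    def initial_center(self):
        y = self.y
        m3 = float(np.mean((y - y.mean()) ** 3))
        tau0 = max(np.cbrt(m3 / 2.0) if m3 > 0 else 0.1, 0.1)
        sigma0 = float(np.sqrt(max(np.var(y) - tau0 * tau0, 0.25)))
        guess = {
            "intercept": float(y.mean()) - tau0,
            "b_treatment": 0.0,
            "sigma": sigma0,
            "atoll_sd": 0.1 * sigma0,
            "log_tau": float(np.log(tau0)),
            "log_tau_treatment": 0.0,
        }
        for c in self.cov_names:
            guess[f"b_{c}"] = 0.0
        for j in range(self.n_atolls):
            guess[f"z_atoll_{j}"] = 0.0
        return np.array([guess[n] for n in self.param_names])

    def simulate(self, theta, rng):
        p = self._unpack(np.atleast_2d(theta))
        mu = self._linpred(p)[0]
        tau = self._tau(p)[0]
        return mu + rng.normal(0.0, float(p["sigma"][0]), mu.size) + rng.exponential(tau)


# ---------------------------------------------------------------------------
# Fitting wrapper
# ---------------------------------------------------------------------------


@dataclass
class TreatmentEffectPosterior:
    """Posterior of a treatment-effect model plus the metadata needed to
    interpret it (family, link, covariate centers, baseline)."""

    posterior: PosteriorSamples
    spec: TreatmentEffectSpec
    covariate_centers: dict[str, float] = field(default_factory=dict)
    atoll_labels: list[str] = field(default_factory=list)
    n_dropped: int = 0
    n_obs: int = 0

    def treatment_effect_draws(self) -> np.ndarray:
        """Treatment effect on the link scale (rat_free minus baseline)."""
        return self.posterior.get("b_treatment")

    def treatment_effect_summary(self) -> IntervalSummary:
        return interval_summary(self.treatment_effect_draws())

    def summary(self) -> pd.DataFrame:
        return self.posterior.summary()


def _prepare(
    data: pd.DataFrame, spec: TreatmentEffectSpec
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray | None, list[str], dict[str, float], int]:
    required = [spec.response, "treatment", *spec.covariates]
    for col in required:
        if col not in data.columns:
            raise ValueError(f"data lacks required column '{col}'")
    complete = data.dropna(subset=required)
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("dropped %d rows missing %s", n_dropped, "/".join(required))
    if complete.empty:
        raise ValueError("no complete rows for this model")
    is_free = (complete["treatment"] == Treatment.RAT_FREE.value).to_numpy(float)
    if is_free.min() == is_free.max():
        raise ValueError("both treatments must be present")
    if "island_id" in complete.columns:
        for flag, label in ((1.0, "rat_free"), (0.0, "rat_infested")):
            n_isl = complete.loc[is_free == flag, "island_id"].nunique()
            if n_isl < 2:
                warnings.warn(
                    f"only {n_isl} island(s) in treatment {label}; the treatment "
                    "effect is confounded with island identity",
                    stacklevel=3,
                )
    centers = {c: float(complete[c].mean()) for c in spec.covariates}
    X = np.column_stack(
        [complete[c].to_numpy(float) - centers[c] for c in spec.covariates]
    ) if spec.covariates else np.empty((len(complete), 0))
    atoll_idx = None
    labels: list[str] = []
    if spec.group_atoll:
        if "atoll_id" not in complete.columns:
            warnings.warn("group_atoll=True but no atoll_id column; pooling", stacklevel=3)
        else:
            labels = sorted(complete["atoll_id"].astype(str).unique())
            if len(labels) < 2:
                warnings.warn(
                    "fewer than 2 atolls: pooling instead of varying intercepts",
                    stacklevel=3,
                )
                labels = []
            else:
                lookup = {a: j for j, a in enumerate(labels)}
                atoll_idx = complete["atoll_id"].astype(str).map(lookup).to_numpy(int)
    return complete, is_free, X, atoll_idx, labels, centers, n_dropped


def fit_treatment_effect(
    data: pd.DataFrame,
    spec: TreatmentEffectSpec,
    mcmc: MCMCConfig | None = None,
    priors: Mapping[str, Prior] | None = None,
) -> TreatmentEffectPosterior:
    """Fit ``response ~ treatment (+ covariates)`` with an atoll varying
    intercept under the requested response family."""
    mcmc = mcmc or MCMCConfig()
    complete, is_free, X, atoll_idx, labels, centers, n_dropped = _prepare(data, spec)
    y = complete[spec.response].to_numpy(float)
    if float(np.std(y)) == 0.0:
        warnings.warn("response is constant; residual SD will shrink toward 0", stacklevel=2)
    n_atolls = len(labels)
    common = dict(
        is_free=is_free, X=X, cov_names=spec.covariates,
        atoll_idx=atoll_idx, n_atolls=n_atolls, priors=priors,
    )
    if spec.family == "gaussian":
        model = GaussianModel(y, **common)
    elif spec.family == "lognormal":
        if np.any(y <= 0):
            raise ValueError("lognormal family requires a strictly positive response")
        model = GaussianModel(y, log_response=True, **common)
    elif spec.family == "hurdle_gamma":
        model = HurdleGammaModel(y, hurdle_treatment=spec.hurdle_treatment, **common)
    else:
        model = ExGaussianModel(y, **common)
    post = fit(model, mcmc)
    return TreatmentEffectPosterior(
        posterior=post,
        spec=spec,
        covariate_centers=centers,
        atoll_labels=labels,
        n_dropped=n_dropped,
        n_obs=len(complete),
    )


# ---------------------------------------------------------------------------
# GSI
# ---------------------------------------------------------------------------


@dataclass
class GSIResult:
    """GSI model fit: treatment difference at the sample-mean covariate and
    the percent difference relative to the rat-infested adjusted mean."""

    effect: TreatmentEffectPosterior
    difference: IntervalSummary
    percent_difference: IntervalSummary
    adjusted: dict[str, IntervalSummary]
    percent_draws: np.ndarray


def fit_gsi_model(
    fish: Sequence[FishRecord],
    covariate: str = "length",
    include_day: bool = False,
    mcmc: MCMCConfig | None = None,
    priors: Mapping[str, Prior] | None = None,
) -> GSIResult:
    """Gaussian GSI model on spawning-capable females.

    GSI ~ treatment + centered covariate (length or age) [+ collection day],
    with atoll varying intercepts. The treatment difference is evaluated at
    the sample-mean covariate; the percent difference is per-draw
    100 * effect / (rat-infested adjusted GSI).
    """
    if covariate not in ("length", "age"):
        raise ValueError("covariate must be 'length' or 'age'")
    rows = [
        r
        for r in fish
        if r.stage is Stage.SPAWNING_CAPABLE_FEMALE and r.gonad_weight is not None
    ]
    if not rows:
        raise ValueError("no spawning-capable females with gonad weights")
    covcol = {"length": "total_length", "age": "age"}[covariate]
    covs = [covcol] + (["collection_day"] if include_day else [])
    df = pd.DataFrame(
        {
            "gsi": [r.gsi for r in rows],
            "treatment": [r.treatment.value for r in rows],
            "atoll_id": [r.atoll_id for r in rows],
            "island_id": [r.island_id for r in rows],
            "total_length": [r.total_length for r in rows],
            "age": [r.age for r in rows],
            "collection_day": [r.collection_day for r in rows],
        }
    )
    spec = TreatmentEffectSpec(response="gsi", family="gaussian", covariates=tuple(covs))
    tep = fit_treatment_effect(df, spec, mcmc, priors)
    eff = tep.treatment_effect_draws()
    base = tep.posterior.get("intercept")
    pct = 100.0 * eff / base
    return GSIResult(
        effect=tep,
        difference=interval_summary(eff),
        percent_difference=interval_summary(pct),
        adjusted={
            Treatment.RAT_INFESTED.value: interval_summary(base),
            Treatment.RAT_FREE.value: interval_summary(base + eff),
        },
        percent_draws=pct,
    )


@dataclass(frozen=True)
class CorrelationResult:
    estimate: float
    ci_low: float
    ci_high: float
    n: int


def growth_gsi_correlation(
    fish: Sequence[FishRecord],
    vbgf_posterior: PosteriorSamples,
    gsi_result: GSIResult,
    n_boot: int = 2000,
    seed: int = 0,
) -> CorrelationResult:
    """Individual-level growth-fecundity trade-off.

    Per fish: growth deviate = observed length minus the posterior-median
    VBGF mean at its age and treatment; GSI deviate = observed GSI minus the
    posterior-median fitted GSI at its length and treatment (including the
    median atoll offset). Reports the Pearson correlation of the deviates
    with a 95% percentile interval from nonparametric bootstrap resamples.
    """
    tep = gsi_result.effect
    rows = [
        r
        for r in fish
        if r.stage is Stage.SPAWNING_CAPABLE_FEMALE and r.gonad_weight is not None
    ]
    if len(rows) < 10:
        raise ValueError(f"need >= 10 paired fish, got {len(rows)}")

    vmed = {n: float(np.median(vbgf_posterior.get(n))) for n in vbgf_posterior.param_names}
    from .growth_models import VBGFParams, vbgf_mean_length

    vparams = VBGFParams(
        L_inf=vmed["L_inf"], L_0=vmed["L_0"], k=vmed["k"],
        k_b=vmed.get("k_b", 0.0), sigma_L=vmed.get("sigma_L", 0.0),
    )
    gmed = {n: float(np.median(tep.posterior.get(n))) for n in tep.posterior.param_names}
    covcol = tep.spec.covariates[0]
    center = tep.covariate_centers[covcol]
    atoll_pos = {a: j for j, a in enumerate(tep.atoll_labels)}

    gdev, fdev = [], []
    for r in rows:
        mu_len = vbgf_mean_length(r.age, vparams, r.treatment is Treatment.RAT_FREE)
        gdev.append(r.total_length - mu_len)
        x = getattr(r, "total_length" if covcol == "total_length" else covcol)
        mu_gsi = (
            gmed["intercept"]
            + gmed["b_treatment"] * (r.treatment is Treatment.RAT_FREE)
            + gmed[f"b_{covcol}"] * (x - center)
        )
        if r.atoll_id in atoll_pos:
            mu_gsi += gmed.get("atoll_sd", 0.0) * gmed.get(f"z_atoll_{atoll_pos[r.atoll_id]}", 0.0)
        fdev.append(r.gsi - mu_gsi)
    gdev = np.asarray(gdev)
    fdev = np.asarray(fdev)
    rho = float(np.corrcoef(gdev, fdev)[0, 1])
    rng = np.random.default_rng(seed)
    n = gdev.size
    boots = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = np.corrcoef(gdev[idx], fdev[idx])[0, 1]
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return CorrelationResult(estimate=rho, ci_low=float(lo), ci_high=float(hi), n=n)


# ---------------------------------------------------------------------------
# Ratios & size structure
# ---------------------------------------------------------------------------


def back_transform_ratio(tep: TreatmentEffectPosterior) -> tuple[np.ndarray, IntervalSummary]:
    """Fold difference rat_free : rat_infested for log-linked models:
    per-draw exp(treatment effect)."""
    if tep.spec.family not in ("lognormal", "hurdle_gamma"):
        raise ValueError(
            f"family '{tep.spec.family}' has an identity-link treatment effect; "
            "a back-transformed ratio is undefined"
        )
    ratio = np.exp(tep.treatment_effect_draws())
    return ratio, interval_summary(ratio)


@dataclass
class SizeStructureResult:
    effect: TreatmentEffectPosterior
    mean_contrast: IntervalSummary
    mean_percent: IntervalSummary
    skew_contrast: IntervalSummary
    mean_contrast_draws: np.ndarray
    skew_contrast_draws: np.ndarray
    means: dict[str, IntervalSummary]


def fit_size_structure(
    data: pd.DataFrame,
    mcmc: MCMCConfig | None = None,
    group_atoll: bool | None = None,
    min_per_treatment: int = 30,
    priors: Mapping[str, Prior] | None = None,
) -> SizeStructureResult:
    """Ex-Gaussian size-distribution model on pooled surveyed lengths.

    ``data`` needs columns ``length`` and ``treatment`` (``atoll_id``
    optional). Treatment shifts both the normal location mu and, on the log
    scale, the exponential (skew) component tau; the distribution mean is
    mu + tau per draw, so the mean-size contrast propagates both effects.
    """
    mcmc = mcmc or MCMCConfig()
    if group_atoll is None:
        group_atoll = "atoll_id" in data.columns
    for treat in (Treatment.RAT_FREE.value, Treatment.RAT_INFESTED.value):
        n = int((data["treatment"] == treat).sum())
        if n < min_per_treatment:
            raise ValueError(
                f"size-structure model needs >= {min_per_treatment} lengths per "
                f"treatment; {treat} has {n}"
            )
    spec = TreatmentEffectSpec(response="length", family="exgaussian", group_atoll=group_atoll)
    tep = fit_treatment_effect(data, spec, mcmc, priors)
    post = tep.posterior
    mu0 = post.get("intercept")
    dmu = post.get("b_treatment")
    tau0 = np.exp(post.get("log_tau"))
    tau1 = np.exp(post.get("log_tau") + post.get("log_tau_treatment"))
    mean_inf = mu0 + tau0
    mean_free = mu0 + dmu + tau1
    mean_contrast = mean_free - mean_inf
    skew_contrast = tau1 - tau0
    return SizeStructureResult(
        effect=tep,
        mean_contrast=interval_summary(mean_contrast),
        mean_percent=interval_summary(100.0 * mean_contrast / mean_inf),
        skew_contrast=interval_summary(skew_contrast),
        mean_contrast_draws=mean_contrast,
        skew_contrast_draws=skew_contrast,
        means={
            Treatment.RAT_INFESTED.value: interval_summary(mean_inf),
            Treatment.RAT_FREE.value: interval_summary(mean_free),
        },
    )


def size_frequency(
    data: pd.DataFrame, binwidth: float = 2.5, origin: float = 8.0
) -> pd.DataFrame:
    """Size-frequency histogram per treatment.

    Left-closed right-open bins aligned at the survey cutoff (8 cm): the
    first bin is [8, 10.5) for the default 2.5 cm width.
    """
    if data.empty:
        return pd.DataFrame(columns=["bin_low", "bin_high", "treatment", "count"])
    lengths = data["length"].to_numpy(float)
    if np.any(lengths < origin):
        raise ValueError(f"lengths below the {origin} cm survey cutoff")
    top = float(lengths.max())
    n_bins = int(np.floor((top - origin) / binwidth)) + 1
    edges = origin + binwidth * np.arange(n_bins + 1)
    rows = []
    for treat, grp in data.groupby("treatment"):
        vals = grp["length"].to_numpy(float)
        idx = np.floor((vals - origin) / binwidth).astype(int)
        counts = np.bincount(idx, minlength=n_bins)
        for b in range(n_bins):
            rows.append(
                {
                    "bin_low": edges[b],
                    "bin_high": edges[b + 1],
                    "treatment": treat,
                    "count": int(counts[b]),
                }
            )
    return pd.DataFrame(rows)
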