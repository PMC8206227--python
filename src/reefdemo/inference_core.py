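"""Shared Bayesian machinery.

Models are expressed as log-density objects (prior + vectorised pointwise
likelihood) and sampled with the affine-invariant ensemble MCMC of
``emcee``. The ``chains`` of :class:`MCMCConfig` map to independent
ensembles started from jittered initial points with distinct seeds; within
an ensemble the walkers are flattened into the draw dimension, so
convergence diagnostics compare genuinely independent chains.

Diagnostics (rank-normalised split R-hat, bulk ESS) and model comparison
(PSIS-LOO expected log predictive density) are delegated to ``arviz``;
highest-posterior-density intervals are computed here with an explicitly
specified narrowest-window rule so they can be checked against a
brute-force scan.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

import emcee

logger = logging.getLogger("reefdemo")

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "IntervalSummary",
    "Prior",
    "Normal",
    "HalfNormal",
    "StudentT",
    "HalfStudentT",
    "TruncatedNormal",
    "BayesModel",
    "fit",
    "hpdi",
    "rhat",
    "ess",
    "compare_models",
    "posterior_predictive_check",
    "interval_summary",
    "summarize_posterior",
]

RHAT_WARN_THRESHOLD = 1.01


# ---------------------------------------------------------------------------
# Priors (closed-form log-densities, vectorised; scipy-free for speed in the
# sampler hot loop)
# ---------------------------------------------------------------------------

_LOG_2PI = math.log(2.0 * math.pi)


class Prior:
    """A univariate prior: vectorised log-density plus a sampler for inits."""

    def logpdf(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class Normal(Prior):
    mu: float
    sd: float

    def logpdf(self, x):
        z = (np.asarray(x, float) - self.mu) / self.sd
        return -0.5 * (z * z + _LOG_2PI) - math.log(self.sd)

    def sample(self, rng, size):
        return rng.normal(self.mu, self.sd, size)


@dataclass(frozen=True)
class HalfNormal(Prior):
    sd: float

    def logpdf(self, x):
        x = np.asarray(x, float)
        z = x / self.sd
        out = math.log(2.0) - 0.5 * (z * z + _LOG_2PI) - math.log(self.sd)
        return np.where(x >= 0, out, -np.inf)

    def sample(self, rng, size):
        return np.abs(rng.normal(0.0, self.sd, size))


@dataclass(frozen=True)
class StudentT(Prior):
    df: float
    loc: float
    scale: float

    def _const(self) -> float:
        v = self.df
        return (
            math.lgamma((v + 1) / 2)
            - math.lgamma(v / 2)
            - 0.5 * math.log(v * math.pi)
            - math.log(self.scale)
        )

    def logpdf(self, x):
        z = (np.asarray(x, float) - self.loc) / self.scale
        return self._const() - (self.df + 1) / 2 * np.log1p(z * z / self.df)

    def sample(self, rng, size):
        return self.loc + self.scale * rng.standard_t(self.df, size)


@dataclass(frozen=True)
class HalfStudentT(Prior):
    df: float
    scale: float

    def logpdf(self, x):
        x = np.asarray(x, float)
        base = StudentT(self.df, 0.0, self.scale).logpdf(x) + math.log(2.0)
        return np.where(x >= 0, base, -np.inf)

    def sample(self, rng, size):
        return np.abs(self.scale * rng.standard_t(self.df, size))


@dataclass(frozen=True)
class TruncatedNormal(Prior):
    """Normal(mu, sd) truncated to [lower, inf); the normalising constant is
    dropped (it is parameter-free, so posterior inference is unaffected)."""

    mu: float
    sd: float
    lower: float = -np.inf

    def logpdf(self, x):
        x = np.asarray(x, float)
        z = (x - self.mu) / self.sd
        out = -0.5 * (z * z + _LOG_2PI) - math.log(self.sd)
        return np.where(x >= self.lower, out, -np.inf)

    def sample(self, rng, size):
        draws = rng.normal(self.mu, self.sd, size)
        for _ in range(100):
            bad = draws < self.lower
            if not bad.any():
                break
            draws[bad] = rng.normal(self.mu, self.sd, bad.sum())
        return np.clip(draws, self.lower, None)


# ---------------------------------------------------------------------------
# Model protocol and sampler configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler contract: 4 chains of >= 3,000 iterations with 1,000 warm-up
    by default. ``iterations`` counts ensemble moves per chain; the draws
    retained per chain are ``(iterations - warmup) * walkers``."""

    chains: int = 4
    iterations: int = 3000
    warmup: int = 1000
    seed: int = 0
    target_accept: float = 0.9
    walkers: int | None = None  # default: max(2*ndim + 2, 10)
    loglik_thin_target: int = 500  # draws/chain kept for pointwise log-lik

    def __post_init__(self) -> None:
        if self.iterations <= self.warmup:
            raise ValueError("iterations must exceed warmup")
        if self.chains < 2:
            raise ValueError("at least 2 chains are required for diagnostics")


class BayesModel:
    """Base class for a Bayesian model: named parameters with priors and a
    vectorised Gaussian-or-otherwise likelihood.

    Subclasses implement :meth:`log_likelihood` (vectorised over parameter
    rows), :meth:`pointwise_log_likelihood` (per-observation, for LOO and
    posterior predictive work), :meth:`initial_center` and optionally
    :meth:`simulate` (one replicated response vector per parameter row).
    """

    param_names: Sequence[str]
    priors: Mapping[str, Prior]
    n_obs: int

    # -- interface -----------------------------------------------------
    def log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        return self.pointwise_log_likelihood(theta).sum(axis=-1)

    def pointwise_log_likelihood(self, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def initial_center(self) -> np.ndarray:
        raise NotImplementedError

    def simulate(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError(f"{type(self).__name__} does not simulate replicates")

    # -- shared machinery ----------------------------------------------
    @property
    def ndim(self) -> int:
        return len(self.param_names)

    def log_prior(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = np.zeros(theta.shape[0])
        for j, name in enumerate(self.param_names):
            lp += self.priors[name].logpdf(theta[:, j])
        return lp

    def log_prob(self, theta: np.ndarray) -> np.ndarray:
        theta = np.atleast_2d(theta)
        lp = self.log_prior(theta)
        ok = np.isfinite(lp)
        out = np.full(theta.shape[0], -np.inf)
        if ok.any():
            ll = self.log_likelihood(theta[ok])
            out[ok] = lp[ok] + np.where(np.isfinite(ll), ll, -np.inf)
        return out


@dataclass
class PosteriorSamples:
    """Joint posterior draws indexed (chain, draw), with pointwise
    log-likelihood on a thinned subset of draws and sampler diagnostics."""

    param_names: list[str]
    draws: np.ndarray  # (chains, ndraws, ndim)
    log_likelihood: np.ndarray | None  # (chains, nthin, n_obs)
    rhat: dict[str, float] = field(default_factory=dict)
    ess: dict[str, float] = field(default_factory=dict)
    divergences: int = 0
    acceptance_fraction: float = float("nan")
    model: BayesModel | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("posterior draws contain non-finite values")

    # -- accessors -----------------------------------------------------
    def get(self, name: str) -> np.ndarray:
        """Flattened draws (all chains pooled) for one parameter."""
        j = self.param_names.index(name)
        return self.draws[:, :, j].reshape(-1)

    def by_chain(self, name: str) -> np.ndarray:
        j = self.param_names.index(name)
        return self.draws[:, :, j]

    def stacked(self) -> np.ndarray:
        """All draws pooled: shape (chains*ndraws, ndim)."""
        return self.draws.reshape(-1, self.draws.shape[-1])

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0] * self.draws.shape[1]

    def to_inferencedata(self) -> az.InferenceData:
        posterior = {
            name: self.draws[:, :, j] for j, name in enumerate(self.param_names)
        }
        groups: dict = {"posterior": posterior}
        if self.log_likelihood is not None:
            groups["log_likelihood"] = {"obs": self.log_likelihood}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return az.from_dict(**groups)

    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self)


@dataclass(frozen=True)
class IntervalSummary:
    """Posterior point-and-interval summary: median plus 75% and 95% HPDIs."""

    median: float
    hpdi75: tuple[float, float]
    hpdi95: tuple[float, float]

    @classmethod
    def from_draws(cls, draws: np.ndarray) -> "IntervalSummary":
        return cls(
            median=float(np.median(draws)),
            hpdi75=hpdi(draws, 0.75),
            hpdi95=hpdi(draws, 0.95),
        )

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        return {
            f"{prefix}median": self.median,
            f"{prefix}hpdi75_low": self.hpdi75[0],
            f"{prefix}hpdi75_high": self.hpdi75[1],
            f"{prefix}hpdi95_low": self.hpdi95[0],
            f"{prefix}hpdi95_high": self.hpdi95[1],
        }


def interval_summary(draws: np.ndarray) -> IntervalSummary:
    return IntervalSummary.from_draws(np.asarray(draws, float))


# ---------------------------------------------------------------------------
# fit
# ---------------------------------------------------------------------------


def fit(
    model: BayesModel,
    mcmc: MCMCConfig,
    init_jitter: float = 0.05,
    compute_loglik: bool = True,
) -> PosteriorSamples:
    """Sample a model's posterior.

    Runs ``mcmc.chains`` independent stretch-move ensembles, each seeded
    from ``mcmc.seed``, discards ``warmup`` moves, and flattens walkers into
    the draw axis. Warns when any parameter's R-hat exceeds 1.01.

    Raises
    ------
    RuntimeError
        if the log-density is non-finite at the initial points (with a
        report of the offending parameters).
    ValueError
        if the model has no observations (fit a prior-only model explicitly
        by constructing a model whose likelihood is zero, not by passing
        empty data).
    """
    if model.n_obs == 0:
        raise ValueError("model has no observations; refusing a silent prior-only fit")
    ndim = model.ndim
    nwalkers = mcmc.walkers or max(2 * ndim + 2, 10)
    if nwalkers % 2:
        nwalkers += 1
    keep = mcmc.iterations - mcmc.warmup

    center = np.asarray(model.initial_center(), float)
    if center.shape != (ndim,):
        raise ValueError("initial_center must return one value per parameter")

    all_chains = []
    acc = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng((mcmc.seed, c))
        scale = np.maximum(np.abs(center) * init_jitter, 1e-3)
        p0 = center + rng.normal(0.0, 1.0, (nwalkers, ndim)) * scale
        lp0 = model.log_prob(p0)
        for _ in range(200):
            bad = ~np.isfinite(lp0)
            if not bad.any():
                break
            p0[bad] = center + rng.normal(0.0, 1.0, (int(bad.sum()), ndim)) * scale * 0.5
            lp0[bad] = model.log_prob(p0[bad])
        if not np.all(np.isfinite(lp0)):
            report = ", ".join(
                f"{n}={v:.4g}" for n, v in zip(model.param_names, center)
            )
            raise RuntimeError(
                f"non-finite log-density at initialization (center: {report})"
            )
        sampler = emcee.EnsembleSampler(nwalkers, ndim, model.log_prob, vectorize=True)
        sampler.random_state = np.random.RandomState(
            int(np.random.SeedSequence((mcmc.seed, c, 7)).generate_state(1)[0])
        ).get_state()
        sampler.run_mcmc(p0, mcmc.iterations, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=mcmc.warmup)  # (keep, nwalkers, ndim)
        all_chains.append(chain.transpose(1, 0, 2).reshape(keep * nwalkers, ndim))
        acc.append(float(np.mean(sampler.acceptance_fraction)))

    draws = np.stack(all_chains)  # (chains, keep*nwalkers, ndim)

    rhats, esss = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for j, name in enumerate(model.param_names):
            arr = draws[:, :, j]
            if np.allclose(arr, arr.flat[0]):
                rhats[name], esss[name] = float("nan"), float("nan")
            else:
                rhats[name] = float(az.rhat(arr))
                esss[name] = float(az.ess(arr))
    bad_rhat = {n: r for n, r in rhats.items() if np.isfinite(r) and r > RHAT_WARN_THRESHOLD}
    if bad_rhat:
        msg = ", ".join(f"{n}: {r:.4f}" for n, r in bad_rhat.items())
        warnings.warn(f"R-hat above {RHAT_WARN_THRESHOLD}: {msg}", stacklevel=2)
        logger.warning("convergence warning — %s", msg)

    loglik = None
    if compute_loglik:
        nthin = min(mcmc.loglik_thin_target, draws.shape[1])
        idx = np.linspace(0, draws.shape[1] - 1, nthin).astype(int)
        loglik = np.stack(
            [model.pointwise_log_likelihood(draws[c, idx]) for c in range(mcmc.chains)]
        )

    return PosteriorSamples(
        param_names=list(model.param_names),
        draws=draws,
        log_likelihood=loglik,
        rhat=rhats,
        ess=esss,
        divergences=0,  # stretch moves have no divergence concept
        acceptance_fraction=float(np.mean(acc)),
        model=model,
    )


# ---------------------------------------------------------------------------
# HPDI
# ---------------------------------------------------------------------------


def hpdi(draws: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Highest posterior density interval.

    The narrowest contiguous window of the sorted draws containing
    ``ceil(mass * n)`` draws; ties are broken by the smallest lower bound.

    Parameters
    ----------
    draws : array-like
        Finite posterior draws (at least one).
    mass : float
        Probability mass, strictly between 0 and 1.
    """
    x = np.sort(np.asarray(draws, float).ravel())
    if x.size == 0:
        raise ValueError("hpdi requires at least one draw")
    if not np.all(np.isfinite(x)):
        raise ValueError("hpdi requires finite draws")
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie strictly between 0 and 1")
    n = x.size
    m = min(n, int(math.ceil(mass * n)))
    if m == n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: smallest lower bound
    return float(x[i]), float(x[i + m - 1])


# ---------------------------------------------------------------------------
# Diagnostics & model comparison
# ---------------------------------------------------------------------------


def rhat(chains: np.ndarray) -> float:
    """Rank-normalised split R-hat for one parameter, draws shaped (chain, draw).

    Constant chains (zero variance) return NaN with a warning rather than
    failing.
    """
    arr = np.asarray(chains, float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("rhat requires draws shaped (chains, draws) with >= 2 chains")
    if np.allclose(arr, arr.flat[0]):
        warnings.warn("constant chains: R-hat undefined, returning NaN", stacklevel=2)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.rhat(arr))


def ess(chains: np.ndarray) -> float:
    """Bulk effective sample size, draws shaped (chain, draw)."""
    arr = np.asarray(chains, float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("ess requires draws shaped (chains, draws) with >= 2 chains")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(arr))


def compare_models(posteriors: Mapping[str, PosteriorSamples]) -> pd.DataFrame:
    """Rank models by PSIS-LOO expected log predictive density.

    All models must have been fit to the identical set of observations.
    Returns the arviz comparison table (rank 0 = best), with columns for
    elpd_loo, the pairwise elpd difference to the best model and its SE.
    """
    n_obs = None
    idatas = {}
    for name, post in posteriors.items():
        if post.log_likelihood is None:
            raise ValueError(f"model '{name}' has no stored pointwise log-likelihood")
        if n_obs is None:
            n_obs = post.log_likelihood.shape[-1]
        elif post.log_likelihood.shape[-1] != n_obs:
            raise ValueError("models were fit to different observation sets")
        idatas[name] = post.to_inferencedata()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = az.compare(idatas, ic="loo")
    return table


def posterior_predictive_check(
    posterior: PosteriorSamples,
    observed: np.ndarray,
    statistics: Mapping[str, Callable[[np.ndarray], float]],
    n_replicates: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed-vs-replicated test statistics.

    For each statistic, simulates ``n_replicates`` datasets from randomly
    chosen posterior draws and reports the observed value together with its
    quantile among the replicated values. Quantiles near 0 or 1 flag
    misfit of that feature of the data.
    """
    if not statistics:
        return pd.DataFrame(columns=["statistic", "observed", "quantile"])
    model = posterior.model
    if model is None:
        raise ValueError("posterior carries no model; cannot simulate replicates")
    rng = np.random.default_rng(seed)
    flat = posterior.stacked()
    idx = rng.integers(0, flat.shape[0], n_replicates)
    reps = [model.simulate(flat[i], rng) for i in idx]
    rows = []
    observed = np.asarray(observed, float)
    for name, fn in statistics.items():
        obs_val = float(fn(observed))
        rep_vals = np.array([fn(r) for r in reps], float)
        q = float(np.mean(rep_vals < obs_val) + 0.5 * np.mean(rep_vals == obs_val))
        rows.append({"statistic": name, "observed": obs_val, "quantile": q})
    return pd.DataFrame(rows)


def summarize_posterior(post: PosteriorSamples) -> pd.DataFrame:
    """Per-parameter summary table: median, 75%/95% HPDIs, R-hat, ESS."""
    rows = []
    for name in post.param_names:
        s = IntervalSummary.from_draws(post.get(name))
        rows.append(
            {
                "parameter": name,
                **s.as_dict(),
                "rhat": post.rhat.get(name, float("nan")),
                "ess": post.ess.get(name, float("nan")),
            }
        )
    return pd.DataFrame(rows)
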