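"""The response-family engine: gaussian/lognormal/hurdle-gamma/ex-Gaussian
likelihoods, GSI models, the growth-GSI correlation, back-transformed
ratios, size structure and size-frequency binning."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reefdemo.data_model import Treatment
from reefdemo.inference_core import MCMCConfig, PosteriorSamples
from reefdemo.growth_models import fit_vbgf
from reefdemo.synthetic_data import (
    GsiGen,
    SyntheticConfig,
    draw_exgaussian_lengths,
    simulate_fish,
)
from reefdemo.treatment_effects import (
    ExGaussianModel,
    HurdleGammaModel,
    TreatmentEffectPosterior,
    TreatmentEffectSpec,
    back_transform_ratio,
    fit_gsi_model,
    fit_size_structure,
    fit_treatment_effect,
    growth_gsi_correlation,
    size_frequency,
)


def _toy_frame(rng, n=400, effect=1.0, sd=1.0):
    free = rng.random(n) < 0.5
    y = 2.0 + effect * free + rng.normal(0, sd, n)
    return pd.DataFrame(
        {"y": y, "treatment": np.where(free, "rat_free", "rat_infested")}
    )


class TestGaussianEngine:
    def test_pooled_effect_converges_to_difference_of_means(self, rng, fast_mcmc):
        df = _toy_frame(rng, n=600, effect=0.8)
        spec = TreatmentEffectSpec(response="y", family="gaussian", group_atoll=False)
        tep = fit_treatment_effect(df, spec, fast_mcmc)
        sample_diff = df.loc[df.treatment == "rat_free", "y"].mean() - df.loc[
            df.treatment == "rat_infested", "y"
        ].mean()
        draws = tep.treatment_effect_draws()
        mcse = 3 * draws.std() / np.sqrt(200)
        assert draws.mean() == pytest.approx(sample_diff, abs=max(3 * mcse, 0.05))

    def test_constant_response_warns_and_centres_on_zero(self, rng, fast_mcmc):
        df = _toy_frame(rng, n=60, effect=0.0, sd=1.0)
        df["y"] = 5.0
        spec = TreatmentEffectSpec(response="y", family="gaussian", group_atoll=False)
        with pytest.warns(UserWarning, match="constant"):
            tep = fit_treatment_effect(df, spec, fast_mcmc)
        s = tep.treatment_effect_summary()
        assert s.hpdi95[0] < 0 < s.hpdi95[1]
        assert abs(s.median) < 0.05

    def test_missing_treatment_rejected(self, rng, fast_mcmc):
        df = _toy_frame(rng, n=40)
        df["treatment"] = "rat_free"
        spec = TreatmentEffectSpec(response="y", family="gaussian")
        with pytest.raises(ValueError, match="both treatments"):
            fit_treatment_effect(df, spec, fast_mcmc)

    def test_single_atoll_pools_with_warning(self, rng, fast_mcmc):
        df = _toy_frame(rng, n=60)
        df["atoll_id"] = "only_one"
        spec = TreatmentEffectSpec(response="y", family="gaussian", group_atoll=True)
        with pytest.warns(UserWarning, match="pooling"):
            tep = fit_treatment_effect(df, spec, fast_mcmc)
        assert "atoll_sd" not in tep.posterior.param_names

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError, match="family"):
            TreatmentEffectSpec(response="y", family="poisson")


class TestLikelihoodCrossChecks:
    """Our closed-form log-densities against scipy's reference distributions."""

    def test_exgaussian_logpdf_matches_scipy_exponnorm(self, rng):
        y = rng.normal(15, 3, 50) + rng.exponential(2.5, 50)
        model = ExGaussianModel(
            y, is_free=np.zeros(50), X=np.empty((50, 0)), cov_names=[],
            atoll_idx=None, n_atolls=0,
        )
        mu, sigma, tau = 14.0, 2.0, 3.0
        theta = np.array([[mu, 0.0, sigma, np.log(tau), 0.0]])
        ours = model.pointwise_log_likelihood(theta)[0]
        ref = stats.exponnorm.logpdf(y, K=tau / sigma, loc=mu, scale=sigma)
        np.testing.assert_allclose(ours, ref, rtol=1e-8, atol=1e-8)

    def test_hurdle_gamma_logpdf_matches_composition(self, rng):
        y = np.concatenate([np.zeros(10), rng.gamma(2.0, 3.0, 30)])
        model = HurdleGammaModel(
            y, is_free=np.zeros(40), X=np.empty((40, 0)), cov_names=[],
            atoll_idx=None, n_atolls=0,
        )
        log_mu, logit_p0, shape = 1.8, -0.4, 2.5
        theta = np.array([[log_mu, 0.0, logit_p0, shape]])
        ours = model.pointwise_log_likelihood(theta)[0]
        p0 = 1 / (1 + np.exp(-logit_p0))
        mu = np.exp(log_mu)
        ref = np.where(
            y == 0,
            np.log(p0),
            np.log(1 - p0) + stats.gamma.logpdf(y, a=shape, scale=mu / shape),
        )
        np.testing.assert_allclose(ours, ref, rtol=1e-8, atol=1e-8)

    def test_hurdle_zero_probability_matches_zero_fraction(self, rng, fast_mcmc):
        n = 400
        zero = rng.random(n) < 0.35
        y = np.where(zero, 0.0, rng.gamma(2.0, 4.0, n))
        df = pd.DataFrame({"y": y, "treatment": np.where(rng.random(n) < 0.5, "rat_free", "rat_infested")})
        spec = TreatmentEffectSpec(response="y", family="hurdle_gamma", group_atoll=False)
        tep = fit_treatment_effect(df, spec, fast_mcmc)
        model = tep.posterior.model
        p0 = float(np.median(model.zero_probability_draws(tep.posterior.stacked())))
        obs = float((y == 0).mean())
        assert p0 == pytest.approx(obs, abs=3 * np.sqrt(obs * (1 - obs) / n))


@pytest.fixture(scope="module")
def gsi_fish():
    return simulate_fish(SyntheticConfig(n_atolls=4, seed=55))


class TestGSI:

    def test_recovers_negative_treatment_shift(self, gsi_fish, fast_mcmc):
        res = fit_gsi_model(gsi_fish, covariate="length", mcmc=fast_mcmc)
        lo, hi = res.difference.hpdi95
        assert lo <= -0.25 <= hi
        # percent difference has the sign of the shift and a sane magnitude
        assert -60 < res.percent_difference.median < 0

    def test_variants_agree_on_the_treatment_difference(self, gsi_fish, fast_mcmc):
        meds = []
        for kwargs in (
            dict(covariate="length"),
            dict(covariate="age"),
            dict(covariate="length", include_day=True),
        ):
            res = fit_gsi_model(gsi_fish, mcmc=fast_mcmc, **kwargs)
            meds.append(res.difference.median)
        assert max(meds) - min(meds) < 0.1

    def test_requires_spawning_capable_females(self, fast_mcmc):
        import dataclasses as dc

        from reefdemo.data_model import Stage

        fish = [
            dc.replace(f, stage=Stage.IP_MALE, gonad_weight=None)
            for f in simulate_fish(SyntheticConfig(seed=1))
        ]
        with pytest.raises(ValueError, match="spawning-capable"):
            fit_gsi_model(fish, mcmc=fast_mcmc)

    def test_correlation_null_case_covers_zero(self, fast_mcmc):
        cfg = SyntheticConfig(
            n_atolls=4, gsi=GsiGen(rho_growth_gsi=0.0), seed=202
        )
        fish = simulate_fish(cfg)
        vb = fit_vbgf(fish, mcmc=fast_mcmc)
        gs = fit_gsi_model(fish, mcmc=fast_mcmc)
        corr = growth_gsi_correlation(fish, vb, gs, seed=3)
        assert corr.ci_low <= 0.0 <= corr.ci_high

    def test_correlation_needs_enough_fish(self, fast_mcmc, study_fish):
        vb = fit_vbgf(study_fish, mcmc=fast_mcmc)
        gs = fit_gsi_model(study_fish, mcmc=fast_mcmc)
        with pytest.raises(ValueError, match=">= 10"):
            growth_gsi_correlation(study_fish[:5], vb, gs)


def _fake_tep(effect_draws, family):
    draws = np.asarray(effect_draws, float).reshape(2, -1, 1)
    post = PosteriorSamples(param_names=["b_treatment"], draws=draws, log_likelihood=None)
    return TreatmentEffectPosterior(
        posterior=post, spec=TreatmentEffectSpec(response="y", family=family)
    )


class TestBackTransformRatio:
    def test_zero_effect_gives_ratio_one(self):
        _, s = back_transform_ratio(_fake_tep(np.zeros(100), "lognormal"))
        assert s.median == 1.0

    def test_log2_effect_gives_ratio_two(self):
        _, s = back_transform_ratio(_fake_tep(np.full(100, np.log(2.0)), "hurdle_gamma"))
        assert s.median == pytest.approx(2.0, abs=1e-12)

    def test_identity_link_rejected(self):
        with pytest.raises(ValueError, match="identity-link"):
            back_transform_ratio(_fake_tep(np.zeros(10), "gaussian"))

    def test_label_swap_gives_reciprocal(self, rng, fast_mcmc):
        n = 200
        free = rng.random(n) < 0.5
        y = np.exp(1.0 + 0.7 * free + rng.normal(0, 0.4, n))
        df = pd.DataFrame({"y": y, "treatment": np.where(free, "rat_free", "rat_infested")})
        swapped = df.assign(
            treatment=df.treatment.map({"rat_free": "rat_infested", "rat_infested": "rat_free"})
        )
        spec = TreatmentEffectSpec(response="y", family="lognormal", group_atoll=False)
        r1, s1 = back_transform_ratio(fit_treatment_effect(df, spec, fast_mcmc))
        r2, s2 = back_transform_ratio(fit_treatment_effect(swapped, spec, fast_mcmc))
        assert s1.median == pytest.approx(1.0 / s2.median, rel=0.1)


class TestSizeStructure:
    def test_null_simulation_contrasts_cover_zero(self, fast_mcmc, rng):
        li = draw_exgaussian_lengths(400, 12.0, 2.5, 3.0, rng)
        lf = draw_exgaussian_lengths(400, 12.0, 2.5, 3.0, rng)
        df = pd.DataFrame(
            {
                "length": np.concatenate([li, lf]),
                "treatment": ["rat_infested"] * 400 + ["rat_free"] * 400,
            }
        )
        res = fit_size_structure(df, mcmc=fast_mcmc)
        assert res.mean_contrast.hpdi95[0] <= 0 <= res.mean_contrast.hpdi95[1]
        assert res.skew_contrast.hpdi95[0] <= 0 <= res.skew_contrast.hpdi95[1]

    def test_mean_identity_mu_plus_tau(self, fast_mcmc, rng):
        li = draw_exgaussian_lengths(200, 12.0, 2.5, 3.0, rng)
        lf = draw_exgaussian_lengths(200, 14.0, 2.5, 3.5, rng)
        df = pd.DataFrame(
            {
                "length": np.concatenate([li, lf]),
                "treatment": ["rat_infested"] * 200 + ["rat_free"] * 200,
            }
        )
        res = fit_size_structure(df, mcmc=fast_mcmc)
        post = res.effect.posterior
        mean_inf = post.get("intercept") + np.exp(post.get("log_tau"))
        mean_free = (
            post.get("intercept") + post.get("b_treatment")
            + np.exp(post.get("log_tau") + post.get("log_tau_treatment"))
        )
        np.testing.assert_allclose(res.mean_contrast_draws, mean_free - mean_inf)

    def test_insufficient_lengths_rejected(self, fast_mcmc):
        df = pd.DataFrame(
            {"length": np.full(40, 12.0), "treatment": ["rat_free"] * 35 + ["rat_infested"] * 5}
        )
        with pytest.raises(ValueError, match=">= 30"):
            fit_size_structure(df, mcmc=fast_mcmc)


class TestSizeFrequency:
    def test_single_length_single_bin(self):
        df = pd.DataFrame({"length": [8.0], "treatment": ["rat_free"]})
        out = size_frequency(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row["bin_low"], row["bin_high"], row["count"]) == (8.0, 10.5, 1)

    def test_boundary_split_under_left_closed_convention(self):
        df = pd.DataFrame({"length": [10.4, 10.5], "treatment": ["rat_free"] * 2})
        out = size_frequency(df)
        counts = dict(zip(out["bin_low"], out["count"]))
        assert counts[8.0] == 1 and counts[10.5] == 1

    def test_empty_input_empty_table(self):
        assert size_frequency(pd.DataFrame(columns=["length", "treatment"])).empty
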