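"""VBGF mean function, three-age reparameterisation algebra, extremes, and
null-recovery behaviour of the Bayesian growth fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import least_squares

from reefdemo.data_model import FishRecord, Stage, Treatment
from reefdemo.growth_models import (
    ThreeAgeModel,
    ThreeAgeParams,
    VBGFParams,
    fit_three_age_vbgf,
    fit_vbgf,
    island_upper_quartile,
    length_at_age_contrast,
    percent_growth_difference,
    three_age_from_vbgf,
    upper_quartile_extremes,
    vbgf_from_three_age,
    vbgf_mean_length,
)
from reefdemo.inference_core import hpdi
from reefdemo.synthetic_data import GrowthGen, SyntheticConfig, simulate_fish


class TestMeanFunction:
    def test_age_zero_returns_L0_for_either_treatment(self):
        p = VBGFParams(25.0, 8.0, 0.27, k_b=0.11)
        assert vbgf_mean_length(0.0, p, False) == 8.0
        assert vbgf_mean_length(0.0, p, True) == 8.0

    def test_known_evaluations(self):
        p = VBGFParams(25.0, 8.0, 0.27, k_b=0.11)
        expected_infested = 25.0 - 17.0 * math.exp(-0.27 * 4)
        expected_free = 25.0 - 17.0 * math.exp(-0.38 * 4)
        assert vbgf_mean_length(4.0, p, False) == pytest.approx(expected_infested, abs=1e-9)
        assert vbgf_mean_length(4.0, p, True) == pytest.approx(expected_free, abs=1e-9)
        assert round(expected_infested, 3) == 19.227
        assert round(expected_free, 3) == 21.282

    @given(
        L_inf=st.floats(15.0, 60.0),
        L_0=st.floats(0.0, 12.0),
        k=st.floats(0.05, 1.0),
        k_b=st.floats(-0.04, 0.5),
        flag=st.booleans(),
    )
    def test_monotone_increasing_and_asymptotic(self, L_inf, L_0, k, k_b, flag):
        p = VBGFParams(L_inf, L_0, k, k_b)
        rate = k + (k_b if flag else 0.0)
        t_star = math.log(100.0) / rate
        # strict increase over the approach region (beyond it the curve is
        # numerically flat at L_inf)
        ages = np.linspace(0, t_star, 200)
        lengths = vbgf_mean_length(ages, p, flag)
        assert np.all(np.diff(lengths) > 0)
        tail = vbgf_mean_length(t_star * 1.001, p, flag)
        assert abs(tail - L_inf) < 0.01 * (L_inf - L_0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(L_inf=10.0, L_0=12.0, k=0.3),     # L_inf <= L_0
            dict(L_inf=25.0, L_0=8.0, k=-0.1),     # k <= 0
            dict(L_inf=25.0, L_0=8.0, k=0.1, k_b=-0.2),  # k + k_b <= 0
            dict(L_inf=25.0, L_0=8.0, k=0.3, sigma_L=-1.0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VBGFParams(**kwargs)

    def test_negative_age_rejected(self):
        with pytest.raises(ValueError):
            vbgf_mean_length(-1.0, VBGFParams(25.0, 8.0, 0.27))


class TestThreeAgeAlgebra:
    @given(
        L_inf=st.floats(18.0, 50.0),
        L_0=st.floats(0.0, 12.0),
        k=st.floats(0.05, 1.2),
    )
    def test_round_trip_recovers_parameters(self, L_inf, L_0, k):
        lphi, lchi, lpsi = three_age_from_vbgf(L_inf, L_0, k)
        back = vbgf_from_three_age(lphi, lchi, lpsi)
        assert back[0] == pytest.approx(L_inf, abs=1e-9, rel=1e-9)
        assert back[1] == pytest.approx(L_0, abs=1e-9, rel=1e-9)
        assert back[2] == pytest.approx(k, abs=1e-9, rel=1e-9)

    def test_middle_age_must_be_midpoint(self):
        with pytest.raises(ValueError):
            ThreeAgeParams(l_phi=12.0, l_chi=16.0, l_psi=19.0, tau_phi=2, tau_chi=3, tau_psi=6)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            vbgf_from_three_age(18.0, 16.0, 19.0)

    def test_accelerating_lengths_rejected(self):
        # gaps widening with age cannot come from a decelerating VBGF
        with pytest.raises(ValueError):
            vbgf_from_three_age(10.0, 12.0, 16.0)


def _fish(island, atoll, treatment, length, age, fid):
    return FishRecord(
        fish_id=fid, island_id=island, atoll_id=atoll, treatment=treatment,
        total_length=length, wet_weight=0.2, age=age,
        stage=Stage.SPAWNING_CAPABLE_FEMALE, gonad_weight=1.0,
    )


class TestFitVBGF:
    def test_single_age_group_unidentifiable(self, fast_mcmc):
        fish = [
            _fish("I1", "A1", Treatment.RAT_FREE, 15.0 + i * 0.1, 3, f"a{i}") for i in range(5)
        ] + [
            _fish("I2", "A1", Treatment.RAT_INFESTED, 15.0 + i * 0.1, i + 1, f"b{i}")
            for i in range(5)
        ]
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_vbgf(fish, mcmc=fast_mcmc)

    def test_null_simulation_covers_zero(self, fast_mcmc):
        cfg = SyntheticConfig(n_atolls=4, growth=GrowthGen(k_b=0.0), seed=77)
        post = fit_vbgf(simulate_fish(cfg), variant="offset_k", mcmc=fast_mcmc)
        lo, hi = hpdi(post.get("k_b"), 0.95)
        assert lo <= 0.0 <= hi

    def test_offset_symmetry_under_label_swap(self, fast_mcmc):
        cfg = SyntheticConfig(n_atolls=4, growth=GrowthGen(k_b=0.10), seed=21)
        fish = simulate_fish(cfg)
        swap = {
            Treatment.RAT_FREE: Treatment.RAT_INFESTED,
            Treatment.RAT_INFESTED: Treatment.RAT_FREE,
        }
        import dataclasses

        swapped = [dataclasses.replace(f, treatment=swap[f.treatment]) for f in fish]
        post = fit_vbgf(fish, mcmc=fast_mcmc)
        post_swapped = fit_vbgf(swapped, mcmc=fast_mcmc)
        kb = float(np.median(post.get("k_b")))
        kb_swapped = float(np.median(post_swapped.get("k_b")))
        pooled_sd = float(np.std(post.get("k_b")))
        assert kb_swapped == pytest.approx(-kb, abs=3 * pooled_sd)

    def test_percent_growth_difference_point_masses(self):
        from reefdemo.inference_core import PosteriorSamples

        draws = np.zeros((2, 50, 5))
        draws[:, :, 0] = 25.0
        draws[:, :, 1] = 8.0
        draws[:, :, 2] = 0.27
        draws[:, :, 3] = 0.10
        draws[:, :, 4] = 1.0
        post = PosteriorSamples(
            param_names=["L_inf", "L_0", "k", "k_b", "sigma_L"],
            draws=draws, log_likelihood=None,
        )
        pct, s = percent_growth_difference(post)
        assert s.median == pytest.approx(100 * 0.10 / 0.27, abs=1e-9)
        contrasts = length_at_age_contrast(post, [4.0])
        expected = (25 - 17 * math.exp(-0.37 * 4)) - (25 - 17 * math.exp(-0.27 * 4))
        assert contrasts[4.0][1].median == pytest.approx(expected, abs=1e-9)
        # all-zero offset draws give exactly zero everywhere
        draws[:, :, 3] = 0.0
        post0 = PosteriorSamples(
            param_names=["L_inf", "L_0", "k", "k_b", "sigma_L"],
            draws=draws, log_likelihood=None,
        )
        assert percent_growth_difference(post0)[1].median == 0.0
        assert length_at_age_contrast(post0, [2.0, 6.0])[2.0][1].median == 0.0


class TestThreeAgeFit:
    def test_maximum_likelihood_curves_agree_between_parameterizations(self):
        # same Gaussian likelihood, two coordinate systems: the fitted mean
        # curves must coincide
        rng = np.random.default_rng(5)
        ages = np.repeat(np.arange(1, 9), 12).astype(float)
        truth = VBGFParams(25.0, 8.0, 0.3)
        lengths = vbgf_mean_length(ages, truth) + rng.normal(0, 1.0, ages.size)

        def resid_vbgf(p):
            L_inf, L_0, k = p
            return L_inf - (L_inf - L_0) * np.exp(-k * ages) - lengths

        def resid_three(p):
            L_inf, L_0, k = vbgf_from_three_age(*p)
            return L_inf - (L_inf - L_0) * np.exp(-k * ages) - lengths

        fit1 = least_squares(resid_vbgf, [26.0, 7.0, 0.25], xtol=1e-15, ftol=1e-15, gtol=1e-15)
        start3 = three_age_from_vbgf(26.0, 7.0, 0.25)
        fit3 = least_squares(resid_three, list(start3), xtol=1e-15, ftol=1e-15, gtol=1e-15)
        curve1 = fit1.x[0] - (fit1.x[0] - fit1.x[1]) * np.exp(-fit1.x[2] * ages)
        L_inf, L_0, k = vbgf_from_three_age(*fit3.x)
        curve3 = L_inf - (L_inf - L_0) * np.exp(-k * ages)
        assert np.max(np.abs(curve1 - curve3)) < 1e-6

    def test_noiseless_curve_recovered(self, fast_mcmc):
        cfg = SyntheticConfig(
            n_atolls=4,
            growth=GrowthGen(sigma_L=0.0, k_b=0.11),
            atoll_sd={"length": 0.0, "gsi": 0.05, "percent_N": 0.05, "d15N": 0.05},
            seed=13,
        )
        fish = simulate_fish(cfg)
        post = fit_three_age_vbgf(fish, mcmc=fast_mcmc)
        truth = vbgf_mean_length(4.0, cfg.growth.params(), False)
        est = float(np.median(post.get("l_chi_infested")))
        assert est == pytest.approx(truth, abs=0.15)  # sampler + 0.1 cm rounding

    def test_treatment_contrast_consistent_with_offset_model(self, fast_mcmc):
        cfg = SyntheticConfig(n_atolls=4, growth=GrowthGen(k_b=0.11), seed=31)
        fish = simulate_fish(cfg)
        three = fit_three_age_vbgf(fish, mcmc=fast_mcmc)
        offset = fit_vbgf(fish, variant="offset_k", mcmc=fast_mcmc)
        d3 = np.median(three.get("l_chi_free") - three.get("l_chi_infested"))
        dk = length_at_age_contrast(offset, [4.0])[4.0][1].median
        assert d3 == pytest.approx(dk, abs=0.6)


class TestUpperQuartileExtremes:
    def test_constant_island_sample(self):
        assert island_upper_quartile(np.array([2.0, 2.0, 2.0, 2.0])) == 2.0

    def test_one_to_eight_brute_force(self):
        vals = np.arange(1.0, 9.0)
        q75 = np.quantile(vals, 0.75)  # 6.25 under linear interpolation
        expected = vals[vals >= q75].mean()  # {7, 8} -> 7.5
        assert island_upper_quartile(vals) == expected == 7.5

    def test_contrast_direction_on_simulated_data(self, study_fish, fast_mcmc):
        ext = upper_quartile_extremes(study_fish, metric="length", mcmc=fast_mcmc)
        assert set(ext.island_table["treatment"]) == {"rat_free", "rat_infested"}
        assert len(ext.island_table) == 8
        # rat-free fish grow faster, so upper-quartile lengths should trend larger
        assert ext.contrast.median > 0

    def test_unknown_metric_rejected(self, study_fish, fast_mcmc):
        with pytest.raises(ValueError, match="metric"):
            upper_quartile_extremes(study_fish, metric="weight", mcmc=fast_mcmc)
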