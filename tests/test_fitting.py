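"""Least-squares fitting, goodness-of-fit statistics, and model ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import drykin as dk
from drykin.fitting import goodness_of_fit
from drykin.models import ModelParams, evaluate
from drykin.synthetic import sampling_schedule


def brute_force_gof(y, yhat, z):
    """Independent two-pass computation of the three statistics."""
    n = len(y)
    ybar = sum(y) / n
    ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
    ss_tot = sum((a - ybar) ** 2 for a in y)
    return 1 - ss_res / ss_tot, ss_res / (n - z), (ss_res / n) ** 0.5


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        g = goodness_of_fit([1.0, 0.5, 0.2], [1.0, 0.5, 0.2], 1)
        assert (g.r2, g.chi2_reduced, g.rmse) == (1.0, 0.0, 0.0)

    def test_mean_prediction_gives_zero_r2(self):
        y = [1.0, 0.5, 0.3]
        g = goodness_of_fit(y, [np.mean(y)] * 3, 1)
        assert g.r2 == pytest.approx(0.0, abs=1e-15)

    def test_hand_worked_example(self):
        g = goodness_of_fit([1.0, 0.5, 0.25], [0.9, 0.55, 0.2], 1)
        assert g.rmse == pytest.approx(np.sqrt(0.005), rel=1e-12)
        assert g.chi2_reduced == pytest.approx(0.0075, rel=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            goodness_of_fit([1.0, 0.5], [1.0, 0.5], 2)

    def test_zero_variance_flagged_not_raised(self):
        g = goodness_of_fit([0.5, 0.5, 0.5], [0.5, 0.4, 0.5], 1)
        assert g.zero_variance and np.isnan(g.r2)

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=4, max_size=30),
        st.integers(0, 10**6),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, y, seed):
        if np.var(y) == 0:
            return
        rng = np.random.default_rng(seed)
        yhat = np.clip(np.array(y) + rng.normal(0, 0.05, len(y)), 0, 1)
        g = goodness_of_fit(y, yhat, 2)
        r2, chi2, rmse = brute_force_gof(y, list(yhat), 2)
        assert g.r2 == pytest.approx(r2, abs=1e-12)
        assert g.chi2_reduced == pytest.approx(chi2, abs=1e-12)
        assert g.rmse == pytest.approx(rmse, abs=1e-12)


class TestFitModel:
    def test_newton_exact_refit(self):
        t = sampling_schedule(300)
        mr = evaluate(ModelParams("newton", (0.0341,)), t)
        res = dk.fit_model("newton", t, mr)
        assert res.params.values[0] == pytest.approx(0.0341, abs=1e-8)
        assert res.converged

    @pytest.mark.parametrize("condition", [(50.0, 2.0), (70.0, 4.0), (80.0, 8.0)])
    def test_diffusion_approach_noiseless_recovery(self, condition, study_params):
        a, k, b = study_params[condition]
        run = dk.generate_run(
            dk.SyntheticConfig(
                temperature=condition[0], thickness_mm=condition[1], noise_sd=0.0
            )
        )
        ratio = dk.moisture_ratio(dk.moisture_from_weights(run))
        res = dk.ThinLayerModel(ratio.times, ratio.mr).fit()
        np.testing.assert_allclose(res.params.values, (a, k, b), atol=1e-4)
        assert res.r2 >= 0.999999

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            dk.fit_model("verma", [0.0, 10.0], [1.0, 0.8])

    def test_seed_determinism(self, noiseless_ratio):
        r1 = dk.fit_model("page", noiseless_ratio.times, noiseless_ratio.mr, seed=42)
        r2 = dk.fit_model("page", noiseless_ratio.times, noiseless_ratio.mr, seed=42)
        assert r1.params.values == r2.params.values
        assert r1.r2 == r2.r2

    def test_summary_lists_coefficients(self, noiseless_ratio):
        res = dk.ThinLayerModel(noiseless_ratio.times, noiseless_ratio.mr).fit()
        s = res.summary()
        assert "diffusion_approach" in s and "R^2" in s and "a " in s


class TestRankModels:
    def test_noisy_diffusion_data_selects_diffusion(self, study_params):
        a, k, b = study_params[(60.0, 2.0)]
        t = sampling_schedule(2000)
        rng = np.random.default_rng(1)
        mr = np.clip(
            evaluate(ModelParams("diffusion_approach", (a, k, b)), t)
            + rng.normal(0, 0.005, len(t)),
            0.0, 1.05,
        )
        ranking = dk.rank_models(t, mr)
        assert ranking.best == "diffusion_approach"

    def test_deterministic_ordering_on_ties(self):
        t = sampling_schedule(300)
        mr = evaluate(ModelParams("newton", (0.03,)), t)
        r1 = dk.rank_models(t, mr)
        r2 = dk.rank_models(t, mr)
        assert [m for m, _ in r1.ranked] == [m for m, _ in r2.ranked]

    def test_constant_series_flagged(self):
        t = np.arange(0.0, 100.0, 10.0)
        mr = np.full(len(t), 0.5)
        ranking = dk.rank_models(t, mr)
        for _, res in ranking.ranked:
            assert res.gof.zero_variance

    def test_ordering_consistent_with_r2(self, noiseless_ratio):
        ranking = dk.rank_models(noiseless_ratio.times, noiseless_ratio.mr)
        r2s = [res.r2 for _, res in ranking.ranked if np.isfinite(res.r2)]
        assert all(a >= b - 1e-9 for a, b in zip(r2s, r2s[1:]))


class TestNestedModels:
    def test_ssres_non_increasing_with_nesting(self, study_params):
        """newton -> henderson_pabis -> diffusion_approach can only fit better."""
        a, k, b = study_params[(70.0, 6.0)]
        t = sampling_schedule(2500)
        rng = np.random.default_rng(5)
        mr = np.clip(
            evaluate(ModelParams("diffusion_approach", (a, k, b)), t)
            + rng.normal(0, 0.003, len(t)),
            0.0, 1.05,
        )
        ss = {
            m: dk.fit_model(m, t, mr).ss_res
            for m in ("newton", "henderson_pabis", "diffusion_approach")
        }
        assert ss["henderson_pabis"] <= ss["newton"] + 1e-10
        assert ss["diffusion_approach"] <= ss["henderson_pabis"] + 1e-10
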