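import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from milenorm.calibration import (
    DegenerateItemError,
    NonInvertibleError,
    calibrate_all,
    calibrations_to_frame,
    fit_item_logistic,
    invert_probability,
    model_fit_test,
)


class TestInvertProbability:
    def test_closed_form_values(self):
        assert invert_probability(-6.0, 0.02, 0.5) == pytest.approx(300.0)
        assert invert_probability(0.0, 1.0, 0.9) == pytest.approx(np.log(9), abs=1e-12)
        x = invert_probability(-6.0, 0.02, 0.9)
        assert x == pytest.approx((np.log(9) + 6) / 0.02, abs=1e-9)  # ~409.86
        assert expit(-6.0 + 0.02 * x) == pytest.approx(0.9, abs=1e-12)

    @pytest.mark.parametrize("alpha,beta,p", [(0, -1, 0.5), (0, 0, 0.5), (0, 1, 0.0), (0, 1, 1.0)])
    def test_invalid_inputs(self, alpha, beta, p):
        with pytest.raises(NonInvertibleError):
            invert_probability(alpha, beta, p)

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        alpha=st.floats(-20, 5),
        beta=st.floats(0.001, 0.5),
        x=st.floats(0, 1825),
    )
    def test_roundtrip_identity(self, alpha, beta, x):
        """invert(P(x)) == x: the curve and its inverse compose to identity."""
        if abs(alpha + beta * x) > 10:
            return  # saturated probabilities are not representable to this precision
        p = float(expit(alpha + beta * x))
        assert invert_probability(alpha, beta, p) == pytest.approx(x, abs=1e-6, rel=1e-9)


def _simulate(alpha, beta, n, seed, ages=None):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1825, n) if ages is None else ages
    y = (rng.random(n) < expit(alpha + beta * x)).astype(float)
    return x, y


class TestFit:
    def test_parameter_recovery_within_3se(self):
        x, y = _simulate(-6.0, 0.02, 2000, seed=7)
        cal = fit_item_logistic(x, y)
        assert cal.converged and not cal.separation_flag
        assert abs(cal.alpha_hat - (-6.0)) < 3 * cal.se_alpha
        assert abs(cal.beta_hat - 0.02) < 3 * cal.se_beta
        # thresholds strictly increasing and hitting the stated probabilities
        ages = [cal.age_at[p] for p in (0.25, 0.5, 0.75, 0.9)]
        assert np.all(np.diff(ages) > 0)
        for p in (0.25, 0.5, 0.75, 0.9):
            assert expit(cal.alpha_hat + cal.beta_hat * cal.age_at[p]) == pytest.approx(p, abs=1e-9)
        assert cal.age_at[0.5] == pytest.approx(-cal.alpha_hat / cal.beta_hat, abs=1e-9)

    def test_complete_separation_flagged(self):
        x = np.concatenate([np.arange(100, 290, 10), np.arange(310, 500, 10)]).astype(float)
        y = (x > 300).astype(float)
        cal = fit_item_logistic(x, y)
        assert cal.separation_flag
        assert not cal.valid

    @pytest.mark.parametrize("value", [0, 1])
    def test_no_variation_is_degenerate(self, value):
        with pytest.raises(DegenerateItemError):
            fit_item_logistic(np.array([100.0, 200.0, 300.0]), np.full(3, value))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            fit_item_logistic(np.arange(5.0), np.array([0.0, 1.0]))

    def test_mle_matches_brute_force_grid(self):
        """Newton MLE agrees with an exhaustive grid maximizer at small n."""
        x, y = _simulate(-4.0, 0.01, 50, seed=3)
        cal = fit_item_logistic(x, y)

        def loglik(a, b):
            eta = a + b * x
            return np.sum(y * eta - np.logaddexp(0.0, eta))

        alphas = np.linspace(-10, 0, 201)  # resolution 0.05
        betas = np.linspace(0.001, 0.05, 491)  # resolution 1e-4
        eta = alphas[:, None, None] + betas[None, :, None] * x[None, None, :]
        ll = np.sum(y * eta - np.logaddexp(0.0, eta), axis=-1)
        ia, ib = np.unravel_index(np.argmax(ll), ll.shape)
        # the Newton solution dominates every grid point and sits at the
        # grid argmax up to localization error (~2 grid steps)
        assert loglik(cal.alpha_hat, cal.beta_hat) >= ll[ia, ib] - 1e-9
        assert abs(cal.alpha_hat - alphas[ia]) <= 2 * 0.05
        assert abs(cal.beta_hat - betas[ib]) <= 2 * 1e-4


class TestModelFit:
    def test_strong_age_effect_detected(self):
        x, y = _simulate(-6.0, 0.02, 2000, seed=7)
        cal = fit_item_logistic(x, y)
        assert cal.fit_p_value < 0.05
        assert cal.good_fit
        assert cal.wald_p_value < 0.05

    def test_probability_range_tiny_sample(self):
        x = np.array([100.0, 200.0, 300.0])
        y = np.array([0.0, 1.0, 0.0])
        cal = fit_item_logistic(x, y)
        p = model_fit_test(cal, x, y)
        assert 0.0 <= p <= 1.0


class TestCalibrateAll:
    def test_one_record_per_item(self, bank, recovery_run):
        cals = recovery_run.calibrations
        assert len(cals) == 133
        assert [c.item_id for c in cals] == bank.item_ids
        frame = calibrations_to_frame(cals)
        assert len(frame) == 133 and "age_p90" in frame.columns

    def test_observed_only_mode_correlates(self, bank, recovery_run):
        """P50 ages from observed-only cells track the imputation-completed run."""
        cals_obs = calibrate_all(
            recovery_run.scored,
            recovery_run.ages,
            bank,
            provenance=recovery_run.provenance,
            use_imputed=False,
        )
        p50_imp = np.array([c.age_at.get(0.5, np.nan) for c in recovery_run.calibrations])
        p50_obs = np.array([c.age_at.get(0.5, np.nan) for c in cals_obs])
        ok = np.isfinite(p50_imp) & np.isfinite(p50_obs)
        assert ok.mean() > 0.9
        r = np.corrcoef(p50_imp[ok], p50_obs[ok])[0, 1]
        assert r > 0.95

    def test_degenerate_item_flagged_not_raised(self, bank):
        rng = np.random.default_rng(2)
        ages = pd.Series(rng.uniform(60, 1825, 200))
        scores = pd.DataFrame(
            rng.integers(0, 2, size=(200, 133)), columns=bank.item_ids
        )
        scores[bank.item_ids[0]] = 1  # no variation
        cals = calibrate_all(scores, ages, bank)
        assert cals[0].degenerate and not cals[0].valid and cals[0].age_at == {}

    def test_observed_only_requires_provenance(self, bank, recovery_run):
        with pytest.raises(ValueError):
            calibrate_all(recovery_run.scored, recovery_run.ages, bank, use_imputed=False)

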