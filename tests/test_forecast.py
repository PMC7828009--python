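"""Yule-Walker fitting, Levinson-Durbin, LMS adaptation and AR forecasting."""

import numpy as np
import pytest
from scipy import signal as sps

from phaseloop import (
    ARModel,
    LMSState,
    fit_yule_walker,
    forecast,
    levinson_durbin,
    lms_step,
)
from phaseloop.errors import (
    DegenerateInputError,
    LengthError,
    ParameterError,
    ShapeError,
)

FS = 500.0
OMEGA = 2 * np.pi * 10.0 / FS  # 10 Hz at 500 Hz


def naive_forecast(coeffs, history, horizon):
    """Reference AR recursion: predictions fed back one step at a time."""
    order = len(coeffs)
    buf = list(history[-order:][::-1])  # newest first
    out = []
    for _ in range(horizon):
        nxt = float(np.dot(coeffs, buf))
        out.append(nxt)
        buf = [nxt] + buf[:-1]
    return np.asarray(out)


class TestYuleWalker:
    def test_recovers_ar2_representation_of_sinusoid(self):
        """A noiseless sinusoid obeys x(t+1) = 2cos(w) x(t) - x(t-1)."""
        n = 1_000_000
        x = np.cos(OMEGA * np.arange(n) + 0.3)
        model = fit_yule_walker(x, order=2)
        assert np.allclose(model.coeffs, [2 * np.cos(OMEGA), -1.0], atol=1e-3)

    def test_recovers_ar1_coefficient(self, rng):
        noise = rng.standard_normal(100_000)
        x = sps.lfilter([1.0], [1.0, -0.9], noise)
        model = fit_yule_walker(x, order=1)
        assert abs(model.coeffs[0] - 0.9) < 0.01

    def test_white_noise_coefficients_are_small(self, rng):
        x = rng.standard_normal(100_000)
        model = fit_yule_walker(x, order=30)
        assert np.max(np.abs(model.coeffs)) < 0.05

    def test_matches_statsmodels_biased_fit(self, rng):
        """Independent oracle: statsmodels Yule-Walker with the biased
        (mle) autocovariance gives the same coefficients."""
        statsmodels = pytest.importorskip("statsmodels.api")
        noise = rng.standard_normal(5_000)
        x = sps.lfilter([1.0], [1.0, -1.6, 0.72], noise)  # AR(2), poles 0.8/0.9
        model = fit_yule_walker(x, order=4)
        rho, _ = statsmodels.regression.yule_walker(x, order=4, method="mle")
        assert np.allclose(model.coeffs, rho, atol=1e-10)

    def test_reflection_coefficients_inside_unit_circle(self, rng):
        for _ in range(10):
            x = rng.standard_normal(400)
            model = fit_yule_walker(x, order=30)
            assert np.max(np.abs(model.reflection)) < 1.0

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            fit_yule_walker(np.full(200, 2.0), order=5)

    def test_short_input_rejected(self):
        with pytest.raises(LengthError):
            fit_yule_walker(np.arange(60.0), order=30)

    def test_levinson_needs_a_lag(self):
        with pytest.raises(LengthError):
            levinson_durbin([1.0])


class TestLMS:
    def history(self, rng, order=30):
        return rng.standard_normal(order)

    def test_zero_error_leaves_weights_unchanged(self, rng):
        state = LMSState(order=30, mu=0.05)
        state.weights = rng.standard_normal(30)
        h = self.history(rng)
        target = float(np.dot(state.weights, h))  # perfect prediction
        before = state.weights.copy()
        _, y, e = lms_step(state, h, target)
        assert e == 0.0
        assert np.array_equal(state.weights, before)
        assert state.update_count == 1

    def test_zero_mu_freezes_weights_but_predicts(self, rng):
        state = LMSState(order=30, mu=0.0)
        state.weights = rng.standard_normal(30)
        h = self.history(rng)
        before = state.weights.copy()
        _, y, e = lms_step(state, h, 3.0)
        assert y == pytest.approx(float(np.dot(before, h)))
        assert np.array_equal(state.weights, before)

    def test_wrong_history_length_raises(self, rng):
        with pytest.raises(ShapeError):
            lms_step(LMSState(order=30), rng.standard_normal(29), 0.0)

    def test_converges_on_stationary_inband_sinusoid(self):
        """After 2000 updates the one-step MSE is far below 1% of signal power."""
        t = np.arange(4000) / FS
        x = np.sqrt(2.0) * np.cos(2 * np.pi * 10.0 * t)  # unit power
        state = LMSState(order=30, mu=0.001)
        errors = []
        for i in range(30, 3000):
            _, _, e = lms_step(state, x[i : i - 30 : -1], x[i + 1])
            errors.append(e)
        late = np.asarray(errors[2000:2500])
        assert np.mean(late**2) < 0.01

    def test_update_rule_matches_definition(self, rng):
        state = LMSState(order=4, mu=0.01)
        state.weights = rng.standard_normal(4)
        h = rng.standard_normal(4)
        w0 = state.weights.copy()
        _, y, e = lms_step(state, h, 1.5)
        assert np.allclose(state.weights, w0 + 2 * 0.01 * e * h)


class TestForecast:
    def test_zero_horizon_gives_empty_series(self):
        model = ARModel(order=2, coeffs=[1.0, -0.5], reflection=[0.5, -0.5])
        assert forecast(model, np.arange(10.0), 0).size == 0

    def test_negative_horizon_rejected(self):
        model = ARModel(order=2, coeffs=[1.0, -0.5], reflection=[0.5, -0.5])
        with pytest.raises(ParameterError):
            forecast(model, np.arange(10.0), -1)

    def test_exact_ar2_coefficients_continue_the_sinusoid(self):
        """With the closed-form AR(2) coefficients the 85-step forecast is
        the analytic continuation of the sinusoid to float precision."""
        coeffs = np.array([2 * np.cos(OMEGA), -1.0])
        model = ARModel(order=2, coeffs=coeffs, reflection=[0.0, 0.0])
        n = 330
        x = np.cos(OMEGA * np.arange(n + 85) + 1.1)
        pred = forecast(model, x[:n], 85)
        assert pred.size == 85
        assert np.allclose(pred, x[n:], rtol=1e-6, atol=1e-6)

    def test_filter_route_matches_naive_recursion(self, rng):
        """The zero-input-response implementation equals the textbook loop."""
        for _ in range(5):
            x = rng.standard_normal(200)
            model = fit_yule_walker(x, order=12)
            hist = rng.standard_normal(40)
            assert np.allclose(
                forecast(model, hist, 60),
                naive_forecast(model.coeffs, hist, 60),
                rtol=1e-10,
                atol=1e-10,
            )

    def test_lms_state_usable_as_forecaster(self, rng):
        state = LMSState(order=5)
        state.weights = np.array([0.5, 0.1, 0.0, 0.0, 0.0])
        hist = rng.standard_normal(10)
        assert np.allclose(
            forecast(state, hist, 20), naive_forecast(state.weights, hist, 20)
        )

    def test_yule_walker_forecasts_remain_bounded(self, rng):
        """Biased-autocovariance fits are stable: an 85-step forecast of a
        bounded window never exceeds 10x the window's peak amplitude."""
        for _ in range(20):
            x = rng.standard_normal(330)
            model = fit_yule_walker(x, order=30)
            pred = forecast(model, x, 85)
            assert np.max(np.abs(pred)) <= 10.0 * np.max(np.abs(x))

    def test_history_shorter_than_order_raises(self):
        model = ARModel(order=5, coeffs=np.zeros(5), reflection=np.zeros(5))
        with pytest.raises(LengthError):
            forecast(model, np.arange(3.0), 10)
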