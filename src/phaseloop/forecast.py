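"""Autoregressive forward prediction: Yule-Walker and adaptive LMS.

Both methods share the AR(K) forecasting recursion (K = 30 by default)

    x_hat(t+1) = sum_{k=0}^{K-1} alpha_k * x(t-k),

iterated with predictions fed back as inputs, which extrapolates the
trimmed, filtered window beyond its last valid sample.

The Yule-Walker route solves the normal equations built from the biased
sample autocovariance via the Levinson-Durbin recursion; the biased
estimator keeps the Toeplitz system positive semidefinite, so every
reflection coefficient has magnitude below one and the recursion is
stable (forecasts of bounded history stay bounded).

The LMS route maintains a persistent weight vector A(t) updated by the
stochastic-gradient rule

    y(t) = A(t)' X(t),   e(t) = x(t+1) - y(t),
    A(t+1) = A(t) + 2 * mu * e(t) * X(t),

with X(t) the K most recent samples, newest first. Plain LMS stability
depends on input power, so by default the caller feeds it RMS-normalised
windows (see the pipeline), making mu = 0.001 scale-free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal

from .errors import DegenerateInputError, LengthError, ParameterError, ShapeError

__all__ = [
    "ARModel",
    "LMSState",
    "levinson_durbin",
    "fit_yule_walker",
    "lms_step",
    "forecast",
]


@dataclass(frozen=True)
class ARModel:
    """Yule-Walker-fitted AR coefficients (newest-lag first)."""

    order: int
    coeffs: np.ndarray
    reflection: np.ndarray
    method: str = "yw"

    def __post_init__(self):
        object.__setattr__(self, "coeffs", np.asarray(self.coeffs, dtype=float))
        object.__setattr__(self, "reflection", np.asarray(self.reflection, dtype=float))
        if self.coeffs.size != self.order:
            raise ShapeError("coeffs length must equal order")
        if not np.all(np.isfinite(self.coeffs)):
            raise DegenerateInputError("AR coefficients must be finite")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "order": self.order,
                "coeffs": self.coeffs.tolist(),
                "reflection": self.reflection.tolist(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


@dataclass
class LMSState:
    """Persistent adaptive-filter state (weights, step size, update count)."""

    order: int = 30
    mu: float = 0.001
    weights: np.ndarray = None
    update_count: int = 0
    method: str = "lms"

    def __post_init__(self):
        if self.mu < 0:
            raise ParameterError("mu must be non-negative")
        if self.weights is None:
            self.weights = np.zeros(self.order)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.size != self.order:
            raise ShapeError("weights length must equal order")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "method": self.method,
                "order": self.order,
                "mu": self.mu,
                "weights": self.weights.tolist(),
                "update_count": self.update_count,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload


def levinson_durbin(r) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the Yule-Walker system for autocovariances ``r[0..K]``.

    Returns ``(coeffs, reflection, final_error)`` where ``coeffs[k]``
    multiplies ``x(t-k)`` in the one-step predictor of ``x(t+1)`` and
    ``reflection`` holds the K partial correlation coefficients.
    """
    r = np.asarray(r, dtype=float)
    order = r.size - 1
    if order < 1:
        raise LengthError("need autocovariances up to at least lag 1")
    if r[0] <= 0:
        raise DegenerateInputError("zero-variance input: autocovariance r[0] <= 0")
    a = np.zeros(order)
    k_hist = np.zeros(order)
    err = r[0]
    for i in range(1, order + 1):
        if i == 1:
            acc = r[1]
        else:
            acc = r[i] - np.dot(a[: i - 1], r[i - 1 : 0 : -1])
        if err <= 0:
            raise DegenerateInputError("Levinson-Durbin error power became non-positive")
        k = acc / err
        prev = a[: i - 1].copy()
        a[: i - 1] = prev - k * prev[::-1]
        a[i - 1] = k
        k_hist[i - 1] = k
        err *= 1.0 - k * k
    return a, k_hist, float(err)


def fit_yule_walker(x, order: int = 30, demean: bool = True) -> ARModel:
    """Fit an AR model by the Yule-Walker equations (biased autocovariance).

    Deterministic for fixed input. Raises :class:`DegenerateInputError`
    for (near-)constant input and :class:`LengthError` when fewer than
    ``2 * order`` samples are supplied.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n <= 2 * order:
        raise LengthError(f"need more than {2 * order} samples to fit order {order}")
    if demean:
        x = x - x.mean()
    # biased autocovariance (divide by n): positive semidefinite by construction
    r = np.empty(order + 1)
    for lag in range(order + 1):
        r[lag] = np.dot(x[: n - lag], x[lag:]) / n
    if r[0] <= 0 or not np.isfinite(r[0]):
        raise DegenerateInputError("zero-variance input cannot be fitted")
    coeffs, reflection, _ = levinson_durbin(r)
    return ARModel(order=order, coeffs=coeffs, reflection=reflection)


def lms_step(state: LMSState, history, nxt: float) -> tuple[LMSState, float, float]:
    """One adaptive update: predict ``nxt`` from ``history`` and adjust weights.

    ``history`` holds the K most recent samples, *newest first*. Returns
    ``(state, y, e)`` with the prediction ``y`` and error ``e``; the state
    is updated in place (weights and update count).
    """
    h = np.asarray(history, dtype=float)
    if h.size != state.order:
        raise ShapeError(f"history must hold exactly {state.order} samples")
    y = float(np.dot(state.weights, h))
    e = float(nxt) - y
    state.weights += 2.0 * state.mu * e * h
    state.update_count += 1
    return state, y, e


def _coefficients_of(model) -> np.ndarray:
    if isinstance(model, ARModel):
        return model.coeffs
    if isinstance(model, LMSState):
        return model.weights
    raise ShapeError("model must be an ARModel or LMSState")


def forecast(model, history, horizon: int = 85) -> np.ndarray:
    """Recursively extrapolate ``history`` by ``horizon`` samples.

    Predictions are fed back as inputs; LMS weights are frozen for the
    duration of the forecast. Implemented as the zero-input response of
    the all-pole filter ``1 / (1 - sum_k alpha_k z^{-(k+1)})`` with initial
    conditions taken from the history, which is algebraically identical to
    the naive recursion.
    """
    if horizon < 0:
        raise ParameterError("horizon must be non-negative")
    coeffs = _coefficients_of(model)
    h = np.asarray(history, dtype=float)
    if h.size < coeffs.size:
        raise LengthError("history must be at least as long as the model order")
    if horizon == 0:
        return np.empty(0)
    a_poly = np.concatenate(([1.0], -coeffs))
    zi = signal.lfiltic([1.0], a_poly, h[::-1][: coeffs.size])
    out, _ = signal.lfilter([1.0], a_poly, np.zeros(horizon), zi=zi)
    return out
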