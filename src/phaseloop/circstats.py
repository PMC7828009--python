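"""Circular statistics for evaluating phase-locked triggering.

The quantities implemented here are the standard tools for asking "did the
triggers land at the intended oscillatory phase?":

* the phase-locking factor (PLF) -- the resultant length of unit phasors
  over trials, 1 for perfectly repeatable phase, 0 for maximal dispersion;
* Rayleigh's Z statistic ``Z = N * PLF**2`` with its large-sample critical
  value ``-ln(alpha)`` (2.996 at p < 0.05), testing non-uniformity;
* the circular mean angle and recentering (subtracting the mean direction),
  used to compare dispersion between two samples irrespective of their mean;
* the two-sample Watson U^2 test, a rotation-invariant rank test for a
  difference between two circular distributions, with its asymptotic
  critical value (0.187 at p < 0.05);
* the phase-triggered response (PTR) -- the trigger-locked average of the
  raw signal, analogous to an evoked potential but aligned to internally
  generated phase triggers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import (
    EmptyResultError,
    LengthError,
    ParameterError,
    UndefinedMeanError,
)

__all__ = [
    "wrap_phase",
    "plf",
    "zplf",
    "zplf_all",
    "rayleigh_critical",
    "circular_mean",
    "recenter",
    "watson_u2",
    "watson_critical",
    "summarize",
    "ptr",
    "rose_histogram",
    "SummaryStats",
    "WatsonResult",
    "PTRResult",
]


def wrap_phase(theta):
    """Wrap angles (radians) into the half-open interval ``(-pi, pi]``.

    Accepts scalars or arrays; returns the same shape.
    """
    theta = np.asarray(theta, dtype=float)
    out = np.remainder(theta + np.pi, 2.0 * np.pi) - np.pi
    # remainder maps multiples of 2*pi to -pi; the convention here is +pi
    out = np.where(out == -np.pi, np.pi, out)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class SummaryStats:
    """Phase-locking summary for one sample of trigger phases.

    ``zplf == n * plf**2`` by construction; ``significant`` compares it
    against the large-sample Rayleigh critical value at the chosen alpha.
    """

    n: int
    plf: float
    zplf: float
    mean_angle: float
    significant: bool
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "plf": self.plf,
            "zplf": self.zplf,
            "mean_angle_rad": self.mean_angle,
            "significant": bool(self.significant),
            "alpha": self.alpha,
        }


@dataclass(frozen=True)
class WatsonResult:
    """Two-sample Watson U^2 outcome."""

    u2: float
    critical: float
    significant: bool
    alpha: float = 0.05
    n: int = 0
    m: int = 0

    def to_dict(self) -> dict:
        return {
            "u2": self.u2,
            "critical": self.critical,
            "significant": bool(self.significant),
            "alpha": self.alpha,
            "n": self.n,
            "m": self.m,
        }


@dataclass(frozen=True)
class PTRResult:
    """Trigger-locked average waveform.

    ``waveform`` has ``2 * half_window + 1`` samples with the trigger at
    index ``half_window`` (1001 samples / index 500 at the defaults).
    """

    waveform: np.ndarray
    n_trials: int
    n_excluded: int
    fs: float
    half_window: int = field(default=500)


def _phase_array(phases, name: str = "phases") -> np.ndarray:
    arr = np.asarray(phases, dtype=float).ravel()
    if arr.size == 0:
        raise LengthError(f"{name} must contain at least one angle")
    return arr


def plf(phases) -> float:
    """Phase-locking factor: ``|sum_n exp(i*theta_n)| / N``, in [0, 1]."""
    arr = _phase_array(phases)
    return float(np.abs(np.mean(np.exp(1j * arr))))


def zplf(n: int, plf_value: float) -> float:
    """Rayleigh's Z computed from the PLF: ``Z = n * PLF**2``."""
    return float(n) * float(plf_value) ** 2


def zplf_all(values) -> float:
    """Participant-averaged Rayleigh Z: the arithmetic mean of per-sample Z values."""
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise LengthError("need at least one Z value to average")
    return float(np.mean(arr))


def rayleigh_critical(alpha: float) -> float:
    """Large-sample critical value of Rayleigh's Z: ``-ln(alpha)``.

    ``Z = N * PLF**2`` exceeds this with probability ``alpha`` under
    uniformly distributed phases (large N). At alpha = 0.05 this is
    2.9957..., conventionally quoted truncated as 2.995.
    """
    if not 0.0 < alpha <= 1.0:
        raise ParameterError("alpha must lie in (0, 1]")
    return float(-np.log(alpha))


def circular_mean(phases) -> float:
    """Mean direction ``atan2(S, C)`` of a circular sample, in ``(-pi, pi]``.

    ``C`` and ``S`` are the mean cosine and sine of the angles. Raises
    :class:`UndefinedMeanError` when the resultant length is (numerically)
    zero, e.g. for an exactly antipodal pair.
    """
    arr = _phase_array(phases)
    c = float(np.mean(np.cos(arr)))
    s = float(np.mean(np.sin(arr)))
    if np.hypot(c, s) < 1e-12:
        raise UndefinedMeanError("zero resultant length: circular mean undefined")
    return wrap_phase(np.arctan2(s, c))


def recenter(phases) -> np.ndarray:
    """Subtract the circular mean and re-wrap, so the output mean direction is ~0.

    Used before Watson's U^2 when only the dispersion of two samples is to
    be compared: recentering removes any difference in mean angle.
    """
    arr = _phase_array(phases)
    return wrap_phase(arr - circular_mean(arr))


def watson_u2(a, b, alpha: float = 0.05) -> WatsonResult:
    """Two-sample Watson U^2 test for a difference between circular samples.

    Pools and sorts the ``N = n + m`` angles; with cumulative fractions
    ``i_k/n`` and ``j_k/m`` of each sample up to pooled order statistic
    ``k`` and ``d_k = i_k/n - j_k/m``,

        ``U^2 = (n*m / N**2) * (sum_k d_k**2 - (sum_k d_k)**2 / N)``.

    The statistic depends only on circular ranks, so it is invariant under
    a joint rotation of both samples and symmetric in its arguments. Tied
    pooled values are processed as one group (both cumulative counts are
    advanced before ``d`` is recorded, once per tied member).
    """
    xa = _phase_array(a, "a")
    xb = _phase_array(b, "b")
    n, m = xa.size, xb.size
    big_n = n + m
    pooled = np.concatenate([xa, xb])
    labels = np.concatenate([np.ones(n, dtype=bool), np.zeros(m, dtype=bool)])
    order = np.argsort(pooled, kind="stable")
    values = pooled[order]
    from_a = labels[order]

    # group tied values; within a group advance both counts, then record d
    # once per member of the group
    boundaries = np.flatnonzero(np.diff(values)) + 1
    group_ends = np.concatenate([boundaries, [big_n]])
    counts_a = np.cumsum(from_a)[group_ends - 1]
    counts_b = group_ends - counts_a
    weights = np.diff(np.concatenate([[0], group_ends]))
    d = counts_a / n - counts_b / m
    sum_d = float(np.sum(weights * d))
    sum_d2 = float(np.sum(weights * d * d))
    u2 = (n * m) / big_n**2 * (sum_d2 - sum_d**2 / big_n)
    crit = watson_critical(alpha)
    return WatsonResult(
        u2=float(u2), critical=crit, significant=u2 > crit, alpha=alpha, n=n, m=m
    )


def _watson_tail(u: float, terms: int = 100) -> float:
    """Asymptotic tail probability P(U^2 >= u) of Watson's statistic."""
    k = np.arange(1, terms + 1)
    return float(2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k**2 * np.pi**2 * u)))


def watson_critical(alpha: float) -> float:
    """Invert the asymptotic Watson U^2 tail series at ``alpha``.

    ``P(U^2 >= u) = 2 * sum_{k>=1} (-1)**(k-1) exp(-2 k^2 pi^2 u)``; at
    alpha = 0.05 the root is 0.18689... (quoted as 0.187). Monotone
    decreasing in alpha.
    """
    if not 0.0 < alpha < 0.5:
        raise ParameterError("alpha must lie in (0, 0.5)")
    # leading-term start: u ~ ln(2/alpha) / (2*pi^2)
    u0 = np.log(2.0 / alpha) / (2.0 * np.pi**2)
    return float(brentq(lambda u: _watson_tail(u) - alpha, 0.25 * u0, 4.0 * u0))


def summarize(phases, alpha: float = 0.05) -> SummaryStats:
    """PLF, Rayleigh Z, mean direction and significance for one phase sample."""
    arr = _phase_array(phases)
    r = plf(arr)
    z = zplf(arr.size, r)
    return SummaryStats(
        n=int(arr.size),
        plf=r,
        zplf=z,
        mean_angle=circular_mean(arr),
        significant=z > rayleigh_critical(alpha),
        alpha=alpha,
    )


def ptr(samples, event_indices, fs: float, half_window: int = 500) -> PTRResult:
    """Phase-triggered response: trigger-locked average of the raw signal.

    Extracts ``2*half_window + 1``-sample epochs of the *unfiltered*
    signal centred on each trigger index and averages them. Events closer
    than ``half_window`` to either end are dropped and counted in
    ``n_excluded``.
    """
    x = np.asarray(samples, dtype=float).ravel()
    idx = np.asarray(event_indices, dtype=int).ravel()
    usable = idx[(idx >= half_window) & (idx <= x.size - 1 - half_window)]
    n_excluded = idx.size - usable.size
    if usable.size == 0:
        raise EmptyResultError("no trigger has a full epoch on both sides")
    offsets = np.arange(-half_window, half_window + 1)
    epochs = x[usable[:, None] + offsets[None, :]]
    return PTRResult(
        waveform=epochs.mean(axis=0),
        n_trials=int(usable.size),
        n_excluded=int(n_excluded),
        fs=fs,
        half_window=half_window,
    )


def rose_histogram(phases, bins: int = 24):
    """Bin phases over ``(-pi, pi]`` for rose-plot export.

    Returns ``(edges, counts)`` with ``len(edges) == bins + 1``; the total
    count equals the number of input phases.
    """
    arr = wrap_phase(_phase_array(phases))
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    counts, _ = np.histogram(arr, bins=edges)
    return edges, counts
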