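"""Causal front end of the online pipeline.

Stages, in acquisition order: integer-factor decimation with an
anti-aliasing FIR (2 kHz -> 500 Hz by default), a 500-sample sliding
window, demeaning, a two-pass (forward-backward, zero net phase lag)
linear-phase FIR bandpass over the alpha band, and symmetric trimming of
the filter-transient edges (85 samples per side, leaving 330).

The two-pass filter runs without padding or reflection: transients are
handled entirely by the edge trim, which comfortably exceeds the 64-sample
group delay of the 129-tap filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

from .errors import ConfigError, LengthError, ParameterError

__all__ = [
    "FilterSpec",
    "WindowBuffer",
    "Decimator",
    "decimate",
    "demean",
    "bandpass_two_pass",
    "trim_edges",
]


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR bandpass specification.

    ``order`` is the filter order (taps = order + 1) and must be even so
    the filter is type I (symmetric, integer group delay of order/2).
    """

    band: tuple[float, float] = (8.0, 13.0)
    order: int = 128
    fs: float = 500.0
    two_pass: bool = True

    def __post_init__(self):
        lo, hi = self.band
        if not 0.0 < lo < hi < self.fs / 2.0:
            raise ConfigError(f"band {self.band} must satisfy 0 < low < high < fs/2")
        if self.order <= 0 or self.order % 2 != 0:
            raise ConfigError("filter order must be a positive even integer")

    @property
    def taps(self) -> np.ndarray:
        """Windowed-sinc (Hamming) coefficients, unity gain at band centre."""
        return _design_bandpass(self.band, self.order, self.fs)

    def to_dict(self) -> dict:
        return {
            "band": list(self.band),
            "order": self.order,
            "fs": self.fs,
            "two_pass": self.two_pass,
        }


@lru_cache(maxsize=32)
def _design_bandpass(band: tuple, order: int, fs: float) -> np.ndarray:
    return signal.firwin(order + 1, band, pass_zero=False, fs=fs)


@lru_cache(maxsize=32)
def _design_antialias(numtaps: int, cutoff: float, fs: float) -> np.ndarray:
    return signal.firwin(numtaps, cutoff, fs=fs)


class WindowBuffer:
    """Fixed-capacity FIFO over the most recent samples, oldest first.

    Appending when full drops the oldest samples. ``ready`` flips once the
    buffer has filled to capacity (and stays set).
    """

    def __init__(self, capacity: int = 500):
        if capacity < 1:
            raise ParameterError("capacity must be >= 1")
        self.capacity = int(capacity)
        self._buf = np.zeros(self.capacity)
        self._count = 0  # total samples ever appended
        self._pos = 0  # next write position (ring)

    def __len__(self) -> int:
        return min(self._count, self.capacity)

    @property
    def ready(self) -> bool:
        return self._count >= self.capacity

    def append(self, samples) -> None:
        arr = np.atleast_1d(np.asarray(samples, dtype=float))
        for block in np.array_split(arr, max(1, arr.size // self.capacity + 1)):
            k = block.size
            if k == 0:
                continue
            if k >= self.capacity:
                self._buf[:] = block[-self.capacity :]
                self._pos = 0
            else:
                end = self._pos + k
                if end <= self.capacity:
                    self._buf[self._pos : end] = block
                else:
                    split = self.capacity - self._pos
                    self._buf[self._pos :] = block[:split]
                    self._buf[: end - self.capacity] = block[split:]
                self._pos = end % self.capacity
            self._count += k

    def content(self) -> np.ndarray:
        """Current samples, oldest first (a copy)."""
        if self._count < self.capacity:
            return self._buf[: self._count].copy()
        return np.roll(self._buf, -self._pos)


class Decimator:
    """Stateful integer-factor decimator (anti-alias FIR + pick every q-th).

    Filter state is carried across calls, so chunk-wise processing agrees
    bit-for-bit with whole-record processing. The anti-alias low-pass cuts
    at 0.8 * (fs_out / 2), preserving the alpha band (<= 13 Hz) to well
    within 2% while attenuating everything beyond the output Nyquist by
    more than 40 dB.
    """

    def __init__(self, fs_in: float, fs_out: float, numtaps: int = 101):
        ratio = fs_in / fs_out
        if abs(ratio - round(ratio)) > 1e-9:
            raise ParameterError(
                f"fs_in ({fs_in}) must be an integer multiple of fs_out ({fs_out})"
            )
        self.fs_in = float(fs_in)
        self.fs_out = float(fs_out)
        self.factor = int(round(ratio))
        self.taps = _design_antialias(numtaps, 0.8 * fs_out / 2.0, fs_in)
        # causal FIR state: the last (numtaps - 1) raw inputs (zeros before
        # the record starts). Each output sample is a fixed-length inner
        # product over the same window regardless of how the input is
        # chunked, so chunked and whole-record processing are bit-identical.
        self._tail = np.zeros(len(self.taps) - 1)
        self._n_in = 0  # input samples consumed so far

    def process(self, block) -> np.ndarray:
        """Filter one chunk and return the decimated samples it yields."""
        x = np.atleast_1d(np.asarray(block, dtype=float))
        if x.size == 0:
            return np.empty(0)
        extended = np.concatenate([self._tail, x])
        y = np.convolve(extended, self.taps, mode="valid")
        self._tail = extended[-(len(self.taps) - 1) :]
        # keep global indices that are multiples of the factor
        start = (-self._n_in) % self.factor
        self._n_in += x.size
        return y[start :: self.factor]


def decimate(block, fs_in: float, fs_out: float) -> np.ndarray:
    """One-shot decimation of a whole record (fresh filter state)."""
    return Decimator(fs_in, fs_out).process(block)


def demean(window) -> np.ndarray:
    """Subtract the arithmetic mean of the window."""
    x = np.asarray(window, dtype=float)
    if x.size == 0:
        raise LengthError("cannot demean an empty window")
    return x - x.mean()


def bandpass_two_pass(window, spec: FilterSpec) -> np.ndarray:
    """Apply the FIR forward then backward over the window (zero net phase).

    No padding is applied; the caller is expected to trim the edges. Output
    length equals input length. With ``spec.two_pass`` false, a single
    causal forward pass is applied instead.
    """
    x = np.asarray(window, dtype=float)
    if x.size <= spec.order:
        raise LengthError(
            f"window of {x.size} samples is too short for filter order {spec.order}"
        )
    b = spec.taps
    y = signal.lfilter(b, 1.0, x)
    if not spec.two_pass:
        return y
    return signal.lfilter(b, 1.0, y[::-1])[::-1]


def trim_edges(window, margin: int = 85) -> np.ndarray:
    """Drop ``margin`` samples from both ends (filter-transient removal).

    For the standard 500-sample window with margin 85 this returns the 330
    retained samples at indices ``[85, 415)``.
    """
    x = np.asarray(window, dtype=float)
    if margin < 0:
        raise ParameterError("margin must be non-negative")
    if x.size <= 2 * margin:
        raise LengthError(
            f"window of {x.size} samples cannot be trimmed by {margin} per side"
        )
    if margin == 0:
        return x.copy()
    return x[margin:-margin].copy()
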