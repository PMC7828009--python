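"""Synthetic single-channel EEG with a known alpha phase.

The generator emulates an occipital channel (O_z-like) sampled at 2 kHz:
a narrowband stochastic alpha oscillation -- white Gaussian noise shaped
in the Fourier domain to a spectral peak at ``alpha_center`` with a
configurable width (default 1 Hz FWHM, a typical individual alpha peak) --
embedded in 1/f-type background noise at a configurable band-limited SNR.
Because the oscillation component is synthesised separately, its
instantaneous phase (the argument of its analytic signal) is known exactly
and is stored on the record as ``truth_phase``.

A deterministic pure-cosine mode (``alpha_mode="cosine"``) is provided for
exact tests; ``snr_db=inf`` disables the noise entirely.

SNR is defined over the alpha analysis band (8-13 Hz by default): the
ratio of oscillation power to noise power within that band, measured on
the actual realisation, so the requested SNR holds exactly for every seed.

Offline ground truth for evaluating the online predictor is computed by
:func:`ground_truth_phase`: a non-causal two-pass (forward-backward) FIR
bandpass over the full record followed by the Hilbert transform, mirroring
the offline convention of the evaluation statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
from scipy import signal

from .circstats import wrap_phase
from .errors import ConfigError, LengthError, ParameterError

__all__ = [
    "SignalConfig",
    "EEGRecord",
    "PhaseTrack",
    "generate",
    "ground_truth_phase",
    "stream",
    "write_record",
    "read_record",
    "read_edf",
]


@dataclass(frozen=True)
class SignalConfig:
    """Parameters of the synthetic EEG generator.

    Parameters
    ----------
    duration:
        Record length in seconds (> 0).
    fs_acq:
        Acquisition sampling rate in Hz; must exceed twice the upper edge
        of ``alpha_band``.
    alpha_center:
        Centre frequency of the alpha oscillation in Hz; must lie strictly
        inside ``alpha_band``.
    alpha_band:
        The (low, high) analysis band in Hz over which SNR is defined.
    alpha_fwhm:
        Full width at half maximum of the oscillation's spectral peak in
        Hz (stochastic mode only). ~1 Hz is a typical resting occipital
        alpha peak; wider values drift faster and are harder to predict.
    snr_db:
        Band-limited SNR in decibels (oscillation power over noise power
        within ``alpha_band``); ``inf`` disables the noise.
    noise_exponent:
        Spectral slope of the background noise (PSD ~ 1/f^exponent).
    amplitude:
        RMS of the oscillation component in microvolts.
    alpha_mode:
        ``"stochastic"`` (default) or ``"cosine"`` for a deterministic
        pure cosine at ``alpha_center``.
    seed:
        Seed for the pseudo-random generator; identical seeds give
        bit-identical records.
    """

    duration: float
    fs_acq: float = 2000.0
    alpha_center: float = 10.0
    alpha_band: tuple[float, float] = (8.0, 13.0)
    alpha_fwhm: float = 1.0
    snr_db: float = 10.0
    noise_exponent: float = 1.0
    amplitude: float = 5.0
    alpha_mode: str = "stochastic"
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.alpha_band
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.fs_acq <= 2.0 * hi:
            raise ConfigError("fs_acq must exceed twice the upper band edge")
        if not lo < self.alpha_center < hi:
            raise ConfigError("alpha_center must lie strictly inside alpha_band")
        if self.alpha_fwhm <= 0:
            raise ConfigError("alpha_fwhm must be positive")
        if self.amplitude <= 0:
            raise ConfigError("amplitude must be positive")
        if self.alpha_mode not in ("stochastic", "cosine"):
            raise ConfigError("alpha_mode must be 'stochastic' or 'cosine'")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs_acq))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alpha_band"] = list(self.alpha_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SignalConfig":
        d = dict(d)
        if "alpha_band" in d:
            d["alpha_band"] = tuple(d["alpha_band"])
        return cls(**d)


@dataclass
class EEGRecord:
    """A single-channel sampled signal (microvolts) with optional ground truth."""

    samples: np.ndarray
    fs: float
    label: str = "Oz-sim"
    truth_phase: Optional[np.ndarray] = None
    meta: Optional[SignalConfig] = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ConfigError("record samples must all be finite")
        if self.truth_phase is not None:
            self.truth_phase = np.asarray(self.truth_phase, dtype=float)
            if self.truth_phase.shape != self.samples.shape:
                raise ConfigError("truth_phase must match samples in length")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class PhaseTrack:
    """Per-sample phase in ``(-pi, pi]`` with an edge-unreliable margin.

    The first and last ``edge_margin`` samples carry filter edge effects
    and should be excluded from quantitative use; ``reliable`` is the
    corresponding boolean mask.
    """

    phase: np.ndarray
    fs: float
    edge_margin: int

    @property
    def reliable(self) -> np.ndarray:
        mask = np.ones(self.phase.size, dtype=bool)
        m = self.edge_margin
        if m > 0:
            mask[:m] = False
            mask[-m:] = False
        return mask


def _band_mask(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Total periodogram power of ``x`` within ``band`` (arbitrary units)."""
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(x.size, 1.0 / fs)
    return float(spec[_band_mask(freqs, band)].sum())


def _alpha_component(config: SignalConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    if config.alpha_mode == "cosine":
        t = np.arange(n) / config.fs_acq
        x = np.cos(2.0 * np.pi * config.alpha_center * t)
        return x * (config.amplitude * math.sqrt(2.0))  # RMS = amplitude
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs_acq)
    sigma_f = config.alpha_fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    shape = np.exp(-0.5 * ((freqs - config.alpha_center) / sigma_f) ** 2)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    rms = math.sqrt(float(np.mean(x**2)))
    return x * (config.amplitude / rms)


def _noise_component(config: SignalConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / config.fs_acq)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-config.noise_exponent / 2.0)
    return np.fft.irfft(spec * shape, n)


def generate(config: SignalConfig) -> EEGRecord:
    """Synthesise one record according to ``config``.

    The noise component is rescaled so that the ratio of oscillation to
    noise power within ``alpha_band``, measured on this realisation,
    equals ``snr_db`` exactly. ``truth_phase`` holds the instantaneous
    phase of the noiseless oscillation component.
    """
    rng = np.random.default_rng(config.seed)
    alpha = _alpha_component(config, rng)
    if config.alpha_mode == "cosine":
        t = np.arange(config.n_samples) / config.fs_acq
        truth = wrap_phase(2.0 * np.pi * config.alpha_center * t)
    else:
        truth = wrap_phase(np.angle(signal.hilbert(alpha)))
    if math.isinf(config.snr_db):
        samples = alpha
    else:
        noise = _noise_component(config, rng)
        p_alpha = _band_power(alpha, config.fs_acq, config.alpha_band)
        p_noise = _band_power(noise, config.fs_acq, config.alpha_band)
        target_ratio = 10.0 ** (config.snr_db / 10.0)
        noise *= math.sqrt(p_alpha / (p_noise * target_ratio))
        samples = alpha + noise
    return EEGRecord(
        samples=samples, fs=config.fs_acq, truth_phase=truth, meta=config
    )


def ground_truth_phase(
    record: EEGRecord,
    band: tuple[float, float] = (8.0, 13.0),
    filter_order: int = 128,
) -> PhaseTrack:
    """Offline, non-causal reference phase of a record.

    Applies a forward-backward (zero-phase) linear-phase FIR bandpass of
    the given order over the *full* record, then takes the argument of
    the analytic signal. This is the reference against which the causal
    online predictor is scored; the first and last ``filter_order``
    samples are flagged edge-unreliable.
    """
    x = record.samples
    if x.size <= 4 * filter_order:
        raise LengthError(
            f"record of {x.size} samples is too short for filter order {filter_order}"
        )
    taps = signal.firwin(filter_order + 1, band, pass_zero=False, fs=record.fs)
    filtered = signal.filtfilt(taps, 1.0, x)
    phase = wrap_phase(np.angle(signal.hilbert(filtered)))
    return PhaseTrack(phase=phase, fs=record.fs, edge_margin=filter_order)


def stream(record: EEGRecord, chunk: int) -> Iterator[np.ndarray]:
    """Yield the record as consecutive blocks of ``chunk`` samples.

    The concatenation of the yielded blocks reproduces ``record.samples``
    exactly; the final block may be shorter.
    """
    if chunk < 1:
        raise ParameterError("chunk must be >= 1")
    x = record.samples
    for start in range(0, x.size, chunk):
        yield x[start : start + chunk]


# ---------------------------------------------------------------------------
# plain-text record I/O: one sample per line plus a JSON sidecar

def write_record(record: EEGRecord, base_path) -> tuple[Path, Path]:
    """Write ``<base>.txt`` (one microvolt sample per line) and ``<base>.json``."""
    base = Path(base_path)
    txt = base.with_suffix(".txt")
    meta = base.with_suffix(".json")
    np.savetxt(txt, record.samples, fmt="%.10g")
    sidecar = {"fs": record.fs, "label": record.label}
    if record.meta is not None:
        sidecar["config"] = record.meta.to_dict()
    meta.write_text(json.dumps(sidecar, indent=2))
    return txt, meta


def read_record(base_path, fs: Optional[float] = None) -> EEGRecord:
    """Read a record written by :func:`write_record` (or any one-column text file).

    When no JSON sidecar exists, ``fs`` must be supplied.
    """
    base = Path(base_path)
    txt = base if base.suffix == ".txt" else base.with_suffix(".txt")
    meta_path = txt.with_suffix(".json")
    label = "file"
    config = None
    if meta_path.exists():
        sidecar = json.loads(meta_path.read_text())
        fs = sidecar.get("fs", fs)
        label = sidecar.get("label", label)
        if "config" in sidecar:
            config = SignalConfig.from_dict(sidecar["config"])
    if fs is None:
        raise ParameterError("sampling rate unknown: no sidecar and no fs given")
    samples = np.loadtxt(txt, ndmin=1)
    return EEGRecord(samples=samples, fs=float(fs), label=label, meta=config)


def read_edf(path, channel: Optional[str] = None) -> EEGRecord:
    """Load one channel of an EDF file as an :class:`EEGRecord` (requires mne)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading EDF files requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    name = channel if channel is not None else raw.ch_names[0]
    data = raw.get_data(picks=[name])[0] * 1e6  # volts -> microvolts
    return EEGRecord(samples=data, fs=float(raw.info["sfreq"]), label=name)
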