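"""Seeded generators for EEG-like and gait-like multi-channel recordings.

Both generators build a shared source with a controlled spectral layout and
add independent per-channel noise, so channel averaging behaves like the
real preprocessing it stands in for.  Sinusoidal components use
RMS-normalized amplitude envelopes, so a component with amplitude ``a``
carries power ``a**2 / 2`` regardless of modulation depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .timeseries import TimeSeries

__all__ = [
    "EEGSimSpec",
    "IMUSimSpec",
    "generate_eeg_like",
    "generate_imu_like",
    "grand_average",
    "imu_axis_average",
]


@dataclass(frozen=True)
class EEGSimSpec:
    """Spectral layout of a synthetic EEG-like recording.

    ``oscillations`` lists ``(center_hz, amplitude, bandwidth_hz)`` narrowband
    components (bandwidth 0 means an unmodulated sinusoid); ``drift`` and
    ``line_noise`` are ``(frequency_hz, amplitude)`` pairs.
    """

    fs: float = 512.0
    duration_s: float = 60.0
    n_channels: int = 8
    background_slope: float = 1.0
    background_sd: float = 1.0
    oscillations: tuple[tuple[float, float, float], ...] = (
        (10.0, 1.0, 2.0),   # alpha-like
        (20.0, 0.5, 4.0),   # beta-like
    )
    line_noise: tuple[float, float] = (60.0, 0.5)
    drift: tuple[float, float] = (0.1, 2.0)
    white_noise_sd: float = 0.3
    channel_noise_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.duration_s < 4:
            raise ConfigurationError("EEG-like records must be >= 4 s long")
        for f0, amp, bw in self.oscillations:
            if amp < 0 or f0 >= self.fs / 2:
                raise ConfigurationError(
                    f"oscillation ({f0}, {amp}, {bw}) invalid for fs={self.fs}")


@dataclass(frozen=True)
class IMUSimSpec:
    """Spectral layout of a synthetic walking (IMU-like) recording."""

    fs: float = 128.0
    duration_s: float = 60.0
    n_sensors: int = 6
    n_axes: int = 6
    stride_hz: float = 1.0
    n_harmonics: int = 4
    harmonic_decay: float = 0.6
    chatter_band: tuple[float, float] = (20.0, 60.0)
    chatter_sd: float = 0.5
    drift: tuple[float, float] = (0.1, 0.5)
    white_noise_sd: float = 0.02
    sensor_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.stride_hz * self.n_harmonics >= self.fs / 2:
            raise ConfigurationError("highest harmonic must stay below Nyquist")
        if self.duration_s < 10.0 / self.stride_hz:
            raise ConfigurationError("record must cover at least 10 strides")
        for v in (self.chatter_sd, self.white_noise_sd, self.sensor_noise_sd,
                  self.harmonic_decay):
            if v < 0:
                raise ConfigurationError("amplitudes must be >= 0")


def _shaped_noise(rng: np.random.Generator, n: int, fs: float,
                  shape_fn, sd: float) -> np.ndarray:
    """White noise spectrally reweighted by ``shape_fn(f)``, rescaled to ``sd``."""
    if sd == 0:
        # burn the same number of draws so later components are unchanged
        rng.standard_normal(n)
        return np.zeros(n)
    w = rng.standard_normal(n)
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = shape_fn(f)
    x = np.fft.irfft(spec * gain, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _pink(f: np.ndarray, alpha: float) -> np.ndarray:
    g = np.zeros_like(f)
    g[1:] = f[1:] ** (-alpha / 2.0)
    return g


def _band_mask(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return ((f >= lo) & (f <= hi)).astype(float)


def _modulated_sinusoid(t: np.ndarray, f0: float, amp: float, mod_hz: float,
                        phase: float, mod_phase: float,
                        depth: float = 0.5) -> np.ndarray:
    """``amp`` RMS-calibrated sinusoid with a slow amplitude envelope.

    The envelope ``(1 + depth*sin)/sqrt(1 + depth^2/2)`` has unit RMS, so
    the component power is ``amp**2 / 2`` exactly in expectation.
    """
    carrier = np.sin(2.0 * np.pi * f0 * t + phase)
    if mod_hz <= 0 or depth == 0:
        return amp * carrier
    env = 1.0 + depth * np.sin(2.0 * np.pi * mod_hz * t + mod_phase)
    env /= np.sqrt(1.0 + depth ** 2 / 2.0)
    return amp * env * carrier


def generate_eeg_like(spec: EEGSimSpec, seed: int) -> TimeSeries:
    """Deterministic EEG-like multi-channel record for a given (spec, seed)."""
    rng = np.random.default_rng(seed)
    n = int(round(spec.fs * spec.duration_s))
    t = np.arange(n) / spec.fs

    shared = _shaped_noise(rng, n, spec.fs,
                           lambda f: _pink(f, spec.background_slope),
                           spec.background_sd)
    for f0, amp, bw in spec.oscillations:
        shared += _modulated_sinusoid(t, f0, amp, bw / 2.0,
                                      rng.uniform(0, 2 * np.pi),
                                      rng.uniform(0, 2 * np.pi))
    lf, lamp = spec.line_noise
    shared += lamp * np.sin(2.0 * np.pi * lf * t + rng.uniform(0, 2 * np.pi))
    df_, damp = spec.drift
    shared += damp * np.sin(2.0 * np.pi * df_ * t + rng.uniform(0, 2 * np.pi))
    if spec.white_noise_sd > 0:
        shared += spec.white_noise_sd * rng.standard_normal(n)
    else:
        rng.standard_normal(n)

    chans = shared[:, np.newaxis] + spec.channel_noise_sd * rng.standard_normal(
        (n, spec.n_channels))
    labels = tuple(f"ch{i:02d}" for i in range(spec.n_channels))
    return TimeSeries(chans, spec.fs, labels)


_AXIS_NAMES = ("accx", "accy", "accz", "gyrx", "gyry", "gyrz")


def generate_imu_like(spec: IMUSimSpec, seed: int) -> TimeSeries:
    """Deterministic gait-like record: ``n_sensors * n_axes`` channels.

    The shared source is a harmonic stack at the stride frequency (slowly
    amplitude-modulated), plus drift, band-limited high-frequency chatter
    and broadband noise; each channel adds independent sensor noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.fs * spec.duration_s))
    t = np.arange(n) / spec.fs

    gait = np.zeros(n)
    for h in range(1, spec.n_harmonics + 1):
        amp = spec.harmonic_decay ** (h - 1)
        gait += _modulated_sinusoid(t, h * spec.stride_hz, amp, 0.05,
                                    rng.uniform(0, 2 * np.pi),
                                    rng.uniform(0, 2 * np.pi), depth=0.2)
    df_, damp = spec.drift
    gait += damp * np.sin(2.0 * np.pi * df_ * t + rng.uniform(0, 2 * np.pi))
    lo, hi = spec.chatter_band
    hi = min(hi, spec.fs / 2.0)
    gait += _shaped_noise(rng, n, spec.fs, lambda f: _band_mask(f, lo, hi),
                          spec.chatter_sd)
    if spec.white_noise_sd > 0:
        gait += spec.white_noise_sd * rng.standard_normal(n)
    else:
        rng.standard_normal(n)

    n_chan = spec.n_sensors * spec.n_axes
    chans = gait[:, np.newaxis] + spec.sensor_noise_sd * rng.standard_normal(
        (n, n_chan))
    labels = tuple(
        f"s{s}_{_AXIS_NAMES[a % len(_AXIS_NAMES)]}"
        for s in range(spec.n_sensors) for a in range(spec.n_axes))
    return TimeSeries(chans, spec.fs, labels)


def grand_average(x: TimeSeries) -> TimeSeries:
    """Arithmetic mean across all channels at each sample."""
    avg = x.samples.mean(axis=1, keepdims=True)
    return TimeSeries(avg, x.fs, ("grand_average",))


def imu_axis_average(x: TimeSeries, n_sensors: int, n_axes: int,
                     collapse: bool = True) -> TimeSeries:
    """Average across sensors within each axis; optionally collapse axes too.

    Channels are assumed ordered sensor-major (all axes of sensor 0, then
    sensor 1, ...).  With equal sensor counts per axis the fully collapsed
    result equals the plain grand average.
    """
    if x.n_channels != n_sensors * n_axes:
        raise ConfigurationError(
            f"{x.n_channels} channels != {n_sensors} sensors x {n_axes} axes")
    cube = x.samples.reshape(x.n_samples, n_sensors, n_axes)
    per_axis = cube.mean(axis=1)
    if not collapse:
        labels = tuple(_AXIS_NAMES[a % len(_AXIS_NAMES)] for a in range(n_axes))
        return TimeSeries(per_axis, x.fs, labels)
    return TimeSeries(per_axis.mean(axis=1, keepdims=True), x.fs,
                      ("composite",))
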