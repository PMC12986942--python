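"""Welch PSD estimation and band-power / SNR outcome measures."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DataError, ResolutionError
from .timeseries import BandSpec, TimeSeries

__all__ = [
    "WelchSpec",
    "PSDEstimate",
    "welch_psd",
    "band_power",
    "total_power",
    "band_snr",
    "residual_snr",
]


@dataclass(frozen=True)
class WelchSpec:
    """Welch estimator settings (Hann window, no overlap by default)."""

    window: str = "hann"
    nperseg: int = 1024
    noverlap: int = 0
    detrend: str = "constant"
    scaling: str = "density"

    def __post_init__(self) -> None:
        if self.nperseg < 8:
            raise DataError("nperseg must be >= 8")
        if not (0 <= self.noverlap < self.nperseg):
            raise DataError("need 0 <= noverlap < nperseg")
        if self.detrend not in ("constant", "none"):
            raise DataError(f"unknown detrend {self.detrend!r}")
        if self.scaling != "density":
            raise DataError("only density scaling is supported")


@dataclass
class PSDEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    density: np.ndarray
    fs: float
    n_segments: int

    @property
    def df(self) -> float:
        """Grid spacing in Hz."""
        return float(self.freqs[1] - self.freqs[0])

    def to_text(self, path) -> None:
        """Write a two-column delimited table (frequency_hz, density)."""
        np.savetxt(path, np.column_stack([self.freqs, self.density]),
                   delimiter=",", header="frequency_hz,density", comments="")


def welch_psd(x: TimeSeries | np.ndarray, spec: WelchSpec | None = None,
              fs: float | None = None) -> PSDEstimate:
    """Welch PSD of a single-channel signal.

    If the signal is shorter than ``nperseg`` the segment length shrinks to
    the signal length with a warning (scipy's behavior, made explicit).
    """
    if spec is None:
        spec = WelchSpec()
    if isinstance(x, TimeSeries):
        if x.n_channels != 1:
            raise DataError("welch_psd expects a single-channel signal")
        data, fs = x.channel(0), x.fs
    else:
        data = np.asarray(x, dtype=float).ravel()
        if fs is None:
            raise DataError("fs is required for bare-array input")
    if not np.all(np.isfinite(data)):
        raise DataError("signal contains non-finite samples")
    nperseg = spec.nperseg
    if data.size < nperseg:
        warnings.warn(
            f"signal of {data.size} samples is shorter than nperseg="
            f"{nperseg}; shrinking the segment", UserWarning, stacklevel=2)
        nperseg = data.size
    noverlap = min(spec.noverlap, nperseg - 1)
    detrend = spec.detrend if spec.detrend != "none" else False
    freqs, dens = signal.welch(data, fs=fs, window=spec.window, nperseg=nperseg,
                               noverlap=noverlap, detrend=detrend,
                               scaling=spec.scaling)
    step = nperseg - noverlap
    n_segments = 1 + (data.size - nperseg) // step
    return PSDEstimate(freqs=freqs, density=dens, fs=float(fs),
                       n_segments=int(n_segments))


def band_power(psd: PSDEstimate, band: BandSpec) -> float:
    """Rectangle-rule power over bins with ``f_lo <= f_k <= f_hi`` (inclusive)."""
    mask = (psd.freqs >= band.f_lo) & (psd.freqs <= band.f_hi)
    if not mask.any():
        raise ResolutionError(
            f"no PSD bins inside [{band.f_lo}, {band.f_hi}] "
            f"(grid spacing {psd.df:g} Hz)")
    return float(psd.density[mask].sum() * psd.df)


def total_power(psd: PSDEstimate) -> float:
    """Power integrated over the full one-sided grid (0 to Nyquist)."""
    return float(psd.density.sum() * psd.df)


def band_snr(psd: PSDEstimate, band: BandSpec) -> float:
    """Band-limited SNR: ``10 log10(P_band / (P_total - P_band))`` in dB.

    Returns ``+inf`` (with a warning) when out-of-band power is zero and
    ``-inf`` when in-band power is zero; never raises on degenerate power
    splits so batch tables stay rectangular.
    """
    p_band = band_power(psd, band)
    p_out = total_power(psd) - p_band
    if p_band <= 0.0:
        return float("-inf")
    if p_out <= 0.0:
        warnings.warn("zero out-of-band power; SNR is +inf", UserWarning,
                      stacklevel=2)
        return float("inf")
    return float(10.0 * np.log10(p_band / p_out))


def residual_snr(raw: TimeSeries, filtered: TimeSeries) -> float:
    """Residual-based SNR: filtered power over power of (raw - filtered), dB.

    Powers are mean squares over the full record.
    """
    if raw.n_samples != filtered.n_samples or raw.fs != filtered.fs:
        raise DataError("raw and filtered series must share length and fs")
    sig = float(np.mean(filtered.samples ** 2))
    noise = float(np.mean((raw.samples - filtered.samples) ** 2))
    if noise == 0.0:
        return float("inf")
    if sig == 0.0:
        return float("-inf")
    return float(10.0 * np.log10(sig / noise))
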