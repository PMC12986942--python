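"""Core data carriers: uniformly sampled multi-channel signals and frequency bands."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DataError

__all__ = ["TimeSeries", "BandSpec"]


@dataclass
class TimeSeries:
    """A uniformly sampled real-valued signal.

    Parameters
    ----------
    samples
        Array of shape ``(n_samples,)`` or ``(n_samples, n_channels)``.
        A 1-D array is promoted to a single-channel column.
    fs
        Sampling rate in Hz. Must be positive.
    labels
        Optional channel names; length must match ``n_channels`` when given.
    """

    samples: np.ndarray
    fs: float
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, np.newaxis]
        if arr.ndim != 2:
            raise DataError(f"samples must be 1-D or 2-D, got ndim={arr.ndim}")
        if arr.shape[0] < 2:
            raise DataError("a TimeSeries needs at least 2 samples")
        if not np.all(np.isfinite(arr)):
            raise DataError("samples contain non-finite values")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")
        if self.labels is not None:
            self.labels = tuple(str(x) for x in self.labels)
            if len(self.labels) != arr.shape[1]:
                raise ConfigurationError(
                    f"{len(self.labels)} labels for {arr.shape[1]} channels"
                )
        self.samples = arr
        self.fs = float(self.fs)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0

    def channel(self, index: int) -> np.ndarray:
        """Return one channel as a flat array."""
        return self.samples[:, index]

    def with_samples(self, samples: np.ndarray) -> "TimeSeries":
        """New TimeSeries with the same metadata but different samples."""
        return TimeSeries(samples, self.fs, self.labels)


@dataclass(frozen=True)
class BandSpec:
    """A frequency band ``[f_lo, f_hi]`` in Hz (edges inclusive)."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ConfigurationError(
                f"need 0 < f_lo < f_hi, got [{self.f_lo}, {self.f_hi}]"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    def validate_against(self, fs: float) -> None:
        """Raise if the band is not strictly inside (0, fs/2)."""
        if self.f_hi >= fs / 2.0:
            raise ConfigurationError(
                f"band [{self.f_lo}, {self.f_hi}] must lie below Nyquist {fs / 2.0}"
            )

    def contains(self, f: float | np.ndarray) -> np.ndarray:
        return (np.asarray(f) >= self.f_lo) & (np.asarray(f) <= self.f_hi)
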