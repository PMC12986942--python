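"""Classical IIR band-pass comparators (Butterworth, Chebyshev-I, elliptic).

Designs are realized as second-order sections and can be applied either
zero-phase (forward-backward) or causally (single forward pass).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, DataError, DesignError
from .timeseries import BandSpec, TimeSeries

__all__ = [
    "IIRDesignSpec",
    "DesignedFilter",
    "design_iir",
    "apply_zero_phase",
    "apply_causal",
    "frequency_response",
    "measure_ripple_and_attenuation",
    "sos_to_text",
    "sos_from_text",
]

_FAMILIES = ("butterworth", "chebyshev1", "elliptic")

#: dB value substituted for exact spectral zeros
DB_FLOOR = -300.0


@dataclass(frozen=True)
class IIRDesignSpec:
    """Parameters of a band-pass IIR design.

    ``order`` is the value passed to the design routine; a band-pass of
    design order ``n`` has ``2n`` poles.  ``rp_db`` applies to
    chebyshev1/elliptic, ``rs_db`` to elliptic only.
    """

    family: str
    order: int
    band: BandSpec
    fs: float
    rp_db: float | None = None
    rs_db: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.order < 1:
            raise ConfigurationError("order must be >= 1")
        if self.family in ("chebyshev1", "elliptic"):
            if self.rp_db is None or self.rp_db <= 0:
                raise ConfigurationError(f"{self.family} needs rp_db > 0")
        if self.family == "elliptic":
            if self.rs_db is None or self.rs_db <= self.rp_db:
                raise ConfigurationError("elliptic needs rs_db > rp_db")
        self.band.validate_against(self.fs)


@dataclass
class DesignedFilter:
    """A realized design: SOS coefficient matrix plus its design spec."""

    sos: np.ndarray
    spec: IIRDesignSpec

    @property
    def n_sections(self) -> int:
        return self.sos.shape[0]

    def poles(self) -> np.ndarray:
        """All poles of the cascade (roots of the section denominators)."""
        return np.concatenate([np.roots(sec[3:]) for sec in self.sos])

    def is_stable(self) -> bool:
        return bool(np.all(np.abs(self.poles()) < 1.0))


def design_iir(spec: IIRDesignSpec) -> DesignedFilter:
    """Design a band-pass prototype of the requested family in SOS form.

    Uses the bilinear transform with band-edge prewarping (via scipy's
    ``fs`` argument).  Raises :class:`DesignError` if any pole lands on or
    outside the unit circle.
    """
    wn = [spec.band.f_lo, spec.band.f_hi]
    if spec.family == "butterworth":
        sos = signal.butter(spec.order, wn, btype="bandpass", output="sos", fs=spec.fs)
    elif spec.family == "chebyshev1":
        sos = signal.cheby1(spec.order, spec.rp_db, wn, btype="bandpass",
                            output="sos", fs=spec.fs)
    else:
        sos = signal.ellip(spec.order, spec.rp_db, spec.rs_db, wn,
                           btype="bandpass", output="sos", fs=spec.fs)
    filt = DesignedFilter(sos=np.asarray(sos, dtype=float), spec=spec)
    if not filt.is_stable():
        raise DesignError(f"{spec.family} design has poles outside the unit circle")
    return filt


def _min_filtfilt_len(sos: np.ndarray) -> int:
    # scipy's default padlen for sosfiltfilt
    ntaps = 2 * sos.shape[0] + 1
    return 3 * (ntaps - min((sos[:, 2] == 0).sum(), (sos[:, 5] == 0).sum()))


def apply_zero_phase(filt: DesignedFilter, x: TimeSeries) -> TimeSeries:
    """Forward-backward (two-pass) application: zero phase, squared magnitude.

    Uses odd-reflection edge padding of 3x the effective filter length
    (scipy's convention).  Raises :class:`DataError` if the input is too
    short for the padding scheme.
    """
    if x.n_samples <= _min_filtfilt_len(filt.sos):
        raise DataError(
            f"input of {x.n_samples} samples is too short for zero-phase "
            f"application (need > {_min_filtfilt_len(filt.sos)})"
        )
    y = signal.sosfiltfilt(filt.sos, x.samples, axis=0)
    return x.with_samples(y)


def apply_causal(filt: DesignedFilter, x: TimeSeries) -> TimeSeries:
    """Single forward pass from zero initial conditions (delayed output)."""
    y = signal.sosfilt(filt.sos, x.samples, axis=0)
    return x.with_samples(np.asarray(y))


def frequency_response(filt: DesignedFilter, freqs) -> np.ndarray:
    """Single-pass magnitude response in dB at the given frequencies (Hz).

    Exact zeros are clamped to a floor of -300 dB.
    """
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    _, h = signal.sosfreqz(filt.sos, worN=freqs, fs=filt.spec.fs)
    mag = np.abs(h)
    db = np.full_like(mag, DB_FLOOR)
    nz = mag > 10 ** (DB_FLOOR / 20.0)
    db[nz] = 20.0 * np.log10(mag[nz])
    return db


def measure_ripple_and_attenuation(filt: DesignedFilter, n_grid: int = 20001,
                                   f_min: float = 0.01) -> dict:
    """Quantify passband ripple and stopband attenuation of a realized design.

    * ``passband_ripple_db``: (max - min) dB magnitude on a dense linear
      grid spanning the design band.
    * ``min_stopband_attenuation_db``: for an elliptic design, the smallest
      attenuation anywhere beyond the first frequency (on each side) at
      which attenuation first reaches the design target ``rs_db`` —
      i.e. the attenuation at the worst equiripple stopband maximum.  For
      monotone-stopband families, the attenuation at half the lower edge
      and twice the upper edge (whichever is smaller).
    """
    spec = filt.spec
    pass_grid = np.linspace(spec.band.f_lo, spec.band.f_hi, n_grid)
    pdb = frequency_response(filt, pass_grid)
    ripple = float(pdb.max() - pdb.min())

    if spec.family == "elliptic":
        nyq = spec.fs / 2.0
        atten = None
        worst = np.inf
        for lo, hi, toward_band in (
            (f_min, spec.band.f_lo, False),   # lower stopband, scan up toward band
            (spec.band.f_hi, nyq * 0.9999, True),  # upper stopband
        ):
            grid = np.geomspace(lo, hi, n_grid)
            db = frequency_response(filt, grid)
            att = -db
            reach = att >= spec.rs_db - 1e-9
            if not reach.any():
                continue
            if toward_band:
                start = np.argmax(reach)  # first crossing moving away from band
                region = att[start:]
            else:
                stop = len(att) - np.argmax(reach[::-1])  # last crossing index + 1
                region = att[:stop]
            worst = min(worst, float(region.min()))
        atten = worst if np.isfinite(worst) else float("nan")
    else:
        probe = np.array([spec.band.f_lo / 2.0, min(2.0 * spec.band.f_hi,
                                                    spec.fs / 2.0 * 0.999)])
        atten = float((-frequency_response(filt, probe)).min())

    return {"passband_ripple_db": ripple, "min_stopband_attenuation_db": atten}


def sos_to_text(filt: DesignedFilter, path) -> None:
    """Write one SOS row per line (6 comma-separated coefficients)."""
    np.savetxt(path, filt.sos, delimiter=",",
               header="b0,b1,b2,a0,a1,a2", comments="# ")


def sos_from_text(path, spec: IIRDesignSpec) -> DesignedFilter:
    """Read a coefficient table written by :func:`sos_to_text`."""
    sos = np.atleast_2d(np.loadtxt(path, delimiter=","))
    if sos.shape[1] != 6:
        raise ConfigurationError("SOS table must have 6 columns")
    return DesignedFilter(sos=sos, spec=spec)
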