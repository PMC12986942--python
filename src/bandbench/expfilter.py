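"""Exponential frequency-domain band-pass filter with adaptive edge sharpening.

The filter shapes an explicit magnitude template on the one-sided FFT grid,

    G_d(f) = exp(-c * (u(f) + offset) ** d),

where ``u(f)`` is the distance from ``f`` to the pass band (zero inside it)
expressed either in FFT bins (default) or in Hz.  The exponent ``d`` is not
fixed a priori: it is grown in fixed steps from an initial value until the
jump of the template across each band edge — the edge sharpness ``S(d)`` —
stops changing, which drives the template toward a brick wall at single-bin
resolution.  The filtered signal is obtained by real-valued magnitude
weighting of the FFT coefficients, so the operation is exactly zero-phase
(and therefore offline / non-causal).
"""

from __future__ import annotations

import functools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ResolutionError
from .timeseries import BandSpec, TimeSeries

__all__ = [
    "ExpBandpassParams",
    "GainTemplate",
    "ExponentSelection",
    "distance_to_band",
    "exp_gain",
    "gain_template",
    "edge_sharpness",
    "select_exponent",
    "exp_bandpass_filter",
]

#: largest exponent fed to :func:`math.exp`; beyond it the gain is exactly 0
_LOG_CLAMP = 700.0


@dataclass(frozen=True)
class ExpBandpassParams:
    """Shape and search parameters of the exponential band-pass template.

    Attributes
    ----------
    c
        Coefficient setting the initial rate of attenuation (> 0).
    offset
        Small positive constant added to the distance so the template is
        well behaved exactly at the band edges; must satisfy
        ``0 < offset < 1`` so that in-band gain tends to 1 as ``d`` grows.
    d0, delta_d, tol
        Initial exponent, step size and convergence tolerance of the
        sharpness-driven exponent search.
    d_max
        Hard cap on the exponent search (a warning is issued if hit).
    dist_mode
        ``"bins"`` divides the Hz distance by the FFT bin width (default);
        ``"hz"`` uses the raw Hz distance.
    pad_mode
        ``"reflect"`` mirrors ``pad_len`` samples at each end before the
        FFT to soften boundary effects; ``"none"`` applies the bare
        algorithm.
    pad_len
        Padding length in samples; ``None`` selects
        ``min(n_samples - 1, round(fs))``.
    """

    c: float = 1.0
    offset: float = 0.05
    d0: float = 10.0
    delta_d: float = 5.0
    tol: float = 1e-4
    d_max: float = 10_000.0
    dist_mode: str = "bins"
    pad_mode: str = "reflect"
    pad_len: int | None = None

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ConfigurationError("c must be > 0")
        if not (0 < self.offset < 1):
            raise ConfigurationError("offset must lie in (0, 1)")
        if self.d0 <= 0 or self.delta_d <= 0 or self.tol <= 0:
            raise ConfigurationError("d0, delta_d and tol must be positive")
        if self.d_max <= self.d0:
            raise ConfigurationError("d_max must exceed d0")
        if self.dist_mode not in ("bins", "hz"):
            raise ConfigurationError(f"unknown dist_mode {self.dist_mode!r}")
        if self.pad_mode not in ("reflect", "none"):
            raise ConfigurationError(f"unknown pad_mode {self.pad_mode!r}")


@dataclass(frozen=True)
class ExponentSelection:
    """Outcome of the adaptive exponent search."""

    d: float
    sharpness: float
    converged: bool
    n_evaluations: int


@dataclass
class GainTemplate:
    """The magnitude template evaluated on a one-sided FFT grid."""

    freqs: np.ndarray
    gains: np.ndarray
    d_used: float

    def to_text(self, path) -> None:
        """Write a two-column delimited table (frequency_hz, gain)."""
        np.savetxt(
            path,
            np.column_stack([self.freqs, self.gains]),
            delimiter=",",
            header="frequency_hz,gain",
            comments="",
        )


def distance_to_band(f, band: BandSpec):
    """Distance in Hz from frequency ``f`` to the band (0 inside it).

    Total on finite inputs; accepts scalars or arrays.
    """
    f = np.asarray(f, dtype=float)
    below = np.clip(band.f_lo - f, 0.0, None)
    above = np.clip(f - band.f_hi, 0.0, None)
    out = below + above  # at most one is non-zero
    return out if out.ndim else float(out)


def exp_gain(freqs, band: BandSpec, params: ExpBandpassParams, d: float,
             delta_f: float | None = None):
    """Evaluate the exponential gain template at ``freqs``.

    The exponentiation runs in log space with a clamp so that large
    arguments underflow cleanly to gain 0 instead of overflowing.
    """
    if d <= 0:
        raise ConfigurationError("exponent d must be positive")
    u = np.asarray(distance_to_band(freqs, band), dtype=float)
    if params.dist_mode == "bins":
        if delta_f is None or delta_f <= 0:
            raise ConfigurationError("dist_mode='bins' requires delta_f > 0")
        u = u / delta_f
    t = d * np.log(u + params.offset)
    t = np.minimum(t, _LOG_CLAMP)
    g = np.exp(-params.c * np.exp(t))
    return g if g.ndim else float(g)


def _grid_edges(fs: float, n_samples: int, band: BandSpec):
    """Bin indices of the four sharpness evaluation points.

    Returns ``(k_lo_out, k_lo_in, k_hi_in, k_hi_out)`` on the one-sided
    grid of a length-``n_samples`` FFT: the nearest in-band bin for each
    edge and the adjacent out-of-band bin one step further out.  An edge
    sitting exactly on a bin counts as in-band.
    """
    df = fs / n_samples
    n_bins = n_samples // 2 + 1
    k_lo_in = int(math.ceil(band.f_lo / df - 1e-9))
    k_hi_in = int(math.floor(band.f_hi / df + 1e-9))
    k_lo_out = k_lo_in - 1
    k_hi_out = k_hi_in + 1
    if k_lo_out < 0 or k_hi_out > n_bins - 1 or k_lo_in > k_hi_in:
        raise ResolutionError(
            f"grid (fs={fs}, N={n_samples}, df={df:g}) cannot place a bin "
            f"inside and outside each edge of [{band.f_lo}, {band.f_hi}]"
        )
    return k_lo_out, k_lo_in, k_hi_in, k_hi_out


def edge_sharpness(d: float, fs: float, n_samples: int, band: BandSpec,
                   params: ExpBandpassParams) -> float:
    """Average gain jump of the template across the two band edges.

    ``S(d) = 1/2 [ (G(f_lo_in) - G(f_lo_out)) + (G(f_hi_in) - G(f_hi_out)) ]``
    where each ``G`` is read at the grid bin nearest the stated point:
    the nearest in-band bin for the edge terms, the adjacent out-of-band
    bin for the outside terms.
    """
    band.validate_against(fs)
    df = fs / n_samples
    k = _grid_edges(fs, n_samples, band)
    freqs = np.array(k, dtype=float) * df
    g = exp_gain(freqs, band, params, d, delta_f=df)
    return float(0.5 * ((g[1] - g[0]) + (g[2] - g[3])))


@functools.lru_cache(maxsize=256)
def _select_exponent_cached(fs: float, n_samples: int, band: BandSpec,
                            params: ExpBandpassParams) -> ExponentSelection:
    s_prev = edge_sharpness(params.d0, fs, n_samples, band, params)
    if not np.isfinite(s_prev):
        raise ConfigurationError("edge sharpness is not finite at d0")
    d = params.d0
    n_eval = 1
    while d + params.delta_d <= params.d_max:
        d = d + params.delta_d
        s = edge_sharpness(d, fs, n_samples, band, params)
        n_eval += 1
        if not np.isfinite(s):
            raise ConfigurationError(f"edge sharpness is not finite at d={d}")
        if abs(s - s_prev) < params.tol:
            return ExponentSelection(d, s, True, n_eval)
        s_prev = s
    warnings.warn(
        f"exponent search hit the cap d_max={params.d_max} without converging",
        RuntimeWarning,
        stacklevel=3,
    )
    return ExponentSelection(d, s_prev, False, n_eval)


def select_exponent(fs: float, n_samples: int, band: BandSpec,
                    params: ExpBandpassParams | None = None) -> ExponentSelection:
    """Grow the exponent ``d0, d0+Δd, ...`` until the sharpness settles.

    Returns the first ``d`` whose sharpness differs from the previous
    step's by less than ``tol``.  If the cap ``d_max`` is reached first,
    the last evaluated ``d`` is returned with ``converged=False`` and a
    :class:`RuntimeWarning`.
    """
    if params is None:
        params = ExpBandpassParams()
    return _select_exponent_cached(float(fs), int(n_samples), band, params)


def gain_template(fs: float, n_samples: int, band: BandSpec,
                  params: ExpBandpassParams | None = None,
                  d: float | None = None) -> GainTemplate:
    """Build the template on the one-sided grid of a length-``n_samples`` FFT.

    When ``d`` is omitted it is chosen by :func:`select_exponent`.
    """
    if params is None:
        params = ExpBandpassParams()
    band.validate_against(fs)
    if d is None:
        d = select_exponent(fs, n_samples, band, params).d
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gains = exp_gain(freqs, band, params, d, delta_f=fs / n_samples)
    return GainTemplate(freqs=freqs, gains=gains, d_used=float(d))


def _resolve_pad_len(params: ExpBandpassParams, n_samples: int, fs: float) -> int:
    if params.pad_mode == "none":
        return 0
    if params.pad_len is not None:
        return min(int(params.pad_len), n_samples - 1)
    return min(n_samples - 1, int(round(fs)))


def exp_bandpass_filter(x: TimeSeries, band: BandSpec,
                        params: ExpBandpassParams | None = None) -> TimeSeries:
    """Zero-phase band-pass via FFT magnitude weighting.

    Pipeline: optional reflect-padding → one-sided FFT → multiply by the
    adaptive :class:`GainTemplate` → inverse FFT → crop padding.  Output is
    real, with the same length and sampling rate as the input.  The Nyquist
    bin (even length) is weighted like any other grid point.
    """
    if params is None:
        params = ExpBandpassParams()
    band.validate_against(x.fs)
    pad = _resolve_pad_len(params, x.n_samples, x.fs)
    data = x.samples
    if pad > 0:
        data = np.pad(data, ((pad, pad), (0, 0)), mode="reflect")
    n_fft = data.shape[0]
    template = gain_template(x.fs, n_fft, band, params)
    spec = np.fft.rfft(data, axis=0)
    y = np.fft.irfft(spec * template.gains[:, np.newaxis], n=n_fft, axis=0)
    if pad > 0:
        y = y[pad:-pad]
    return x.with_samples(y)
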