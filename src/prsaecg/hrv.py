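"""Time- and frequency-domain heart-rate-variability indices.

Frequency analysis uses the standard short-term bands: LF 0.04–0.15 Hz and
HF 0.15–0.4 Hz, integrated from the power spectral density of the RR
series.  Because the RR series is unevenly sampled in time, it is
cubic-spline resampled at 4 Hz over the beats that survived ectopic
flagging, linearly detrended, Hann-windowed, and transformed with a
single-segment FFT periodogram (2-minute epochs are too short for Welch
averaging at 0.04 Hz resolution).  The periodogram scaling preserves total
power, so the integral of the PSD matches the variance of the detrended
series and a sinusoidal modulation of amplitude a contributes a²/2 ms²
inside its band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .delineation import Tachogram

__all__ = [
    "LF_BAND",
    "HF_BAND",
    "SpectralResult",
    "HRVError",
    "time_domain",
    "rr_psd",
    "band_power",
]

log = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
RESAMPLE_FS = 4.0
MIN_SPAN_S = 30.0
WARN_SPAN_S = 60.0
MIN_VALID_BEATS = 30


class HRVError(Exception):
    """Raised when the tachogram cannot support the requested index."""


@dataclass
class SpectralResult:
    """PSD of the NN series and its band powers.

    ``psd`` is in ms²/Hz on the ``frequencies`` grid; ``lf_power`` /
    ``hf_power`` are trapezoidal integrals over the standard bands (ms²).
    ``lf_hf_ratio`` is NaN (undefined, logged) when HF power is zero.
    ``meta`` records the method: resample rate, window, detrend.
    """

    frequencies: np.ndarray
    psd: np.ndarray
    lf_power: float
    hf_power: float
    lf_hf_ratio: float
    meta: dict = field(default_factory=dict)


def time_domain(tach: Tachogram) -> tuple[float, float]:
    """(mean RR in ms, heart rate in bpm) over unflagged beats."""
    rr = tach.valid_rr
    if rr.size < 2:
        raise HRVError("fewer than 2 valid beats")
    mean_rr = float(np.mean(rr))
    return mean_rr, 60000.0 / mean_rr


def rr_psd(tach: Tachogram, resample_fs: float = RESAMPLE_FS) -> SpectralResult:
    """Windowed periodogram of the evenly resampled NN series.

    Ectopic-flagged beats are removed before spline interpolation, so the
    spline bridges the gap; this is standard NN-series practice.  Raises
    for spans under 30 s or fewer than 30 valid beats; warns under 60 s
    (marginal LF resolution).
    """
    keep = ~tach.ectopic
    t, rr = tach.t_s[keep], tach.rr_ms[keep]
    if rr.size < MIN_VALID_BEATS:
        raise HRVError(f"only {rr.size} valid beats; need {MIN_VALID_BEATS}")
    span = t[-1] - t[0]
    if span < MIN_SPAN_S:
        raise HRVError(f"tachogram span {span:.1f} s below minimum {MIN_SPAN_S:.0f} s")
    if span < WARN_SPAN_S:
        log.warning("tachogram span %.1f s < %.0f s: LF resolution marginal",
                    span, WARN_SPAN_S)
    spline = CubicSpline(t, rr)
    n = int(np.floor(span * resample_fs)) + 1
    tt = t[0] + np.arange(n) / resample_fs
    x = spline(tt)
    freqs, psd = sps.periodogram(
        x, fs=resample_fs, window="hann", detrend="linear", scaling="density"
    )
    lf = band_power_arrays(freqs, psd, LF_BAND)
    hf = band_power_arrays(freqs, psd, HF_BAND)
    if hf > 0:
        ratio = lf / hf
    else:
        ratio = float("nan")
        log.warning("HF power is zero; LF/HF undefined")
    return SpectralResult(
        frequencies=freqs,
        psd=psd,
        lf_power=lf,
        hf_power=hf,
        lf_hf_ratio=ratio,
        meta={
            "resample_fs_hz": resample_fs,
            "window": "hann",
            "detrend": "linear",
            "segments": 1,
            "n_valid_beats": int(rr.size),
            "span_s": float(span),
        },
    )


def band_power_arrays(
    freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]
) -> float:
    """Trapezoidal integral of the PSD over [f1, f2].

    The band edges are placed exactly on the integration grid (PSD linearly
    interpolated there), so powers are additive over adjacent bands no
    matter where the split falls relative to the frequency bins.
    """
    f1, f2 = band
    if f2 <= f1:
        log.warning("empty band (%s, %s): power 0", f1, f2)
        return 0.0
    interior = (freqs > f1) & (freqs < f2)
    grid = np.concatenate(([f1], freqs[interior], [f2]))
    vals = np.interp(grid, freqs, psd)
    return float(np.trapezoid(vals, grid))


def band_power(spec: SpectralResult, band: tuple[float, float]) -> float:
    """Band power (ms²) from an existing spectral result."""
    nyq = spec.frequencies[-1]
    if band[0] < 0 or band[1] > nyq + 1e-12:
        raise HRVError(f"band {band} outside [0, {nyq:.3f}] Hz")
    return band_power_arrays(spec.frequencies, spec.psd, band)
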