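"""Beat detection and delineation on the vectorcardiogram.

R-peaks are detected on the spatial vector magnitude |V| =
sqrt(Vx²+Vy²+Vz²) with a Pan–Tompkins-style energy detector: squared
magnitude, 15 ms moving average, adaptive threshold at 0.4x the rolling
2-second maximum, 250 ms refractory.  No training data, fully
deterministic.

The RR tachogram applies the sequential 20 % ectopic rule: a beat is
flagged when its RR differs by more than 20 % (strictly) from the most
recent *unflagged* RR; flagged beats do not update the reference, so a
single ectopic flags both the early beat and its compensatory pause while
the rhythm re-locks on the next normal interval.

T-wave windows use the QRS-anchored fallback rule, which is deterministic
and robust to the low T/P amplitudes that defeat peak-based delineators on
the tetrahedron's Vy/Vz:

    Ton_i  = QRS_i + 90 ms
    Tend_i = QRS_i + min(360 ms, 2/3 * RR_i)   (so 360 ms once RR >= 720 ms)

"QRS_i mark" is taken as the R-peak index, and RR_i as the interval
*preceding* beat i; both are config switches (``qrs_mark``, ``rr_mode``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal as sps

from .vcg import VCGSignal

__all__ = [
    "Tachogram",
    "BeatAnnotations",
    "DelineationError",
    "detect_r_peaks",
    "build_tachogram",
    "flag_ectopic",
    "assign_twave_windows",
    "delineate",
]

log = logging.getLogger(__name__)

REFRACTORY_S = 0.25
ENERGY_SMOOTH_S = 0.015
THRESHOLD_FRACTION = 0.4
ROLLING_MAX_S = 2.0
ECTOPIC_THRESHOLD = 0.20
TON_OFFSET_MS = 90.0
TEND_CAP_MS = 360.0
TEND_RR_FRACTION = 2.0 / 3.0
QRS_HALF_SPAN_MS = 50.0


class DelineationError(Exception):
    """Raised when a recording cannot be delineated."""


def _round_half_up(x: float) -> int:
    # ms -> samples rounding: nearest integer, ties away from zero upward
    return int(np.floor(x + 0.5))


@dataclass
class Tachogram:
    """Beat-to-beat RR series with ectopic flags.

    ``rr_ms[i]`` is the interval ending at beat time ``t_s[i]`` (seconds,
    strictly increasing).  ``ectopic`` marks beats excluded from averages.
    """

    rr_ms: np.ndarray
    t_s: np.ndarray
    ectopic: np.ndarray = None  # type: ignore[assignment]
    fs: float | None = None

    def __post_init__(self) -> None:
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if self.ectopic is None:
            self.ectopic = np.zeros(self.rr_ms.size, dtype=bool)
        self.ectopic = np.asarray(self.ectopic, dtype=bool)
        if not (self.rr_ms.size == self.t_s.size == self.ectopic.size):
            raise ValueError("rr_ms, t_s and ectopic must have equal length")
        if np.any(self.rr_ms <= 0):
            raise ValueError("all RR intervals must be positive")
        if self.t_s.size > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.rr_ms.size)

    @property
    def valid_rr(self) -> np.ndarray:
        return self.rr_ms[~self.ectopic]

    @property
    def ectopic_fraction(self) -> float:
        return float(self.ectopic.mean()) if self.n_beats else 0.0


@dataclass
class BeatAnnotations:
    """Per-beat fiducials in samples; invalid beats carry ``valid=False``.

    For valid beats: qrs_onset < r_index < qrs_offset < t_onset < t_end and
    t_end does not reach the next beat's R-peak.
    """

    r_index: np.ndarray
    qrs_onset: np.ndarray
    qrs_offset: np.ndarray
    t_onset: np.ndarray
    t_end: np.ndarray
    valid: np.ndarray
    ectopic: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    @property
    def n_beats(self) -> int:
        return int(self.r_index.size)

    def to_frame(self, tach: "Tachogram | None" = None):
        """Annotations as a DataFrame (columns match the CSV export:
        beat, r_sample, qrs_on, qrs_off, t_on, t_end, rr_ms, ectopic, valid)."""
        import numpy as np
        import pandas as pd

        rr = np.full(self.n_beats, np.nan)
        if tach is not None:
            if self.meta.get("rr_mode", "preceding") == "preceding":
                rr[1:] = tach.rr_ms
            else:
                rr[:-1] = tach.rr_ms
        return pd.DataFrame(
            {
                "beat": np.arange(self.n_beats),
                "r_sample": self.r_index,
                "qrs_on": self.qrs_onset,
                "qrs_off": self.qrs_offset,
                "t_on": self.t_onset,
                "t_end": self.t_end,
                "rr_ms": rr,
                "ectopic": self.ectopic,
                "valid": self.valid,
            }
        )


def detect_r_peaks(vcg: VCGSignal) -> np.ndarray:
    """Detect R-peak sample indices on the vector magnitude.

    Returns strictly increasing indices at local maxima of |V| with an
    enforced refractory of 250 ms.  Raises ``DelineationError`` for a flat
    signal, short signal, or fewer than 5 detected beats.
    """
    fs = vcg.fs
    if vcg.n_samples < 10 * fs:
        raise DelineationError("need at least 10 s of signal for beat detection")
    mag = vcg.magnitude()
    if np.max(mag) <= 0:
        raise DelineationError("no beats: flat zero signal")
    energy = mag**2
    width = max(1, int(round(ENERGY_SMOOTH_S * fs)))
    energy = ndimage.uniform_filter1d(energy, size=width, mode="nearest")
    roll = max(1, int(round(ROLLING_MAX_S * fs)))
    threshold = THRESHOLD_FRACTION * ndimage.maximum_filter1d(
        energy, size=roll, mode="nearest"
    )
    peaks, _ = sps.find_peaks(
        energy, height=threshold, distance=max(1, int(round(REFRACTORY_S * fs)))
    )
    if peaks.size < 5:
        raise DelineationError(f"no beats: only {peaks.size} peaks found")
    # refine each peak to the local maximum of |V| in a small neighbourhood
    half = max(1, int(round(0.02 * fs)))
    refined = np.empty_like(peaks)
    for i, pk in enumerate(peaks):
        lo, hi = max(0, pk - half), min(len(mag), pk + half + 1)
        refined[i] = lo + int(np.argmax(mag[lo:hi]))
    refined = np.unique(refined)
    keep = [int(refined[0])]
    for r in refined[1:]:
        if r - keep[-1] >= REFRACTORY_S * fs:
            keep.append(int(r))
    return np.asarray(keep, dtype=np.intp)


def build_tachogram(r_indices: np.ndarray, fs: float) -> Tachogram:
    """RR series (ms) from R-peak sample indices; t is the later peak time."""
    r = np.asarray(r_indices, dtype=np.intp)
    if r.size < 2:
        raise DelineationError("need at least 2 R-peaks for a tachogram")
    rr = np.diff(r) * 1000.0 / fs
    t = r[1:] / fs
    return Tachogram(rr_ms=rr, t_s=t, fs=fs)


def flag_ectopic(tach: Tachogram, threshold: float = ECTOPIC_THRESHOLD) -> Tachogram:
    """Sequential 20 % rule; idempotent; first interval accepted by definition.

    Beat i is flagged when |rr_i - rr_ref| / rr_ref > threshold, with
    rr_ref the most recent unflagged RR (flagged beats never update it);
    equality at the threshold keeps the beat (strict inequality).
    """
    rr = tach.rr_ms
    flags = np.zeros(rr.size, dtype=bool)
    ref = rr[0]
    for i in range(1, rr.size):
        if abs(rr[i] - ref) / ref > threshold:
            flags[i] = True
        else:
            ref = rr[i]
    if flags.mean() > 0.20:
        log.warning("quality: %.0f%% of beats flagged ectopic", 100 * flags.mean())
    return replace(tach, ectopic=flags)


def assign_twave_windows(
    r_indices: np.ndarray,
    tach: Tachogram,
    fs: float,
    n_samples: int,
    rr_mode: str = "preceding",
    qrs_mark: str = "r_peak",
) -> BeatAnnotations:
    """QRS-anchored T-wave windows for each beat.

    ``rr_mode`` selects which interval is "RR of beat i": ``"preceding"``
    (default; the first beat has none and is invalid) or ``"following"``
    (the last beat is invalid).  ``qrs_mark`` is the anchor of the window
    rule; only ``"r_peak"`` is implemented (onset-based marks shift both
    window edges by a constant and change no angle).
    """
    if rr_mode not in ("preceding", "following"):
        raise ValueError(f"unknown rr_mode {rr_mode!r}")
    if qrs_mark != "r_peak":
        raise ValueError(f"unknown qrs_mark {qrs_mark!r}")
    r = np.asarray(r_indices, dtype=np.intp)
    nb = r.size
    rr_of_beat = np.full(nb, np.nan)
    ect = np.zeros(nb, dtype=bool)
    if rr_mode == "preceding":
        rr_of_beat[1:] = tach.rr_ms
        ect[1:] = tach.ectopic
    else:
        rr_of_beat[:-1] = tach.rr_ms
        ect[:-1] = tach.ectopic

    qrs_half = _round_half_up(QRS_HALF_SPAN_MS * fs / 1000.0)
    ton_off = _round_half_up(TON_OFFSET_MS * fs / 1000.0)
    t_on = r + ton_off
    t_end = np.full(nb, -1, dtype=np.intp)
    valid = np.zeros(nb, dtype=bool)
    for i in range(nb):
        if not np.isfinite(rr_of_beat[i]):
            continue
        tend_ms = min(TEND_CAP_MS, TEND_RR_FRACTION * rr_of_beat[i])
        t_end[i] = r[i] + _round_half_up(tend_ms * fs / 1000.0)
        inside = t_end[i] <= n_samples - 1
        clear_of_next = i == nb - 1 or t_end[i] <= r[i + 1]
        valid[i] = inside and clear_of_next and t_on[i] < t_end[i]
    return BeatAnnotations(
        r_index=r,
        qrs_onset=r - qrs_half,
        qrs_offset=r + qrs_half,
        t_onset=t_on,
        t_end=t_end,
        valid=valid,
        ectopic=ect,
        fs=fs,
        meta={"rr_mode": rr_mode, "qrs_mark": qrs_mark},
    )


def delineate(
    vcg: VCGSignal,
    ectopic_threshold: float = ECTOPIC_THRESHOLD,
    rr_mode: str = "preceding",
) -> tuple[BeatAnnotations, Tachogram]:
    """Full chain: R-peaks -> tachogram -> ectopic flags -> T windows."""
    r = detect_r_peaks(vcg)
    tach = flag_ectopic(build_tachogram(r, vcg.fs), threshold=ectopic_threshold)
    ann = assign_twave_windows(r, tach, vcg.fs, vcg.n_samples, rr_mode=rr_mode)
    return ann, tach
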