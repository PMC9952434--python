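"""Multi-lead ECG container, CSV I/O, and preprocessing.

The recording model is the Wilson tetrahedron: four electrodes on the right
arm (v_r), left arm (v_l), left leg (v_f) and back (v_b), sampled at a
common rate, voltages in microvolts.  Preprocessing follows the standard
chain for this lead system: zero-phase 2–26 Hz band-pass, robust isoline
offset removal, and re-referencing to the common average of the four
channels.  Only lead *differences* enter the vectorcardiographic transform,
so the common-average step cannot change downstream results — it is kept
for signal-inspection parity.

CSV dialect: header ``t,v_r,v_l,v_f,v_b``, comma-separated, voltages in µV,
time in seconds, UTF-8, ``.`` decimal.  The sampling rate may be given
explicitly or inferred from the ``t`` column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "CHANNELS",
    "MultiLeadECG",
    "FilterSpec",
    "SignalIOError",
    "MissingChannelError",
    "ShortRecordingError",
    "read_recording",
    "write_recording",
    "zero_phase_bandpass",
    "remove_isoline_offset",
    "common_average_rereference",
    "preprocess",
]

log = logging.getLogger(__name__)

CHANNELS = ("v_r", "v_l", "v_f", "v_b")

MIN_DURATION_S = 10.0


class SignalIOError(Exception):
    """Base error for recording I/O and preprocessing."""


class MissingChannelError(SignalIOError):
    """A required electrode column is absent from the file."""


class ShortRecordingError(SignalIOError):
    """Recording shorter than the minimum analyzable duration."""


@dataclass
class MultiLeadECG:
    """Four synchronous electrode voltage series (µV) at sampling rate fs.

    ``quality`` holds per-channel diagnostics (non-finite fraction, RMS)
    filled in by :func:`read_recording`; ``bad_samples`` marks rows that
    contained non-finite values before interpolation.
    """

    v_r: np.ndarray
    v_l: np.ndarray
    v_f: np.ndarray
    v_b: np.ndarray
    fs: float
    t0: float = 0.0
    quality: dict = field(default_factory=dict)
    bad_samples: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.v_r)
        for ch in CHANNELS[1:]:
            if len(getattr(self, ch)) != n:
                raise SignalIOError("channel length mismatch")
        if self.fs <= 0:
            raise SignalIOError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return len(self.v_r)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def stack(self) -> np.ndarray:
        """Channels as an (n, 4) array in (v_r, v_l, v_f, v_b) order."""
        return np.column_stack([getattr(self, ch) for ch in CHANNELS])

    def with_channels(self, arr: np.ndarray) -> "MultiLeadECG":
        return replace(
            self,
            v_r=arr[:, 0].copy(),
            v_l=arr[:, 1].copy(),
            v_f=arr[:, 2].copy(),
            v_b=arr[:, 3].copy(),
        )


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase Butterworth band-pass, defaults 2–26 Hz, order 4.

    Applied forward-backward, so the effective magnitude response is the
    squared 4th-order response (8 poles) with exactly zero phase shift.
    ``gain`` is a documented scale factor, unit by default (the recordings
    are analysed at scale 1).
    """

    low_cut: float = 2.0
    high_cut: float = 26.0
    order: int = 4
    gain: float = 1.0

    def validate(self, fs: float) -> None:
        if not 0 < self.low_cut < self.high_cut < fs / 2:
            raise SignalIOError(
                f"need 0 < low_cut < high_cut < fs/2; got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}"
            )


def read_recording(
    path: str | Path,
    fs: float | None = None,
    columns: dict[str, str] | None = None,
) -> MultiLeadECG:
    """Load a 4-electrode CSV recording.

    Parameters
    ----------
    path
        CSV file with header; must contain the four electrode columns.
    fs
        Sampling rate in Hz; if omitted, inferred from the ``t`` column.
    columns
        Optional mapping from canonical names (``v_r`` …) to the file's
        column names, so column order and naming in the file are free.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"recording not found: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    colmap = {ch: ch for ch in CHANNELS}
    if columns:
        colmap.update(columns)
    for ch, name in colmap.items():
        if name not in df.columns:
            raise MissingChannelError(
                f"column {name!r} (electrode {ch}) missing from {path.name}"
            )
    if fs is None:
        if "t" not in df.columns:
            raise SignalIOError("no sampling rate given and no 't' column to infer it")
        dt = np.median(np.diff(df["t"].to_numpy(dtype=float)))
        if dt <= 0:
            raise SignalIOError("non-increasing 't' column")
        fs = 1.0 / dt
    if fs <= 0:
        raise SignalIOError(f"sampling rate must be positive, got {fs}")

    arr = np.column_stack([df[colmap[ch]].to_numpy(dtype=float) for ch in CHANNELS])
    if arr.shape[0] < MIN_DURATION_S * fs:
        raise ShortRecordingError(
            f"{path.name}: {arr.shape[0] / fs:.1f} s < required {MIN_DURATION_S:.0f} s"
        )
    bad = ~np.isfinite(arr).all(axis=1)
    if bad.any():
        # bridge non-finite rows channel-wise so downstream filters see
        # finite data; the rows stay flagged in bad_samples
        idx = np.arange(arr.shape[0])
        for j in range(arr.shape[1]):
            col = arr[:, j]
            m = np.isfinite(col)
            arr[:, j] = np.interp(idx, idx[m], col[m])
    quality = {
        ch: {
            "nonfinite_frac": float(bad.mean()),
            "rms_uv": float(np.sqrt(np.mean(arr[:, j] ** 2))),
        }
        for j, ch in enumerate(CHANNELS)
    }
    for ch, q in quality.items():
        log.info("channel %s: rms %.1f µV, non-finite fraction %.4f",
                 ch, q["rms_uv"], q["nonfinite_frac"])
    t0 = float(df["t"].iloc[0]) if "t" in df.columns else 0.0
    ecg = MultiLeadECG(
        v_r=arr[:, 0], v_l=arr[:, 1], v_f=arr[:, 2], v_b=arr[:, 3],
        fs=float(fs), t0=t0, quality=quality, bad_samples=bad,
    )
    return ecg


def write_recording(ecg: MultiLeadECG, path: str | Path) -> Path:
    """Write the CSV dialect (``t,v_r,v_l,v_f,v_b``); round-trip exact."""
    path = Path(path)
    arr = np.column_stack([ecg.t, ecg.stack()])
    np.savetxt(
        path, arr, fmt="%.17g", delimiter=",",
        header="t," + ",".join(CHANNELS), comments="",
    )
    return path


def _impulse_span_samples(spec: FilterSpec, fs: float) -> int:
    # dominant transient of the band-pass is set by the low cutoff
    return int(round(3 * fs / spec.low_cut))


def zero_phase_bandpass(ecg: MultiLeadECG, spec: FilterSpec | None = None) -> MultiLeadECG:
    """Forward-backward Butterworth band-pass; net phase shift is zero.

    Edges are reflect-padded over three low-cut time constants so the
    transient of the IIR filter does not leak into the analysed span.
    DC and baseline wander fall in the stopband and are removed.
    """
    spec = spec or FilterSpec()
    spec.validate(ecg.fs)
    span = _impulse_span_samples(spec, ecg.fs)
    if ecg.n_samples <= span:
        raise ShortRecordingError(
            f"signal of {ecg.n_samples} samples shorter than "
            f"filter transient span ({span} samples)"
        )
    sos = sps.butter(
        spec.order, [spec.low_cut, spec.high_cut], btype="bandpass",
        fs=ecg.fs, output="sos",
    )
    arr = ecg.stack()
    padlen = min(span, ecg.n_samples - 1)
    out = sps.sosfiltfilt(sos, arr, axis=0, padtype="even", padlen=padlen)
    return ecg.with_channels(out * spec.gain)


def remove_isoline_offset(ecg: MultiLeadECG) -> MultiLeadECG:
    """Subtract the per-channel median (robust isoline estimate).

    After band-pass filtering the residual offset is small; the median is
    insensitive to QRS outliers, so each output channel has median ~0.
    """
    arr = ecg.stack()
    offsets = np.median(arr, axis=0)
    for ch, off in zip(CHANNELS, offsets):
        log.debug("isoline offset %s: %.2f µV", ch, off)
    return ecg.with_channels(arr - offsets)


def common_average_rereference(ecg: MultiLeadECG) -> MultiLeadECG:
    """Subtract the per-sample mean of the four channels from each channel.

    Lead differences are exactly invariant under this step, so the
    vectorcardiographic transform does not depend on the reference choice.
    """
    arr = ecg.stack()
    return ecg.with_channels(arr - arr.mean(axis=1, keepdims=True))


def preprocess(ecg: MultiLeadECG, spec: FilterSpec | None = None) -> MultiLeadECG:
    """Band-pass -> isoline removal -> common-average re-reference."""
    return common_average_rereference(
        remove_isoline_offset(zero_phase_bandpass(ecg, spec))
    )
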