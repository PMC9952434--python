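"""Phase-rectified signal averaging (PRSA) over beat-indexed series.

PRSA isolates quasi-periodic oscillations from a nonstationary series by
selecting "anchor" beats with a predicate, cutting a window of 2L samples
around each anchor, and averaging the aligned windows.  Two scalars are
derived here:

* deceleration capacity (DC) of heart rate — anchors are RR intervals longer
  than their predecessor; DC = (X0 + X1 - X-1 - X-2) / 4 over the averaged
  curve, in ms.  Indexes vagal modulation of the sinus node.
* periodic repolarization dynamics (PRD) — anchors on the beat-to-beat
  T-wave-vector angle series selected by comparing M-beat forward/backward
  averages; PRD = max(curve) - min(curve), in degrees.  Indexes
  low-frequency sympathetic modulation of ventricular repolarization.

The window index convention is k = -L .. L-1 with the anchor at k = 0, so
the point X1 immediately after the anchor exists for every L >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PRSAConfig",
    "PRSAResult",
    "find_anchors_increment",
    "find_anchors_averaged",
    "prsa_average",
    "deceleration_capacity",
    "acceleration_capacity",
    "prd_from_curve",
    "dc_from_series",
    "prd_from_series",
]

#: default half-window for deceleration capacity (beats)
DC_HALF_WINDOW = 12
#: default half-window for periodic repolarization dynamics (beats)
PRD_HALF_WINDOW = 20
#: default averaging span of the PRD anchor predicate (beats)
PRD_ANCHOR_SPAN = 9


@dataclass(frozen=True)
class PRSAConfig:
    """Parameters of a PRSA run.

    half_window
        L, the number of beats kept on each side of an anchor; the averaged
        curve has 2L points.  Defaults: 12 for DC, 20 for PRD — the minimum
        values resolving the 0.04–0.15 Hz and 0.025–0.1 Hz bands of
        interest at typical heart rates.
    anchor_mode
        ``"increment"`` (value strictly greater than its predecessor) or
        ``"averaged"`` (forward M-mean strictly greater than backward
        M-mean).
    span
        M, the averaging span of the ``"averaged"`` predicate.
    """

    half_window: int = DC_HALF_WINDOW
    anchor_mode: str = "increment"
    span: int = PRD_ANCHOR_SPAN

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError(f"half_window must be >= 1, got {self.half_window}")
        if self.span < 1:
            raise ValueError(f"span must be >= 1, got {self.span}")
        if self.anchor_mode not in ("increment", "averaged"):
            raise ValueError(f"unknown anchor_mode {self.anchor_mode!r}")


@dataclass
class PRSAResult:
    """Averaged PRSA window and the scalar derived from it.

    ``curve[j]`` is the mean over anchors a of ``series[a + k]`` with
    k = j - L, so the anchor sits at index L.  ``scalar`` is DC (ms) or PRD
    (degrees) depending on the deriving function; it is NaN when no anchor
    was found (``defined`` False).
    """

    curve: np.ndarray
    half_window: int
    anchor_indices: np.ndarray
    scalar: float = float("nan")
    scalar_name: str = ""
    central: dict = field(default_factory=dict)

    @property
    def anchor_count(self) -> int:
        return int(len(self.anchor_indices))

    @property
    def defined(self) -> bool:
        return self.anchor_count >= 1

    def to_frame(self):
        """Curve as a DataFrame (columns k, value, n_anchors) for export."""
        import pandas as pd

        L = self.half_window
        return pd.DataFrame(
            {
                "k": range(-L, L),
                "value": self.curve,
                "n_anchors": self.anchor_count,
            }
        )

    def value_at(self, k: int) -> float:
        """Curve value at signed window index k in [-L, L-1]."""
        L = self.half_window
        if not -L <= k <= L - 1:
            raise IndexError(f"k={k} outside window [-{L}, {L - 1}]")
        return float(self.curve[L + k])


def _eligible(n: int, idx: np.ndarray, L: int) -> np.ndarray:
    """Keep anchors whose full 2L window [i-L, i+L-1] fits in the series.

    Edge exclusion is applied at both ends: a window is two-sided, so
    anchors in the first L samples are as undefined as those in the last L.
    """
    return idx[(idx >= L) & (idx + L - 1 <= n - 1)]


def _drop_flagged_windows(
    idx: np.ndarray, L: int, exclude: np.ndarray | None
) -> np.ndarray:
    """Discard anchors whose window contains an excluded (ectopic) beat."""
    if exclude is None or not np.any(exclude):
        return idx
    bad = np.flatnonzero(np.asarray(exclude, dtype=bool))
    keep = [
        i for i in idx if not np.any((bad >= i - L) & (bad <= i + L - 1))
    ]
    return np.asarray(keep, dtype=np.intp)


def find_anchors_increment(
    series: np.ndarray,
    half_window: int,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Anchors where the value strictly exceeds its predecessor.

    This is the deceleration predicate on an RR series: the interval is
    longer than the preceding one.  Ties are not anchors.  Anchors whose 2L
    window leaves the series, or whose window contains a beat flagged in
    ``exclude``, are discarded.  The returned index array may be empty.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to find increment anchors")
    idx = np.flatnonzero(x[1:] > x[:-1]) + 1
    idx = _eligible(x.size, idx, half_window)
    return _drop_flagged_windows(idx, half_window, exclude)


def find_anchors_averaged(
    series: np.ndarray,
    span: int,
    half_window: int,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Anchors where the forward M-mean strictly exceeds the backward M-mean.

    Beat i is an anchor when mean(x[i .. i+M-1]) > mean(x[i-M .. i-1])
    (the candidate itself belongs to the forward average).  Used for PRD,
    where the single-increment rule would be dominated by beat-to-beat
    noise of the angle series.
    """
    x = np.asarray(series, dtype=float)
    M = int(span)
    if x.size < 2 * M + 1:
        raise ValueError(
            f"series of length {x.size} too short for averaged anchors with M={M}"
        )
    c = np.concatenate(([0.0], np.cumsum(x)))
    i = np.arange(M, x.size - M + 1)
    fwd = (c[i + M] - c[i]) / M       # mean of x[i .. i+M-1]
    bwd = (c[i] - c[i - M]) / M       # mean of x[i-M .. i-1]
    idx = i[fwd > bwd]
    idx = _eligible(x.size, idx, half_window)
    return _drop_flagged_windows(idx, half_window, exclude)


def prsa_average(
    series: np.ndarray, anchors: np.ndarray, half_window: int
) -> PRSAResult:
    """Average the 2L windows around the anchors.

    Every curve point is the arithmetic mean over exactly ``anchor_count``
    aligned samples.  With zero anchors the curve is all-NaN and the result
    reports ``defined`` False.
    """
    x = np.asarray(series, dtype=float)
    L = int(half_window)
    a = np.asarray(anchors, dtype=np.intp)
    if a.size and (a.min() < L or a.max() + L - 1 > x.size - 1):
        raise ValueError("anchor without a full 2L window in the series")
    if a.size == 0:
        curve = np.full(2 * L, np.nan)
    else:
        ks = np.arange(-L, L)
        curve = x[a[:, None] + ks[None, :]].mean(axis=0)
    return PRSAResult(curve=curve, half_window=L, anchor_indices=a)


def deceleration_capacity(result: PRSAResult) -> PRSAResult:
    """DC = (X0 + X1 - X-1 - X-2) / 4 from the central curve points (ms)."""
    if result.half_window < 2:
        raise ValueError("deceleration capacity needs half_window >= 2")
    result.scalar_name = "DC"
    if not result.defined:
        result.scalar = float("nan")
        return result
    x0, x1 = result.value_at(0), result.value_at(1)
    xm1, xm2 = result.value_at(-1), result.value_at(-2)
    result.central = {"X-2": xm2, "X-1": xm1, "X0": x0, "X1": x1}
    result.scalar = (x0 + x1 - xm1 - xm2) / 4.0
    return result


def prd_from_curve(result: PRSAResult) -> PRSAResult:
    """PRD = max(curve) - min(curve); non-negative whenever defined."""
    result.scalar_name = "PRD"
    result.scalar = (
        float(np.max(result.curve) - np.min(result.curve))
        if result.defined
        else float("nan")
    )
    return result


def dc_from_series(
    rr_ms: np.ndarray,
    half_window: int = DC_HALF_WINDOW,
    exclude: np.ndarray | None = None,
) -> PRSAResult:
    """Deceleration capacity of an RR series (ms), increment anchors."""
    anchors = find_anchors_increment(rr_ms, half_window, exclude=exclude)
    return deceleration_capacity(prsa_average(rr_ms, anchors, half_window))

def acceleration_capacity(
    rr_ms: np.ndarray,
    half_window: int = DC_HALF_WINDOW,
    exclude: np.ndarray | None = None,
) -> PRSAResult:
    # internal counterpart of DC (decrement anchors); used by symmetry tests
    x = np.asarray(rr_ms, dtype=float)
    idx = np.flatnonzero(x[1:] < x[:-1]) + 1
    idx = _drop_flagged_windows(_eligible(x.size, idx, half_window), half_window, exclude)
    res = deceleration_capacity(prsa_average(x, idx, half_window))
    res.scalar_name = "AC"
    return res


def prd_from_series(
    dtheta_deg: np.ndarray,
    half_window: int = PRD_HALF_WINDOW,
    span: int = PRD_ANCHOR_SPAN,
    exclude: np.ndarray | None = None,
) -> PRSAResult:
    """PRD of a (median-filtered) T-wave-angle series, averaged anchors."""
    anchors = find_anchors_averaged(dtheta_deg, span, half_window, exclude=exclude)
    return prd_from_curve(prsa_average(dtheta_deg, anchors, half_window))
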