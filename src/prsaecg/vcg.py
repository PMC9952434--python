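"""Wilson-tetrahedron surface potentials -> orthogonal vectorcardiogram.

The four-electrode Wilson tetrahedron (right arm, left arm, left leg, back)
determines the spatial heart vector up to a linear transform.  Axes follow
the anatomical convention: X right-to-left, Y head-to-foot, Z
front-to-back.  Per sample,

    (vpx, vpy, vpz) = (1/s) * M * (VL-VR, VF-VR, VB-VR)
    (px, py, pz)    = (vpx, vpy, vpz) / |vp|        (direction cosines)
    (Vx, Vy, Vz)    = 3 * K * (px, py, pz)

where K > 0 is a per-sample gain built from the Einthoven frontal-plane
magnitude E and the back potential.  The numeric coefficients live in a
versioned text file (``data/vcg_coefficients.txt``), never inline: the
transform is data, and every property here (unit-norm cosines, gain
invariance, sample locality, forward/inverse round trip) holds for any
fixed coefficient set.

Samples where all three lead differences vanish have no defined direction;
they are bridged by linear interpolation and counted, never silently
NaN-propagated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .signal_io import MultiLeadECG

__all__ = [
    "VCGCoefficients",
    "VCGSignal",
    "DipoleProjection",
    "load_coefficients",
    "lead_differences",
    "direction_cosines",
    "wilson_to_vcg",
    "TooManyUndefinedError",
]

log = logging.getLogger(__name__)


class TooManyUndefinedError(Exception):
    """More than half of the samples have no defined dipole direction."""


@dataclass(frozen=True)
class VCGCoefficients:
    """Numeric constants of the tetrahedron transform (see module docs)."""

    matrix: np.ndarray      # 3x3, already divided by matrix_scale
    k_scale: float
    k_e2: float
    k_vb2: float
    e2_div: float
    source: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("coefficient matrix must be 3x3")
        object.__setattr__(self, "matrix", m)


def load_coefficients(path: str | Path | None = None) -> VCGCoefficients:
    """Read the coefficient file (``key = value`` lines, ``#`` comments)."""
    if path is None:
        ref = resources.files("prsaecg").joinpath("data/vcg_coefficients.txt")
        text = ref.read_text(encoding="utf-8")
        source = "prsaecg/data/vcg_coefficients.txt"
    else:
        text = Path(path).read_text(encoding="utf-8")
        source = str(path)
    vals: dict[str, float] = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, raw = line.partition("=")
        vals[key.strip()] = float(raw)
    try:
        m = np.array(
            [
                [vals["m_xx"], vals["m_xy"], vals["m_xz"]],
                [vals["m_yx"], vals["m_yy"], vals["m_yz"]],
                [vals["m_zx"], vals["m_zy"], vals["m_zz"]],
            ]
        ) / vals["matrix_scale"]
        return VCGCoefficients(
            matrix=m,
            k_scale=vals["k_scale"],
            k_e2=vals["k_e2"],
            k_vb2=vals["k_vb2"],
            e2_div=vals["e2_div"],
            source=source,
        )
    except KeyError as exc:  # pragma: no cover - config authoring error
        raise ValueError(f"coefficient file {source} missing entry {exc}") from exc


@dataclass
class VCGSignal:
    """Orthogonal VCG components (µV) on the source time base."""

    v_x: np.ndarray
    v_y: np.ndarray
    v_z: np.ndarray
    fs: float

    @property
    def n_samples(self) -> int:
        return len(self.v_x)

    def stack(self) -> np.ndarray:
        """Components as an (n, 3) array."""
        return np.column_stack([self.v_x, self.v_y, self.v_z])

    def magnitude(self) -> np.ndarray:
        return np.sqrt(self.v_x**2 + self.v_y**2 + self.v_z**2)


@dataclass
class DipoleProjection:
    """Per-sample dipole direction cosines and gain.

    ``p`` is (n, 3) with unit rows wherever ``defined``; ``k_gain`` is K in
    µV, ``e_sq`` the squared frontal-plane magnitude E² in µV², and
    ``lead_diffs`` the (VL-VR, VF-VR, VB-VR) differences the transform
    consumed.
    """

    p: np.ndarray
    k_gain: np.ndarray
    e_sq: np.ndarray
    lead_diffs: np.ndarray
    defined: np.ndarray


def lead_differences(ecg: MultiLeadECG) -> np.ndarray:
    """(VL-VR, VF-VR, VB-VR) as an (n, 3) array; reference-free."""
    return np.column_stack(
        [ecg.v_l - ecg.v_r, ecg.v_f - ecg.v_r, ecg.v_b - ecg.v_r]
    )


def direction_cosines(
    diffs: np.ndarray, coeffs: VCGCoefficients | None = None
) -> DipoleProjection:
    """Unnormalized projection and unit direction cosines per sample.

    Samples whose lead differences are all zero are marked undefined
    (``p`` rows NaN there) and counted in the log; they are bridged later
    by :func:`wilson_to_vcg`.
    """
    coeffs = coeffs or load_coefficients()
    d = np.asarray(diffs, dtype=float)
    vp = d @ coeffs.matrix.T
    norm = np.linalg.norm(vp, axis=1)
    defined = norm > 0
    p = np.full_like(vp, np.nan)
    p[defined] = vp[defined] / norm[defined, None]
    n_undef = int((~defined).sum())
    if n_undef:
        log.info("direction cosines undefined at %d samples", n_undef)
    e_sq = d[:, 0] ** 2 + (d[:, 1] + (d[:, 1] - d[:, 0])) ** 2 / coeffs.e2_div
    return DipoleProjection(
        p=p, k_gain=np.zeros(len(d)), e_sq=e_sq, lead_diffs=d, defined=defined
    )


def wilson_to_vcg(
    ecg: MultiLeadECG, coeffs: VCGCoefficients | None = None
) -> tuple[VCGSignal, DipoleProjection]:
    """Full transform: leads -> (Vx, Vy, Vz) = 3*K*(px, py, pz).

    K = (1/k_scale)*sqrt(k_e2*E² + k_vb2*VB²) per sample, so the vector
    magnitude equals 3K wherever the direction is defined.  Undefined
    samples (zero differences) are linearly interpolated component-wise and
    flagged; above 5 % a warning is logged, above 50 % the transform
    refuses.
    """
    coeffs = coeffs or load_coefficients()
    proj = direction_cosines(lead_differences(ecg), coeffs)
    proj.k_gain = (
        np.sqrt(coeffs.k_e2 * proj.e_sq + coeffs.k_vb2 * np.asarray(ecg.v_b) ** 2)
        / coeffs.k_scale
    )
    v = 3.0 * proj.k_gain[:, None] * proj.p
    frac_undef = 1.0 - proj.defined.mean()
    if frac_undef > 0.5:
        raise TooManyUndefinedError(
            f"{frac_undef:.0%} of samples have undefined dipole direction"
        )
    if frac_undef > 0.05:
        log.warning("dipole direction undefined at %.1f%% of samples",
                    100 * frac_undef)
    if frac_undef > 0:
        idx = np.arange(len(v))
        ok = proj.defined
        if ok.sum() == 0:  # pragma: no cover - guarded by the 50 % check
            raise TooManyUndefinedError("no defined samples")
        for j in range(3):
            v[~ok, j] = np.interp(idx[~ok], idx[ok], v[ok, j])
    return VCGSignal(v_x=v[:, 0], v_y=v[:, 1], v_z=v[:, 2], fs=ecg.fs), proj
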