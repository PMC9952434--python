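"""Synthetic multi-lead ECG with known autonomic structure.

Every downstream stage of the pipeline is exercised against recordings
whose truth is known exactly: the RR series carries prescribed LF
(0.04–0.15 Hz) and HF (0.15–0.4 Hz) sinusoidal modulation plus white
beat-to-beat jitter and optional ectopic beats (early beat followed by a
compensatory pause); the vectorcardiogram is built from Gaussian P/QRS/T
templates placed at the beat times; and the spatial T-wave vector of beat
i is the base direction rigidly rotated by

    theta_i = twave_osc_amp * sin(2*pi*twave_osc_freq * t_i + phase)

about a fixed axis orthogonal to the base direction, so the ground-truth
angle between consecutive T vectors is exactly |theta_{i+1} - theta_i| and
T amplitude is untouched — the angle signal PRD measures is isolated from
amplitude effects.

Default parameters emulate the resting cohort the pipeline targets: mean
RR 800 ms, LF and HF modulation amplitudes of 38 ms (band powers ≈ 725
ms²), a 0.05 Hz T-vector oscillation, and 250 Hz sampling.  The surface
leads are produced by inverting the same tetrahedron transform the
analysis applies, so forward/inverse consistency is testable to machine
precision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .delineation import Tachogram
from .signal_io import CHANNELS, MultiLeadECG, write_recording
from .vcg import VCGCoefficients, VCGSignal, load_coefficients

__all__ = [
    "TachogramSpec",
    "MorphologySpec",
    "CohortSpec",
    "GroundTruth",
    "generate_tachogram",
    "generate_vcg",
    "project_to_wilson",
    "generate_recording",
    "generate_cohort",
    "write_cohort",
    "default_rest_specs",
    "default_stress_specs",
]

MIN_RR_MS = 200.0


@dataclass(frozen=True)
class TachogramSpec:
    """Parameters of the simulated RR series.

    Amplitudes in ms, frequencies in Hz; ``jitter_sd`` is white
    beat-to-beat noise; ``ectopic_rate`` is the per-beat probability of an
    inserted early-beat/compensatory-pause pair.
    """

    mean_rr: float = 800.0
    lf_amp: float = 38.0
    lf_freq: float = 0.1
    hf_amp: float = 38.0
    hf_freq: float = 0.25
    lf_phase: float = 0.0
    hf_phase: float = 0.0
    jitter_sd: float = 10.0
    ectopic_rate: float = 0.0
    duration_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.jitter_sd < 0:
            raise ValueError("amplitudes must be non-negative")
        if not self.lf_freq < self.hf_freq:
            raise ValueError("lf_freq must be below hf_freq")
        if not 0 <= self.ectopic_rate < 1:
            raise ValueError("ectopic_rate must be in [0, 1)")
        if self.mean_rr - self.lf_amp - self.hf_amp <= MIN_RR_MS:
            raise ValueError(
                "spec can produce RR at or below the physiological floor "
                f"({MIN_RR_MS:.0f} ms): mean_rr - lf_amp - hf_amp = "
                f"{self.mean_rr - self.lf_amp - self.hf_amp:.0f} ms"
            )


@dataclass(frozen=True)
class MorphologySpec:
    """Beat-template and noise parameters of the simulated VCG.

    Templates are Gaussians per axis: the QRS is a triphasic Q/R/S lobe
    train along ``qrs_amp`` (µV per axis), the P and T waves are single
    lobes of amplitude ``p_amp_uv`` / ``t_amp_uv`` along unit direction
    vectors.  Widths are Gaussian sigmas in ms, centers are offsets from
    the R peak in ms.  ``twave_osc_amp_deg`` rotates the T direction
    rigidly beat by beat (see module docstring).  ``baseline_offset_uv``
    and ``baseline_wander_amp_uv`` / ``noise_sd_uv`` act on the surface
    leads, not on the VCG.
    """

    fs: float = 250.0
    qrs_amp: tuple[float, float, float] = (867.0, 488.0, -106.0)
    qrs_width_ms: float = 12.0
    t_amp_uv: float = 500.0
    t_dir: tuple[float, float, float] = (0.8, 0.45, -0.3)
    t_width_ms: float = 50.0
    t_center_ms: float = 220.0
    p_amp_uv: float = 40.0
    p_dir: tuple[float, float, float] = (0.7, 0.6, -0.2)
    p_width_ms: float = 25.0
    p_center_ms: float = -160.0
    twave_osc_amp_deg: float = 6.0
    twave_osc_freq_hz: float = 0.05
    twave_osc_phase: float = 0.0
    noise_sd_uv: float = 2.0
    baseline_offset_uv: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    baseline_wander_amp_uv: float = 50.0
    baseline_wander_freq_hz: float = 0.3

    def __post_init__(self) -> None:
        if self.twave_osc_amp_deg < 0:
            raise ValueError("twave_osc_amp_deg must be non-negative")
        min_width = min(self.qrs_width_ms, self.t_width_ms, self.p_width_ms)
        if min_width <= 0:
            raise ValueError("template widths must be positive")
        # Gaussian of sigma w ms has negligible content above ~3/(2*pi*w);
        # require fs above twice that
        if self.fs <= 2 * 3000.0 / (2 * np.pi * min_width):
            raise ValueError(
                f"fs={self.fs} Hz under-samples templates of width {min_width} ms"
            )
        if np.linalg.norm(self.t_dir) == 0 or np.linalg.norm(self.p_dir) == 0:
            raise ValueError("wave direction vectors must be non-zero")

    def unit_t_dir(self) -> np.ndarray:
        d = np.asarray(self.t_dir, dtype=float)
        return d / np.linalg.norm(d)

    def unit_p_dir(self) -> np.ndarray:
        d = np.asarray(self.p_dir, dtype=float)
        return d / np.linalg.norm(d)


@dataclass(frozen=True)
class CohortSpec:
    """Paired rest/stress cohort; per-subject seeds derive from master_seed."""

    n_subjects: int = 17
    rest_tachogram: TachogramSpec = field(default_factory=TachogramSpec)
    rest_morphology: MorphologySpec = field(default_factory=MorphologySpec)
    stress_tachogram: TachogramSpec = field(default_factory=TachogramSpec)
    stress_morphology: MorphologySpec = field(
        default_factory=lambda: MorphologySpec(twave_osc_amp_deg=12.0)
    )
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


@dataclass
class GroundTruth:
    """Machine-readable truth carried with every generated recording."""

    r_indices: np.ndarray          # R-peak sample index per beat
    r_times_s: np.ndarray          # R-peak time per beat
    rr_ms: np.ndarray              # interval ending at beat i >= 1
    ectopic_beats: np.ndarray      # bool per beat (beat-level)
    theta_deg: np.ndarray          # T-vector rotation angle per beat
    t_dirs: np.ndarray             # (n_beats, 3) unit T directions
    dtheta_deg: np.ndarray         # |theta_{i+1}-theta_i| per pair
    params: dict = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "r_indices": self.r_indices.tolist(),
            "r_times_s": self.r_times_s.tolist(),
            "rr_ms": self.rr_ms.tolist(),
            "ectopic_beats": self.ectopic_beats.tolist(),
            "theta_deg": self.theta_deg.tolist(),
            "t_dirs": self.t_dirs.tolist(),
            "dtheta_deg": self.dtheta_deg.tolist(),
            "params": self.params,
        }


def generate_tachogram(spec: TachogramSpec) -> tuple[Tachogram, GroundTruth]:
    """Simulate the RR series.

    rr_i = mean_rr + lf_amp*sin(2*pi*lf_freq*t) + hf_amp*sin(2*pi*hf_freq*t
    + hf_phase) + N(0, jitter_sd), evaluated at the cumulative time of the
    preceding beat; beats are appended while the series stays inside
    ``duration_s``.  Ectopic pairs shorten one interval by 30–50 % and add
    the deficit to the next (compensatory pause), preserving cumulative
    time.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    rr: list[float] = []
    t = 0.0
    while True:
        val = (
            spec.mean_rr
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * t + spec.lf_phase)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * t + spec.hf_phase)
        )
        if spec.jitter_sd > 0:
            val += rng.normal(0.0, spec.jitter_sd)
        if t + val / 1000.0 > spec.duration_s:
            break
        rr.append(val)
        t += val / 1000.0
    rr_arr = np.asarray(rr)
    n = rr_arr.size
    flags = np.zeros(n, dtype=bool)
    if spec.ectopic_rate > 0 and n >= 3:
        draws = rng.random(n) < spec.ectopic_rate
        fracs = rng.uniform(0.3, 0.5, size=n)
        for i in range(1, n - 1):
            if not draws[i] or flags[i - 1] or flags[i]:
                continue
            delta = rr_arr[i] * fracs[i]
            rr_arr[i] -= delta
            rr_arr[i + 1] += delta
            flags[i] = flags[i + 1] = True
    if np.any(rr_arr <= MIN_RR_MS):
        raise ValueError(
            f"generated RR fell to {rr_arr.min():.0f} ms "
            f"(<= {MIN_RR_MS:.0f} ms floor); spec rejected"
        )
    t_s = np.cumsum(rr_arr) / 1000.0
    tach = Tachogram(rr_ms=rr_arr, t_s=t_s, ectopic=flags)
    truth = GroundTruth(
        r_indices=np.array([], dtype=np.intp),
        r_times_s=t_s.copy(),
        rr_ms=rr_arr.copy(),
        ectopic_beats=flags.copy(),
        theta_deg=np.array([]),
        t_dirs=np.empty((0, 3)),
        dtheta_deg=np.array([]),
        params={"tachogram_spec": asdict(spec)},
    )
    return tach, truth


def _orthogonal_axis(base: np.ndarray) -> np.ndarray:
    """A fixed unit axis orthogonal to ``base`` (Gram-Schmidt vs z then x)."""
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])):
        a = ref - np.dot(ref, base) * base
        if np.linalg.norm(a) > 1e-6:
            return a / np.linalg.norm(a)
    raise ValueError("degenerate base direction")  # pragma: no cover


def _add_lobe(
    v: np.ndarray, fs: float, center_s: float, sigma_ms: float, amp_vec: np.ndarray
) -> None:
    """Accumulate a Gaussian lobe into the (n, 3) signal, clipped at edges."""
    sigma_s = sigma_ms / 1000.0
    lo = max(0, int(np.floor((center_s - 5 * sigma_s) * fs)))
    hi = min(v.shape[0], int(np.ceil((center_s + 5 * sigma_s) * fs)) + 1)
    if hi <= lo:
        return
    tt = np.arange(lo, hi) / fs
    g = np.exp(-((tt - center_s) ** 2) / (2 * sigma_s**2))
    v[lo:hi] += g[:, None] * amp_vec[None, :]


def generate_vcg(
    tach: Tachogram, morph: MorphologySpec, truth: GroundTruth | None = None
) -> tuple[VCGSignal, GroundTruth]:
    """Continuous (Vx, Vy, Vz) from P/QRS/T templates at the beat times.

    Noise-free and deterministic: channel noise and baseline effects belong
    to the surface leads (:func:`project_to_wilson`).  Returns the signal
    and the ground truth extended with fiducials and per-beat T-vector
    rotation angles.
    """
    if tach.n_beats == 0:
        raise ValueError("empty tachogram")
    fs = morph.fs
    span_ms = (
        (morph.t_center_ms + 4 * morph.t_width_ms)
        - (morph.p_center_ms - 4 * morph.p_width_ms)
    )
    typical_rr = float(np.median(tach.rr_ms))
    if span_ms > typical_rr:
        raise ValueError(
            f"beat template spans {span_ms:.0f} ms, wider than the typical "
            f"RR ({typical_rr:.0f} ms)"
        )
    r_times = tach.t_s
    n = int(np.round((r_times[-1] + 0.6) * fs))
    v = np.zeros((n, 3))

    base = morph.unit_t_dir()
    axis = _orthogonal_axis(base)
    cross = np.cross(axis, base)
    theta = morph.twave_osc_amp_deg * np.sin(
        2 * np.pi * morph.twave_osc_freq_hz * r_times + morph.twave_osc_phase
    )
    th = np.radians(theta)
    t_dirs = np.cos(th)[:, None] * base[None, :] + np.sin(th)[:, None] * cross[None, :]

    qrs_amp = np.asarray(morph.qrs_amp, dtype=float)
    p_vec = morph.p_amp_uv * morph.unit_p_dir()
    for i, tr in enumerate(r_times):
        # triphasic QRS: Q and S lobes opposite to the R lobe direction
        _add_lobe(v, fs, tr - 0.028, 0.6 * morph.qrs_width_ms, -0.15 * qrs_amp)
        _add_lobe(v, fs, tr, morph.qrs_width_ms, qrs_amp)
        _add_lobe(v, fs, tr + 0.030, 0.7 * morph.qrs_width_ms, -0.25 * qrs_amp)
        _add_lobe(v, fs, tr + morph.p_center_ms / 1000.0, morph.p_width_ms, p_vec)
        _add_lobe(
            v, fs, tr + morph.t_center_ms / 1000.0, morph.t_width_ms,
            morph.t_amp_uv * t_dirs[i],
        )

    r_idx = np.round(r_times * fs).astype(np.intp)
    beat_ect = tach.ectopic.copy()
    out_truth = GroundTruth(
        r_indices=r_idx,
        r_times_s=r_times.copy(),
        rr_ms=tach.rr_ms.copy(),
        ectopic_beats=beat_ect,
        theta_deg=theta,
        t_dirs=t_dirs,
        dtheta_deg=np.abs(np.diff(theta)),
        params={
            **(truth.params if truth is not None else {}),
            "morphology_spec": asdict(morph),
        },
    )
    return VCGSignal(v_x=v[:, 0], v_y=v[:, 1], v_z=v[:, 2], fs=fs), out_truth


def project_to_wilson(
    vcg: VCGSignal,
    morph: MorphologySpec,
    seed: int | None = None,
    coeffs: VCGCoefficients | None = None,
) -> MultiLeadECG:
    """Surface leads whose tetrahedron transform recovers the VCG direction.

    Inverts the coefficient matrix for the direction and exploits that the
    gain K is homogeneous of degree 1 in the lead differences to set the
    per-sample difference scale such that the reconstructed magnitude 3K
    equals the source magnitude — so the noise- and offset-free round trip
    through ``wilson_to_vcg`` reproduces the VCG exactly, not just its
    direction cosines.  The right-arm potential is fixed at zero, then
    per-channel baseline offset, slow baseline wander, and white noise
    (seeded) are added.
    """
    coeffs = coeffs or load_coefficients()
    v = vcg.stack()
    mag = np.linalg.norm(v, axis=1)
    nz = mag > 0
    d = np.zeros_like(v)
    p_hat = v[nz] / mag[nz, None]
    d0 = p_hat @ np.linalg.inv(coeffs.matrix).T
    e_sq0 = d0[:, 0] ** 2 + (2 * d0[:, 1] - d0[:, 0]) ** 2 / coeffs.e2_div
    k0 = np.sqrt(coeffs.k_e2 * e_sq0 + coeffs.k_vb2 * d0[:, 2] ** 2) / coeffs.k_scale
    d[nz] = (mag[nz] / (3.0 * k0))[:, None] * d0
    n = d.shape[0]
    leads = np.zeros((n, 4))
    leads[:, 1] = d[:, 0]  # v_l - v_r with v_r = 0
    leads[:, 2] = d[:, 1]  # v_f
    leads[:, 3] = d[:, 2]  # v_b
    leads += np.asarray(morph.baseline_offset_uv, dtype=float)[None, :]
    if morph.baseline_wander_amp_uv > 0:
        t = np.arange(n) / vcg.fs
        wander = morph.baseline_wander_amp_uv * np.sin(
            2 * np.pi * morph.baseline_wander_freq_hz * t
        )
        leads += wander[:, None]
    if morph.noise_sd_uv > 0:
        rng = np.random.default_rng(seed)
        leads += rng.normal(0.0, morph.noise_sd_uv, size=leads.shape)
    return MultiLeadECG(
        v_r=leads[:, 0], v_l=leads[:, 1], v_f=leads[:, 2], v_b=leads[:, 3],
        fs=vcg.fs,
    )


def generate_recording(
    tspec: TachogramSpec, morph: MorphologySpec, noise_seed: int | None = None
) -> tuple[MultiLeadECG, GroundTruth]:
    """Tachogram -> VCG -> surface leads, with ground truth."""
    tach, truth = generate_tachogram(tspec)
    vcg_sig, truth = generate_vcg(tach, morph, truth)
    seed = noise_seed if noise_seed is not None else tspec.seed + 1
    ecg = project_to_wilson(vcg_sig, morph, seed=seed)
    return ecg, truth


def _derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic sub-seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_cohort(
    spec: CohortSpec,
) -> list[dict]:
    """Per-subject paired recordings with ground truth.

    Each (subject, condition) gets its own derived seed for RR jitter,
    modulation phases, and channel noise, so rest and stress are
    independent realizations of their specs — as two separate epochs of
    one subject would be.  Deterministic under ``master_seed``.
    """
    subjects = []
    for j in range(spec.n_subjects):
        entry: dict = {"subject": j}
        for cond_idx, (cond, ts, ms) in enumerate(
            [
                ("rest", spec.rest_tachogram, spec.rest_morphology),
                ("stress", spec.stress_tachogram, spec.stress_morphology),
            ]
        ):
            seed = _derive_seed(spec.master_seed, j, cond_idx)
            rng = np.random.default_rng(seed)
            ts_j = replace(
                ts,
                seed=seed,
                lf_phase=float(rng.uniform(0, 2 * np.pi)),
                hf_phase=float(rng.uniform(0, 2 * np.pi)),
            )
            ms_j = replace(ms, twave_osc_phase=float(rng.uniform(0, 2 * np.pi)))
            ecg, truth = generate_recording(ts_j, ms_j, noise_seed=seed + 1)
            entry[cond] = {"ecg": ecg, "truth": truth}
        subjects.append(entry)
    return subjects


def write_cohort(subjects: list[dict], out_dir: str | Path) -> Path:
    """Write each recording as CSV + ground-truth JSON, plus a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for entry in subjects:
        j = entry["subject"]
        for cond in ("rest", "stress"):
            stem = f"subject{j:02d}_{cond}"
            write_recording(entry[cond]["ecg"], out_dir / f"{stem}.csv")
            (out_dir / f"{stem}.truth.json").write_text(
                json.dumps(entry[cond]["truth"].to_jsonable())
            )
            manifest.append(
                {
                    "subject": j,
                    "condition": cond,
                    "recording": f"{stem}.csv",
                    "ground_truth": f"{stem}.truth.json",
                    "fs_hz": entry[cond]["ecg"].fs,
                    "channels": list(CHANNELS),
                }
            )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir / "manifest.json"


def default_rest_specs() -> tuple[TachogramSpec, MorphologySpec]:
    """Resting-condition defaults (see module docstring)."""
    return TachogramSpec(), MorphologySpec()


def default_stress_specs() -> tuple[TachogramSpec, MorphologySpec]:
    """Cold-pressor defaults: identical autonomic RR structure, doubled
    T-vector oscillation amplitude (the sympathetic signature PRD targets)."""
    return TachogramSpec(), MorphologySpec(twave_osc_amp_deg=12.0)
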