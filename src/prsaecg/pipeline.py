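"""Recording-level biomarker extraction and paired condition comparison.

``analyze_recording`` runs the full chain — preprocessing, tetrahedron ->
VCG transform, beat delineation, HRV indices, deceleration capacity, and
periodic repolarization dynamics — and returns one BiomarkerPanel per
recording.  ``compare_conditions`` assembles matched rest/stress panels
and applies the study's statistics: Shapiro–Wilk normality on the paired
differences and a paired t-test per biomarker, reported as mean ± SE per
condition.  Raw p-values are the headline (no correction across the seven
biomarkers); a Holm-adjusted column is printed alongside as a clearly
labelled extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import delineation, hrv, prsa, repolarization, signal_io, vcg

__all__ = [
    "BIOMARKERS",
    "BiomarkerPanel",
    "PairedComparison",
    "PipelineError",
    "analyze_ecg",
    "analyze_recording",
    "compare_conditions",
    "comparison_table",
]

log = logging.getLogger(__name__)

BIOMARKERS = ("mean_rr", "hr", "lf", "hf", "lf_hf", "dc", "prd")


class PipelineError(Exception):
    """A stage failed; the message names the stage."""


@dataclass
class BiomarkerPanel:
    """Per-recording biomarker values with quality metadata.

    Units: mean_rr ms, hr bpm, lf/hf ms², lf_hf dimensionless, dc ms,
    prd degrees.  Undefined values are NaN with the reason in ``quality``.
    """

    mean_rr: float
    hr: float
    lf: float
    hf: float
    lf_hf: float
    dc: float
    prd: float
    quality: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in BIOMARKERS}
        d.update({f"quality_{k}": v for k, v in self.quality.items()})
        return d


@dataclass
class PairedComparison:
    """Per-biomarker paired rest/stress statistics."""

    biomarker: str
    n_pairs: int
    mean_rest: float
    se_rest: float
    mean_stress: float
    se_stress: float
    shapiro_p: float
    p_value: float
    test: str
    degenerate: bool = False
    holm_p: float = float("nan")


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {name!r}: {exc}") from exc
            return False

    return _Ctx()


def analyze_ecg(ecg: signal_io.MultiLeadECG, config: dict | None = None) -> BiomarkerPanel:
    """Full biomarker chain on an in-memory recording (deterministic)."""
    from .config import default_config

    cfg = config or default_config()
    with _stage("preprocess"):
        fspec = signal_io.FilterSpec(
            low_cut=cfg["filter"]["low_cut_hz"],
            high_cut=cfg["filter"]["high_cut_hz"],
            order=cfg["filter"]["order"],
            gain=cfg["signal"]["gain"],
        )
        clean = signal_io.preprocess(ecg, fspec)
    with _stage("vcg"):
        coeffs = vcg.load_coefficients(cfg["vcg"]["coeff_file"])
        v, _proj = vcg.wilson_to_vcg(clean, coeffs)
    with _stage("delineation"):
        ann, tach = delineation.delineate(
            v,
            ectopic_threshold=cfg["delineation"]["ectopic_threshold"],
            rr_mode=cfg["delineation"]["rr_mode"],
        )
    with _stage("hrv"):
        mean_rr, hr_bpm = hrv.time_domain(tach)
        spec = hrv.rr_psd(tach, resample_fs=cfg["hrv"]["resample_fs_hz"])
        lf = hrv.band_power(spec, tuple(cfg["hrv"]["lf_band_hz"]))
        hf = hrv.band_power(spec, tuple(cfg["hrv"]["hf_band_hz"]))
        ratio = lf / hf if hf > 0 else float("nan")
    with _stage("dc"):
        dc_res = prsa.dc_from_series(
            tach.rr_ms, half_window=cfg["dc"]["half_window"], exclude=tach.ectopic
        )
    with _stage("prd"):
        angles = repolarization.build_angle_series(
            v, ann,
            filter_order=cfg["prd"]["median_window"] - 1,
            norm_floor_uv=cfg["prd"]["norm_floor_uv"],
            min_pairs=2 * cfg["prd"]["half_window"] + 1,
        )
        prd_res = prsa.prd_from_series(
            angles.filtered,
            half_window=cfg["prd"]["half_window"],
            span=cfg["prd"]["anchor_span"],
        )
    return BiomarkerPanel(
        mean_rr=mean_rr,
        hr=hr_bpm,
        lf=lf,
        hf=hf,
        lf_hf=ratio,
        dc=dc_res.scalar,
        prd=prd_res.scalar,
        quality={
            "n_beats": int(ann.n_beats),
            "ectopic_fraction": tach.ectopic_fraction,
            "dc_anchors": dc_res.anchor_count,
            "prd_anchors": prd_res.anchor_count,
            "n_angle_pairs": angles.n_pairs,
        },
    )


def analyze_recording(path: str | Path, config: dict | None = None) -> BiomarkerPanel:
    """Load a CSV recording and run :func:`analyze_ecg`."""
    from .config import default_config

    cfg = config or default_config()
    with _stage("signal_io"):
        ecg = signal_io.read_recording(
            path, fs=cfg["signal"]["fs"], columns=cfg["signal"]["columns"]
        )
    return analyze_ecg(ecg, cfg)


def compare_conditions(
    panels_rest: dict[object, BiomarkerPanel],
    panels_stress: dict[object, BiomarkerPanel],
) -> list[PairedComparison]:
    """Paired rest-vs-stress statistics per biomarker.

    Subjects missing either condition are dropped (logged).  Paired t-test
    on at least 2 complete pairs; zero-variance differences are reported
    as degenerate (p NaN) rather than p=0.  A Holm-adjusted column across
    the biomarker family is filled in as an extension.
    """
    common = sorted(set(panels_rest) & set(panels_stress), key=str)
    dropped = (set(panels_rest) | set(panels_stress)) - set(common)
    if dropped:
        log.info("dropping %d subject(s) missing one condition: %s",
                 len(dropped), sorted(dropped, key=str))
    if len(common) < 2:
        raise PipelineError("need >=2 complete rest/stress pairs")
    results: list[PairedComparison] = []
    for name in BIOMARKERS:
        rest = np.array([getattr(panels_rest[s], name) for s in common], float)
        stress = np.array([getattr(panels_stress[s], name) for s in common], float)
        ok = np.isfinite(rest) & np.isfinite(stress)
        r, s = rest[ok], stress[ok]
        n = int(ok.sum())
        if n < 2:
            results.append(
                PairedComparison(name, n, np.nan, np.nan, np.nan, np.nan,
                                 np.nan, np.nan, "paired t", degenerate=True)
            )
            continue
        diff = s - r
        degenerate = bool(np.allclose(diff, diff[0]) and np.std(diff) == 0)
        if degenerate:
            sw_p = float("nan")
            p = float("nan") if diff[0] != 0 else 1.0
            log.warning("biomarker %s: zero-variance paired differences", name)
        else:
            sw_p = float(stats.shapiro(diff).pvalue) if n >= 3 else float("nan")
            p = float(stats.ttest_rel(s, r).pvalue)
        results.append(
            PairedComparison(
                biomarker=name,
                n_pairs=n,
                mean_rest=float(np.mean(r)),
                se_rest=float(np.std(r, ddof=1) / np.sqrt(n)),
                mean_stress=float(np.mean(s)),
                se_stress=float(np.std(s, ddof=1) / np.sqrt(n)),
                shapiro_p=sw_p,
                p_value=p,
                test="paired t",
                degenerate=degenerate,
            )
        )
    # Holm adjustment across the family — extension, not the headline
    ps = [(i, r.p_value) for i, r in enumerate(results) if np.isfinite(r.p_value)]
    ps.sort(key=lambda t: t[1])
    m = len(ps)
    running = 0.0
    for rank, (i, p) in enumerate(ps):
        running = max(running, min(1.0, (m - rank) * p))
        results[i].holm_p = running
    return results


def comparison_table(results: list[PairedComparison]) -> pd.DataFrame:
    """Comparison results as a tidy DataFrame."""
    return pd.DataFrame([vars(r) for r in results])
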