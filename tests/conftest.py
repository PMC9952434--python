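"""Shared fixtures: synthetic recordings at the default study conditions."""

from dataclasses import replace

import numpy as np
import pytest

from prsaecg import signal_io, vcg
from prsaecg.synth import (
    MorphologySpec,
    TachogramSpec,
    generate_recording,
    generate_tachogram,
    generate_vcg,
    project_to_wilson,
)


@pytest.fixture(scope="session")
def rest_tspec() -> TachogramSpec:
    return TachogramSpec(seed=7)


@pytest.fixture(scope="session")
def clean_morph() -> MorphologySpec:
    """Noise-free, offset-free morphology (ground-truth comparisons)."""
    return MorphologySpec(
        noise_sd_uv=0.0, baseline_wander_amp_uv=0.0, twave_osc_amp_deg=0.0
    )


@pytest.fixture(scope="session")
def clean_vcg(rest_tspec, clean_morph):
    """Noise-free VCG + ground truth at default rest conditions."""
    tach, truth = generate_tachogram(rest_tspec)
    return generate_vcg(tach, clean_morph, truth)


@pytest.fixture(scope="session")
def clean_recording(rest_tspec, clean_morph):
    """Noise-free surface-lead recording + ground truth."""
    return generate_recording(rest_tspec, clean_morph)


@pytest.fixture(scope="session")
def noisy_recording(rest_tspec):
    """Default (2 µV noise, wander, oscillating T) recording + truth."""
    return generate_recording(rest_tspec, MorphologySpec(), noise_seed=11)


@pytest.fixture(scope="session")
def coeffs() -> vcg.VCGCoefficients:
    return vcg.load_coefficients()


@pytest.fixture()
def csv_recording(tmp_path, noisy_recording):
    """Noisy recording round-tripped to a CSV file."""
    ecg, _ = noisy_recording
    return signal_io.write_recording(ecg, tmp_path / "rec.csv")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230205)
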