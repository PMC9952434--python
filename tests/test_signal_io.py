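"""Recording I/O and the preprocessing chain (filter, isoline, re-reference)."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from prsaecg import signal_io
from prsaecg.signal_io import (
    FilterSpec,
    MissingChannelError,
    MultiLeadECG,
    ShortRecordingError,
    common_average_rereference,
    preprocess,
    read_recording,
    remove_isoline_offset,
    write_recording,
    zero_phase_bandpass,
)

FS = 250.0


def make_ecg(arr4, fs=FS):
    return MultiLeadECG(
        v_r=arr4[:, 0], v_l=arr4[:, 1], v_f=arr4[:, 2], v_b=arr4[:, 3], fs=fs
    )


# ------------------------------------------------------------------- I/O


def test_zero_csv_roundtrip(tmp_path):
    n = int(12 * FS)
    ecg = make_ecg(np.zeros((n, 4)))
    path = write_recording(ecg, tmp_path / "z.csv")
    back = read_recording(path, fs=FS)
    assert back.n_samples == n
    assert np.all(back.stack() == 0)


def test_synthetic_roundtrip_bit_exact(csv_recording, noisy_recording):
    ecg, _ = noisy_recording
    back = read_recording(csv_recording, fs=ecg.fs)
    assert np.array_equal(back.stack(), ecg.stack())


def test_missing_channel_error_names_channel(tmp_path):
    n = int(12 * FS)
    df = pd.DataFrame(
        {"t": np.arange(n) / FS, "v_r": 0.0, "v_l": 0.0, "v_f": 0.0}
    )
    df.to_csv(tmp_path / "m.csv", index=False)
    with pytest.raises(MissingChannelError, match="v_b"):
        read_recording(tmp_path / "m.csv", fs=FS)


def test_short_recording_rejected(tmp_path):
    n = int(5 * FS)
    ecg = make_ecg(np.zeros((int(12 * FS), 4)))
    path = write_recording(ecg, tmp_path / "s.csv")
    df = pd.read_csv(path).iloc[:n]
    df.to_csv(tmp_path / "s.csv", index=False)
    with pytest.raises(ShortRecordingError):
        read_recording(tmp_path / "s.csv", fs=FS)


def test_fs_inferred_from_time_column(tmp_path):
    n = int(15 * FS)
    ecg = make_ecg(np.random.default_rng(0).normal(size=(n, 4)))
    path = write_recording(ecg, tmp_path / "r.csv")
    back = read_recording(path)  # no fs given
    assert back.fs == pytest.approx(FS, rel=1e-6)


def test_nonfinite_rows_flagged_and_bridged(tmp_path):
    n = int(12 * FS)
    arr = np.ones((n, 4))
    ecg = make_ecg(arr)
    path = write_recording(ecg, tmp_path / "n.csv")
    df = pd.read_csv(path)
    df.loc[100, "v_l"] = np.nan
    df.to_csv(tmp_path / "n.csv", index=False)
    back = read_recording(tmp_path / "n.csv", fs=FS)
    assert back.bad_samples[100]
    assert np.isfinite(back.stack()).all()


# ------------------------------------------------------------------- filter


def test_zero_phase_preserves_symmetric_pulse_peak():
    n = int(40 * FS)
    k = n // 2
    t = np.arange(n)
    pulse = np.exp(-((t - k) ** 2) / (2 * (0.02 * FS) ** 2))
    ecg = make_ecg(np.tile(pulse[:, None], (1, 4)))
    out = zero_phase_bandpass(ecg)
    assert int(np.argmax(out.v_r)) == k


def test_passband_and_stopband_amplitudes():
    n = int(60 * FS)
    t = np.arange(n) / FS
    in_band = np.sin(2 * np.pi * 10.0 * t)
    stop = np.sin(2 * np.pi * 0.5 * t)
    ecg = make_ecg(np.column_stack([in_band, in_band, stop, stop]))
    out = zero_phase_bandpass(ecg)
    mid = slice(int(10 * FS), int(50 * FS))  # away from edges
    assert 0.9 <= np.max(np.abs(out.v_r[mid])) <= 1.0
    assert np.max(np.abs(out.v_f[mid])) < 0.1


def test_dc_offset_removed_to_numerical_floor():
    n = int(30 * FS)
    ecg = make_ecg(np.full((n, 4), 500.0))
    out = zero_phase_bandpass(ecg)
    mid = slice(int(5 * FS), int(25 * FS))
    assert np.max(np.abs(out.v_r[mid])) < 1e-6 * 500.0


def test_filter_spec_validation():
    with pytest.raises(signal_io.SignalIOError):
        FilterSpec(low_cut=30.0, high_cut=26.0).validate(FS)
    short = make_ecg(np.zeros((100, 4)))
    with pytest.raises(ShortRecordingError):
        zero_phase_bandpass(short)


def test_designed_filter_squared_magnitude_response():
    """Forward-backward filtering realizes |H|^2 of the designed filter."""
    spec = FilterSpec()
    sos = sps.butter(spec.order, [spec.low_cut, spec.high_cut],
                     btype="bandpass", fs=FS, output="sos")
    w, h = sps.sosfreqz(sos, worN=[0.5, 10.0], fs=FS)
    assert abs(h[1]) ** 2 > 0.9       # 10 Hz in passband
    assert abs(h[0]) ** 2 < 1e-4      # 0.5 Hz deep in stopband


# ------------------------------------------------------------------- isoline


def test_isoline_offset_subtracts_channel_median():
    n = int(12 * FS)
    rng = np.random.default_rng(1)
    arr = rng.normal(0, 5, (n, 4)) + np.array([300.0, -40.0, 10.0, 0.0])
    out = remove_isoline_offset(make_ecg(arr))
    assert np.all(np.abs(np.median(out.stack(), axis=0)) < 1.0)
    zeros = remove_isoline_offset(make_ecg(np.zeros((n, 4))))
    assert np.all(zeros.stack() == 0)


def test_injected_baseline_offsets_recovered(rest_tspec, clean_morph):
    """Preprocessing removes known per-channel offsets injected upstream."""
    from dataclasses import replace

    from prsaecg.synth import generate_recording

    offsets = (500.0, -200.0, 120.0, 0.0)
    morph_off = replace(clean_morph, baseline_offset_uv=offsets)
    ecg_off, _ = generate_recording(rest_tspec, morph_off)
    ecg_ref, _ = generate_recording(rest_tspec, clean_morph)
    a = preprocess(ecg_off).stack()
    b = preprocess(ecg_ref).stack()
    mid = slice(int(5 * FS), int(100 * FS))
    assert np.max(np.abs(a[mid] - b[mid])) < 2.0  # µV


# --------------------------------------------------------------- rereference


def test_common_average_arithmetic():
    n = int(12 * FS)
    arr = np.tile(np.array([1.0, 2.0, 3.0, 6.0]), (n, 1))
    out = common_average_rereference(make_ecg(arr)).stack()
    assert np.allclose(out[0], [-2.0, -1.0, 0.0, 3.0])
    same = common_average_rereference(make_ecg(np.ones((n, 4)))).stack()
    assert np.all(same == 0)


def test_rereferenced_channels_sum_to_zero(rng):
    arr = rng.normal(0, 100, (int(12 * FS), 4))
    out = common_average_rereference(make_ecg(arr)).stack()
    assert np.max(np.abs(out.sum(axis=1))) < 1e-9


def test_lead_differences_invariant_under_rereference(rng):
    from prsaecg.vcg import lead_differences

    ecg = make_ecg(rng.normal(0, 100, (int(12 * FS), 4)))
    d1 = lead_differences(ecg)
    d2 = lead_differences(common_average_rereference(ecg))
    assert np.max(np.abs(d1 - d2)) < 1e-9  # machine precision at ~100 µV scale


def test_double_filtering_moves_no_fiducial(clean_recording):
    """Phase idempotence: filtering twice shifts detected R-peaks <=1 sample."""
    from prsaecg import delineation, vcg

    ecg, _ = clean_recording
    once = preprocess(ecg)
    twice = zero_phase_bandpass(once)
    r1 = delineation.detect_r_peaks(vcg.wilson_to_vcg(once)[0])
    r2 = delineation.detect_r_peaks(vcg.wilson_to_vcg(twice)[0])
    assert r1.size == r2.size
    assert np.max(np.abs(r1 - r2)) <= 1
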