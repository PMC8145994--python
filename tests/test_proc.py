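"""Demodulation, calibration and the raw-data closed loop."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sfdi2layer.proc import (
    CalibrationSet,
    FrameTriplet,
    calibrate,
    demodulate,
    find_blank_frames,
    iter_triplets,
    phantom_reference_rd,
    read_raw_stack,
    reference_phantom_properties,
    saturation_mask,
    write_raw_stack,
)
from sfdi2layer.synthetic import NoiseModel, make_raw_stack
from sfdi2layer.transport import SfdReflectance


def _triplet(i1, i2, i3, wl=735):
    return FrameTriplet(
        i1=np.asarray(i1, float), i2=np.asarray(i2, float),
        i3=np.asarray(i3, float), wavelength=wl,
    )


def _sinusoid_triplet(B, A, phi, shape=(4, 5)):
    frames = [
        np.full(shape, B + A * np.cos(phi + p * 2 * np.pi / 3)) for p in range(3)
    ]
    return _triplet(*frames)


def test_demodulate_constant_illumination():
    t = _triplet(np.full((3, 3), 7.0), np.full((3, 3), 7.0), np.full((3, 3), 7.0))
    pair = demodulate(t)
    np.testing.assert_allclose(pair.m0, 7.0)
    np.testing.assert_allclose(pair.m1, 0.0, atol=1e-12)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    B=st.floats(1.0, 1e4),
    A=st.floats(0.0, 1.0),
    phi=st.floats(0.0, 2 * np.pi),
)
def test_demodulation_identity_for_ideal_sinusoids(B, A, phi):
    """M(0)=B and M(0.1)=A exactly, for any phase offset (A scaled to B)."""
    pair = demodulate(_sinusoid_triplet(B, A * B, phi))
    np.testing.assert_allclose(pair.m0, B, rtol=1e-10)
    np.testing.assert_allclose(pair.m1, A * B, rtol=1e-7, atol=1e-9 * B)


def test_demodulation_symmetric_under_frame_permutation():
    t = _sinusoid_triplet(10.0, 2.0, 0.7)
    base = demodulate(t)
    for perm in [(t.i2, t.i3, t.i1), (t.i3, t.i1, t.i2), (t.i2, t.i1, t.i3)]:
        p = demodulate(_triplet(*perm))
        np.testing.assert_allclose(p.m0, base.m0, rtol=1e-12)
        np.testing.assert_allclose(p.m1, base.m1, rtol=1e-9)


def test_demodulate_input_contracts():
    with pytest.raises(ValueError):
        _triplet(np.zeros((2, 2)), np.zeros((2, 3)), np.zeros((2, 2)))
    with pytest.raises(ValueError):
        _triplet(-np.ones((2, 2)), np.ones((2, 2)), np.ones((2, 2)))


def _calset(mref0, mref1, rd0=0.6, rd1=0.25, wl=735):
    return CalibrationSet(
        phantom_mua={wl: 0.0495}, phantom_musp={wl: 6.4},
        mref0={wl: mref0}, mref1={wl: mref1},
        rd_ref0={wl: rd0}, rd_ref1={wl: rd1},
    )


def test_calibration_identity_and_linearity():
    mref0 = np.full((4, 4), 100.0)
    mref1 = np.full((4, 4), 40.0)
    cal = _calset(mref0, mref1)
    rd, valid = calibrate(
        type("P", (), {"m0": mref0, "m1": mref1})(), cal, 735
    )
    assert valid.all()
    np.testing.assert_allclose(rd.rd0, 0.6)
    np.testing.assert_allclose(rd.rd1, 0.25)
    half, _ = calibrate(
        type("P", (), {"m0": 0.5 * mref0, "m1": 0.5 * mref1})(), cal, 735
    )
    np.testing.assert_allclose(half.rd0, 0.3)


@pytest.mark.parametrize("k", [0.1, 3.0, 250.0])
def test_calibration_scale_invariance(k):
    """Multiplying all raw frames (meas + ref) by k > 0 leaves Rd unchanged."""
    t_meas = _sinusoid_triplet(80.0, 30.0, 0.3)
    t_ref = _sinusoid_triplet(100.0, 45.0, 1.1)
    cal = lambda ref: _calset(ref.m0, ref.m1)
    base_rd, _ = calibrate(demodulate(t_meas), cal(demodulate(t_ref)), 735)
    scaled_meas = _triplet(k * t_meas.i1, k * t_meas.i2, k * t_meas.i3)
    scaled_ref = _triplet(k * t_ref.i1, k * t_ref.i2, k * t_ref.i3)
    rd, _ = calibrate(demodulate(scaled_meas), cal(demodulate(scaled_ref)), 735)
    np.testing.assert_allclose(rd.rd0, base_rd.rd0, rtol=1e-10)
    np.testing.assert_allclose(rd.rd1, base_rd.rd1, rtol=1e-10)


def test_calibration_flags_dead_reference_pixels():
    mref0 = np.full((3, 3), 50.0)
    mref0[1, 1] = 0.0
    mref1 = np.full((3, 3), 20.0)
    rd, valid = calibrate(
        type("P", (), {"m0": mref0, "m1": mref1})(), _calset(mref0, mref1), 735
    )
    assert not valid[1, 1] and valid.sum() == 8
    assert np.isnan(np.asarray(rd.rd0)[1, 1])


def test_reference_phantom_properties():
    mua, musp = reference_phantom_properties()
    assert mua == pytest.approx(0.0495)
    # two-point power law through (690, 7.1) and (830, 5.3)
    b = np.log(7.1 / 5.3) / np.log(830.0 / 690.0)
    assert b == pytest.approx(1.5817, abs=2e-3)
    assert musp[735] == pytest.approx(7.1 * (735.0 / 690.0) ** (-b), rel=1e-6)
    assert musp[662] > musp[735] > musp[859]


def test_phantom_reference_rd_is_physical(lut_set):
    rd_ref = phantom_reference_rd(lut_set.homogeneous)
    for wl, rd in rd_ref.items():
        assert 0.0 < rd.rd1 < rd.rd0 < 1.0


def test_saturation_and_blank_frame_utilities():
    frames = np.ones((5, 4, 4)) * 100.0
    frames[2] = 0.5  # blank marker
    frames[3, 1, 2] = 4095.0
    assert find_blank_frames(frames).tolist() == [2]
    mask = saturation_mask(frames, sensor_max=4095.0)
    assert mask[1, 2] and mask.sum() == 1


def test_closed_loop_raw_stack_to_reflectance(lut_set, tmp_path):
    """Noise-free synthetic stack -> demod -> calibrate reproduces Rd truth."""
    rd_ref = phantom_reference_rd(lut_set.homogeneous)
    rd_truth = {
        662: SfdReflectance(rd0=0.55, rd1=0.21),
        735: SfdReflectance(rd0=0.62, rd1=0.25),
        859: SfdReflectance(rd0=0.68, rd1=0.30),
    }
    frames, ref_frames, sidecar = make_raw_stack(
        rd_truth, rd_ref, noise=NoiseModel(0, 0, 0, 0, 0, 0), seed=5
    )
    # round trip through the TIFF + sidecar reader
    sidecar.pop("truth")
    write_raw_stack(tmp_path / "meas.tif", frames, sidecar)
    frames_r, sidecar_r = read_raw_stack(tmp_path / "meas.tif")
    ref_pairs = {
        int(t.wavelength): demodulate(t) for t in iter_triplets(ref_frames, sidecar_r)
    }
    cal = CalibrationSet(
        phantom_mua={wl: 0.0495 for wl in rd_truth},
        phantom_musp=dict(reference_phantom_properties()[1]),
        mref0={wl: p.m0 for wl, p in ref_pairs.items()},
        mref1={wl: p.m1 for wl, p in ref_pairs.items()},
        rd_ref0={wl: float(rd_ref[wl].rd0) for wl in rd_truth},
        rd_ref1={wl: float(rd_ref[wl].rd1) for wl in rd_truth},
    )
    seen = 0
    for t in iter_triplets(frames_r, sidecar_r):
        rd, valid = calibrate(demodulate(t), cal, int(t.wavelength))
        truth = rd_truth[int(t.wavelength)]
        assert valid.all()
        np.testing.assert_allclose(rd.rd0, truth.rd0, rtol=1e-6)
        np.testing.assert_allclose(rd.rd1, truth.rd1, rtol=1e-6)
        seen += 1
    assert seen == 3


def test_raw_stack_determinism_and_artifact_bookkeeping(lut_set):
    rd_ref = phantom_reference_rd(lut_set.homogeneous)
    rd_truth = {735: SfdReflectance(rd0=0.6, rd1=0.24)}
    noise = NoiseModel(shot_sd_frac=0.01, n_specular=2)
    f1, r1, s1 = make_raw_stack(rd_truth, {735: rd_ref[735]}, noise=noise, seed=9)
    f2, r2, s2 = make_raw_stack(rd_truth, {735: rd_ref[735]}, noise=noise, seed=9)
    assert np.array_equal(f1, f2)
    assert s1["truth"]["artifact_pixels"] > 0
    assert s1["truth"]["artifact_mask"].sum() == s1["truth"]["artifact_pixels"]
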