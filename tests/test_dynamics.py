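"""Dynamic-compression processing: rejection rules, ROIs, slope fits."""

import numpy as np
import pytest

from sfdi2layer.dynamics import (
    compression_slope,
    partition_rois,
    process_measurement,
    reject_dynamic_pixels,
    reject_specular_pixels,
    roi_artifact_screen,
    screen_baseline,
    baseline_average_rd,
    unmix_hemoglobin_stack,
    MeasurementTimeSeries,
)
from sfdi2layer.spectral import ChromophoreTable, hemoglobin_to_mua


def _disc_mask(n=64):
    yy, xx = np.mgrid[0:n, 0:n]
    r = n / 2 - 1
    return (yy - (n - 1) / 2) ** 2 + (xx - (n - 1) / 2) ** 2 <= r**2


# --- specular pixel rejection ------------------------------------------------

def test_specular_rejection_uniform_image_keeps_everything():
    stack = np.ones((4, 3, 16, 16))
    assert not reject_specular_pixels(stack).any()


def test_specular_rejection_single_hot_pixel_any_frame():
    # structured background bounded well inside 2.5 SD; one hot pixel in a
    # single frame/wavelength must exclude that pixel for the whole series
    base = np.fromfunction(
        lambda y, x: 100.0 + np.sin(y) + np.cos(x), (16, 16)
    )
    stack = np.tile(base, (5, 3, 1, 1))
    stack[3, 1, 7, 9] = 200.0
    rejected = reject_specular_pixels(stack)
    assert rejected[7, 9]
    assert rejected.sum() == 1


def test_specular_rejection_recovers_planted_disc():
    rng = np.random.default_rng(1)
    stack = 100.0 + rng.normal(0, 1.0, (6, 3, 32, 32))
    yy, xx = np.mgrid[0:32, 0:32]
    disc = (yy - 10) ** 2 + (xx - 20) ** 2 <= 9
    stack[:, :, disc] += 50.0
    rejected = reject_specular_pixels(stack)
    assert (rejected & disc).sum() == disc.sum()  # rejected set contains the disc


def test_specular_rejection_total_wipeout_is_an_error():
    stack = np.zeros((1, 1, 4, 4))
    stack[0, 0] = np.arange(16).reshape(4, 4) * 1e6  # everything extreme
    fov = np.ones((4, 4), bool)
    with pytest.raises(RuntimeError):
        # alternating huge outliers: every pixel trips somewhere
        reject_specular_pixels(
            np.stack([stack[0], -stack[0]]), fov, sd_limit=0.01
        )


# --- baseline averaging ------------------------------------------------------

def _series(rd0, rd1, times=None, pitch=0.8):
    nt, nwl = rd0.shape[:2]
    times = np.arange(nt) * 2.0 if times is None else times
    fov = _disc_mask(rd0.shape[-1])
    return MeasurementTimeSeries(
        times=times, wavelengths=(662, 735, 859)[:nwl], rd0=rd0, rd1=rd1,
        pixel_pitch_mm=pitch, fov_mask=fov,
        timeline=((0, 60), (60, 120), (120, max(180, times[-1]))),
    )


def test_baseline_average_constant_stack():
    rd0 = np.full((90, 3, 16, 16), 0.61)
    rd1 = np.full((90, 3, 16, 16), 0.24)
    out = baseline_average_rd(_series(rd0, rd1))
    for wl in (662, 735, 859):
        assert out[wl].rd0 == pytest.approx(0.61)
        assert out[wl].rd1 == pytest.approx(0.24)


def test_baseline_window_boundaries_inclusive():
    times = np.arange(0, 180, 2.0)
    in_window = (times >= 10.0) & (times <= 55.0)
    rd0 = np.zeros((times.size, 1, 8, 8))
    rd0[in_window] = 1.0  # only boundary-inclusive frames carry signal
    out = baseline_average_rd(_series(rd0, rd0 * 0.4, times))
    assert out[662].rd0 == pytest.approx(1.0)
    assert np.isclose(times[in_window][0], 10.0)
    assert np.isclose(times[in_window][-1], 54.0)  # 2 s cadence: 54 is last <= 55


def test_baseline_average_linear_drift():
    times = np.arange(0, 180, 2.0)
    c, r0 = 1e-3, 0.5
    rd0 = r0 + c * times[:, None, None, None] * np.ones((times.size, 1, 8, 8))
    out = baseline_average_rd(_series(rd0, rd0 * 0.3, times))
    kept = times[(times >= 10) & (times <= 55)]
    assert out[662].rd0 == pytest.approx(r0 + c * kept.mean(), rel=1e-12)


# --- dynamic (mua) rejection -------------------------------------------------

def test_dynamic_rejection_homogeneous_stack():
    stack = np.full((10, 3, 40, 40), 0.05)
    stack += np.random.default_rng(3).normal(0, 1e-4, stack.shape)
    assert not reject_dynamic_pixels(stack, pixel_pitch_mm=1.0).any()


def test_dynamic_rejection_planted_transient():
    rng = np.random.default_rng(4)
    stack = 0.05 + rng.normal(0, 1e-3, (10, 3, 40, 40))
    stack[4, 2, 5, 6] += 9.0 * 1e-3  # 9 SD excursion at one (t, wl)
    rejected = reject_dynamic_pixels(stack, pixel_pitch_mm=1.0)
    assert rejected[5, 6]


@pytest.mark.parametrize("k", [0.1, 10.0])
def test_dynamic_rejection_scale_invariant(k):
    rng = np.random.default_rng(5)
    stack = 0.05 + rng.normal(0, 1e-3, (8, 3, 30, 30))
    stack[2, 0, 3, 3] += 0.02
    a = reject_dynamic_pixels(stack, pixel_pitch_mm=1.0)
    b = reject_dynamic_pixels(k * stack, pixel_pitch_mm=1.0)
    assert np.array_equal(a, b)


def test_dynamic_rejection_needs_central_region():
    with pytest.raises(ValueError):
        reject_dynamic_pixels(np.ones((2, 1, 40, 40)), pixel_pitch_mm=50.0)


# --- ROI partition -----------------------------------------------------------

def test_partition_covers_fov_exactly():
    fov = _disc_mask(64)
    rois = partition_rois(fov)
    assert rois.shape[0] == 8
    assert np.array_equal(rois.sum(axis=0).astype(bool), fov)
    assert rois.sum(axis=0).max() == 1  # pixelwise disjoint


def test_partition_equal_areas_at_large_radius():
    fov = _disc_mask(512)
    rois = partition_rois(fov)
    areas = rois.sum(axis=(1, 2))
    assert areas.max() / areas.min() < 1.01


def test_partition_rotation_permutes_labels():
    fov = _disc_mask(128)
    rois = partition_rois(fov)
    rot = partition_rois(np.rot90(fov).copy())
    # rotating a sector clockwise by 90 degrees advances its label by 2
    for k in range(8):
        overlap = [
            (rois[k] & np.rot90(rot[j], -1)).sum() / rois[k].sum()
            for j in range(8)
        ]
        assert np.argmax(overlap) == (k - 2) % 8
        assert max(overlap) > 0.97


def test_partition_rejects_non_circular_mask():
    mask = np.zeros((40, 40), bool)
    mask[:5, :] = True  # a bar, not a disc
    with pytest.raises(ValueError):
        partition_rois(mask)


# --- baseline screen and compression slope -----------------------------------

def _trace_times():
    return np.arange(0, 180, 2.0)


def test_screen_baseline_flat_trace_kept():
    t = _trace_times()
    slope, rms, keep = screen_baseline(t, np.full(t.size, 0.7))
    assert slope == pytest.approx(0.0, abs=1e-12)
    assert rms == pytest.approx(0.0, abs=1e-12)
    assert keep


def test_screen_baseline_slope_threshold():
    t = _trace_times()
    drift = 0.7 + 0.05e-2 * t  # 0.05 pp/s in fraction units
    slope, _, keep = screen_baseline(t, drift)
    assert slope == pytest.approx(0.05, rel=1e-9)
    assert not keep
    ok_drift = 0.7 + 0.044e-2 * t
    _, _, keep_ok = screen_baseline(t, ok_drift)
    assert keep_ok


def test_screen_baseline_rms_threshold():
    t = _trace_times()
    wobble = 0.7 + 0.5e-2 * np.sqrt(2) * np.sin(2 * np.pi * t / 9.0)
    slope, rms, keep = screen_baseline(t, wobble)
    assert rms > 0.4
    assert not keep


def test_compression_slope_recovery_and_offsets():
    t = _trace_times()
    trace = 0.7 - 0.011e-2 * (t - 60.0)
    assert compression_slope(t, trace) == pytest.approx(-0.011, rel=1e-9)
    assert compression_slope(t, trace + 0.1) == pytest.approx(-0.011, rel=1e-9)
    assert compression_slope(t, np.full(t.size, 0.6)) == pytest.approx(
        0.0, abs=1e-12
    )


# --- ROI artifact screen -----------------------------------------------------

def test_roi_artifact_screen_thresholds():
    roi = np.zeros((10, 10), bool)
    roi[:10] = True
    rejected = np.zeros((10, 10), bool)
    assert roi_artifact_screen(roi, rejected)  # 0%
    rejected.flat[:61] = True
    assert not roi_artifact_screen(roi, rejected)  # 61%
    rejected = np.zeros((10, 10), bool)
    rejected.flat[:60] = True
    assert roi_artifact_screen(roi, rejected)  # exactly 60%: kept


# --- hemoglobin stack unmixing ----------------------------------------------

def test_unmix_stack_matches_pointwise_fit():
    table = ChromophoreTable()
    thb_true = np.array([[15.0, 22.0], [19.0, 25.0]])
    sto2_true = np.array([[0.6, 0.8], [0.75, 0.5]])
    stack = np.empty((1, 3, 2, 2))
    for i in range(2):
        for j in range(2):
            stack[0, :, i, j] = hemoglobin_to_mua(
                thb_true[i, j], sto2_true[i, j], table
            )
    thb, sto2 = unmix_hemoglobin_stack(stack, table)
    np.testing.assert_allclose(thb[0], thb_true, rtol=1e-10)
    np.testing.assert_allclose(sto2[0], sto2_true, rtol=1e-10)


# --- end-to-end on a synthetic compression movie ------------------------------

@pytest.fixture(scope="module")
def movie_products(lut_set):
    from sfdi2layer.spectral import mi_to_mua_epi
    from sfdi2layer.synthetic import NoiseModel, make_compression_movie

    mi = 0.0
    collapsed = {
        wl: lut_set.two_layer[wl].collapse(float(mi_to_mua_epi(mi, wl)))
        for wl in lut_set.wavelengths
    }
    series, truth = make_compression_movie(
        collapsed,
        sto2_slope_pp_s=-0.03,
        roi_slope_jitter_pp_s=0.002,
        rd_noise_frac=0.002,
        noise=None,
        seed=17,
    )
    results, diag = process_measurement(series, collapsed)
    return series, truth, results, diag


def test_movie_pipeline_recovers_planted_hemodynamics(movie_products):
    series, truth, results, diag = movie_products
    kept = [r for r in results if not r.rejected]
    assert len(kept) >= 6
    for r in kept:
        # planted blanching: tHb dips during compression, recovers after
        in_comp = (series.times >= 60) & (series.times < 120)
        base = r.thb_t[series.times < 60].mean()
        assert r.thb_t[in_comp].min() < base - 1.0
        assert abs(r.thb_t[series.times >= 160].mean() - base) < 1.0
        # sign-correct compression slope
        assert r.compression_slope < 0
        truth_slope = truth["sto2_slopes_pp_s"][r.roi_id - 1]
        assert r.compression_slope == pytest.approx(truth_slope, abs=0.01)


def test_movie_pipeline_is_idempotent(movie_products, lut_set):
    from sfdi2layer.spectral import mi_to_mua_epi

    series, truth, results, diag = movie_products
    collapsed = {
        wl: lut_set.two_layer[wl].collapse(float(mi_to_mua_epi(0.0, wl)))
        for wl in lut_set.wavelengths
    }
    again, diag2 = process_measurement(series, collapsed)
    for a, b in zip(results, again):
        assert a.rejected == b.rejected and a.reason == b.reason
        np.testing.assert_array_equal(a.thb_t, b.thb_t)
        assert a.compression_slope == b.compression_slope or (
            np.isnan(a.compression_slope) and np.isnan(b.compression_slope)
        )
    np.testing.assert_array_equal(diag["rejected_mask"], diag2["rejected_mask"])


def test_movie_specular_artifacts_drive_roi_rejection(lut_set):
    from sfdi2layer.spectral import mi_to_mua_epi
    from sfdi2layer.synthetic import NoiseModel, make_compression_movie

    collapsed = {
        wl: lut_set.two_layer[wl].collapse(float(mi_to_mua_epi(0.0, wl)))
        for wl in lut_set.wavelengths
    }
    series, truth = make_compression_movie(
        collapsed,
        noise=NoiseModel(shot_sd_frac=0.002, n_specular=3,
                         specular_radius_px=6),
        seed=23,
    )
    results, diag = process_measurement(series, collapsed)
    planted = truth["artifact_mask"]
    assert planted.any()
    assert (diag["rejected_mask"] & planted).sum() / planted.sum() > 0.9
    # ROI rejection must follow the >60% coverage rule for the planted discs
    rois = diag["roi_masks"]
    for r in results:
        cover = (rois[r.roi_id - 1] & diag["rejected_mask"]).sum() / max(
            1, rois[r.roi_id - 1].sum()
        )
        if cover > 0.60:
            assert r.rejected and r.reason == "artifact"
        elif r.rejected:
            assert r.reason == "baseline-unstable"
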