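"""Pixel/ROI time-series processing of dynamic compression measurements.

A measurement is three minutes at 2 s cadence: one minute of baseline
contact, one minute of sustained compression (target 7.6 kPa), one minute
of recovery.  Processing follows a fixed recipe:

1. specular/artifact pixels are rejected from the demodulated DC magnitude
   (|value - image mean| > 2.5 SD at any timepoint or wavelength),
2. baseline reflectance is averaged over t in [10, 55] s for the
   melanin-index fit,
3. per-pixel inverted absorption is screened against the statistics of a
   ~20 mm central square (8 SD),
4. the circular field of view is partitioned into eight equal-area angular
   sectors (ROIs), averaged into tHb(t)/StO2(t) traces,
5. ROIs are dropped when artifacts cover more than 60% of their pixels or
   when the StO2 baseline is unstable (|slope| > 0.045 percentage points/s
   or RMS deviation from the linear fit > 0.4 points), and
6. the StO2 compression slope is fit over t in [65, 113] s.

StO2 is stored as a fraction everywhere; slopes and RMS figures convert to
percentage points (pp) at the reporting boundary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .spectral import LN10, ChromophoreTable
from .transport import SfdReflectance

__all__ = [
    "BASELINE_WINDOW_S",
    "COMPRESSION_FIT_WINDOW_S",
    "BASELINE_SLOPE_LIMIT_PP_S",
    "BASELINE_RMS_LIMIT_PP",
    "ROI_ARTIFACT_FRACTION_LIMIT",
    "SPECULAR_SD_LIMIT",
    "DYNAMIC_SD_LIMIT",
    "MeasurementTimeSeries",
    "RoiResult",
    "reject_specular_pixels",
    "baseline_average_rd",
    "reject_dynamic_pixels",
    "partition_rois",
    "screen_baseline",
    "compression_slope",
    "roi_artifact_screen",
    "unmix_hemoglobin_stack",
    "process_measurement",
]

logger = logging.getLogger(__name__)

#: closed time windows (s) for the baseline fit/average and compression fit
BASELINE_WINDOW_S = (10.0, 55.0)
COMPRESSION_FIT_WINDOW_S = (65.0, 113.0)
#: ROI baseline-stability thresholds (percentage points)
BASELINE_SLOPE_LIMIT_PP_S = 0.045
BASELINE_RMS_LIMIT_PP = 0.4
#: reject an ROI when artifacts cover strictly more than this fraction
ROI_ARTIFACT_FRACTION_LIMIT = 0.60
#: pixel rejection thresholds
SPECULAR_SD_LIMIT = 2.5
DYNAMIC_SD_LIMIT = 8.0
#: edge length of the central reference square for dynamic screening (mm)
CENTRAL_SQUARE_MM = 20.0


@dataclass
class MeasurementTimeSeries:
    """Reflectance movie plus geometry and timeline for one measurement.

    ``rd0``/``rd1`` have shape (n_times, n_wavelengths, ny, nx).  The
    timeline markers default to the protocol's 60/60/60 s phases.
    """

    times: np.ndarray  # s
    wavelengths: tuple[int, ...]
    rd0: np.ndarray
    rd1: np.ndarray
    pixel_pitch_mm: float
    fov_mask: np.ndarray  # bool (ny, nx)
    pressure_kpa: np.ndarray | None = None
    timeline: tuple[tuple[float, float], ...] = ((0, 60), (60, 120), (120, 180))

    def __post_init__(self) -> None:
        nt = self.times.size
        if self.rd0.shape[0] != nt or self.rd0.shape != self.rd1.shape:
            raise ValueError("rd stacks must match times and each other")
        if self.rd0.shape[1] != len(self.wavelengths):
            raise ValueError("rd stacks must have one plane per wavelength")
        dt = np.diff(self.times)
        if dt.size and not np.allclose(dt, dt[0]):
            raise ValueError("cadence must be uniform")
        if self.timeline[-1][1] > self.times[-1] + (dt[0] if dt.size else 0) + 1e-9:
            raise ValueError("timeline extends past the recording span")


@dataclass
class RoiResult:
    """Per-ROI hemodynamics traces, fits, and rejection bookkeeping."""

    roi_id: int  # 1-8
    thb_t: np.ndarray  # uM
    sto2_t: np.ndarray  # fraction
    baseline_slope: float  # pp/s
    baseline_rms: float  # pp
    compression_slope: float  # pp/s
    rejected: bool = False
    reason: str | None = None  # "baseline-unstable" | "artifact"


def _window_indices(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    """Frame indices with window-inclusive timestamps (closed interval)."""
    lo, hi = window
    return np.flatnonzero((times >= lo - 1e-9) & (times <= hi + 1e-9))


def reject_specular_pixels(
    m0_stack: np.ndarray,
    fov_mask: np.ndarray | None = None,
    *,
    sd_limit: float = SPECULAR_SD_LIMIT,
) -> np.ndarray:
    """Specular/outlier pixel mask from the DC magnitude stack.

    A pixel is rejected for the whole measurement if its value differs from
    the image mean by more than ``sd_limit`` standard deviations in *any*
    frame (any timepoint, any wavelength).  Statistics are per frame.
    Returns a boolean (ny, nx) mask, True = rejected.
    """
    stack = np.asarray(m0_stack, float)
    frames = stack.reshape(-1, *stack.shape[-2:])
    if fov_mask is None:
        fov_mask = np.ones(frames.shape[-2:], dtype=bool)
    vals = frames[:, fov_mask]
    mean = vals.mean(axis=1)[:, None]
    sd = vals.std(axis=1)[:, None]
    outlier = np.zeros(frames.shape[-2:], dtype=bool)
    with np.errstate(invalid="ignore"):
        hit = np.abs(vals - mean) > sd_limit * sd
    outlier[fov_mask] = hit.any(axis=0)
    if np.all(outlier[fov_mask]):
        raise RuntimeError("specular rejection removed every pixel")
    n = int(outlier.sum())
    if n:
        logger.info("specular rejection: %d pixel(s) removed", n)
    return outlier


def baseline_average_rd(
    series: MeasurementTimeSeries,
    rejected: np.ndarray | None = None,
    *,
    window: tuple[float, float] = BASELINE_WINDOW_S,
) -> dict[int, SfdReflectance]:
    """Scalar baseline reflectance per wavelength.

    Mean over retained field-of-view pixels and all frames whose timestamp
    lies in the closed ``window`` (boundary frames included).
    """
    idx = _window_indices(series.times, window)
    if idx.size < 2:
        raise ValueError("need at least two frames in the baseline window")
    keep = series.fov_mask if rejected is None else (series.fov_mask & ~rejected)
    if not keep.any():
        raise RuntimeError("no pixels retained for baseline averaging")
    out = {}
    for k, wl in enumerate(series.wavelengths):
        rd0 = float(np.nanmean(series.rd0[idx][:, k][:, keep]))
        rd1 = float(np.nanmean(series.rd1[idx][:, k][:, keep]))
        out[int(wl)] = SfdReflectance(rd0=rd0, rd1=rd1)
    return out


def reject_dynamic_pixels(
    mua_stack: np.ndarray,
    pixel_pitch_mm: float,
    fov_mask: np.ndarray | None = None,
    *,
    sd_limit: float = DYNAMIC_SD_LIMIT,
    square_mm: float = CENTRAL_SQUARE_MM,
) -> np.ndarray:
    """Artifact mask from the inverted absorption stack.

    A pixel is rejected if ``mua_sub`` at any wavelength or timepoint
    differs by more than ``sd_limit`` standard deviations from the mean of
    a ``square_mm`` square at the image center (statistics pooled over the
    whole measurement per wavelength).
    """
    stack = np.asarray(mua_stack, float)  # (nt, n_wl, ny, nx)
    ny, nx = stack.shape[-2:]
    half = max(1, int(round(square_mm / 2.0 / pixel_pitch_mm)))
    cy, cx = ny // 2, nx // 2
    ys = slice(max(0, cy - half), min(ny, cy + half))
    xs = slice(max(0, cx - half), min(nx, cx + half))
    if (ys.stop - ys.start) < 3 or (xs.stop - xs.start) < 3:
        raise ValueError("central reference region smaller than 3x3 pixels")
    center = stack[..., ys, xs].reshape(stack.shape[0], stack.shape[1], -1)
    mean = np.nanmean(center, axis=(0, 2))[:, None, None]
    sd = np.nanstd(center, axis=(0, 2))[:, None, None]
    with np.errstate(invalid="ignore"):
        hit = np.abs(stack - mean) > sd_limit * sd
    rejected = hit.any(axis=(0, 1))
    if fov_mask is not None:
        rejected &= fov_mask
    n = int(rejected.sum())
    if n:
        logger.info("dynamic rejection: %d pixel(s) removed", n)
    return rejected


def partition_rois(fov_mask: np.ndarray, *, n_rois: int = 8) -> np.ndarray:
    """Partition a circular field of view into equal-angle sectors.

    Sectors are numbered clockwise starting at image-up.  Returns a boolean
    array (n_rois, ny, nx); every field-of-view pixel belongs to exactly
    one sector.
    """
    mask = np.asarray(fov_mask, bool)
    if not mask.any():
        raise ValueError("empty field-of-view mask")
    ny, nx = mask.shape
    yy, xx = np.nonzero(mask)
    cy, cx = yy.mean(), xx.mean()
    r_equiv = np.sqrt(mask.sum() / np.pi)
    rr = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    # crude circularity check: nearly all pixels inside the equivalent disc
    if np.mean(rr <= r_equiv * 1.05) < 0.98:
        raise ValueError("field-of-view mask is not approximately circular")
    ys, xs = np.mgrid[0:ny, 0:nx]
    dy = ys - cy
    dx = xs - cx
    theta = np.mod(np.arctan2(dx, -dy), 2.0 * np.pi)  # clockwise from up
    sector = np.floor(theta / (2.0 * np.pi / n_rois)).astype(int) % n_rois
    rois = np.zeros((n_rois, ny, nx), dtype=bool)
    for k in range(n_rois):
        rois[k] = mask & (sector == k)
    return rois


def _linear_fit(times: np.ndarray, trace_pp: np.ndarray) -> tuple[float, float]:
    """(slope pp/s, rms deviation pp) of a least-squares line."""
    coef = np.polyfit(times, trace_pp, 1)
    resid = trace_pp - np.polyval(coef, times)
    return float(coef[0]), float(np.sqrt(np.mean(resid**2)))


def screen_baseline(
    times: np.ndarray,
    sto2_t: np.ndarray,
    *,
    window: tuple[float, float] = BASELINE_WINDOW_S,
    slope_limit: float = BASELINE_SLOPE_LIMIT_PP_S,
    rms_limit: float = BASELINE_RMS_LIMIT_PP,
) -> tuple[float, float, bool]:
    """Baseline-stability screen of an StO2 trace (fraction in, pp out).

    Returns (slope pp/s, rms pp, keep); keep requires |slope| <= 0.045 pp/s
    and RMS deviation from the fit <= 0.4 pp.
    """
    idx = _window_indices(np.asarray(times, float), window)
    if idx.size < 3:
        raise ValueError("need at least three baseline points")
    slope, rms = _linear_fit(times[idx], 100.0 * np.asarray(sto2_t, float)[idx])
    keep = abs(slope) <= slope_limit and rms <= rms_limit
    return slope, rms, keep


def compression_slope(
    times: np.ndarray,
    sto2_t: np.ndarray,
    *,
    window: tuple[float, float] = COMPRESSION_FIT_WINDOW_S,
) -> float:
    """StO2 slope (pp/s) over the compression fit window."""
    idx = _window_indices(np.asarray(times, float), window)
    if idx.size < 3:
        raise ValueError("need at least three points in the compression window")
    slope, _ = _linear_fit(times[idx], 100.0 * np.asarray(sto2_t, float)[idx])
    return slope


def roi_artifact_screen(
    roi_mask: np.ndarray,
    rejected: np.ndarray,
    *,
    limit: float = ROI_ARTIFACT_FRACTION_LIMIT,
) -> bool:
    """True (keep) unless rejected pixels cover strictly more than 60%."""
    n = int(roi_mask.sum())
    if n == 0:
        return False
    frac = float((roi_mask & rejected).sum()) / n
    return not frac > limit


def unmix_hemoglobin_stack(
    mua_stack: np.ndarray, table: ChromophoreTable | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized HbO/Hb unmixing of a (nt, n_wl, ny, nx) absorption stack.

    Returns (thb, sto2) arrays of shape (nt, ny, nx); concentrations in uM,
    saturation as a fraction.
    """
    table = table or ChromophoreTable()
    design = LN10 * table.matrix * 1e-6
    pinv = np.linalg.pinv(design)  # (2, n_wl)
    conc = np.einsum("cw,twyx->tcyx", pinv, np.asarray(mua_stack, float))
    thb = conc.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sto2 = np.where(thb != 0, conc[:, 0] / thb, np.nan)
    return thb, sto2


def process_measurement(
    series: MeasurementTimeSeries,
    collapsed_luts: Mapping[int, "CollapsedLUT"],
    table: ChromophoreTable | None = None,
) -> tuple[list[RoiResult], dict]:
    """Full dynamic pipeline for one measurement at a fixed melanin index.

    ``collapsed_luts`` maps wavelength to the 2-D table collapsed at the
    subject's optimized ``mua_epi(lambda)``.  Returns the eight ROI results
    and a diagnostics dict (masks and ROI geometry); rerunning is
    idempotent because every decision derives deterministically from the
    inputs.
    """
    table = table or ChromophoreTable(wavelengths=series.wavelengths)
    specular = reject_specular_pixels(series.rd0, series.fov_mask)

    nt, n_wl, ny, nx = series.rd0.shape
    fov = series.fov_mask
    mua = np.full_like(series.rd0, np.nan)
    for k, wl in enumerate(series.wavelengths):
        props = collapsed_luts[int(wl)].invert(
            series.rd0[:, k][:, fov].ravel(), series.rd1[:, k][:, fov].ravel()
        )
        plane = np.full((nt, ny, nx), np.nan)
        plane[:, fov] = props.mua.reshape(nt, -1)
        mua[:, k] = plane
    dynamic = reject_dynamic_pixels(mua, series.pixel_pitch_mm, series.fov_mask)
    rejected = specular | dynamic

    thb, sto2 = unmix_hemoglobin_stack(mua, table)
    rois = partition_rois(series.fov_mask)

    results: list[RoiResult] = []
    for k in range(rois.shape[0]):
        keep_px = rois[k] & ~rejected
        if keep_px.any():
            thb_t = thb[:, keep_px].mean(axis=1)
            sto2_t = sto2[:, keep_px].mean(axis=1)
        else:
            thb_t = np.full(nt, np.nan)
            sto2_t = np.full(nt, np.nan)
        result = RoiResult(
            roi_id=k + 1, thb_t=thb_t, sto2_t=sto2_t,
            baseline_slope=np.nan, baseline_rms=np.nan,
            compression_slope=np.nan,
        )
        if not roi_artifact_screen(rois[k], rejected):
            result.rejected = True
            result.reason = "artifact"
            logger.info("ROI %d rejected: artifact coverage > 60%%", result.roi_id)
        else:
            slope, rms, keep = screen_baseline(series.times, sto2_t)
            result.baseline_slope = slope
            result.baseline_rms = rms
            if not keep:
                result.rejected = True
                result.reason = "baseline-unstable"
                logger.info(
                    "ROI %d rejected: baseline slope %.4f pp/s rms %.3f pp",
                    result.roi_id, slope, rms,
                )
            else:
                result.compression_slope = compression_slope(
                    series.times, sto2_t
                )
        results.append(result)

    diagnostics = {
        "specular_mask": specular,
        "dynamic_mask": dynamic,
        "rejected_mask": rejected,
        "roi_masks": rois,
        "mua_stack": mua,
    }
    return results, diagnostics
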