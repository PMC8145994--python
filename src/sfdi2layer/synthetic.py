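"""Software phantoms and synthetic raw data for the full pipeline.

Everything the pipeline consumes can be generated here without any
external data:

* forward-simulated two-layer reflectance phantoms — the 8-level melanin
  battery (MI = 0 to 0.16 at tHb = 20 uM, StO2 = 75%) plus the epidermis
  thickness- and scattering-mismatch batteries used for sensitivity
  analysis;
* raw phase-shifted frame stacks (with a matching reference-phantom stack)
  whose demodulation and calibration reproduce a prescribed reflectance
  exactly in the noise-free limit;
* dynamic compression movies with planted hemodynamics (U-shaped tHb
  blanching, per-ROI StO2 compression slopes) mapped through the forward
  model, with the ground truth emitted alongside.

Noise defaults are declared presets (shot noise 0.5% of signal, read noise
0.1% of full scale), not fitted to any instrument.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .dynamics import MeasurementTimeSeries, partition_rois
from .lut import DEPI_CM, MUS_EPI_PRIME, WAVELENGTHS_NM, CollapsedLUT
from .spectral import ChromophoreTable, hemoglobin_to_mua, mi_to_mua_epi
from .transport import (
    ExitRecords,
    SfdReflectance,
    TransportMedium,
    run_white_mc,
    score_sfd,
)

__all__ = [
    "PHANTOM_MUS_SUB_PRIME",
    "MATCHED_MI_LEVELS",
    "PhantomSpec",
    "NoiseModel",
    "ForwardEngine",
    "matched_battery",
    "thickness_battery",
    "scattering_amplitude_battery",
    "scattering_power_battery",
    "make_raw_stack",
    "make_compression_movie",
]

#: subcutaneous reduced scattering of the software phantoms (cm^-1)
PHANTOM_MUS_SUB_PRIME = {662: 10.21, 735: 8.94, 859: 7.78}
#: the eight skin-pigmentation levels of the validation battery
MATCHED_MI_LEVELS = (0.0, 0.005, 0.01, 0.04, 0.07, 0.1, 0.13, 0.16)
#: thickness-mismatch battery: nine epidermal thicknesses (cm)
THICKNESS_MISMATCH_CM = tuple(np.linspace(0.003, 0.019, 9).round(6))
#: scattering-mismatch battery: amplitude / power scale factors
SCATTER_MISMATCH_SCALES = (0.7, 0.8, 0.9, 1.1, 1.2, 1.3)


@dataclass(frozen=True)
class PhantomSpec:
    """One software phantom: melanin level, geometry, scattering, blood."""

    mi: float
    depi: float = DEPI_CM
    mus_epi_prime: tuple[tuple[int, float], ...] = tuple(MUS_EPI_PRIME.items())
    mus_sub_prime: tuple[tuple[int, float], ...] = tuple(
        PHANTOM_MUS_SUB_PRIME.items()
    )
    thb: float = 20.0  # uM
    sto2: float = 0.75

    def __post_init__(self) -> None:
        if self.mi < 0 or self.depi <= 0 or self.thb <= 0:
            raise ValueError("phantom parameters must be positive (mi >= 0)")
        if not 0.0 <= self.sto2 <= 1.0:
            raise ValueError("sto2 must lie in [0, 1]")
        if any(v <= 0 for _, v in self.mus_epi_prime + self.mus_sub_prime):
            raise ValueError("scattering values must be positive")

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(w for w, _ in self.mus_sub_prime)

    def mus_epi(self, wl: int) -> float:
        return dict(self.mus_epi_prime)[wl]

    def mus_sub(self, wl: int) -> float:
        return dict(self.mus_sub_prime)[wl]

    def mua_epi(self, wl: int) -> float:
        return float(mi_to_mua_epi(self.mi, wl, depi=self.depi))

    def mua_sub(self, table: ChromophoreTable | None = None) -> np.ndarray:
        return hemoglobin_to_mua(self.thb, self.sto2, table)


def matched_battery(mi_levels: Sequence[float] = MATCHED_MI_LEVELS) -> list[PhantomSpec]:
    """The 8-phantom battery with geometry/scattering matched to the LUT."""
    return [PhantomSpec(mi=float(mi)) for mi in mi_levels]


def thickness_battery(
    mi_levels: Sequence[float] = MATCHED_MI_LEVELS,
    thicknesses: Sequence[float] = THICKNESS_MISMATCH_CM,
) -> list[PhantomSpec]:
    """Epidermis thickness mismatch: mua_epi co-varies to preserve MI."""
    return [
        PhantomSpec(mi=float(mi), depi=float(d))
        for d in thicknesses
        for mi in mi_levels
        if d != DEPI_CM
    ]


def scattering_amplitude_battery(
    mi_levels: Sequence[float] = MATCHED_MI_LEVELS,
    scales: Sequence[float] = SCATTER_MISMATCH_SCALES,
) -> list[PhantomSpec]:
    """Epidermal scattering amplitude scaled by +-10/20/30% at all wavelengths."""
    return [
        PhantomSpec(
            mi=float(mi),
            mus_epi_prime=tuple((w, s * v) for w, v in MUS_EPI_PRIME.items()),
        )
        for s in scales
        for mi in mi_levels
    ]


def scattering_power_battery(
    mi_levels: Sequence[float] = MATCHED_MI_LEVELS,
    scales: Sequence[float] = SCATTER_MISMATCH_SCALES,
) -> list[PhantomSpec]:
    """Epidermal scattering power b scaled by +-10/20/30%, anchored at 735 nm.

    The base power law is the fit through the three nominal epidermal
    values; scaling b moves mus'_epi(662) and mus'_epi(859) while leaving
    the 735 nm anchor unchanged.
    """
    from .spectral import fit_scatter_powerlaw

    wls = tuple(MUS_EPI_PRIME)
    fit = fit_scatter_powerlaw(list(MUS_EPI_PRIME.values()), wls, lambda0=735.0)
    anchor = MUS_EPI_PRIME[735]
    out = []
    for s in scales:
        scaled = tuple(
            (w, anchor * (w / 735.0) ** (-fit.power * s)) for w in wls
        )
        out.extend(
            PhantomSpec(mi=float(mi), mus_epi_prime=scaled) for mi in mi_levels
        )
    return out


class ForwardEngine:
    """White-MC forward simulator with record reuse across absorption changes.

    Phantoms that share geometry and scattering (e.g. the 8 MI levels of
    the matched battery) reuse a single white-MC record set; only the
    Beer-Lambert rescaling differs.  Seeds are derived deterministically
    from the base seed and the scattering/geometry key.
    """

    def __init__(self, n_photons: int = 1_000_000, seed: int = 0) -> None:
        self.n_photons = int(n_photons)
        self.seed = int(seed)
        self._cache: dict[tuple, ExitRecords] = {}

    #: transport-time subcutaneous absorption floor; phantom mua_sub derived
    #: from blood content always exceeds it, so rescaling never upweights
    MUA_SUB_FLOOR = 0.01

    def _records(self, depi: float, mus_epi: float, mus_sub: float) -> ExitRecords:
        key = (round(depi, 9), round(mus_epi, 9), round(mus_sub, 9))
        if key not in self._cache:
            child = (self.seed * 1_000_003 + zlib.crc32(repr(key).encode())) % (
                2**31 - 1
            )
            medium = TransportMedium.two_layer(depi, mus_epi, mus_sub)
            self._cache[key] = run_white_mc(
                medium, self.n_photons, child,
                mua_baseline=(0.0, self.MUA_SUB_FLOOR),
            )
        return self._cache[key]

    def forward_rd(
        self, spec: PhantomSpec, table: ChromophoreTable | None = None
    ) -> dict[int, SfdReflectance]:
        """Simulate Rd(0), Rd(0.1) per wavelength for one phantom."""
        table = table or ChromophoreTable(wavelengths=spec.wavelengths)
        mua_sub = spec.mua_sub(table)
        out = {}
        for k, wl in enumerate(spec.wavelengths):
            records = self._records(spec.depi, spec.mus_epi(wl), spec.mus_sub(wl))
            out[wl] = score_sfd(records, [spec.mua_epi(wl), float(mua_sub[k])])
        return out


def make_forward_rd(
    spec: PhantomSpec,
    engine: ForwardEngine,
    table: ChromophoreTable | None = None,
) -> dict[int, SfdReflectance]:
    """Functional wrapper over :meth:`ForwardEngine.forward_rd`."""
    return engine.forward_rd(spec, table)


# ---------------------------------------------------------------------------
# raw frame synthesis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Declared noise preset for synthetic raw data (all non-negative)."""

    shot_sd_frac: float = 0.005  # SD proportional to signal
    read_sd_frac: float = 0.001  # SD as a fraction of full scale
    n_specular: int = 0
    specular_radius_px: int = 4
    specular_gain: float = 5.0  # artifact brightness over full scale
    drift_frac_per_s: float = 0.0  # multiplicative baseline drift

    def __post_init__(self) -> None:
        if min(self.shot_sd_frac, self.read_sd_frac, self.n_specular,
               self.specular_radius_px, self.specular_gain) < 0:
            raise ValueError("noise parameters must be non-negative")

    @property
    def silent(self) -> bool:
        return (
            self.shot_sd_frac == 0 and self.read_sd_frac == 0
            and self.n_specular == 0 and self.drift_frac_per_s == 0
        )


def make_raw_stack(
    rd_truth: Mapping[int, SfdReflectance],
    rd_ref: Mapping[int, SfdReflectance],
    *,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch_mm: float = 0.8,
    fx_mm: float = 0.1,
    gain: float = 10_000.0,
    sensor_max: float = 65_535.0,
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthesize one measurement's raw frames plus a reference stack.

    Returns ``(frames, ref_frames, sidecar)``.  Each stack starts with
    three blank marker frames followed by three phase-shifted sinusoidal
    frames per wavelength; demodulating and calibrating the pair
    reproduces ``rd_truth`` exactly when the noise model is silent.
    Planted specular artifacts are recorded in the sidecar ground truth.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    ny, nx = shape
    wavelengths = sorted(rd_truth)
    x_mm = np.arange(nx) * pixel_pitch_mm
    phase_x = 2.0 * np.pi * fx_mm * x_mm

    artifact = np.zeros(shape, dtype=bool)
    for _ in range(noise.n_specular):
        cy, cx = rng.integers(0, ny), rng.integers(0, nx)
        yy, xx = np.mgrid[0:ny, 0:nx]
        artifact |= (yy - cy) ** 2 + (xx - cx) ** 2 <= noise.specular_radius_px**2

    def _stack(rd_map: Mapping[int, SfdReflectance], with_noise: bool) -> np.ndarray:
        frames = [np.zeros(shape) for _ in range(3)]  # blank markers
        for wl in wavelengths:
            rd = rd_map[wl]
            m0 = gain * np.broadcast_to(np.asarray(rd.rd0, float), shape)
            m1 = gain * np.broadcast_to(np.asarray(rd.rd1, float), shape)
            for p in range(3):
                img = m0 + m1 * np.cos(phase_x + 2.0 * np.pi * p / 3.0)[None, :]
                if with_noise:
                    img = img + rng.normal(0.0, 1.0, shape) * (
                        noise.shot_sd_frac * np.abs(img)
                    )
                    img = img + rng.normal(
                        0.0, noise.read_sd_frac * sensor_max, shape
                    )
                    img = np.where(
                        artifact, noise.specular_gain * sensor_max, img
                    )
                frames.append(np.clip(img, 0.0, sensor_max))
        return np.stack(frames)

    frames = _stack(rd_truth, with_noise=not noise.silent)
    ref_frames = _stack(rd_ref, with_noise=False)
    sidecar = {
        "wavelengths_nm": [int(w) for w in wavelengths],
        "fx_mm": float(fx_mm),
        "pixel_pitch_mm": float(pixel_pitch_mm),
        "frame_cadence_s": 2.0,
        "frames_per_measurement": 3 + 3 * len(wavelengths),
        "gain": float(gain),
        "sensor_max": float(sensor_max),
        "seed": int(seed),
        "truth": {
            "rd0": {int(w): np.asarray(rd_truth[w].rd0).tolist() for w in wavelengths},
            "rd1": {int(w): np.asarray(rd_truth[w].rd1).tolist() for w in wavelengths},
            "artifact_pixels": int(artifact.sum()),
            "artifact_mask_rows": artifact.any(axis=1).tolist(),
        },
    }
    sidecar["truth"]["artifact_mask"] = artifact
    return frames, ref_frames, sidecar


# ---------------------------------------------------------------------------
# dynamic compression movies
# ---------------------------------------------------------------------------


def make_compression_movie(
    collapsed_luts: Mapping[int, CollapsedLUT],
    *,
    thb_baseline: float = 20.0,
    sto2_baseline: float = 0.75,
    thb_dip: float = 4.0,
    sto2_slope_pp_s: float = -0.011,
    roi_slope_jitter_pp_s: float = 0.004,
    thb_heterogeneity_frac: float = 0.10,
    musp_sub: Mapping[int, float] = PHANTOM_MUS_SUB_PRIME,
    shape: tuple[int, int] = (64, 64),
    pixel_pitch_mm: float = 0.8,
    cadence_s: float = 2.0,
    duration_s: float = 180.0,
    rd_noise_frac: float = 0.0,
    noise: NoiseModel | None = None,
    table: ChromophoreTable | None = None,
    seed: int = 0,
) -> tuple[MeasurementTimeSeries, dict]:
    """Generate a reflectance movie of the 60/60/60 s compression protocol.

    Ground-truth hemodynamics are planted per ROI: tHb dips in a U-shape
    during compression (blanching, minimum mid-compression, recovery on
    release) and StO2 follows a linear trend during compression whose
    slope is ``sto2_slope_pp_s`` plus per-ROI jitter.  A smooth static
    spatial field modulates tHb by ``thb_heterogeneity_frac`` (RMS) so
    that, as in real tissue images, the spatial image variance dominates
    the temporal noise (StO2 is unaffected by the multiplicative field).
    Truth traces are returned alongside the series.
    """
    if thb_dip >= thb_baseline:
        raise ValueError("tHb dip must be smaller than the baseline tHb")
    noise = noise or NoiseModel(shot_sd_frac=rd_noise_frac, read_sd_frac=0.0)
    rng = np.random.default_rng(seed)
    wavelengths = tuple(sorted(musp_sub))
    table = table or ChromophoreTable(wavelengths=wavelengths)
    times = np.arange(0.0, duration_s, cadence_s)
    nt = times.size
    ny, nx = shape

    yy, xx = np.mgrid[0:ny, 0:nx]
    radius_px = min(ny, nx) / 2.0 - 1.0
    fov = (yy - (ny - 1) / 2.0) ** 2 + (xx - (nx - 1) / 2.0) ** 2 <= radius_px**2
    rois = partition_rois(fov)
    n_roi = rois.shape[0]

    slopes = sto2_slope_pp_s + rng.normal(0.0, roi_slope_jitter_pp_s, n_roi)

    in_comp = (times >= 60.0) & (times < 120.0)
    u = np.zeros(nt)
    u[in_comp] = np.sin(np.pi * (times[in_comp] - 60.0) / 60.0)
    thb_truth = np.tile(thb_baseline - thb_dip * u, (n_roi, 1))
    sto2_truth = np.full((n_roi, nt), sto2_baseline)
    for r in range(n_roi):
        ramp = np.where(in_comp, (times - 60.0) * slopes[r] / 100.0, 0.0)
        # release: linear return to baseline over 20 s
        post = times >= 120.0
        end_val = 60.0 * slopes[r] / 100.0
        ramp[post] = end_val * np.clip(1.0 - (times[post] - 120.0) / 20.0, 0.0, 1.0)
        sto2_truth[r] += ramp

    # per-pixel hemodynamics from ROI membership
    roi_index = np.full(shape, -1)
    for r in range(n_roi):
        roi_index[rois[r]] = r
    thb_px = np.zeros((nt, ny, nx))
    sto2_px = np.zeros((nt, ny, nx))
    inside = roi_index >= 0
    thb_px[:, inside] = thb_truth[roi_index[inside], :].T
    sto2_px[:, inside] = sto2_truth[roi_index[inside], :].T

    if thb_heterogeneity_frac > 0:
        from scipy.ndimage import zoom

        coarse = rng.normal(0.0, 1.0, (6, 6))
        fld = zoom(coarse, (ny / 6.0, nx / 6.0), order=3)[:ny, :nx]
        fld = 1.0 + thb_heterogeneity_frac * (fld - fld.mean()) / fld.std()
        thb_px *= np.clip(fld, 0.6, 1.4)[None, :, :]

    rd0 = np.empty((nt, len(wavelengths), ny, nx))
    rd1 = np.empty_like(rd0)
    design = np.asarray(table.matrix)
    for k, wl in enumerate(wavelengths):
        eps_hbo, eps_hb = design[k]
        mua = (
            np.log(10.0)
            * 1e-6
            * (eps_hbo * thb_px * sto2_px + eps_hb * thb_px * (1.0 - sto2_px))
        )
        mua[:, ~inside] = np.nan
        lut = collapsed_luts[wl]
        flat = mua[:, inside].ravel()
        fwd = lut.forward(flat, np.full(flat.size, float(musp_sub[wl])))
        r0 = np.full((nt, ny, nx), np.nan)
        r1 = np.full((nt, ny, nx), np.nan)
        r0[:, inside] = np.asarray(fwd.rd0).reshape(nt, -1)
        r1[:, inside] = np.asarray(fwd.rd1).reshape(nt, -1)
        rd0[:, k] = r0
        rd1[:, k] = r1

    if noise.shot_sd_frac > 0:
        rd0 += rng.normal(0.0, noise.shot_sd_frac, rd0.shape) * rd0
        rd1 += rng.normal(0.0, noise.shot_sd_frac, rd1.shape) * rd1
    if noise.drift_frac_per_s > 0:
        drift = 1.0 + noise.drift_frac_per_s * times
        rd0 *= drift[:, None, None, None]
        rd1 *= drift[:, None, None, None]

    artifact = np.zeros(shape, dtype=bool)
    for _ in range(noise.n_specular):
        cy = rng.integers(0, ny)
        cx = rng.integers(0, nx)
        artifact |= (yy - cy) ** 2 + (xx - cx) ** 2 <= noise.specular_radius_px**2
    artifact &= fov
    rd0[:, :, artifact] = np.nanmax(rd0) * noise.specular_gain
    rd1[:, :, artifact] = np.nanmax(rd1) * noise.specular_gain

    series = MeasurementTimeSeries(
        times=times,
        wavelengths=wavelengths,
        rd0=rd0,
        rd1=rd1,
        pixel_pitch_mm=pixel_pitch_mm,
        fov_mask=fov,
    )
    truth = {
        "times": times,
        "roi_masks": rois,
        "thb": thb_truth,
        "sto2": sto2_truth,
        "sto2_slopes_pp_s": slopes,
        "artifact_mask": artifact,
        "seed": int(seed),
    }
    return series, truth
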