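"""Raw-frame demodulation and calibration to diffuse reflectance.

Three sinusoidal illumination patterns per wavelength, phase shifted by
120 degrees, are demodulated pixelwise into the DC magnitude ``M(0)`` and
the AC magnitude ``M(0.1)``:

    M(0)   = (I1 + I2 + I3) / 3
    M(0.1) = sqrt(2)/3 * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)

Diffuse reflectance follows by ratioing against a reference phantom of
known optical properties measured with the same patterns:

    Rd(fx) = M(fx) / Mref(fx) * Rd_ref(fx)

with ``Rd_ref`` computed from the homogeneous Monte Carlo forward table.
Raw stacks travel as multi-page TIFF plus a YAML sidecar describing the
frame order; blank frames mark the start of each pattern sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
import yaml

from .lut import HomogeneousLUT
from .spectral import fit_scatter_powerlaw
from .transport import SfdReflectance

__all__ = [
    "FrameTriplet",
    "DemodulatedPair",
    "CalibrationSet",
    "demodulate",
    "calibrate",
    "reference_phantom_properties",
    "phantom_reference_rd",
    "saturation_mask",
    "find_blank_frames",
    "write_raw_stack",
    "read_raw_stack",
    "iter_triplets",
]

#: reference-phantom characterization: mua (cm^-1) and mus' (cm^-1) measured
#: at 690 and 830 nm by frequency-domain NIRS
REF_PHANTOM_MUA = {690: 0.047, 830: 0.052}
REF_PHANTOM_MUSP = {690: 7.1, 830: 5.3}


@dataclass(frozen=True)
class FrameTriplet:
    """Three equal-shape phase-shifted intensity frames at one wavelength."""

    i1: np.ndarray
    i2: np.ndarray
    i3: np.ndarray
    wavelength: float
    fx: float = 0.1  # mm^-1
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        if not (self.i1.shape == self.i2.shape == self.i3.shape):
            raise ValueError("frames must share a shape")
        for f in (self.i1, self.i2, self.i3):
            if np.any(f < 0):
                raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class DemodulatedPair:
    """DC and AC demodulation magnitudes, pixelwise."""

    m0: np.ndarray
    m1: np.ndarray


def demodulate(t: FrameTriplet) -> DemodulatedPair:
    """Three-phase demodulation; exact for ideal sinusoids at any phase."""
    i1, i2, i3 = (np.asarray(f, float) for f in (t.i1, t.i2, t.i3))
    m0 = (i1 + i2 + i3) / 3.0
    m1 = (math.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    return DemodulatedPair(m0=m0, m1=m1)


@dataclass
class CalibrationSet:
    """Reference-phantom demodulation and theoretical reflectance per wavelength."""

    phantom_mua: Mapping[int, float]
    phantom_musp: Mapping[int, float]
    mref0: Mapping[int, np.ndarray]
    mref1: Mapping[int, np.ndarray]
    rd_ref0: Mapping[int, float]
    rd_ref1: Mapping[int, float]


def calibrate(
    meas: DemodulatedPair,
    cal: CalibrationSet,
    wavelength: int,
    *,
    rel_floor: float = 1e-6,
) -> tuple[SfdReflectance, np.ndarray]:
    """Pixelwise ratio calibration to diffuse reflectance.

    Returns the reflectance image pair and a validity mask; pixels where the
    reference demodulation is zero or near zero (below ``rel_floor`` of its
    median) are flagged invalid and set to NaN.
    """
    mref0 = np.asarray(cal.mref0[wavelength], float)
    mref1 = np.asarray(cal.mref1[wavelength], float)
    valid = (mref0 > rel_floor * np.median(mref0)) & (
        mref1 > rel_floor * np.median(mref1)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rd0 = np.where(valid, meas.m0 / mref0 * cal.rd_ref0[wavelength], np.nan)
        rd1 = np.where(valid, meas.m1 / mref1 * cal.rd_ref1[wavelength], np.nan)
    # AC cannot physically exceed DC; noise can flip the ratio, so clamp AC
    return SfdReflectance(rd0=rd0, rd1=np.minimum(rd0, rd1)), valid


def reference_phantom_properties(
    wavelengths=(662, 735, 859),
    *,
    lambda0: float = 735.0,
) -> tuple[float, dict[int, float]]:
    """Interpolate the phantom's characterization to the device wavelengths.

    mua is taken as the mean of the two characterized values (assumed flat
    in wavelength); mus' follows the power law fit through the two
    characterized points.
    """
    mua = float(np.mean(list(REF_PHANTOM_MUA.values())))
    fit = fit_scatter_powerlaw(
        list(REF_PHANTOM_MUSP.values()), list(REF_PHANTOM_MUSP.keys()),
        lambda0=lambda0,
    )
    return mua, {int(w): float(fit(w)) for w in wavelengths}


def phantom_reference_rd(
    homogeneous: HomogeneousLUT,
    wavelengths=(662, 735, 859),
) -> dict[int, SfdReflectance]:
    """Theoretical Rd_ref(fx) per wavelength from the homogeneous forward LUT."""
    mua, musp = reference_phantom_properties(wavelengths)
    out = {}
    for wl in wavelengths:
        if not (
            homogeneous.mua_axis[0] <= mua <= homogeneous.mua_axis[-1]
            and homogeneous.musp_axis[0] <= musp[wl] <= homogeneous.musp_axis[-1]
        ):
            raise ValueError("phantom properties outside the LUT range")
        rd = homogeneous.forward(mua, musp[wl])
        out[int(wl)] = SfdReflectance(rd0=float(rd.rd0), rd1=float(rd.rd1))
    return out


def saturation_mask(frames: np.ndarray, sensor_max: float) -> np.ndarray:
    """True where any frame saturates (pixel at or above sensor maximum)."""
    return np.any(np.asarray(frames) >= sensor_max, axis=0)


def find_blank_frames(frames: np.ndarray, *, rel_threshold: float = 0.05) -> np.ndarray:
    """Indices of sequence-marker frames (mean below 5% of stack median).

    The device inserts blank frames into each projection sequence as a
    start-of-sequence marker.
    """
    frames = np.asarray(frames, float)
    means = frames.mean(axis=(1, 2))
    return np.flatnonzero(means < rel_threshold * np.median(means))


# ---------------------------------------------------------------------------
# raw stack I/O: multi-page TIFF + YAML sidecar
# ---------------------------------------------------------------------------


def write_raw_stack(path, frames: np.ndarray, sidecar: dict) -> None:
    """Write frames as multi-page TIFF with a ``.yaml`` sidecar next to it."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(frames))
    with open(path.with_suffix(".yaml"), "w") as fh:
        yaml.safe_dump(sidecar, fh)


def read_raw_stack(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    frames = tifffile.imread(path)
    with open(path.with_suffix(".yaml")) as fh:
        sidecar = yaml.safe_load(fh)
    return frames, sidecar


def iter_triplets(frames: np.ndarray, sidecar: dict):
    """Yield :class:`FrameTriplet` per (timepoint, wavelength) from a stack.

    The sidecar lists ``wavelengths_nm``, ``fx_mm``, ``frame_cadence_s`` and
    ``frames_per_measurement``; within one measurement the frame order is
    (wavelength-major, phase-minor) with any blank marker frames first.
    """
    wavelengths = sidecar["wavelengths_nm"]
    fx = float(sidecar.get("fx_mm", 0.1))
    cadence = float(sidecar.get("frame_cadence_s", 2.0))
    per_meas = int(sidecar.get("frames_per_measurement", 3 * len(wavelengths)))
    n_meas = frames.shape[0] // per_meas
    blanks = set(find_blank_frames(frames).tolist())
    for m in range(n_meas):
        base = m * per_meas
        idx = [i for i in range(base, base + per_meas) if i not in blanks]
        if len(idx) < 3 * len(wavelengths):
            raise ValueError(f"measurement {m}: missing frames after blank removal")
        for k, wl in enumerate(wavelengths):
            sel = idx[3 * k : 3 * k + 3]
            yield FrameTriplet(
                i1=frames[sel[0]], i2=frames[sel[1]], i3=frames[sel[2]],
                wavelength=float(wl), fx=fx, timestamp=m * cadence,
            )
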