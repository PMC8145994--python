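"""Monte Carlo lookup tables mapping optical properties to SFD reflectance.

Two table families are built from the white-MC engine in
:mod:`sfdi2layer.transport`:

* :class:`TwoLayerLUT` — per wavelength, a 3-D grid over epidermal
  absorption ``mua_epi`` (0–20 cm^-1, 21 values), subcutaneous absorption
  ``mua_sub`` (0.01–0.75 cm^-1, 75 values) and subcutaneous reduced
  scattering ``musp_sub`` (4–20 cm^-1, 17 values), with the epidermal
  scattering fixed per wavelength and the epidermis 110 um thick.  One
  white-MC run per ``musp_sub`` value is Beer-rescaled over the full
  21 x 75 absorption grid.
* :class:`HomogeneousLUT` — the conventional single-layer SFDI table over
  (``mua``, ``musp``), used both as the comparison inverse model and as the
  forward model for the reference-phantom calibration.

Inversion goes through scattered-data interpolation on the (Rd(0), Rd(0.1))
point cloud of a 2-D table: piecewise-linear on a Delaunay triangulation,
with out-of-gamut measurements flagged and clamped to the convex hull of
the table gamut.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import h5py
import numpy as np
from scipy.interpolate import (
    LinearNDInterpolator,
    RegularGridInterpolator,
    interp1d,
)
from scipy.spatial import ConvexHull, Delaunay

from . import __version__ as _version
from .transport import (
    SfdReflectance,
    TransportMedium,
    rescale_grid,
    run_white_mc,
)

__all__ = [
    "WAVELENGTHS_NM",
    "MUS_EPI_PRIME",
    "DEPI_CM",
    "default_mua_epi_axis",
    "default_mua_sub_axis",
    "default_musp_sub_axis",
    "OpticalProperties",
    "CollapsedLUT",
    "TwoLayerLUT",
    "HomogeneousLUT",
    "LUTSet",
    "build_two_layer_lut",
    "build_homogeneous_lut",
    "build_lut_set",
    "save_lut_set",
    "load_lut_set",
]

#: device emission wavelengths (nm)
WAVELENGTHS_NM = (662, 735, 859)
#: fixed epidermal reduced scattering per wavelength (cm^-1)
MUS_EPI_PRIME = {662: 22.16, 735: 16.89, 859: 11.62}
#: model epidermal thickness (cm); 110 um
DEPI_CM = 0.011


def default_mua_epi_axis() -> np.ndarray:
    """Epidermal absorption axis: 0 to 20 cm^-1 in 21 increments."""
    return np.linspace(0.0, 20.0, 21)


def default_mua_sub_axis() -> np.ndarray:
    """Subcutaneous absorption axis: 0.01 to 0.75 cm^-1 in 75 increments."""
    return np.linspace(0.01, 0.75, 75)


def default_musp_sub_axis() -> np.ndarray:
    """Subcutaneous reduced scattering axis: 4 to 20 cm^-1 in 17 increments."""
    return np.linspace(4.0, 20.0, 17)


@dataclass(frozen=True)
class OpticalProperties:
    """Recovered (mua, musp) pair, with an out-of-gamut flag from inversion."""

    mua: float | np.ndarray
    musp: float | np.ndarray
    in_gamut: bool | np.ndarray = True


class _TableInvertor:
    """Piecewise-linear inverse of a 2-D (mua, musp) -> (rd0, rd1) table.

    The forward map's gamut in (rd0, rd1) space is a curved quadrilateral;
    queries inside it are interpolated on the Delaunay triangulation of the
    grid points, queries outside are clamped to the nearest point of the
    gamut's convex hull (linear along the hull edge) and flagged.

    The triangulation uses the table's own grid nodes without refinement,
    matching the piecewise-linear discretization behavior of conventional
    two-frequency LUT pipelines.
    """

    def __init__(
        self,
        rd0: np.ndarray,
        rd1: np.ndarray,
        mua_axis: np.ndarray,
        musp_axis: np.ndarray,
    ) -> None:
        pts = np.column_stack([rd0.ravel(), rd1.ravel()])
        if not np.all(np.isfinite(pts)):
            raise ValueError("table contains non-finite reflectance values")
        mua_grid, musp_grid = np.meshgrid(mua_axis, musp_axis, indexing="ij")
        vals = np.column_stack([mua_grid.ravel(), musp_grid.ravel()])
        self._tri = Delaunay(pts)
        self._interp = LinearNDInterpolator(self._tri, vals)
        hull = ConvexHull(pts)
        self._hull_pts = pts[hull.vertices]
        self._hull_vals = vals[hull.vertices]

    def __call__(self, rd0, rd1) -> OpticalProperties:
        q = np.column_stack(
            [np.atleast_1d(np.asarray(rd0, float)).ravel(),
             np.atleast_1d(np.asarray(rd1, float)).ravel()]
        )
        if np.any(~np.isfinite(q)):
            raise ValueError("reflectance inputs must be finite")
        out = self._interp(q)
        bad = ~np.isfinite(out[:, 0])
        in_gamut = ~bad
        if np.any(bad):
            out[bad] = self._clamp_to_hull(q[bad])
        shape = np.shape(rd0)
        if shape == ():
            return OpticalProperties(
                float(out[0, 0]), float(out[0, 1]), bool(in_gamut[0])
            )
        return OpticalProperties(
            out[:, 0].reshape(shape), out[:, 1].reshape(shape),
            in_gamut.reshape(shape),
        )

    def _clamp_to_hull(self, q: np.ndarray) -> np.ndarray:
        a = self._hull_pts
        b = np.roll(self._hull_pts, -1, axis=0)
        va = self._hull_vals
        vb = np.roll(self._hull_vals, -1, axis=0)
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        # project each query on every hull edge, keep the closest
        t = np.clip(
            np.einsum("qed,ed->qe", q[:, None, :] - a[None], ab) / denom,
            0.0,
            1.0,
        )
        proj = a[None] + t[..., None] * ab[None]
        d2 = np.sum((proj - q[:, None, :]) ** 2, axis=-1)
        best = np.argmin(d2, axis=1)
        tb = t[np.arange(q.shape[0]), best]
        return va[best] * (1.0 - tb[:, None]) + vb[best] * tb[:, None]


@dataclass
class CollapsedLUT:
    """Conventional 2-D table over (mua_sub, musp_sub) at fixed top layer."""

    wavelength: float
    mua_axis: np.ndarray
    musp_axis: np.ndarray
    rd0: np.ndarray  # (n_mua, n_musp)
    rd1: np.ndarray
    mua_epi: float = 0.0
    _invertor: _TableInvertor | None = field(default=None, repr=False)
    _forward: RegularGridInterpolator | None = field(default=None, repr=False)

    def invert(self, rd0, rd1) -> OpticalProperties:
        """Recover (mua, musp) from a measured reflectance pair."""
        if self._invertor is None:
            self._invertor = _TableInvertor(
                self.rd0, self.rd1, self.mua_axis, self.musp_axis
            )
        return self._invertor(rd0, rd1)

    def forward(self, mua, musp) -> SfdReflectance:
        """Bilinear forward interpolation (mua, musp) -> (rd0, rd1)."""
        if self._forward is None:
            self._forward = RegularGridInterpolator(
                (self.mua_axis, self.musp_axis),
                np.stack([self.rd0, self.rd1], axis=-1),
            )
        scalar = np.ndim(mua) == 0 and np.ndim(musp) == 0
        pts = np.stack(
            np.broadcast_arrays(np.atleast_1d(mua), np.atleast_1d(musp)), axis=-1
        )
        out = self._forward(pts)
        if scalar:
            return SfdReflectance(rd0=float(out[0, 0]), rd1=float(out[0, 1]))
        return SfdReflectance(rd0=out[..., 0], rd1=out[..., 1])


def invert_rd(table: CollapsedLUT | "HomogeneousLUT", rd0, rd1) -> OpticalProperties:
    """Module-level convenience wrapper around ``table.invert``."""
    return table.invert(rd0, rd1)


@dataclass
class TwoLayerLUT:
    """3-D reflectance grids over (mua_epi, mua_sub, musp_sub), one wavelength."""

    wavelength: float
    mua_epi_axis: np.ndarray
    mua_sub_axis: np.ndarray
    musp_sub_axis: np.ndarray
    mus_epi_prime: float
    depi_model: float
    rd0_grid: np.ndarray  # (n_epi, n_sub, n_musp)
    rd1_grid: np.ndarray
    n_photons: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        expected = (
            self.mua_epi_axis.size,
            self.mua_sub_axis.size,
            self.musp_sub_axis.size,
        )
        if self.rd0_grid.shape != expected or self.rd1_grid.shape != expected:
            raise ValueError(
                f"grid shape {self.rd0_grid.shape} != axes shape {expected}"
            )
        for ax in (self.mua_epi_axis, self.mua_sub_axis, self.musp_sub_axis):
            if np.any(np.diff(ax) <= 0):
                raise ValueError("axes must be strictly increasing")
        if not (np.all(np.isfinite(self.rd0_grid)) and np.all(np.isfinite(self.rd1_grid))):
            raise ValueError("grids must be finite")

    def collapse(self, mua_epi: float) -> CollapsedLUT:
        """Linear interpolation along the mua_epi axis only -> 2-D table."""
        ax = self.mua_epi_axis
        if not ax[0] <= mua_epi <= ax[-1]:
            raise ValueError(
                f"mua_epi={mua_epi} outside table range [{ax[0]}, {ax[-1]}]"
            )
        f0 = interp1d(ax, self.rd0_grid, axis=0)
        f1 = interp1d(ax, self.rd1_grid, axis=0)
        return CollapsedLUT(
            wavelength=self.wavelength,
            mua_axis=self.mua_sub_axis,
            musp_axis=self.musp_sub_axis,
            rd0=f0(mua_epi),
            rd1=f1(mua_epi),
            mua_epi=float(mua_epi),
        )


@dataclass
class HomogeneousLUT:
    """Conventional single-layer SFDI table over (mua, musp)."""

    mua_axis: np.ndarray
    musp_axis: np.ndarray
    rd0: np.ndarray
    rd1: np.ndarray
    n_photons: int = 0
    seed: int = 0
    _invertor: _TableInvertor | None = field(default=None, repr=False)
    _forward: RegularGridInterpolator | None = field(default=None, repr=False)

    invert = CollapsedLUT.invert
    forward = CollapsedLUT.forward


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive independent child seeds (< 2**31) from one base seed."""
    ss = np.random.SeedSequence(int(seed))
    return [int(s) for s in ss.generate_state(n) % (2**31 - 1)]


#: polynomial degree for the regularization of the reflectance grids along
#: the reduced-scattering axis (see :func:`_smooth_along_musp`)
MUSP_SMOOTHING_DEGREE = 5


def _smooth_along_musp(grid: np.ndarray, musp_axis: np.ndarray,
                       degree: int = MUSP_SMOOTHING_DEGREE) -> np.ndarray:
    """Least-squares polynomial regularization along the musp axis.

    Each musp grid node comes from an independent Monte Carlo simulation,
    while the absorption axes of one node share a single record set (their
    noise is perfectly correlated and Beer-smooth).  Rd varies smoothly
    and monotonically with musp, so projecting the 17 node values onto a
    degree-5 polynomial basis suppresses the only independent noise
    component by roughly sqrt((degree+1)/n_nodes) at negligible bias.
    """
    x = (musp_axis - musp_axis.mean()) / (np.ptp(musp_axis) / 2.0)
    V = np.vander(x, degree + 1)
    flat = grid.reshape(-1, musp_axis.size)
    coef, *_ = np.linalg.lstsq(V, flat.T, rcond=None)
    return (V @ coef).T.reshape(grid.shape)


def build_two_layer_lut(
    wavelength: float,
    *,
    n_photons: int = 1_000_000,
    seed: int = 0,
    mua_epi_axis: np.ndarray | None = None,
    mua_sub_axis: np.ndarray | None = None,
    musp_sub_axis: np.ndarray | None = None,
    mus_epi_prime: float | None = None,
    depi: float = DEPI_CM,
    smooth_musp: bool = True,
) -> TwoLayerLUT:
    """Build the 3-D two-layer LUT for one wavelength.

    One white-MC simulation runs per ``musp_sub`` grid value (the epidermal
    scattering is fixed per wavelength); each record set is Beer-rescaled
    over the full (mua_epi, mua_sub) grid.  Unless ``smooth_musp`` is
    disabled the finished grids are regularized along the musp axis (the
    only grid direction with independent Monte Carlo noise).
    """
    mua_epi_axis = default_mua_epi_axis() if mua_epi_axis is None else np.asarray(mua_epi_axis, float)
    mua_sub_axis = default_mua_sub_axis() if mua_sub_axis is None else np.asarray(mua_sub_axis, float)
    musp_sub_axis = default_musp_sub_axis() if musp_sub_axis is None else np.asarray(musp_sub_axis, float)
    if mus_epi_prime is None:
        mus_epi_prime = MUS_EPI_PRIME[int(wavelength)]

    rd0 = np.empty((mua_epi_axis.size, mua_sub_axis.size, musp_sub_axis.size))
    rd1 = np.empty_like(rd0)
    seeds = _spawn_seeds(seed, musp_sub_axis.size)
    for j, musp in enumerate(musp_sub_axis):
        medium = TransportMedium.two_layer(depi, mus_epi_prime, float(musp))
        # transport at the grid-minimum subcutaneous absorption: roulette can
        # then retire deep excursions whose rescaled contribution is nil
        records = run_white_mc(
            medium, n_photons, seeds[j],
            mua_baseline=(0.0, float(mua_sub_axis[0])),
        )
        grids = rescale_grid(records, [mua_epi_axis, mua_sub_axis])
        rd0[:, :, j] = grids[0]
        rd1[:, :, j] = grids[1]
    if smooth_musp:
        rd0 = _smooth_along_musp(rd0, musp_sub_axis)
        rd1 = _smooth_along_musp(rd1, musp_sub_axis)
    return TwoLayerLUT(
        wavelength=float(wavelength),
        mua_epi_axis=mua_epi_axis,
        mua_sub_axis=mua_sub_axis,
        musp_sub_axis=musp_sub_axis,
        mus_epi_prime=float(mus_epi_prime),
        depi_model=float(depi),
        rd0_grid=rd0,
        rd1_grid=rd1,
        n_photons=int(n_photons),
        seed=int(seed),
    )


def build_homogeneous_lut(
    *,
    n_photons: int = 1_000_000,
    seed: int = 0,
    mua_axis: np.ndarray | None = None,
    musp_axis: np.ndarray | None = None,
    smooth_musp: bool = True,
) -> HomogeneousLUT:
    """Build the conventional homogeneous SFDI LUT (wavelength independent)."""
    mua_axis = default_mua_sub_axis() if mua_axis is None else np.asarray(mua_axis, float)
    musp_axis = default_musp_sub_axis() if musp_axis is None else np.asarray(musp_axis, float)
    rd0 = np.empty((mua_axis.size, musp_axis.size))
    rd1 = np.empty_like(rd0)
    seeds = _spawn_seeds(seed ^ 0x5F5F5F, musp_axis.size)
    for j, musp in enumerate(musp_axis):
        medium = TransportMedium.homogeneous(float(musp))
        records = run_white_mc(
            medium, n_photons, seeds[j], mua_baseline=(float(mua_axis[0]),)
        )
        grids = rescale_grid(records, [mua_axis])
        rd0[:, j] = grids[0]
        rd1[:, j] = grids[1]
    if smooth_musp:
        rd0 = _smooth_along_musp(rd0, musp_axis)
        rd1 = _smooth_along_musp(rd1, musp_axis)
    return HomogeneousLUT(
        mua_axis=mua_axis, musp_axis=musp_axis, rd0=rd0, rd1=rd1,
        n_photons=int(n_photons), seed=int(seed),
    )


@dataclass
class LUTSet:
    """All tables for one device configuration: 3 wavelengths + homogeneous."""

    two_layer: Mapping[int, TwoLayerLUT]
    homogeneous: HomogeneousLUT

    @property
    def wavelengths(self) -> tuple[int, ...]:
        return tuple(sorted(self.two_layer))


def build_lut_set(
    *,
    n_photons: int = 1_000_000,
    seed: int = 0,
    wavelengths: Sequence[int] = WAVELENGTHS_NM,
    musp_sub_axis: np.ndarray | None = None,
) -> LUTSet:
    """Build the full device LUT container (3x17 + 17 simulations)."""
    two_layer = {}
    for i, wl in enumerate(wavelengths):
        two_layer[int(wl)] = build_two_layer_lut(
            wl, n_photons=n_photons, seed=seed + 1000 * (i + 1),
            musp_sub_axis=musp_sub_axis,
        )
    homo = build_homogeneous_lut(
        n_photons=n_photons, seed=seed, musp_axis=musp_sub_axis
    )
    return LUTSet(two_layer=two_layer, homogeneous=homo)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_lut_set(path, lut_set: LUTSet) -> None:
    """Write every table, with provenance, into one HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["software_version"] = _version
        for wl, lut in lut_set.two_layer.items():
            g = f.create_group(f"two_layer/{int(wl)}")
            for name in ("mua_epi_axis", "mua_sub_axis", "musp_sub_axis",
                         "rd0_grid", "rd1_grid"):
                g.create_dataset(name, data=getattr(lut, name))
            g.attrs.update(
                wavelength=lut.wavelength,
                mus_epi_prime=lut.mus_epi_prime,
                depi_model=lut.depi_model,
                n_photons=lut.n_photons,
                seed=lut.seed,
            )
        g = f.create_group("homogeneous")
        for name in ("mua_axis", "musp_axis", "rd0", "rd1"):
            g.create_dataset(name, data=getattr(lut_set.homogeneous, name))
        g.attrs.update(
            n_photons=lut_set.homogeneous.n_photons, seed=lut_set.homogeneous.seed
        )


def load_lut_set(path) -> LUTSet:
    with h5py.File(path, "r") as f:
        two_layer = {}
        for key, g in f["two_layer"].items():
            two_layer[int(key)] = TwoLayerLUT(
                wavelength=float(g.attrs["wavelength"]),
                mua_epi_axis=g["mua_epi_axis"][()],
                mua_sub_axis=g["mua_sub_axis"][()],
                musp_sub_axis=g["musp_sub_axis"][()],
                mus_epi_prime=float(g.attrs["mus_epi_prime"]),
                depi_model=float(g.attrs["depi_model"]),
                rd0_grid=g["rd0_grid"][()],
                rd1_grid=g["rd1_grid"][()],
                n_photons=int(g.attrs["n_photons"]),
                seed=int(g.attrs["seed"]),
            )
        g = f["homogeneous"]
        homo = HomogeneousLUT(
            mua_axis=g["mua_axis"][()],
            musp_axis=g["musp_axis"][()],
            rd0=g["rd0"][()],
            rd1=g["rd1"][()],
            n_photons=int(g.attrs["n_photons"]),
            seed=int(g.attrs["seed"]),
        )
    return LUTSet(two_layer=two_layer, homogeneous=homo)
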