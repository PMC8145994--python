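"""Chromophore models and the melanin-index optimization.

The epidermis is modeled as containing a single absorber, melanin, whose
molar extinction follows the exponential spectrum
``eps_mel(lambda) = exp(-0.009*lambda + 12.93)``.  Because epidermal
thickness and absorption are strongly coupled in reflectance, the model
optimizes their product, the dimensionless *melanin index*

    MI = d_epi * mua_epi(662 nm),

i.e. the approximate optical thickness of the epidermis at 662 nm.  For a
candidate MI, the two-layer LUT is collapsed at the implied
``mua_epi(lambda)``, subcutaneous properties are inverted, and oxy/deoxy
hemoglobin concentrations are fit to ``mua_sub(lambda)`` by linear least
squares.  The MI minimizing the hemoglobin-fit mean squared error (or the
adjusted MSE, ``MSE/(1-StO2)``, for in-vivo data) is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .lut import DEPI_CM, LUTSet, CollapsedLUT, HomogeneousLUT
from .transport import SfdReflectance

__all__ = [
    "LN10",
    "ChromophoreTable",
    "Hemodynamics",
    "ScatterFit",
    "MIFitResult",
    "melanin_extinction",
    "mi_to_mua_epi",
    "fit_hemoglobin",
    "hemoglobin_to_mua",
    "fit_scatter_powerlaw",
    "default_mi_grid",
    "MIOptimizer",
    "optimize_mi",
]

LN10 = math.log(10.0)

#: Molar extinction coefficients of oxy- and deoxyhemoglobin (cm^-1 / M),
#: compiled from the standard tabulation of hemoglobin absorption spectra
#: (S. Prahl, Oregon Medical Laser Center), linearly interpolated to the
#: device wavelengths.  mua = ln(10) * eps * C with C in mol/L.
_EPS_HBO = {662: 315.4, 735: 417.9, 859: 1056.2}
_EPS_HB = {662: 3144.7, 735: 1203.0, 859: 691.4}


def melanin_extinction(wavelength_nm) -> np.ndarray | float:
    """Melanin extinction spectrum ``exp(-0.009*lambda + 12.93)``."""
    return np.exp(-0.009 * np.asarray(wavelength_nm, float) + 12.93)


@dataclass(frozen=True)
class ChromophoreTable:
    """Extinction coefficients at the device wavelengths (cm^-1 / M)."""

    wavelengths: tuple[int, ...] = (662, 735, 859)
    eps_hbo: tuple[float, ...] = ()
    eps_hb: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not self.eps_hbo:
            object.__setattr__(
                self, "eps_hbo", tuple(_EPS_HBO[w] for w in self.wavelengths)
            )
        if not self.eps_hb:
            object.__setattr__(
                self, "eps_hb", tuple(_EPS_HB[w] for w in self.wavelengths)
            )
        if len(self.wavelengths) < 3:
            raise ValueError("at least three wavelengths required")
        if any(e <= 0 for e in self.eps_hbo + self.eps_hb):
            raise ValueError("extinction coefficients must be positive")

    @property
    def matrix(self) -> np.ndarray:
        """(n_wavelengths, 2) extinction matrix [eps_HbO, eps_Hb]."""
        return np.column_stack([self.eps_hbo, self.eps_hb])

    def melanin_eps(self) -> np.ndarray:
        return melanin_extinction(np.asarray(self.wavelengths, float))


def mi_to_mua_epi(
    mi: float, wavelength_nm, *, depi: float = DEPI_CM
) -> np.ndarray | float:
    """Epidermal absorption implied by a melanin index.

    ``mua_epi(662) = MI / depi`` and the other wavelengths follow the
    melanin spectrum: ``mua_epi(lam) = mua_epi(662) * exp(-0.009*(lam-662))``.
    """
    if mi < 0:
        raise ValueError("melanin index must be >= 0")
    lam = np.asarray(wavelength_nm, float)
    return (mi / depi) * np.exp(-0.009 * (lam - 662.0))


@dataclass(frozen=True)
class Hemodynamics:
    """Hemoglobin unmixing result for one mua_sub spectrum."""

    c_hbo: float  # uM
    c_hb: float  # uM
    residuals: np.ndarray  # cm^-1, one per wavelength
    mse: float  # cm^-2
    adj_mse: float  # cm^-2; +inf where StO2 >= 1 (undefined)

    @property
    def thb(self) -> float:
        return self.c_hbo + self.c_hb

    @property
    def sto2(self) -> float:
        return self.c_hbo / self.thb if self.thb != 0 else float("nan")

    @property
    def physiological(self) -> bool:
        """True when StO2 falls in [0, 1] (non-negative concentrations)."""
        return bool(0.0 <= self.sto2 <= 1.0)


def hemoglobin_to_mua(
    thb_uM: float, sto2: float, table: ChromophoreTable | None = None
) -> np.ndarray:
    """Forward map (tHb, StO2) -> mua(lambda) in cm^-1."""
    table = table or ChromophoreTable()
    c = np.array([thb_uM * sto2, thb_uM * (1.0 - sto2)]) * 1e-6  # mol/L
    return LN10 * table.matrix @ c


def fit_hemoglobin(
    mua_sub: Sequence[float], table: ChromophoreTable | None = None
) -> Hemodynamics:
    """Unconstrained linear least squares of mua_sub against HbO/Hb spectra.

    Residuals are per-wavelength absorption errors (cm^-1); the mean squared
    error averages their squares.  The adjusted MSE divides by ``1 - StO2``
    and is +inf (undefined) when StO2 falls outside [0, 1) — saturations
    above 100% or below 0% imply negative chromophore concentrations — which
    excludes those solutions from any argmin taken over it.
    """
    table = table or ChromophoreTable()
    mua = np.asarray(mua_sub, float)
    if mua.shape != (len(table.wavelengths),):
        raise ValueError(
            f"expected {len(table.wavelengths)} absorption values, got {mua.shape}"
        )
    if not np.all(np.isfinite(mua)):
        raise ValueError("absorption values must be finite")
    design = LN10 * table.matrix * 1e-6  # concentrations in uM
    c, *_ = np.linalg.lstsq(design, mua, rcond=None)
    resid = mua - design @ c
    mse = float(np.mean(resid**2))
    c_hbo, c_hb = float(c[0]), float(c[1])
    thb = c_hbo + c_hb
    sto2 = c_hbo / thb if thb != 0 else float("nan")
    adj = (
        mse / (1.0 - sto2)
        if np.isfinite(sto2) and 0.0 <= sto2 < 1.0
        else float("inf")
    )
    return Hemodynamics(c_hbo=c_hbo, c_hb=c_hb, residuals=resid, mse=mse, adj_mse=adj)


@dataclass(frozen=True)
class ScatterFit:
    """Power-law scattering fit mus'(lambda) = A * (lambda/lambda0)^-b."""

    amplitude: float  # cm^-1 at lambda0
    power: float
    lambda0: float = 735.0

    def __call__(self, wavelength_nm) -> np.ndarray | float:
        lam = np.asarray(wavelength_nm, float)
        return self.amplitude * (lam / self.lambda0) ** (-self.power)


def fit_scatter_powerlaw(
    musp: Sequence[float],
    wavelengths: Sequence[float],
    *,
    lambda0: float = 735.0,
) -> ScatterFit:
    """Least-squares fit of log(mus') against log(lambda/lambda0)."""
    musp = np.asarray(musp, float)
    lam = np.asarray(wavelengths, float)
    if musp.size < 2 or musp.size != lam.size:
        raise ValueError("need >= 2 (wavelength, musp) pairs")
    if np.any(musp <= 0):
        raise ValueError("mus' must be positive")
    x = np.log(lam / lambda0)
    coef = np.polyfit(x, np.log(musp), 1)
    return ScatterFit(amplitude=float(np.exp(coef[1])), power=float(-coef[0]),
                      lambda0=lambda0)


# ---------------------------------------------------------------------------
# melanin-index optimization
# ---------------------------------------------------------------------------


def default_mi_grid() -> np.ndarray:
    """161 evenly spaced MI values on [0, 0.176] (inclusive)."""
    return np.linspace(0.0, 0.176, 161)


@dataclass
class MIFitResult:
    """Full MI-grid curves plus the selected melanin index."""

    mi_grid: np.ndarray
    mua_sub: np.ndarray  # (n_mi, n_wavelengths)
    musp_sub: np.ndarray
    in_gamut: np.ndarray  # (n_mi, n_wavelengths) bool
    thb: np.ndarray  # uM, per MI
    sto2: np.ndarray  # fraction, per MI
    mse: np.ndarray  # cm^-2, per MI
    adj_mse: np.ndarray
    mode: str  # "mse" or "adjusted"
    selected_index: int

    @property
    def mi(self) -> float:
        """The selected melanin index."""
        return float(self.mi_grid[self.selected_index])

    @property
    def hemodynamics(self) -> Hemodynamics:
        i = self.selected_index
        hbo = self.thb[i] * self.sto2[i]
        hb = self.thb[i] - hbo
        return Hemodynamics(
            c_hbo=hbo, c_hb=hb, residuals=np.full(self.mua_sub.shape[1], np.nan),
            mse=float(self.mse[i]), adj_mse=float(self.adj_mse[i]),
        )

    def optical_properties(self) -> tuple[np.ndarray, np.ndarray]:
        """(mua_sub(lambda), musp_sub(lambda)) at the selected MI."""
        i = self.selected_index
        return self.mua_sub[i].copy(), self.musp_sub[i].copy()


class MIOptimizer:
    """Melanin-index grid search against a two-layer LUT set.

    Collapsed tables (and their inversion triangulations) are cached per
    (MI, wavelength), so repeated fits — per measurement, per software
    phantom — reuse the expensive geometry.
    """

    def __init__(
        self,
        lut_set: LUTSet,
        mi_grid: np.ndarray | None = None,
        table: ChromophoreTable | None = None,
    ) -> None:
        self.lut_set = lut_set
        self.mi_grid = default_mi_grid() if mi_grid is None else np.asarray(mi_grid, float)
        if np.any(self.mi_grid < 0) or np.any(np.diff(self.mi_grid) <= 0):
            raise ValueError("MI grid must be non-negative and strictly increasing")
        self.table = table or ChromophoreTable(
            wavelengths=tuple(lut_set.wavelengths)
        )
        self._collapsed: dict[tuple[int, int], CollapsedLUT] = {}

    def collapsed(self, mi_index: int, wavelength: int) -> CollapsedLUT:
        key = (mi_index, wavelength)
        if key not in self._collapsed:
            lut = self.lut_set.two_layer[wavelength]
            mua_epi = float(
                mi_to_mua_epi(self.mi_grid[mi_index], wavelength, depi=lut.depi_model)
            )
            self._collapsed[key] = lut.collapse(mua_epi)
        return self._collapsed[key]

    def fit(
        self,
        rd_avg: Mapping[int, SfdReflectance],
        *,
        use_adjusted: bool = False,
    ) -> MIFitResult:
        """Grid-search MI for one averaged reflectance measurement.

        ``rd_avg`` maps wavelength -> scalar :class:`SfdReflectance` (the
        baseline average).  Selection minimizes the MSE curve, or the
        adjusted MSE when ``use_adjusted`` (ties break to the smallest MI,
        which argmin's first-hit convention provides on an ascending grid).

        MI values whose inversion fell out of the table gamut at any
        wavelength are excluded from the argmin (their hull-clamped
        absorption is pinned to the axis boundary, which manufactures
        spurious near-zero spectral-fit residuals); the full curves are
        retained either way.  If no MI inverts cleanly the argmin falls
        back to the whole grid.
        """
        wls = self.lut_set.wavelengths
        n_mi = self.mi_grid.size
        mua = np.empty((n_mi, len(wls)))
        musp = np.empty_like(mua)
        gamut = np.empty(mua.shape, dtype=bool)
        thb = np.empty(n_mi)
        sto2 = np.empty(n_mi)
        mse = np.empty(n_mi)
        adj = np.empty(n_mi)
        for i in range(n_mi):
            for k, wl in enumerate(wls):
                meas = rd_avg[wl]
                props = self.collapsed(i, wl).invert(meas.rd0, meas.rd1)
                mua[i, k] = props.mua
                musp[i, k] = props.musp
                gamut[i, k] = props.in_gamut
            hemo = fit_hemoglobin(mua[i], self.table)
            thb[i] = hemo.thb
            sto2[i] = hemo.sto2
            mse[i] = hemo.mse
            adj[i] = hemo.adj_mse
        if not gamut.any(axis=1).any():
            raise RuntimeError("inversion failed (out of gamut) at every MI")
        curve = adj if use_adjusted else mse
        valid = gamut.all(axis=1)
        selected = int(
            np.argmin(np.where(valid, curve, np.inf)) if valid.any()
            else np.argmin(curve)
        )
        return MIFitResult(
            mi_grid=self.mi_grid.copy(), mua_sub=mua, musp_sub=musp,
            in_gamut=gamut, thb=thb, sto2=sto2, mse=mse, adj_mse=adj,
            mode="adjusted" if use_adjusted else "mse",
            selected_index=selected,
        )


def optimize_mi(
    rd_avg: Mapping[int, SfdReflectance],
    lut_set: LUTSet,
    mi_grid: np.ndarray | None = None,
    *,
    use_adjusted: bool = False,
    table: ChromophoreTable | None = None,
) -> MIFitResult:
    """One-shot MI optimization (see :class:`MIOptimizer` for batch reuse)."""
    return MIOptimizer(lut_set, mi_grid, table).fit(rd_avg, use_adjusted=use_adjusted)


def invert_homogeneous(
    rd: Mapping[int, SfdReflectance],
    homogeneous: HomogeneousLUT,
    table: ChromophoreTable | None = None,
) -> tuple[Hemodynamics, np.ndarray, np.ndarray]:
    """Single-layer inversion + hemoglobin fit (the comparison model)."""
    table = table or ChromophoreTable(wavelengths=tuple(sorted(rd)))
    mua = np.empty(len(rd))
    musp = np.empty_like(mua)
    for k, wl in enumerate(sorted(rd)):
        props = homogeneous.invert(rd[wl].rd0, rd[wl].rd1)
        mua[k] = props.mua
        musp[k] = props.musp
    return fit_hemoglobin(mua, table), mua, musp
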