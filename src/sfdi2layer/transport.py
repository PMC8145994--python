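"""Layered white Monte Carlo photon transport for spatial frequency domain imaging.

Simulates a collimated pencil beam normally incident on a stack of turbid
layers, with Henyey-Greenstein scattering and unpolarized Fresnel reflection
at the top surface.  Photons are traced *without* absorption ("white" Monte
Carlo) while the geometric pathlength travelled in every layer is recorded
for each photon that escapes the top surface.  Any combination of per-layer
absorption coefficients can then be applied after the fact through
Beer-Lambert weights, so a single simulation serves an entire absorption
grid.

Diffuse reflectance is scored natively in the spatial frequency domain: the
pencil-beam response is radially symmetric, so the reflectance at spatial
frequency ``fx`` under 1-D sinusoidal illumination is the Hankel transform
of the point-spread response, estimated per photon as ``J0(2*pi*fx*rho)``
with ``rho`` the exit radius.  At ``fx = 0`` this reduces to the total
diffuse reflectance.

Units: all lengths cm, all optical coefficients cm^-1 internally.  Spatial
frequencies are mm^-1 at public interfaces (the conventional SFDI unit) and
converted to cm^-1 internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Sequence

import numpy as np
from numba import njit
from scipy.special import j0

__all__ = [
    "Layer",
    "TransportMedium",
    "PhotonExitRecord",
    "ExitRecords",
    "SfdReflectance",
    "run_white_mc",
    "score_sfd",
    "DEFAULT_G",
    "DEFAULT_N",
    "SEMI_INFINITE_THICKNESS_CM",
]

# Tissue-optics defaults shared by every simulation in this package.
DEFAULT_G = 0.8
DEFAULT_N = 1.4
#: thickness used for the "semi-infinite" bottom layer; ~40 transport mean
#: free paths at the softest scattering considered, so it acts as an
#: absorbing far boundary for the few photons that diffuse that deep.
SEMI_INFINITE_THICKNESS_CM = 10.0

# public interfaces use mm^-1 for fx; internal math uses cm^-1
MM_PER_CM = 10.0


@dataclass(frozen=True)
class Layer:
    """One turbid layer: thickness (cm), reduced scattering (cm^-1), g, n."""

    thickness: float
    mus_prime: float
    g: float = DEFAULT_G
    n: float = DEFAULT_N

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"layer thickness must be > 0, got {self.thickness}")
        if not self.mus_prime > 0:
            raise ValueError(f"mus_prime must be > 0, got {self.mus_prime}")
        if not 0.0 <= self.g < 1.0:
            raise ValueError(f"anisotropy must satisfy 0 <= g < 1, got {self.g}")
        if self.n < 1.0:
            raise ValueError(f"refractive index must be >= 1, got {self.n}")

    @property
    def mus(self) -> float:
        """Scattering coefficient via the similarity relation mus = mus'/(1-g)."""
        return self.mus_prime / (1.0 - self.g)


@dataclass(frozen=True)
class TransportMedium:
    """Ordered layer stack (top first) with the ambient index above it.

    Internal interfaces are index matched (all layers share ``n``); only the
    top surface refracts/reflects.  The bottom of the deepest layer is an
    absorbing boundary: photons crossing it are lost.
    """

    layers: tuple[Layer, ...]
    ambient_index: float = 1.0

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("medium must have at least one layer")
        if self.ambient_index < 1.0:
            raise ValueError("ambient index must be >= 1")
        ns = {layer.n for layer in self.layers}
        if len(ns) > 1:
            raise ValueError(
                "layers must share a refractive index (index-matched internal "
                f"interfaces); got {sorted(ns)}"
            )
        object.__setattr__(self, "layers", tuple(self.layers))

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def relative_index(self) -> float:
        """Tissue index relative to ambient at the top surface."""
        return self.layers[0].n / self.ambient_index

    def boundaries(self) -> np.ndarray:
        """Depths of the layer interfaces, ``[0, d1, d1+d2, ...]`` (cm)."""
        return np.concatenate([[0.0], np.cumsum([l.thickness for l in self.layers])])

    @staticmethod
    def two_layer(
        depi: float,
        mus_epi_prime: float,
        mus_sub_prime: float,
        *,
        d_sub: float = SEMI_INFINITE_THICKNESS_CM,
        g: float = DEFAULT_G,
        n: float = DEFAULT_N,
    ) -> "TransportMedium":
        """Epidermis-over-subcutaneous stack used throughout this package."""
        return TransportMedium(
            layers=(
                Layer(depi, mus_epi_prime, g, n),
                Layer(d_sub, mus_sub_prime, g, n),
            )
        )

    @staticmethod
    def homogeneous(
        mus_prime: float,
        *,
        thickness: float = SEMI_INFINITE_THICKNESS_CM,
        g: float = DEFAULT_G,
        n: float = DEFAULT_N,
    ) -> "TransportMedium":
        return TransportMedium(layers=(Layer(thickness, mus_prime, g, n),))


class PhotonExitRecord(NamedTuple):
    """One photon escaping the top surface."""

    exit_weight: float
    exit_radius: float  # cm
    pathlengths: np.ndarray  # cm, one entry per layer


@dataclass
class ExitRecords:
    """Column-oriented collection of :class:`PhotonExitRecord`.

    ``weights[i]``, ``radii[i]`` and ``pathlengths[i, :]`` describe exit
    event ``i``; ``photon_index[i]`` identifies the launched photon it
    belongs to (one photon can score several surface encounters, whose
    contributions are correlated).  ``n_photons`` is the number of photons
    *launched*, which normalizes reflectance estimates.
    """

    weights: np.ndarray
    radii: np.ndarray
    pathlengths: np.ndarray
    photon_index: np.ndarray
    n_photons: int
    seed: int
    medium: TransportMedium = field(repr=False)
    #: per-layer absorption already applied during transport; scoring at a
    #: target absorption rescales by exp(-(mua - baseline) . L)
    mua_baseline: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mua_baseline is None:
            self.mua_baseline = np.zeros(self.pathlengths.shape[1])

    def __len__(self) -> int:
        return self.weights.size

    def __iter__(self) -> Iterator[PhotonExitRecord]:
        for i in range(len(self)):
            yield PhotonExitRecord(
                float(self.weights[i]), float(self.radii[i]), self.pathlengths[i]
            )

    @property
    def n_layers(self) -> int:
        return self.pathlengths.shape[1]


@dataclass(frozen=True)
class SfdReflectance:
    """Diffuse reflectance at the device's two spatial frequencies.

    ``rd0``/``rd1`` may be scalars (LUT entries, ROI averages) or images.
    ``fx_values`` are in mm^-1; ``mc_standard_error`` is the Monte Carlo
    standard error per frequency where applicable (NaN otherwise).
    """

    rd0: np.ndarray | float
    rd1: np.ndarray | float
    fx_values: tuple[float, float] = (0.0, 0.1)
    mc_standard_error: tuple[float, float] = (float("nan"), float("nan"))

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.rd0) < np.asarray(self.rd1) - 1e-12):
            raise ValueError("rd1 must not exceed rd0 (AC cannot exceed DC)")


def save_records(path, records: ExitRecords) -> None:
    """Archive an exit-record set (HDF5) with its provenance metadata."""
    import h5py

    from . import __version__

    with h5py.File(path, "w") as f:
        for name in ("weights", "radii", "pathlengths", "photon_index"):
            f.create_dataset(name, data=getattr(records, name))
        f.create_dataset("mua_baseline", data=records.mua_baseline)
        f.attrs["n_photons"] = records.n_photons
        f.attrs["seed"] = records.seed
        f.attrs["software_version"] = __version__
        m = records.medium
        f.attrs["ambient_index"] = m.ambient_index
        f.create_dataset(
            "medium_layers",
            data=np.array(
                [[l.thickness, l.mus_prime, l.g, l.n] for l in m.layers]
            ),
        )


def load_records(path) -> ExitRecords:
    import h5py

    with h5py.File(path, "r") as f:
        layers = tuple(
            Layer(thickness=row[0], mus_prime=row[1], g=row[2], n=row[3])
            for row in f["medium_layers"][()]
        )
        return ExitRecords(
            weights=f["weights"][()],
            radii=f["radii"][()],
            pathlengths=f["pathlengths"][()],
            photon_index=f["photon_index"][()],
            n_photons=int(f.attrs["n_photons"]),
            seed=int(f.attrs["seed"]),
            medium=TransportMedium(
                layers=layers, ambient_index=float(f.attrs["ambient_index"])
            ),
            mua_baseline=f["mua_baseline"][()],
        )


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------


@njit(cache=True, fastmath=True)
def _fresnel_internal(ci: float, n_rel: float) -> float:
    """Unpolarized reflectance for a photon hitting the surface from inside.

    ``ci`` is the incidence cosine (>0), ``n_rel`` the internal/external
    index ratio.  Returns 1.0 beyond the critical angle.
    """
    si = math.sqrt(max(0.0, 1.0 - ci * ci))
    st = n_rel * si
    if st >= 1.0:
        return 1.0
    ct = math.sqrt(1.0 - st * st)
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (n_rel * ct - ci) / (n_rel * ct + ci)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=True, fastmath=True, inline="always")
def _rng_next(state):
    """xorshift64* step; returns (new_state, uniform in (0, 1))."""
    state ^= state >> np.uint64(12)
    state ^= state << np.uint64(25)
    state &= np.uint64(0xFFFFFFFFFFFFFFFF)
    state ^= state >> np.uint64(27)
    x = (state * np.uint64(0x2545F4914F6CDD1D)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    # take the top 53 bits; add 1 ulp-scale offset so u > 0 strictly
    u = (np.float64(x >> np.uint64(11)) + 0.5) * (1.0 / 9007199254740992.0)
    return state, u


@njit(cache=True, fastmath=True)
def _seed_state(seed):
    """Expand a small integer seed into a full xorshift64* state (splitmix64)."""
    z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & np.uint64(
        0xFFFFFFFFFFFFFFFF
    )
    z = z ^ (z >> np.uint64(31))
    if z == np.uint64(0):
        z = np.uint64(0x9E3779B97F4A7C15)
    return z


#: Russian-roulette parameters for the weight-split surface scoring: when a
#: photon's residual weight falls below the threshold it survives with the
#: given chance (weight boosted accordingly) or terminates.
ROULETTE_THRESHOLD = 1e-2
ROULETTE_SURVIVAL = 0.1


@njit(cache=True, fastmath=True)
def _trace_white(seed, n_photons, z_bounds, mus, g_eff, layer_of, mua_base,
                 n_rel, out_w, out_r, out_L, out_id):
    """Trace photons at mu_a = 0, returning exit radii and per-layer paths.

    The geometry is described as a stack of *regions*: contiguous z-slabs
    with per-region scattering coefficient ``mus``, anisotropy ``g_eff``
    and the index ``layer_of`` of the physical layer whose pathlength tally
    the region feeds.  This lets a deep portion of a layer use the
    similarity-equivalent isotropic walk (g=0, mus = mus') while the
    near-surface portion keeps the exact Henyey-Greenstein kernel.

    Surface scoring splits the photon weight at every top-surface
    encounter: the transmitted fraction ``w * (1 - R(theta))`` is scored as
    an exit record and the photon continues inward with the reflected
    weight ``w * R(theta)``.  Low-weight survivors are terminated by
    Russian roulette.  Compared with analog (all-or-nothing) exit sampling
    this removes the Bernoulli exit noise entirely, at the cost of a few
    records per photon.

    Output arrays are preallocated by the caller; returns ``n_exit`` or -1
    if capacity was exhausted (caller retries with larger buffers).
    """
    rng = _seed_state(seed)
    n_regions = mus.size
    n_layers = layer_of[-1] + 1
    rsp = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
    w0 = 1.0 - rsp
    inv_mus = 1.0 / mus
    absorbing = mua_base.max() > 0.0

    cap = out_w.size
    n_exit = 0
    L = np.zeros(n_layers)

    for pid in range(n_photons):
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        w = w0
        region = 0
        for k in range(n_layers):
            L[k] = 0.0
        alive = True

        while alive:
            rng, u = _rng_next(rng)
            tau = -math.log(u)
            # propagate tau optical depths, possibly across interfaces
            while tau > 0.0:
                s = tau * inv_mus[region]
                if uz > 0.0:
                    db = (z_bounds[region + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[region] - z) / uz
                else:
                    db = 1.0e30
                if s < db:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    L[layer_of[region]] += s
                    if absorbing:
                        w *= math.exp(-mua_base[layer_of[region]] * s)
                    tau = 0.0
                else:
                    x += ux * db
                    y += uy * db
                    L[layer_of[region]] += db
                    if absorbing:
                        w *= math.exp(-mua_base[layer_of[region]] * db)
                    tau -= db * mus[region]
                    if uz > 0.0:
                        region += 1
                        if region == n_regions:
                            alive = False  # lost through the bottom
                            break
                        z = z_bounds[region]
                    else:
                        if region == 0:
                            # top surface: split weight, score transmission
                            refl = _fresnel_internal(-uz, n_rel)
                            if refl < 1.0:
                                if n_exit >= cap:
                                    return -1
                                out_w[n_exit] = w * (1.0 - refl)
                                out_r[n_exit] = math.sqrt(x * x + y * y)
                                out_id[n_exit] = pid
                                for k in range(n_layers):
                                    out_L[n_exit, k] = L[k]
                                n_exit += 1
                                w *= refl
                            uz = -uz
                            z = 0.0
                            if w < ROULETTE_THRESHOLD:
                                rng, u = _rng_next(rng)
                                if u < ROULETTE_SURVIVAL:
                                    w /= ROULETTE_SURVIVAL
                                else:
                                    alive = False
                                    break
                        else:
                            region -= 1
                            z = z_bounds[region + 1]
            if not alive:
                break

            # roulette low-weight photons at collisions (baseline absorption
            # decays weight in flight; without it weight only drops at the
            # surface, where the same check runs)
            if w < ROULETTE_THRESHOLD:
                rng, u = _rng_next(rng)
                if u < ROULETTE_SURVIVAL:
                    w /= ROULETTE_SURVIVAL
                else:
                    break

            # Henyey-Greenstein scatter (isotropic when the region's g = 0)
            g = g_eff[region]
            rng, u = _rng_next(rng)
            if g > 1.0e-6:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                cost = 1.0 - 2.0 * u
            if cost > 1.0:
                cost = 1.0
            elif cost < -1.0:
                cost = -1.0
            sint = math.sqrt(1.0 - cost * cost)
            # azimuth via Marsaglia rejection (no trig calls)
            while True:
                rng, v1 = _rng_next(rng)
                rng, v2 = _rng_next(rng)
                v1 = 2.0 * v1 - 1.0
                v2 = 2.0 * v2 - 1.0
                ssq = v1 * v1 + v2 * v2
                if 0.0 < ssq < 1.0:
                    break
            cosp = (v1 * v1 - v2 * v2) / ssq
            sinp = 2.0 * v1 * v2 / ssq
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                denom = math.sqrt(1.0 - uz * uz)
                ux_new = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                uy_new = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                uz_new = -denom * sint * cosp + uz * cost
                norm = math.sqrt(ux_new * ux_new + uy_new * uy_new + uz_new * uz_new)
                ux = ux_new / norm
                uy = uy_new / norm
                uz = uz_new / norm

    return n_exit


#: transport mean free paths of exact Henyey-Greenstein transport kept below
#: the deepest layer interface before switching to the similarity-equivalent
#: isotropic walk.  The switch happens where the radiance is already
#: diffusive, so reflectance and pathlength statistics are preserved; see
#: docs/methods.md for the validation against fully anisotropic transport.
ISOTROPIZE_AFTER_TMFP = 4.0


def _build_regions(
    medium: TransportMedium, isotropize: bool
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Split layers into transport regions, optionally isotropizing depth."""
    bounds = medium.boundaries()
    z_edges = [0.0]
    mus = []
    gs = []
    layer_of = []
    deepest = medium.layers[-1]
    z_iso = bounds[-2] + ISOTROPIZE_AFTER_TMFP / deepest.mus_prime
    for i, layer in enumerate(medium.layers):
        z_top, z_bot = bounds[i], bounds[i + 1]
        if isotropize and i == medium.n_layers - 1 and z_top < z_iso < z_bot:
            z_edges.extend([z_iso, z_bot])
            mus.extend([layer.mus, layer.mus_prime])
            gs.extend([layer.g, 0.0])
            layer_of.extend([i, i])
        else:
            z_edges.append(z_bot)
            mus.append(layer.mus)
            gs.append(layer.g)
            layer_of.append(i)
    return (
        np.asarray(z_edges),
        np.asarray(mus),
        np.asarray(gs),
        np.asarray(layer_of, dtype=np.int64),
    )


def run_white_mc(
    medium: TransportMedium,
    n_photons: int,
    seed: int,
    *,
    exact: bool = False,
    mua_baseline: Sequence[float] | None = None,
) -> ExitRecords:
    """Run a white (zero-absorption) Monte Carlo simulation.

    Parameters
    ----------
    medium : TransportMedium
        Layer stack; the bottom of the deepest layer terminates photons.
    n_photons : int
        Photons launched (>= 1000).
    seed : int
        RNG seed; identical seed and inputs give a bit-identical record
        stream.
    exact : bool
        When True, keep the exact Henyey-Greenstein kernel at all depths
        instead of switching to the similarity-equivalent isotropic walk in
        the diffusive deep zone.  Slower; intended for validation runs.
    mua_baseline : sequence of float, optional
        Per-layer baseline absorption (cm^-1) applied *during* transport,
        with scoring rescaled relative to it afterwards.  Defaults to zero
        (pure white MC).  A positive baseline lets roulette terminate deep
        low-value excursions early; it must not exceed the smallest
        absorption the records will later be scored at, otherwise the
        killed tail is upweighted and the estimate is biased low.

    Returns
    -------
    ExitRecords
        Expected-transmission weight, exit radius and per-layer pathlength
        for every top-surface encounter.
    """
    if n_photons < 1_000:
        raise ValueError("n_photons must be >= 1000")
    if mua_baseline is None:
        base = np.zeros(medium.n_layers)
    else:
        base = np.asarray(mua_baseline, dtype=float)
        if base.shape != (medium.n_layers,) or np.any(base < 0):
            raise ValueError("mua_baseline needs one non-negative value per layer")
    z_bounds, mus, gs, layer_of = _build_regions(medium, isotropize=not exact)
    cap = 4 * n_photons
    while True:
        out_w = np.empty(cap)
        out_r = np.empty(cap)
        out_L = np.empty((cap, medium.n_layers))
        out_id = np.empty(cap, dtype=np.int64)
        n_exit = _trace_white(
            np.uint32(seed), n_photons, z_bounds, mus, gs, layer_of, base,
            medium.relative_index, out_w, out_r, out_L, out_id,
        )
        if n_exit >= 0:
            break
        cap *= 2
    return ExitRecords(
        weights=out_w[:n_exit].copy(),
        radii=out_r[:n_exit].copy(),
        pathlengths=out_L[:n_exit].copy(),
        photon_index=out_id[:n_exit].copy(),
        n_photons=n_photons,
        seed=int(seed),
        medium=medium,
        mua_baseline=base,
    )


# ---------------------------------------------------------------------------
# spatial-frequency-domain scoring with Beer-Lambert absorption rescaling
# ---------------------------------------------------------------------------


def score_sfd(
    records: ExitRecords,
    mua_per_layer: Sequence[float],
    fx: Sequence[float] = (0.0, 0.1),
) -> SfdReflectance:
    """Score diffuse reflectance at the requested spatial frequencies.

    Each exit record contributes ``w * exp(-sum_k mua_k * L_k)`` weighted by
    ``J0(2*pi*fx*rho)``; the mean over *launched* photons estimates
    ``Rd(fx)``.  ``fx`` is in mm^-1.
    """
    mua = np.asarray(mua_per_layer, dtype=float)
    if mua.shape != (records.n_layers,):
        raise ValueError(
            f"expected {records.n_layers} absorption coefficients, got {mua.shape}"
        )
    if np.any(mua < 0):
        raise ValueError("absorption coefficients must be >= 0")
    fx = tuple(float(f) for f in fx)

    w_eff = records.weights * np.exp(
        -records.pathlengths @ (mua - records.mua_baseline)
    )
    n = records.n_photons
    rd = []
    se = []
    for f in fx:
        contrib = w_eff * j0(2.0 * math.pi * (f * MM_PER_CM) * records.radii)
        # records of one photon are correlated: aggregate per photon first
        per_photon = np.bincount(
            records.photon_index, weights=contrib, minlength=n
        )
        mean = per_photon.sum() / n
        var = max(0.0, (per_photon * per_photon).sum() / n - mean * mean)
        rd.append(mean)
        se.append(math.sqrt(var / n))
    if len(fx) != 2:
        raise ValueError("score_sfd expects exactly two spatial frequencies")
    return SfdReflectance(
        rd0=rd[0], rd1=rd[1], fx_values=fx, mc_standard_error=(se[0], se[1])
    )


def rescale_grid(
    records: ExitRecords,
    mua_axes: Sequence[np.ndarray],
    fx: Sequence[float] = (0.0, 0.1),
) -> np.ndarray:
    """Beer-rescale one record set over a full per-layer absorption grid.

    ``mua_axes`` holds one 1-D axis per layer; the result has shape
    ``(len(fx), *[len(ax) for ax in mua_axes])``.  The per-record Beer
    factors separate by layer, so the grid fill is a dense matrix product —
    this is what makes a 21x75 absorption grid essentially free compared
    with the transport simulation itself.

    Only 1- and 2-layer media are supported (all this package needs).
    """
    axes = [
        np.asarray(a, dtype=float) - records.mua_baseline[i]
        for i, a in enumerate(mua_axes)
    ]
    if len(axes) != records.n_layers:
        raise ValueError("one absorption axis per layer required")
    n = records.n_photons
    fx_cm = [float(f) * MM_PER_CM for f in fx]

    out_shape = (len(fx),) + tuple(a.size for a in axes)
    out = np.empty(out_shape)
    if records.n_layers == 1:
        E = np.exp(-np.outer(records.pathlengths[:, 0], axes[0]))
        for i, f in enumerate(fx_cm):
            wj = records.weights * j0(2.0 * math.pi * f * records.radii)
            out[i] = (wj @ E) / n
    elif records.n_layers == 2:
        E1 = np.exp(-np.outer(records.pathlengths[:, 0], axes[0]))
        E2 = np.exp(-np.outer(records.pathlengths[:, 1], axes[1]))
        for i, f in enumerate(fx_cm):
            wj = records.weights * j0(2.0 * math.pi * f * records.radii)
            out[i] = (E1 * wj[:, None]).T @ E2 / n
    else:
        raise ValueError("rescale_grid supports 1- or 2-layer media only")
    return out
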