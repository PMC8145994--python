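"""Independent oracles for validating the white Monte Carlo engine.

Deliberately separate implementations: a direct *absorbing* analog Monte
Carlo (absorption decided photon-by-photon at collisions, exact
Henyey-Greenstein sampling at every depth, no pathlength bookkeeping, no
weight splitting) and the standard diffusion-approximation expression for
total diffuse reflectance of a semi-infinite medium.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _direct_absorbing_mc(seed, n_photons, z_bounds, mua, mus, g, n_rel):
    """Analog MC with absorption: returns (n_escaped, sum r, sum r^2 helper).

    Collisions are sampled from the total interaction coefficient
    mu_t = mua + mus per layer; at each collision the photon is absorbed
    with probability mua/mu_t, otherwise scattered (HG).  Fresnel escape at
    the top surface is an analog Bernoulli draw.  Returns the escaped
    count and the escaped photons' exit radii (for optional fx scoring).
    """
    np.random.seed(seed)
    n_layers = mus.size
    mut = mua + mus
    rsp = ((n_rel - 1.0) / (n_rel + 1.0)) ** 2
    radii = np.empty(n_photons)
    n_exit = 0

    for _ in range(n_photons):
        # specular reflection at entry (analog)
        if np.random.random() < rsp:
            continue
        x = 0.0
        y = 0.0
        z = 0.0
        ux = 0.0
        uy = 0.0
        uz = 1.0
        layer = 0
        alive = True
        while alive:
            s = -math.log(np.random.random()) / mut[layer]
            while True:
                if uz > 0.0:
                    db = (z_bounds[layer + 1] - z) / uz
                elif uz < 0.0:
                    db = (z_bounds[layer] - z) / uz
                else:
                    db = 1.0e30
                if s < db:
                    x += ux * s
                    y += uy * s
                    z += uz * s
                    break
                x += ux * db
                y += uy * db
                s_remaining = (s - db) * mut[layer]
                if uz > 0.0:
                    layer += 1
                    if layer == n_layers:
                        alive = False
                        break
                    z = z_bounds[layer]
                else:
                    if layer == 0:
                        ci = -uz
                        si = math.sqrt(max(0.0, 1.0 - ci * ci))
                        st = n_rel * si
                        if st >= 1.0:
                            refl = 1.0
                        else:
                            ct = math.sqrt(1.0 - st * st)
                            rs = (n_rel * ci - ct) / (n_rel * ci + ct)
                            rp = (n_rel * ct - ci) / (n_rel * ct + ci)
                            refl = 0.5 * (rs * rs + rp * rp)
                        if np.random.random() > refl:
                            radii[n_exit] = math.sqrt(x * x + y * y)
                            n_exit += 1
                            alive = False
                            break
                        uz = -uz
                        z = 0.0
                    else:
                        layer -= 1
                        z = z_bounds[layer + 1]
                s = s_remaining / mut[layer]
            if not alive:
                break
            # collision: absorb or scatter
            if np.random.random() < mua[layer] / mut[layer]:
                break
            u = np.random.random()
            if g > 1.0e-6:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
                cost = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                cost = 1.0 - 2.0 * u
            cost = min(1.0, max(-1.0, cost))
            sint = math.sqrt(1.0 - cost * cost)
            phi = 2.0 * math.pi * np.random.random()
            cosp = math.cos(phi)
            sinp = math.sin(phi)
            if abs(uz) > 0.99999:
                ux = sint * cosp
                uy = sint * sinp
                uz = cost if uz > 0.0 else -cost
            else:
                denom = math.sqrt(1.0 - uz * uz)
                uxn = sint * (ux * uz * cosp - uy * sinp) / denom + ux * cost
                uyn = sint * (uy * uz * cosp + ux * sinp) / denom + uy * cost
                uzn = -denom * sint * cosp + uz * cost
                norm = math.sqrt(uxn * uxn + uyn * uyn + uzn * uzn)
                ux = uxn / norm
                uy = uyn / norm
                uz = uzn / norm

    return n_exit, radii[:n_exit].copy()


def direct_absorbing_rd(medium, mua_per_layer, n_photons, seed, fx=(0.0, 0.1)):
    """Total/SFD diffuse reflectance by direct absorbing analog MC.

    Returns (rd values per fx, standard errors per fx).  ``medium`` is a
    TransportMedium from the package under test (geometry reuse only).
    """
    from scipy.special import j0

    z_bounds = medium.boundaries()
    mus = np.array([layer.mus for layer in medium.layers])
    mua = np.asarray(mua_per_layer, dtype=float)
    g = medium.layers[0].g
    n_exit, radii = _direct_absorbing_mc(
        np.uint32(seed), n_photons, z_bounds, mua, mus, g, medium.relative_index
    )
    rd = []
    se = []
    for f in fx:
        contrib = j0(2.0 * math.pi * (f * 10.0) * radii)
        s1 = contrib.sum()
        s2 = (contrib**2).sum()
        mean = s1 / n_photons
        var = max(0.0, s2 / n_photons - mean**2)
        rd.append(mean)
        se.append(math.sqrt(var / n_photons))
    return np.asarray(rd), np.asarray(se)


def diffusion_rd0(mua, musp, n=1.4):
    """Diffusion-approximation total diffuse reflectance, semi-infinite medium.

    Standard diffuse-reflectance expression with the empirical effective
    internal reflection coefficient for an index-mismatched boundary:
    Reff = 0.0636 n + 0.668 + 0.710/n - 1.440/n^2.
    """
    mutr = mua + musp
    ap = musp / mutr  # transport albedo
    reff = 0.0636 * n + 0.668 + 0.710 / n - 1.440 / n**2
    A = (1.0 - reff) / (2.0 * (1.0 + reff))
    mueff = math.sqrt(3.0 * mua * mutr)
    x = mueff / mutr
    return 3.0 * A * ap / ((x + 1.0) * (x + 3.0 * A))
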