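"""Shared fixtures: Monte Carlo products are expensive, so the LUT set and
the forward-simulated phantom battery are built once per session and shared
by the unit, property and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from sfdi2layer.lut import build_lut_set
from sfdi2layer.spectral import ChromophoreTable, MIOptimizer
from sfdi2layer.synthetic import ForwardEngine, matched_battery

# problem sizes for the session-wide Monte Carlo products
LUT_PHOTONS = 200_000
FORWARD_PHOTONS = 1_000_000
MISMATCH_PHOTONS = 50_000
LUT_SEED = 29
FORWARD_SEED = 31


@pytest.fixture(scope="session")
def lut_set():
    """Full device LUT set (3 two-layer tables + homogeneous)."""
    return build_lut_set(n_photons=LUT_PHOTONS, seed=LUT_SEED)


@pytest.fixture(scope="session")
def chromophores():
    return ChromophoreTable()


@pytest.fixture(scope="session")
def matched_specs():
    return matched_battery()


@pytest.fixture(scope="session")
def matched_rds(matched_specs, chromophores):
    """Forward-simulated reflectance of the 8-level melanin battery."""
    engine = ForwardEngine(n_photons=FORWARD_PHOTONS, seed=FORWARD_SEED)
    return [engine.forward_rd(spec, chromophores) for spec in matched_specs]


@pytest.fixture(scope="session")
def mi_optimizer(lut_set, chromophores):
    """Session-cached MI grid optimizer (collapsed tables are reused)."""
    return MIOptimizer(lut_set, table=chromophores)


@pytest.fixture()
def analytic_table():
    """A smooth analytic 2-D 'LUT' for inversion tests without Monte Carlo.

    Shapes mimic a reflectance table: rd0 falls with mua and rises with
    musp; rd1 is a compressed copy.  Exactly representable by the
    piecewise-linear machinery at the nodes.
    """
    from sfdi2layer.lut import CollapsedLUT

    mua = np.linspace(0.01, 0.75, 75)
    musp = np.linspace(4.0, 20.0, 17)
    A, S = np.meshgrid(mua, musp, indexing="ij")
    rd0 = 0.9 * np.exp(-1.8 * A / np.sqrt(S)) * (S / 20.0) ** 0.12
    rd1 = rd0 * (0.2 + 0.35 * S / 20.0)
    return CollapsedLUT(
        wavelength=735.0, mua_axis=mua, musp_axis=musp, rd0=rd0, rd1=rd1
    )
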