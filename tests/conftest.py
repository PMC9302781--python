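from __future__ import annotations

import numpy as np
import pytest

from mwbreast.geometry import build_geometry
from mwbreast.recon import MediumModel, reconstruct
from mwbreast.simulate import Inclusion, PhantomSpec, simulate_s21


@pytest.fixture(scope="session")
def fast_geometry():
    """Default geometry on a 500 MHz frequency grid (17 points)."""
    return build_geometry().decimated(500e6)


@pytest.fixture(scope="session")
def point_scatterer_runs(fast_geometry):
    """Single-inclusion reconstructions at two azimuths, two media.

    Shared by localization unit tests and the acceptance tests; computed
    once per session (each reconstruction back-propagates 17 frequencies
    onto the 70 x 120 polar grid).
    """
    runs = {}
    for phi_true in (90.0, 200.0):
        phantom = PhantomSpec(
            inclusions=(Inclusion(center_rho=0.03, center_phi=phi_true),)
        )
        dataset = simulate_s21(phantom, fast_geometry, noise_sd=0.0, seed=0)
        runs[phi_true] = {
            "dataset": dataset,
            "sigma3": reconstruct(dataset, MediumModel(conductivity=0.40)),
            "matched": reconstruct(dataset, MediumModel(conductivity=0.0)),
        }
    return runs


def angular_error(a: float, b: float) -> float:
    """Smallest absolute difference between two azimuths in degrees."""
    return abs((a - b + 180.0) % 360.0 - 180.0)
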