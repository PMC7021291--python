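"""Shared fixtures: small synthetic phantoms and biplane rigs.

Expensive objects (phantom volumes, rendered reference images) are
session-scoped; every test that mutates data works on copies.
"""

from __future__ import annotations

import numpy as np
import pytest

from vertekin.projection import make_biplane_geometry
from vertekin.synthgen import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Two-level 64^3 phantom at 0.5 mm spacing (fast rendering)."""
    return make_phantom(PhantomSpec(levels=2, shape=(64, 64, 64)), seed=0)


@pytest.fixture(scope="session")
def small_rig():
    """Cervical-style 55 deg interbeam rig scaled for the small phantom."""
    return make_biplane_geometry(
        55.0, 800.0, 8.0, pixel_pitch=1.0, image_size=(80, 80)
    )


@pytest.fixture(scope="session")
def cervical_phantom():
    """Full three-level 96^3 phantom matching the packaged geometry."""
    return make_phantom(PhantomSpec(shape=(96, 96, 96)), seed=0)


@pytest.fixture(scope="session")
def cervical_rig():
    """55 deg interbeam, 8 deg elevation biplane rig for the full phantom."""
    return make_biplane_geometry(
        55.0, 1520.0, 8.0, pixel_pitch=1.0, image_size=(100, 100)
    )


def rotation_angle_deg(Ra: np.ndarray, Rb: np.ndarray) -> float:
    """Geodesic angle between two rotations, degrees."""
    c = (np.trace(Ra.T @ Rb) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
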