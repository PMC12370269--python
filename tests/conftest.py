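import numpy as np
import pytest

from socketgen.aop_io import CylindricalGrid, LimbScan
from socketgen.synthetic_limb import CANONICAL_LANDMARKS, LimbShapeParams, generate_limb


@pytest.fixture
def tiny_grid() -> CylindricalGrid:
    """8 x 12 lattice used by brute-force PCA oracles."""
    return CylindricalGrid(np.linspace(0.0, 70.0, 8), 12)


@pytest.fixture
def default_limb() -> LimbScan:
    """A representative synthetic limb on the full clinical grid."""
    params = LimbShapeParams(
        bump_amplitudes={name: 3.0 for name in CANONICAL_LANDMARKS},
        surface_noise=0.3,
    )
    return generate_limb(params, seed=42)


def tiny_scan(tiny_grid: CylindricalGrid, seed: int) -> LimbScan:
    """Small random-but-smooth scan with the landmarks alignment needs."""
    rng = np.random.default_rng(seed)
    z = tiny_grid.slice_z / tiny_grid.slice_z[-1]
    theta = np.deg2rad(tiny_grid.theta_deg)
    radii = (
        45.0
        + 8.0 * np.outer(z, np.ones(tiny_grid.n_theta))
        + rng.normal(0, 1.5) * np.outer(np.sin(np.pi * z), np.cos(theta))
        + rng.normal(0, 1.0) * np.outer(z**2, np.sin(2 * theta))
        + rng.normal(0, 0.3, size=(tiny_grid.n_slices, tiny_grid.n_theta))
    )
    landmarks = {"PATELLAR_TENDON": (6, 0), "DISTAL_END": (0, 0)}
    return LimbScan(tiny_grid, radii, landmarks)
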