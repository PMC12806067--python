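"""Shared fixtures: voxel shapes, band-limited grids, a small embryo."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import sph_harm_y_all

from cellshape3d.grid import SphericalGrid, grid_phi, grid_theta
from cellshape3d.harmonics import _lm_pairs
from cellshape3d.io import CellPointCloud, surface_points
from cellshape3d.synthetic import ShapeSpec, make_embryo, make_shape


@pytest.fixture(scope="session")
def sphere_cloud() -> CellPointCloud:
    return make_shape(ShapeSpec(kind="sphere", radius=10))


@pytest.fixture(scope="session")
def sphere_surface(sphere_cloud):
    return surface_points(sphere_cloud)


def random_band_limited(seed: int, L: int = 25, rows: int = 53,
                        cols: int = 105, amplitude: float = 0.15):
    """A strictly positive band-limited grid with known exact coefficients.

    Returns (grid, packed complex coefficients ordered like _lm_pairs).
    Built as 1 + a sum of random real-valued harmonics of degree <= L, so
    the exact SPHARM coefficients are known by construction.
    """
    rng = np.random.default_rng(seed)
    tt, pp = np.meshgrid(grid_theta(rows), grid_phi(cols), indexing="ij")
    ylm = sph_harm_y_all(L, L, tt, pp)
    ls, ms = _lm_pairs(L)
    packed = np.zeros((L + 1) ** 2, dtype=complex)
    values = np.zeros((rows, cols))
    n_terms = 12
    degrees = rng.integers(1, L + 1, size=n_terms)
    for l in degrees:
        m = int(rng.integers(0, l + 1))
        a = amplitude * rng.standard_normal()
        idx_p = np.flatnonzero((ls == l) & (ms == m))[0]
        if m == 0:
            values += a * ylm[l, 0].real
            packed[idx_p] += a
        else:
            # a * 2*Re(Y_lm) = a*Y_lm + a*(-1)^m Y_{l,-m}
            values += 2 * a * ylm[l, m].real
            idx_n = np.flatnonzero((ls == l) & (ms == -m))[0]
            packed[idx_p] += a
            packed[idx_n] += a * (-1) ** m
    values += 1.0
    packed[0] += np.sqrt(4 * np.pi)  # the constant term: 1 = sqrt(4pi) Y_00
    assert values.min() > 0, "fixture grid must stay positive"
    grid = SphericalGrid(values, volume_voxels=4189, normalized=True)
    return grid, packed


@pytest.fixture(scope="session")
def band_limited_fixtures():
    """Twenty seeded band-limited grids with exact coefficients."""
    return [random_band_limited(seed) for seed in range(20)]


def evaluate_rotated(packed: np.ndarray, L: int, rotation_matrix: np.ndarray,
                     rows: int = 53, cols: int = 105) -> SphericalGrid:
    """Exact samples of the rotated band-limited function on the grid.

    Rotating a shape by R means sampling the original at R^-1 * dir; the
    harmonic sum is evaluated directly at the rotated directions, so no
    interpolation error enters.
    """
    ls, ms = _lm_pairs(L)
    tt, pp = np.meshgrid(grid_theta(rows), grid_phi(cols), indexing="ij")
    st = np.sin(tt)
    dirs = np.stack([np.cos(tt), st * np.sin(pp), st * np.cos(pp)],
                    axis=-1).reshape(-1, 3)
    d = (dirs[:, ::-1] @ rotation_matrix)[:, ::-1]  # R^-1 applied, zyx order
    theta = np.arccos(np.clip(d[:, 0], -1, 1))
    phi = np.mod(np.arctan2(d[:, 1], d[:, 2]), 2 * np.pi)
    ylm = sph_harm_y_all(L, L, theta, phi)
    values = (packed @ ylm[ls, ms]).real.reshape(rows, cols)
    return SphericalGrid(values, volume_voxels=4189, normalized=True)


@pytest.fixture(scope="session")
def small_embryo():
    """A fast 10-leaf embryo for lineage/pipeline tests."""
    return make_embryo(n_cells=10, n_timepoints=60, time_step=10,
                       radius=8, seed=3)
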