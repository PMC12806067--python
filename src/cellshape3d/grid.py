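"""Spherical-grid sampling of a cell surface.

Every surface voxel is expressed in spherical coordinates about the cell
centroid, then resampled homogeneously onto a fixed 53x105 grid of polar
angle theta (0..pi inclusive, 53 rows) by azimuth phi (0..2pi exclusive,
105 columns).  Each grid node takes the radial distance of the surface
point whose direction is nearest on the unit sphere, so the grid is a
"world map" of the cell's radial relief.  Dividing by the
equivalent-sphere radius (3V/4pi)^(1/3) removes cell size: a perfect
sphere maps to a constant grid of ~1, and deviations from 1 are pure
shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .io import SurfacePointSet

DEFAULT_ROWS = 53
DEFAULT_COLS = 105


@dataclass
class SphericalPointList:
    """Surface points in spherical coordinates about the cell centroid."""

    r: np.ndarray      # distances, > 0
    theta: np.ndarray  # polar angle in [0, pi]
    phi: np.ndarray    # azimuth in [0, 2pi)

    def __len__(self) -> int:
        return len(self.r)


@dataclass
class SphericalGrid:
    """Radial-distance matrix F(theta, phi) for one cell.

    ``values[i, j]`` is the (optionally volume-normalized) distance from
    the centroid along direction (theta_i, phi_j).
    """

    values: np.ndarray
    volume_voxels: int
    normalized: bool = False
    theta_axis: np.ndarray = field(default=None)  # type: ignore[assignment]
    phi_axis: np.ndarray = field(default=None)    # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2D")
        rows, cols = self.values.shape
        if self.theta_axis is None:
            self.theta_axis = grid_theta(rows)
        if self.phi_axis is None:
            self.phi_axis = grid_phi(cols)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def grid_theta(rows: int = DEFAULT_ROWS) -> np.ndarray:
    """Polar-angle axis: ``rows`` equal steps from 0 to pi, poles included."""
    return np.linspace(0.0, np.pi, rows)


def grid_phi(cols: int = DEFAULT_COLS) -> np.ndarray:
    """Azimuth axis: ``cols`` equal steps from 0, excluding 2pi."""
    return np.linspace(0.0, 2 * np.pi, cols, endpoint=False)


def to_spherical(surface: SurfacePointSet, scale: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> SphericalPointList:
    """Convert surface voxels to (r, theta, phi) about the cell centroid.

    Coordinates are taken in (z, y, x) voxel index order: axis 0 of the
    volume is z (the polar axis).  ``scale`` rescales the three axes
    before conversion for anisotropic voxels.
    """
    offsets = (surface.points - surface.centroid) * np.asarray(scale, dtype=float)
    r = np.linalg.norm(offsets, axis=1)
    if np.any(r == 0):
        raise ValueError("surface point coincides with the centroid (r = 0)")
    theta = np.arccos(np.clip(offsets[:, 0] / r, -1.0, 1.0))
    phi = np.mod(np.arctan2(offsets[:, 1], offsets[:, 2]), 2 * np.pi)
    return SphericalPointList(r=r, theta=theta, phi=phi)


def _unit_vectors(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Unit direction vectors (z, y, x) for arrays of angles."""
    st = np.sin(theta)
    return np.column_stack([np.cos(theta), st * np.sin(phi), st * np.cos(phi)])


def build_grid(points: SphericalPointList, rows: int = DEFAULT_ROWS,
               cols: int = DEFAULT_COLS, warn_angle_deg: float = 15.0) -> SphericalGrid:
    """Nearest-direction resampling of scattered surface points to a grid.

    Every grid node takes the r of the surface point whose direction is
    closest in angle; nearest-in-chord on unit vectors is used, which is
    order-equivalent to great-circle distance.  Ties are broken toward the
    smallest r by pre-sorting.  One radius per direction assumes a
    star-shaped surface; if any node's nearest point lies more than
    ``warn_angle_deg`` away a warning is emitted (sparse or non-star
    surface).
    """
    if len(points) == 0:
        raise ValueError("empty spherical point list")
    order = np.argsort(points.r, kind="stable")
    r = points.r[order]
    dirs = _unit_vectors(points.theta[order], points.phi[order])
    theta_ax, phi_ax = grid_theta(rows), grid_phi(cols)
    tt, pp = np.meshgrid(theta_ax, phi_ax, indexing="ij")
    nodes = _unit_vectors(tt.ravel(), pp.ravel())
    dist, idx = cKDTree(dirs).query(nodes, k=1)
    max_angle = 2 * np.degrees(np.arcsin(np.clip(dist.max() / 2, 0, 1)))
    if max_angle > warn_angle_deg:
        warnings.warn(
            f"nearest surface point {max_angle:.1f} deg from a grid node; "
            "surface may be sparse or non-star-shaped", stacklevel=2)
    values = r[idx].reshape(rows, cols)
    return SphericalGrid(values, volume_voxels=0, normalized=False,
                         theta_axis=theta_ax, phi_axis=phi_ax)


def grid_from_surface(surface: SurfacePointSet, rows: int = DEFAULT_ROWS,
                      cols: int = DEFAULT_COLS, normalize: bool = True,
                      scale: tuple[float, float, float] = (1.0, 1.0, 1.0)) -> SphericalGrid:
    """Surface point set -> (normalized) spherical grid in one call."""
    g = build_grid(to_spherical(surface, scale=scale), rows=rows, cols=cols)
    g.volume_voxels = int(surface.volume_voxels)
    return normalize_grid(g) if normalize else g


def equivalent_sphere_radius(volume_voxels: float) -> float:
    """Radius of the sphere with the given voxel volume, (3V/4pi)^(1/3)."""
    return float((3.0 * volume_voxels / (4.0 * np.pi)) ** (1.0 / 3.0))


def normalize_grid(grid: SphericalGrid) -> SphericalGrid:
    """Divide the grid by the cell's equivalent-sphere radius.

    Removes cell volume from the representation so that shapes of
    different sizes become comparable; a sphere normalizes to ~1
    everywhere.  Normalizing twice is refused.
    """
    if grid.normalized:
        raise ValueError("grid is already volume-normalized")
    if grid.volume_voxels <= 0:
        raise ValueError("volume_voxels must be set and positive to normalize")
    r0 = equivalent_sphere_radius(grid.volume_voxels)
    return SphericalGrid(grid.values / r0, grid.volume_voxels, normalized=True,
                         theta_axis=grid.theta_axis, phi_axis=grid.phi_axis)


def flatten(grid: SphericalGrid) -> np.ndarray:
    """Row-major flattening of the grid to a vector (length rows*cols)."""
    return grid.values.ravel().copy()


def unflatten(vector: np.ndarray, rows: int = DEFAULT_ROWS,
              cols: int = DEFAULT_COLS, volume_voxels: int = 0,
              normalized: bool = True) -> SphericalGrid:
    """Inverse of :func:`flatten` given the grid dimensions."""
    vector = np.asarray(vector, dtype=float)
    if vector.size != rows * cols:
        raise ValueError(f"vector length {vector.size} != {rows}x{cols}")
    return SphericalGrid(vector.reshape(rows, cols), volume_voxels, normalized)
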