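"""Spherical-harmonic (SPHARM) analysis of spherical grids.

The radial relief F(theta, phi) of a cell is expanded in the orthonormal
complex spherical harmonics Y_lm (Condon-Shortley phase),

    f(theta, phi) = sum_{l=0}^{L} sum_{m=-l}^{l} f_lm Y_lm(theta, phi),

with coefficients obtained from the analysis integral
f_lm = integral f conj(Y_lm) dOmega evaluated by exact quadrature rather
than least squares.  The quadrature follows Driscoll & Healy's sampling
theorem: on colatitudes theta_j = pi j / n (n even) the weights

    w_j = (4/n) sin(theta_j) sum_{k=0}^{n/2-1} sin((2k+1) theta_j)/(2k+1)

integrate any trigonometric polynomial of degree < n exactly, so a grid
whose band limit is at most n/2 - 1 is analyzed without aliasing.  The
default 53x105 storage grid is already compliant for L = 25: its first 52
rows are exactly the DH nodes (the theta = pi row has weight 0), and 105
uniform azimuths resolve orders |m| <= 52 exactly.  Non-compliant grid
shapes are bilinearly resampled to a compliant one first.

The per-degree power spectrum sum_m |f_lm|^2 is invariant to rotation of
the shape and is the basis of the rotation-invariant descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import sph_harm_y_all

from .grid import SphericalGrid, grid_phi, grid_theta

DEFAULT_DEGREE = 25


@dataclass
class SpharmCoefficients:
    """Complex SPHARM coefficients f_lm for 0 <= l <= L, |m| <= l.

    Stored as an (L+1, 2L+1) complex array indexed [l, m] with negative m
    wrapping around (FFT-style), matching scipy's layout.  For a
    real-valued source grid the coefficients obey the conjugate symmetry
    f_{l,-m} = (-1)^m conj(f_lm).
    """

    coeffs: np.ndarray  # (L+1, 2L+1) complex, m wrap-indexed
    max_degree: int
    source_volume: int = 0

    def __post_init__(self) -> None:
        L = self.max_degree
        self.coeffs = np.asarray(self.coeffs, dtype=complex)
        if self.coeffs.shape != (L + 1, 2 * L + 1):
            raise ValueError(
                f"expected coefficient array of shape {(L + 1, 2 * L + 1)}, "
                f"got {self.coeffs.shape}")

    def get(self, l: int, m: int) -> complex:
        """Coefficient f_lm (m may be negative)."""
        if not (0 <= l <= self.max_degree and abs(m) <= l):
            raise IndexError(f"(l={l}, m={m}) outside triangle for L={self.max_degree}")
        return complex(self.coeffs[l, m])

    @property
    def n_coefficients(self) -> int:
        """Number of (l, m) pairs, (L+1)^2."""
        return (self.max_degree + 1) ** 2


def dh_weights(n: int) -> np.ndarray:
    """Driscoll-Healy quadrature weights for colatitudes pi*j/n, j=0..n-1."""
    if n % 2:
        raise ValueError("n must be even")
    theta = np.pi * np.arange(n) / n
    k = np.arange(n // 2)
    s = (np.sin(np.outer(theta, 2 * k + 1)) / (2 * k + 1)).sum(axis=1)
    return (4.0 / n) * np.sin(theta) * s


def _lm_pairs(L: int) -> tuple[np.ndarray, np.ndarray]:
    """All valid (l, m) pairs, l ascending, m from -l to l."""
    ls = np.concatenate([np.full(2 * l + 1, l) for l in range(L + 1)])
    ms = np.concatenate([np.arange(-l, l + 1) for l in range(L + 1)])
    return ls, ms


def _ylm_matrix(L: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Y_lm sampled on a theta x phi grid, packed ((L+1)^2, n_nodes)."""
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    ylm = sph_harm_y_all(L, L, tt, pp)  # (L+1, 2L+1, nt, np), m wrap-indexed
    ls, ms = _lm_pairs(L)
    return ylm[ls, ms].reshape((L + 1) ** 2, -1)


@lru_cache(maxsize=8)
def _analysis_matrix(L: int, n_theta: int, n_cols: int) -> np.ndarray:
    """Cached quadrature operator: coeffs = A @ samples.ravel().

    Rows are packed (l, m) pairs; DH theta weights and the phi measure
    are folded in.
    """
    theta = np.pi * np.arange(n_theta) / n_theta
    Y = _ylm_matrix(L, theta, grid_phi(n_cols))
    w = np.repeat(dh_weights(n_theta), n_cols) * (2 * np.pi / n_cols)
    return np.conj(Y) * w


@lru_cache(maxsize=8)
def _synthesis_matrix(L: int, rows: int, cols: int) -> np.ndarray:
    """Cached evaluation operator: values = coeffs_packed @ S."""
    return _ylm_matrix(L, grid_theta(rows), grid_phi(cols))


def _compliant(grid_shape: tuple[int, int], L: int) -> bool:
    rows, cols = grid_shape
    n = rows - 1
    return n % 2 == 0 and n >= 2 * (L + 1) and cols >= 2 * L + 1


def _resample(values: np.ndarray, new_rows: int, new_cols: int) -> np.ndarray:
    """Bilinear resampling onto an equiangular grid, periodic in phi."""
    from scipy.interpolate import RegularGridInterpolator

    rows, cols = values.shape
    theta = grid_theta(rows)
    phi = np.concatenate([grid_phi(cols), [2 * np.pi]])
    padded = np.concatenate([values, values[:, :1]], axis=1)
    interp = RegularGridInterpolator((theta, phi), padded, method="linear")
    new_theta = np.pi * np.arange(new_rows) / new_rows
    new_phi = grid_phi(new_cols)
    tt, pp = np.meshgrid(new_theta, new_phi, indexing="ij")
    return interp(np.column_stack([tt.ravel(), pp.ravel()])).reshape(new_rows, new_cols)


def forward_transform(grid: SphericalGrid, max_degree: int = DEFAULT_DEGREE) -> SpharmCoefficients:
    """Analyze a spherical grid into SPHARM coefficients by quadrature.

    Exact (to roundoff) for grids band-limited at ``max_degree``.  Raises
    if the grid is too coarse to support the requested band limit.
    """
    L = int(max_degree)
    if L < 0:
        raise ValueError("max_degree must be >= 0")
    rows, cols = grid.shape
    if not np.all(np.isfinite(grid.values)):
        raise ValueError("grid contains non-finite values")
    if rows - 1 < 2 * (L + 1) or cols < 2 * L + 1:
        raise ValueError(
            f"a {rows}x{cols} grid cannot support band limit {L} "
            f"(needs >= {2 * (L + 1) + 1} rows and >= {2 * L + 1} columns)")
    if _compliant((rows, cols), L):
        samples = grid.values[: rows - 1, :]  # drop theta=pi row (weight 0)
        n_theta, n_cols = rows - 1, cols
    else:
        n_theta, n_cols = 2 * (L + 1), cols
        samples = _resample(grid.values, n_theta, n_cols)
    packed = _analysis_matrix(L, n_theta, n_cols) @ samples.ravel()
    ls, ms = _lm_pairs(L)
    coeffs = np.zeros((L + 1, 2 * L + 1), dtype=complex)
    coeffs[ls, ms] = packed
    return SpharmCoefficients(coeffs, L, source_volume=grid.volume_voxels)


def inverse_transform(coeffs: SpharmCoefficients, rows: int = 53,
                      cols: int = 105) -> SphericalGrid:
    """Synthesize f = sum f_lm Y_lm on an equiangular grid.

    The imaginary residual is discarded; it is < 1e-8 for coefficient sets
    with real (conjugate-symmetric) origin.
    """
    L = coeffs.max_degree
    ls, ms = _lm_pairs(L)
    packed = coeffs.coeffs[ls, ms]
    values = (packed @ _synthesis_matrix(L, rows, cols)).reshape(rows, cols)
    return SphericalGrid(values.real, volume_voxels=coeffs.source_volume,
                         normalized=True)


def reconstruction_error(original: SphericalGrid, reconstructed: SphericalGrid) -> float:
    """Relative RMSE between two grids: rms(a - b) / rms(a)."""
    a, b = original.values, reconstructed.values
    if a.shape != b.shape:
        raise ValueError(f"grid shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)) / np.sqrt(np.mean(a ** 2)))


def power_spectrum(coeffs: SpharmCoefficients) -> np.ndarray:
    """Per-degree power P(l) = sum_m |f_lm|^2, a rotation-invariant vector.

    Length L+1; by Parseval its sum equals the integral of |f|^2 over the
    sphere.
    """
    L = coeffs.max_degree
    power = np.empty(L + 1)
    for l in range(L + 1):
        ms = np.r_[np.arange(0, l + 1), np.arange(-l, 0)]
        power[l] = float(np.sum(np.abs(coeffs.coeffs[l, ms]) ** 2))
    return power


def flatten_coeffs(coeffs: SpharmCoefficients, packing: str = "real") -> np.ndarray:
    """Flatten coefficients to a vector with deterministic (l, m) ordering.

    ``packing="complex"`` gives the complex vector
    [f_00, f_1-1, f_10, f_11, ...] of length (L+1)^2.  ``packing="real"``
    exploits conjugate symmetry of real-source coefficients to pack the
    same information into (L+1)^2 real numbers: per degree, Re f_l0 then
    (Re f_lm, Im f_lm) for m = 1..l.
    """
    L = coeffs.max_degree
    if packing == "complex":
        out = np.empty((L + 1) ** 2, dtype=complex)
        i = 0
        for l in range(L + 1):
            for m in range(-l, l + 1):
                out[i] = coeffs.coeffs[l, m]
                i += 1
        return out
    if packing == "real":
        out = np.empty((L + 1) ** 2)
        i = 0
        for l in range(L + 1):
            out[i] = coeffs.coeffs[l, 0].real
            i += 1
            for m in range(1, l + 1):
                out[i] = coeffs.coeffs[l, m].real
                out[i + 1] = coeffs.coeffs[l, m].imag
                i += 2
        return out
    raise ValueError(f"unknown packing {packing!r}")


def unflatten_coeffs(vector: np.ndarray, max_degree: int,
                     packing: str = "real", source_volume: int = 0) -> SpharmCoefficients:
    """Inverse of :func:`flatten_coeffs`."""
    L = int(max_degree)
    vector = np.asarray(vector)
    if vector.size != (L + 1) ** 2:
        raise ValueError(f"expected {(L + 1) ** 2} entries, got {vector.size}")
    c = np.zeros((L + 1, 2 * L + 1), dtype=complex)
    i = 0
    if packing == "complex":
        for l in range(L + 1):
            for m in range(-l, l + 1):
                c[l, m] = vector[i]
                i += 1
    elif packing == "real":
        for l in range(L + 1):
            c[l, 0] = float(vector[i].real)
            i += 1
            for m in range(1, l + 1):
                c[l, m] = vector[i] + 1j * vector[i + 1]
                c[l, -m] = (-1) ** m * np.conj(c[l, m])
                i += 2
    else:
        raise ValueError(f"unknown packing {packing!r}")
    return SpharmCoefficients(c, L, source_volume=source_volume)


def sphere_integral_sq(grid: SphericalGrid) -> float:
    """Quadrature of |f|^2 over the sphere on a DH-compliant grid.

    Independent of the coefficient path; used to check Parseval.
    """
    rows, cols = grid.shape
    n = rows - 1
    if n % 2:
        raise ValueError("grid rows - 1 must be even")
    w = dh_weights(n)
    dphi = 2 * np.pi / cols
    return float(np.sum(np.abs(grid.values[:n, :]) ** 2 * w[:, None]) * dphi)
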