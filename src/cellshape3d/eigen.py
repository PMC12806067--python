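"""PCA eigen-shape bases and static/dynamic shape features.

Flattened spherical grids (d = 5565), real-packed SPHARM coefficient
vectors (d = (L+1)^2) and per-degree power spectra (d = L+1) are each
decomposed over a cell population by mean-centered PCA.  The resulting
weight vectors are the eigengrid, eigenharmonic and eigenspectrum shape
features: a cell at one timepoint yields a static feature, and the mean
of a cell's static features over its cell cycle (from appearance to
division) is its dynamic feature.

PCA is computed by singular-value decomposition of the centered data
matrix with a deterministic sign convention (the largest-magnitude entry
of every component is made positive) so bases are reproducible across
runs and platforms.  Values are centered but not standardized: entries
of one feature kind share units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

KINDS = ("grid", "harmonic", "spectrum")


@dataclass
class EigenBasis:
    """Mean vector and orthonormal principal components of one feature kind."""

    kind: str
    mean: np.ndarray                     # (d,)
    components: np.ndarray               # (K, d), orthonormal rows
    explained_variance_ratio: np.ndarray  # (K,), non-increasing

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance_ratio = np.asarray(self.explained_variance_ratio, dtype=float)

    @property
    def d(self) -> int:
        return self.mean.size

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "kind": self.kind,
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }))

    @classmethod
    def load(cls, path: str | Path) -> "EigenBasis":
        obj = json.loads(Path(path).read_text())
        return cls(obj["kind"], np.asarray(obj["mean"]),
                   np.asarray(obj["components"]),
                   np.asarray(obj["explained_variance_ratio"]))


def fit_basis(matrix: np.ndarray, n_components: int = 96, kind: str = "grid") -> EigenBasis:
    """Fit a PCA basis to an (N, d) population feature matrix.

    ``n_components`` larger than min(N-1, d) is reduced with a warning; a
    constant matrix yields a zero-variance basis.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need an (N, d) matrix with N >= 2")
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    n, d = X.shape
    k_max = min(n - 1, d)
    k = int(n_components)
    if k > k_max:
        warnings.warn(f"n_components reduced from {k} to {k_max} "
                      f"(N={n}, d={d})", stacklevel=2)
        k = k_max
    mean = X.mean(axis=0)
    Xc = X - mean
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float(np.sum(s ** 2))
    if total_var == 0.0:
        warnings.warn("constant feature matrix: zero-variance basis", stacklevel=2)
        comps = np.zeros((k, d))
        comps[:, :k] = np.eye(k)  # arbitrary orthonormal completion
        return EigenBasis(kind, mean, comps, np.zeros(k))
    comps = vt[:k]
    # deterministic sign: largest-magnitude entry of each component positive
    flips = np.sign(comps[np.arange(k), np.argmax(np.abs(comps), axis=1)])
    comps = comps * flips[:, None]
    ratios = (s[:k] ** 2) / total_var
    return EigenBasis(kind, mean, comps, ratios)


def project(basis: EigenBasis, vector: np.ndarray) -> np.ndarray:
    """Weights w = P (F - mu): the eigen-feature vector of one shape.

    With orthonormal components the pseudo-inverse of the component
    matrix is its transpose, so projection is a single matrix product.
    """
    v = np.asarray(vector, dtype=float)
    if v.shape[-1] != basis.d:
        raise ValueError(f"vector length {v.shape[-1]} != basis dimension {basis.d}")
    return (v - basis.mean) @ basis.components.T


def reconstruct(basis: EigenBasis, weights: np.ndarray) -> np.ndarray:
    """Inverse of :func:`project`: mu + sum_k w_k p_k."""
    w = np.asarray(weights, dtype=float)
    if w.shape[-1] != basis.n_components:
        raise ValueError(f"expected {basis.n_components} weights, got {w.shape[-1]}")
    return basis.mean + w @ basis.components


def component_shape(basis: EigenBasis, index: int, scale: float = 0.0):
    """The shape mode mu + scale * p_index, unflattened for rendering.

    Grid bases return a :class:`~cellshape3d.grid.SphericalGrid`; harmonic
    bases a :class:`~cellshape3d.harmonics.SpharmCoefficients`; spectrum
    bases the raw vector (spectra are not invertible to a shape).
    """
    if not 0 <= index < basis.n_components:
        raise IndexError(f"component {index} out of range (K={basis.n_components})")
    vec = basis.mean + scale * basis.components[index]
    if basis.kind == "grid":
        from . import grid as _grid

        cols = 105 if basis.d % 105 == 0 else None
        if cols is None:
            raise ValueError(f"cannot infer grid shape from d={basis.d}")
        return _grid.unflatten(vec, rows=basis.d // cols, cols=cols)
    if basis.kind == "harmonic":
        from .harmonics import unflatten_coeffs

        L = int(round(np.sqrt(basis.d))) - 1
        return unflatten_coeffs(vec, L, packing="real")
    return vec


@dataclass
class DynamicFeature:
    """Per-cell mean of static eigen weights over the cell cycle."""

    embryo_id: str
    cell_name: str
    weights: np.ndarray
    n_timepoints: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)


def dynamic_feature(records: pd.DataFrame) -> DynamicFeature:
    """Average one cell's static weight records over its observed lifespan.

    ``records`` must hold one cell of one embryo with columns
    ``embryo, cell, time`` plus weight columns ``w*``.
    """
    if len(records) == 0:
        raise ValueError("no records")
    if records["cell"].nunique() != 1 or records["embryo"].nunique() != 1:
        raise ValueError("records mix cells or embryos")
    wcols = [c for c in records.columns if c.startswith("w")]
    return DynamicFeature(
        embryo_id=str(records["embryo"].iloc[0]),
        cell_name=str(records["cell"].iloc[0]),
        weights=records[wcols].to_numpy(dtype=float).mean(axis=0),
        n_timepoints=len(records),
    )


def dynamic_table(static: pd.DataFrame) -> pd.DataFrame:
    """Dynamic features for every (embryo, cell) in a static weight table."""
    wcols = [c for c in static.columns if c.startswith("w")]
    out = static.groupby(["embryo", "cell"], as_index=False)[wcols].mean()
    counts = static.groupby(["embryo", "cell"]).size().rename("n_timepoints")
    return out.merge(counts, on=["embryo", "cell"])


def interpolate_missing(series: dict[float, np.ndarray],
                        target_times: list[float] | None = None) -> dict[float, np.ndarray]:
    """Fill gaps in a timepoint -> weights series by linear interpolation.

    Only times strictly inside the observed range are filled (no
    extrapolation); by default every missing integer minute inside the
    range is a target.  Gaps at the series boundary stay unfilled with a
    warning.
    """
    if not series:
        raise ValueError("empty series")
    times = sorted(series)
    lo, hi = times[0], times[-1]
    if target_times is None:
        target_times = [float(t) for t in range(int(np.ceil(lo)), int(np.floor(hi)) + 1)]
    outside = [t for t in target_times if t < lo or t > hi]
    if outside:
        warnings.warn(f"{len(outside)} target times outside the observed "
                      f"range [{lo}, {hi}] left unfilled", stacklevel=2)
    W = np.asarray([series[t] for t in times], dtype=float)
    filled = dict(series)
    for t in target_times:
        if t in filled or t < lo or t > hi:
            continue
        filled[t] = np.array([np.interp(t, times, W[:, j]) for j in range(W.shape[1])])
    return filled
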