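"""End-to-end helpers: labeled volumes -> feature tables -> eigen weights.

Glue over the lower-level modules so that the common workflow — extract
every cell of every timepoint, grid it, transform it, fit the three PCA
bases, project, and analyze on the lineage — is a few calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import eigen, grid as _grid, harmonics, io, lineage as _lineage
from .synthetic import SyntheticEmbryo

META = ["embryo", "cell", "time"]


def cell_feature_vectors(volume: io.LabeledVolume, max_degree: int = 25,
                         rows: int = 53, cols: int = 105) -> list[dict]:
    """Grid, coefficient and spectrum vectors for every cell in a volume."""
    out = []
    for label, cloud in sorted(io.extract_all_cells(volume).items()):
        surf = io.surface_points(cloud)
        g = _grid.grid_from_surface(surf, rows=rows, cols=cols, normalize=True)
        coeffs = harmonics.forward_transform(g, max_degree=max_degree)
        out.append({
            "embryo": volume.embryo_id, "cell": cloud.cell_name,
            "time": volume.timepoint,
            "grid": _grid.flatten(g),
            "harmonic": harmonics.flatten_coeffs(coeffs, packing="real"),
            "spectrum": harmonics.power_spectrum(coeffs),
        })
    return out


def features_from_clouds(clouds: list[io.CellPointCloud], max_degree: int = 25,
                         rows: int = 53, cols: int = 105) -> "FeatureTables":
    """Feature vectors for bare point clouds (no labeled volume needed)."""
    records = []
    for cloud in clouds:
        surf = io.surface_points(cloud)
        g = _grid.grid_from_surface(surf, rows=rows, cols=cols, normalize=True)
        coeffs = harmonics.forward_transform(g, max_degree=max_degree)
        records.append({
            "embryo": cloud.embryo_id, "cell": cloud.cell_name,
            "time": cloud.timepoint,
            "grid": _grid.flatten(g),
            "harmonic": harmonics.flatten_coeffs(coeffs, packing="real"),
            "spectrum": harmonics.power_spectrum(coeffs),
        })
    meta = pd.DataFrame([{k: r[k] for k in META} for r in records])
    return FeatureTables(
        meta=meta,
        grid=np.vstack([r["grid"] for r in records]),
        harmonic=np.vstack([r["harmonic"] for r in records]),
        spectrum=np.vstack([r["spectrum"] for r in records]),
    )


@dataclass
class FeatureTables:
    """Per-cell-instance feature vectors of the three kinds, aligned by row."""

    meta: pd.DataFrame        # embryo, cell, time
    grid: np.ndarray          # (N, rows*cols)
    harmonic: np.ndarray      # (N, (L+1)^2)
    spectrum: np.ndarray      # (N, L+1)

    def matrix(self, kind: str) -> np.ndarray:
        return getattr(self, kind)


def embryo_features(embryos: list[SyntheticEmbryo] | SyntheticEmbryo,
                    max_degree: int = 25) -> FeatureTables:
    """Feature vectors of every cell instance in one or more embryos."""
    if isinstance(embryos, SyntheticEmbryo):
        embryos = [embryos]
    records: list[dict] = []
    for emb in embryos:
        for tp in emb.timepoints():
            records.extend(cell_feature_vectors(emb.volumes[tp], max_degree))
    if not records:
        raise ValueError("no cells found")
    meta = pd.DataFrame([{k: r[k] for k in META} for r in records])
    return FeatureTables(
        meta=meta,
        grid=np.vstack([r["grid"] for r in records]),
        harmonic=np.vstack([r["harmonic"] for r in records]),
        spectrum=np.vstack([r["spectrum"] for r in records]),
    )


def fit_eigen_bases(tables: FeatureTables, n_components: int = 96,
                    kinds: tuple[str, ...] = ("grid", "harmonic", "spectrum"),
                    ) -> dict[str, eigen.EigenBasis]:
    """Fit one PCA basis per feature kind over the whole population."""
    import warnings

    bases = {}
    for kind in kinds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # K is capped for small populations
            bases[kind] = eigen.fit_basis(tables.matrix(kind), n_components, kind)
    return bases


def weight_table(tables: FeatureTables, basis: eigen.EigenBasis) -> pd.DataFrame:
    """Static eigen-weight table ``embryo, cell, time, w1..wK``."""
    W = eigen.project(basis, tables.matrix(basis.kind))
    cols = {f"w{i + 1}": W[:, i] for i in range(W.shape[1])}
    return pd.concat([tables.meta.reset_index(drop=True), pd.DataFrame(cols)], axis=1)


@dataclass
class RecognitionReport:
    """Outcome of threshold-based cell-type recognition on one population."""

    sweep: pd.DataFrame
    best_threshold: float
    precision: float
    recall: float
    predicted: set
    truth: set


def recognize_cells(embryos: list[SyntheticEmbryo] | SyntheticEmbryo,
                    positive_fate: str = "skin",
                    kind: str = "grid",
                    component_index: int = 1,
                    n_components: int = 96,
                    min_time_minutes: float = 100.0,
                    n_thresholds: int = 25,
                    max_degree: int = 25) -> RecognitionReport:
    """Full pipeline: render -> grid -> eigen weights -> threshold call.

    Sweeps thresholds over the score range and reports the row with the
    best F1; truth is the set of ``positive_fate`` cells among those
    observable after ``min_time_minutes``.
    """
    if isinstance(embryos, SyntheticEmbryo):
        embryos = [embryos]
    tables = embryo_features(embryos, max_degree=max_degree)
    basis = fit_eigen_bases(tables, n_components, kinds=(kind,))[kind]
    weights = weight_table(tables, basis)

    trees = [_lineage.build_tree(emb.cell_table, fate_table=emb.fate_table)
             for emb in embryos]
    avg = _lineage.average_lineage(trees)
    values = _lineage.static_on_tree(avg, weights, component_index)

    late = values[values["time"] >= min_time_minutes]
    universe = set(late["cell"])
    fate_map = {}
    for emb in embryos:
        fate_map.update(zip(emb.fate_table["cell"], emb.fate_table["fate"]))
    truth = {c for c in universe if fate_map.get(c) == positive_fate}
    if not truth:
        raise ValueError(f"no {positive_fate!r} cells observable after "
                         f"{min_time_minutes} min")

    scores = late.assign(a=late["value"].abs()).groupby("cell")["a"].mean()
    thresholds = np.linspace(scores.min(), scores.max(), n_thresholds)[1:-1]
    sweep = _lineage.threshold_sweep(values, truth, list(thresholds),
                                     min_time_minutes)
    f1 = 2 * sweep["precision"] * sweep["recall"] / (
        sweep["precision"] + sweep["recall"])
    best = int(np.nanargmax(f1.to_numpy()))
    row = sweep.iloc[best]
    pred = _lineage.classify_by_threshold(values, float(row["threshold"]),
                                          min_time_minutes)
    return RecognitionReport(sweep, float(row["threshold"]),
                             float(row["precision"]), float(row["recall"]),
                             pred, truth)
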