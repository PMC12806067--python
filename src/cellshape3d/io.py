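"""Labeled-volume input and per-cell surface extraction.

A segmented embryo arrives as a 3D integer lattice in which every voxel of a
cell carries that cell's label and background is 0.  A companion cell table
(CSV with columns ``embryo,cell,time,label``) maps labels to lineage names.
The morphological step is deliberately simple: a cell's surface is the
one-voxel outer shell obtained by dilating its voxel set with the full
3x3x3 structuring element (26-connectivity) and removing the original
voxels.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# full 3x3x3 structuring element: all 27 offsets in {-1,0,1}^3
_CUBE_OFFSETS = np.array(
    [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)],
    dtype=np.int64,
)


class FormatError(ValueError):
    """Raised for unreadable or non-integer labeled volumes."""


@dataclass
class LabeledVolume:
    """A 3D integer label lattice for one embryo at one timepoint.

    Parameters
    ----------
    array : ndarray of int, shape (nz, ny, nx)
        Voxel labels; 0 is background.
    embryo_id : str
        Identifier of the embryo the volume belongs to.
    timepoint : float
        Acquisition time in minutes (4-cell stage = 0 by convention).
    label_map : dict[int, str]
        Maps each nonzero label to a lineage cell name.
    """

    array: np.ndarray
    embryo_id: str
    timepoint: float
    label_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if not np.issubdtype(self.array.dtype, np.integer):
            raise FormatError(f"labels must be integer-typed, got {self.array.dtype}")
        if self.array.ndim != 3 or min(self.array.shape) < 1:
            raise FormatError(f"expected a 3D volume, got shape {self.array.shape}")
        if self.array.size and self.array.min() < 0:
            raise FormatError("labels must be non-negative")
        present = self.labels()
        missing = [l for l in self.label_map if l not in present]
        if missing:
            raise ValueError(f"label_map labels absent from array: {missing}")

    def labels(self) -> set[int]:
        """Nonzero labels present in the volume."""
        u = np.unique(self.array)
        return set(int(v) for v in u if v != 0)


@dataclass
class CellPointCloud:
    """Integer voxel coordinates of one cell (the point set A)."""

    points: np.ndarray  # (n, 3) int
    cell_name: str
    embryo_id: str
    timepoint: float
    volume_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 3)
        if len(self.points) == 0:
            raise ValueError("a cell point cloud cannot be empty")

    @property
    def n_voxels(self) -> int:
        return len(self.points)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class SurfacePointSet:
    """One-voxel outer shell S = D \\ A of a cell, with the cell's centroid.

    ``centroid`` and ``volume_voxels`` describe the *cell* (set A), not the
    shell: the centroid is the mean of A and the volume is |A|.
    """

    points: np.ndarray  # (n, 3) int
    centroid: np.ndarray
    volume_voxels: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=np.int64).reshape(-1, 3)
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.volume_voxels <= 0:
            raise ValueError("volume_voxels must be positive")


def read_labeled_volume(path: str | Path, embryo_id: str, timepoint: float,
                        label_map: dict[int, str] | None = None) -> LabeledVolume:
    """Read a multi-page TIFF or NIfTI labeled segmentation volume.

    The voxel type must be integer; float-valued images are rejected rather
    than silently rounded.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    try:
        if suffixes.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            img = nib.load(str(path))
            arr = np.asanyarray(img.dataobj)
        else:
            import tifffile

            arr = tifffile.imread(str(path))
    except FormatError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise FormatError(f"could not read labeled volume {path}: {exc}") from exc
    arr = np.asarray(arr)
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(
            f"labeled volume {path} has non-integer voxel type {arr.dtype}"
        )
    return LabeledVolume(arr, embryo_id, timepoint, label_map or {})


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table CSV with columns ``embryo,cell,time,label``."""
    df = pd.read_csv(path)
    required = {"embryo", "cell", "time", "label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"cell table missing columns: {sorted(missing)}")
    return df


def extract_cell(volume: LabeledVolume, label: int) -> CellPointCloud:
    """Return the voxels carrying ``label`` as a point cloud.

    Connectivity is not enforced: two disjoint blobs sharing a label are
    returned as one cloud.  Background (label 0) is not a cell.
    """
    if label == 0:
        raise KeyError("label 0 is background, not a cell")
    pts = np.argwhere(volume.array == label)
    if len(pts) == 0:
        raise KeyError(f"label {label} not present in volume")
    name = volume.label_map.get(int(label), str(label))
    return CellPointCloud(
        pts, name, volume.embryo_id, volume.timepoint,
        volume_shape=tuple(volume.array.shape),
    )


def extract_all_cells(volume: LabeledVolume) -> dict[int, CellPointCloud]:
    """All cells of a volume in one pass (label -> point cloud)."""
    nz = np.argwhere(volume.array != 0)
    vals = volume.array[nz[:, 0], nz[:, 1], nz[:, 2]]
    order = np.argsort(vals, kind="stable")
    nz, vals = nz[order], vals[order]
    out = {}
    for label, start, count in zip(*np.unique(vals, return_index=True,
                                              return_counts=True)):
        name = volume.label_map.get(int(label), str(label))
        out[int(label)] = CellPointCloud(
            nz[start:start + count], name, volume.embryo_id, volume.timepoint,
            volume_shape=tuple(volume.array.shape))
    return out


def dilate(cloud: CellPointCloud) -> np.ndarray:
    """Minkowski sum D = A (+) B with the full 3x3x3 structuring element.

    Returns the dilated point set D as a unique (n, 3) integer array.
    A is a subset of D by construction (B contains the origin).
    """
    pts = cloud.points
    shifted = (pts[:, None, :] + _CUBE_OFFSETS[None, :, :]).reshape(-1, 3)
    # row-unique via scalar keys: much faster than lexicographic unique
    mins = shifted.min(axis=0)
    span = shifted.max(axis=0) - mins + 1
    keys = np.unique(_encode_rows(shifted, mins, span))
    return _decode_keys(keys, mins, span)


def surface_points(cloud: CellPointCloud) -> SurfacePointSet:
    """Extract the outer surface shell S = D \\ A of a cell.

    The "logical disjunction" of A with its dilation D is taken as the
    symmetric difference; since A ⊆ D this equals the set difference and
    yields the one-voxel shell just outside the cell.
    """
    d = dilate(cloud)
    a = cloud.points
    if cloud.volume_shape is not None:
        lo_touch = (a == 0).any()
        hi = np.asarray(cloud.volume_shape) - 1
        if lo_touch or (a == hi).any():
            warnings.warn(
                f"cell {cloud.cell_name} touches the volume boundary; "
                "its surface shell extends past the acquired field of view",
                stacklevel=2,
            )
    s = _setdiff_rows(d, a)
    return SurfacePointSet(s, cloud.centroid, cloud.n_voxels)


def _encode_rows(x: np.ndarray, mins: np.ndarray, span: np.ndarray) -> np.ndarray:
    y = x - mins
    return (y[:, 0] * span[1] + y[:, 1]) * span[2] + y[:, 2]


def _decode_keys(keys: np.ndarray, mins: np.ndarray, span: np.ndarray) -> np.ndarray:
    z, rem = np.divmod(keys, span[1] * span[2])
    y, x = np.divmod(rem, span[2])
    return np.column_stack([z, y, x]) + mins


def _setdiff_rows(d: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Rows of d not present in a (both int (n,3) arrays)."""
    mins = np.minimum(d.min(axis=0), a.min(axis=0))
    span = np.maximum(d.max(axis=0), a.max(axis=0)) - mins + 1
    mask = ~np.isin(_encode_rows(d, mins, span), _encode_rows(a, mins, span))
    return d[mask]


def write_surface_csv(surface: SurfacePointSet, csv_path: str | Path) -> None:
    """Write a surface as an ``x,y,z`` CSV plus a JSON sidecar.

    The sidecar records the cell centroid and voxel volume so downstream
    steps can normalize without re-reading the volume.
    """
    csv_path = Path(csv_path)
    pd.DataFrame(surface.points, columns=["x", "y", "z"]).to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "centroid": list(map(float, surface.centroid)),
        "volume_voxels": int(surface.volume_voxels),
    }))


def read_surface_csv(csv_path: str | Path) -> SurfacePointSet:
    """Inverse of :func:`write_surface_csv`."""
    csv_path = Path(csv_path)
    pts = pd.read_csv(csv_path)[["x", "y", "z"]].to_numpy()
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return SurfacePointSet(pts, np.asarray(meta["centroid"]), int(meta["volume_voxels"]))
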