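"""Synthetic voxel embryos with known shapes, lineages and fates.

Real segmented embryo volumes are large and not redistributable, so this
module generates controllable stand-ins: star-shaped voxelized cells
whose surface is a radial modulation of a sphere,

    voxel p in cell  iff  |p - c| <= R * g(theta, phi),

with ``g`` chosen per phenotype -- a plain sphere, an ellipsoid, a
horizontal ring depression at the cell equator (the hallmark deformation
of embryonic skin cells), or an azimuthal lobed shape.  A binary-division
lineage with systematic names carries the cells through time; leaf cells
receive fate classes with class-specific shapes, so ground truth for
classifier and clustering benchmarks is known by construction.  All
randomness is driven by seeds: the same seed regenerates the same embryo
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y_all

from .io import CellPointCloud, LabeledVolume

SHAPE_KINDS = ("sphere", "ellipsoid", "ring_depressed", "lobed")

#: canonical parent of each early-lineage founder cell
FOUNDER_PARENTS = {
    "AB": "P0", "P1": "P0", "EMS": "P1", "P2": "P1",
    "MS": "EMS", "E": "EMS", "C": "P2", "P3": "P2", "D": "P3", "P4": "P3",
}


@dataclass
class ShapeSpec:
    """Parameterized star-shaped cell phenotype.

    ``params`` per kind: ellipsoid ``axes=(sz, sy, sx)`` relative
    semi-axes; ring_depressed ``depth`` in [0, 1) and ``width`` (Gaussian
    half-width in theta, radians); lobed ``amplitude`` and ``lobes``.
    ``noise_amplitude`` adds seeded band-limited (l <= 4) radial noise so
    instances of one phenotype differ slightly.
    """

    kind: str = "sphere"
    radius: float = 10.0
    params: dict = field(default_factory=dict)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # Euler zyx, degrees
    noise_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in SHAPE_KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.radius < 6:
            raise ValueError("radius must be >= 6 voxels for voxelization fidelity")
        depth = self.params.get("depth", 0.0)
        if not 0 <= depth < 1:
            raise ValueError("depression depth must be in [0, 1)")


def _noise_coeffs(seed: int, l_max: int = 4) -> tuple[np.ndarray, float, float]:
    """Random coefficients of a band-limited radial field.

    Returns (coefficient array indexed [l, m, re/im], analytic unit-RMS
    normalizer, rigorous sup bound of the normalized field).  The
    normalization uses the exact sphere-average RMS of the drawn
    expansion, so evaluating the field on any subset of directions gives
    identical values.
    """
    rng = np.random.default_rng(seed)
    coef = np.zeros((l_max + 1, l_max + 1, 2))
    var = 0.0
    sup = 0.0
    for l in range(1, l_max + 1):
        for m in range(0, l + 1):
            a, b = rng.standard_normal(2)
            if m == 0:
                coef[l, 0, 0] = a
                var += a ** 2
                sup += abs(a) * np.sqrt((2 * l + 1) / (4 * np.pi))
            else:
                coef[l, m] = (a, b)
                var += (a ** 2 + b ** 2) / 2
                sup += np.hypot(a, b) * np.sqrt((2 * l + 1) / (4 * np.pi))
    rms = np.sqrt(var / (4 * np.pi))
    return coef, rms, sup / rms if rms > 0 else 0.0


def _noise_eval(coef: np.ndarray, rms: float, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the normalized band-limited field at unit directions."""
    l_max = coef.shape[0] - 1
    theta = np.arccos(np.clip(dirs[:, 0], -1, 1))
    phi = np.mod(np.arctan2(dirs[:, 1], dirs[:, 2]), 2 * np.pi)
    ylm = sph_harm_y_all(l_max, l_max, theta, phi)
    f = np.zeros(len(dirs))
    for l in range(1, l_max + 1):
        f += coef[l, 0, 0] * ylm[l, 0].real
        for m in range(1, l + 1):
            f += coef[l, m, 0] * ylm[l, m].real + coef[l, m, 1] * ylm[l, m].imag
    return f / rms if rms > 0 else f


def _noise_field(dirs: np.ndarray, seed: int, l_max: int = 4) -> np.ndarray:
    """Unit-RMS band-limited random radial field sampled at unit dirs."""
    coef, rms, _ = _noise_coeffs(seed, l_max)
    return _noise_eval(coef, rms, dirs)


def _base_modulation(spec: ShapeSpec, dirs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free g at unit dirs, plus the shape-frame (rotated) dirs."""
    rot = Rotation.from_euler("zyx", spec.rotation, degrees=True)
    # rotate the shape by R <=> evaluate the base shape at R^-1 * dir;
    # dirs are (z, y, x), Rotation works in (x, y, z)
    d_xyz = dirs[:, ::-1] @ rot.as_matrix()  # == R^-1 applied to each dir
    d = d_xyz[:, ::-1]
    if spec.kind == "sphere":
        g = np.ones(len(d))
    elif spec.kind == "ellipsoid":
        axes = np.asarray(spec.params.get("axes", (1.3, 1.0, 0.8)), dtype=float)
        g = 1.0 / np.sqrt(((d / axes) ** 2).sum(axis=1))
    elif spec.kind == "ring_depressed":
        depth = float(spec.params.get("depth", 0.3))
        width = float(spec.params.get("width", 0.35))
        theta = np.arccos(np.clip(d[:, 0], -1, 1))
        g = 1.0 - depth * np.exp(-(((theta - np.pi / 2) / width) ** 2))
    else:  # lobed
        amp = float(spec.params.get("amplitude", 0.2))
        k = int(spec.params.get("lobes", 3))
        theta = np.arccos(np.clip(d[:, 0], -1, 1))
        phi = np.arctan2(d[:, 1], d[:, 2])
        g = 1.0 + amp * np.cos(k * phi) * np.sin(theta)
    return g, d


def radial_modulation(spec: ShapeSpec, dirs: np.ndarray) -> np.ndarray:
    """Evaluate the phenotype's g(direction) at unit vectors (z, y, x)."""
    g, d = _base_modulation(spec, dirs)
    if spec.noise_amplitude > 0:
        g = g * (1.0 + spec.noise_amplitude * _noise_field(d, spec.seed))
    if np.any(g <= 0):
        raise ValueError("shape parameters drive the radius non-positive")
    return g


def _max_base_g(spec: ShapeSpec) -> float:
    if spec.kind == "ellipsoid":
        return float(np.max(spec.params.get("axes", (1.3, 1.0, 0.8))))
    if spec.kind == "lobed":
        return 1.0 + abs(float(spec.params.get("amplitude", 0.2)))
    return 1.0


def make_shape(spec: ShapeSpec, center: tuple[float, float, float] | None = None,
               cell_name: str = "cell", embryo_id: str = "synthetic",
               timepoint: float = 0.0) -> CellPointCloud:
    """Voxelize a shape spec into a cell point cloud.

    A voxel is included iff its center lies inside the star-shaped
    surface R * g(direction) about ``center``.  The band-limited noise
    field is only evaluated on the shell of voxels whose in/out status
    it can change (a rigorous sup bound decides the rest), which is a
    large speedup at identical output.
    """
    if spec.noise_amplitude > 0:
        coef, rms, sup = _noise_coeffs(spec.seed)
        band = spec.noise_amplitude * sup
        if band >= 1:
            raise ValueError("noise amplitude too large for a valid shape")
    else:
        coef, rms, band = None, 0.0, 0.0
    pad = 3
    half = int(np.ceil(spec.radius * _max_base_g(spec) * (1 + band))) + pad
    if center is None:
        center = (float(half),) * 3
    c = np.asarray(center, dtype=float)
    lo = np.floor(c - half).astype(int)
    axes = [np.arange(lo[i], lo[i] + 2 * half + 1) for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    coords = np.column_stack([zz.ravel(), yy.ravel(), xx.ravel()])
    offsets = coords - c
    r = np.linalg.norm(offsets, axis=1)
    inside = np.zeros(len(coords), dtype=bool)
    nz = r > 0
    dirs = offsets[nz] / r[nz, None]
    g0, d = _base_modulation(spec, dirs)
    if np.any(g0 <= 0):
        raise ValueError("shape parameters drive the radius non-positive")
    boundary = spec.radius * g0
    if coef is None:
        inside[nz] = r[nz] <= boundary
    else:
        rn = r[nz]
        sure_in = rn <= boundary * (1 - band)
        unsure = (~sure_in) & (rn <= boundary * (1 + band))
        dec = sure_in.copy()
        if unsure.any():
            noise = _noise_eval(coef, rms, d[unsure])
            dec[unsure] = rn[unsure] <= boundary[unsure] * (
                1 + spec.noise_amplitude * noise)
        inside[nz] = dec
    inside[~nz] = True  # the center voxel is always interior
    pts = coords[inside]
    if len(pts) == 0:
        raise ValueError("shape spec voxelized to an empty set")
    return CellPointCloud(pts, cell_name, embryo_id, timepoint)


def rotate_cloud(cloud: CellPointCloud, rotation: Rotation) -> CellPointCloud:
    """Rigidly rotate a voxelized cell about its centroid and re-voxelize.

    The solid is rasterized, resampled through the rotation with
    trilinear interpolation, and re-thresholded, which preserves volume
    to within a few percent.  The identity rotation returns the voxel set
    unchanged.
    """
    pts = cloud.points
    lo = pts.min(axis=0)
    span = pts.max(axis=0) - lo + 1
    pad = int(np.ceil(span.max() * 0.4)) + 2
    vol = np.zeros(tuple(span + 2 * pad), dtype=float)
    idx = pts - lo + pad
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = 1.0
    centroid = cloud.centroid - lo + pad
    # map output voxel x to input R^-1 (x - c) + c; ndimage uses (z, y, x)
    # index order so flip the (x, y, z) rotation matrix accordingly
    m_xyz = rotation.as_matrix()
    m = m_xyz[::-1, ::-1].T  # inverse rotation in (z, y, x) index order
    out = ndimage.affine_transform(vol, m, offset=centroid - m @ centroid, order=1)
    new_pts = np.argwhere(out > 0.5) + lo - pad
    return CellPointCloud(new_pts, cloud.cell_name, cloud.embryo_id, cloud.timepoint)


def rotate_augment(cloud: CellPointCloud, n_rotations: int, seed: int = 0) -> list[CellPointCloud]:
    """Re-voxelized copies of a cell under uniformly random rotations."""
    if n_rotations < 1:
        raise ValueError("n_rotations must be >= 1")
    rots = Rotation.random(n_rotations, rng=np.random.default_rng(seed))
    return [rotate_cloud(cloud, rots[i]) for i in range(n_rotations)]


# --------------------------------------------------------------------------
# lineage + embryo generation

def _division_suffixes(name: str) -> tuple[str, str]:
    """Daughter-name suffixes, alternating a/p and l/r by generation."""
    depth = len(name)
    return ("a", "p") if depth % 2 == 0 else ("l", "r")


def make_lineage(n_leaves: int) -> dict[str, dict]:
    """Binary lineage of ``n_leaves`` terminal cells rooted at AB.

    Returns name -> {parent, generation}; every child's name is its
    parent's name plus one character, following the systematic
    nomenclature of the worm lineage.
    """
    if n_leaves < 1:
        raise ValueError("need at least one leaf")
    nodes = {"AB": {"parent": None, "generation": 0}}
    leaves = ["AB"]
    while len(leaves) < n_leaves:
        name = leaves.pop(0)  # breadth-first: keeps the tree balanced
        gen = nodes[name]["generation"]
        for suf in _division_suffixes(name):
            child = name + suf
            nodes[child] = {"parent": name, "generation": gen + 1}
            leaves.append(child)
    for leaf in leaves:
        nodes[leaf]["leaf"] = True
    return nodes


@dataclass
class SyntheticEmbryo:
    """One generated embryo: labeled volumes plus cell and fate tables."""

    embryo_id: str
    volumes: dict[float, LabeledVolume]
    cell_table: pd.DataFrame      # embryo, cell, time, label
    fate_table: pd.DataFrame      # cell, fate
    generator_params: dict

    def timepoints(self) -> list[float]:
        return sorted(self.volumes)


_CLASS_SHAPES = {
    "skin": ("ring_depressed", {"depth": 0.35, "width": 0.35}),
    "other": ("sphere", {}),
    "lobed": ("lobed", {"amplitude": 0.25, "lobes": 3}),
    "progenitor": ("sphere", {}),
}


def make_embryo(n_cells: int = 40,
                class_fractions: dict[str, float] | None = None,
                n_timepoints: int = 220,
                jitter: float = 2.0,
                seed: int = 0,
                time_step: float = 5.0,
                radius: float = 10.0,
                noise_amplitude: float = 0.03,
                embryo_id: str | None = None) -> SyntheticEmbryo:
    """Generate one time-resolved labeled embryo with known fates.

    ``n_cells`` terminal cells divide out of a single founder over
    ``n_timepoints`` minutes (sampled every ``time_step``); each
    generation occupies one equal time band, jittered per cell by up to
    ``jitter`` minutes per embryo.  Leaf cells draw a fate from
    ``class_fractions`` (default 30% skin / 70% other) and are rendered
    with their fate's phenotype; progenitors are spheres.  Cells are
    packed without overlap on a lattice with a 2-voxel margin.
    """
    if class_fractions is None:
        class_fractions = {"skin": 0.3, "other": 0.7}
    if abs(sum(class_fractions.values()) - 1.0) > 1e-9:
        raise ValueError("class fractions must sum to 1")
    if embryo_id is None:
        embryo_id = f"sim{seed}"
    root_seq = np.random.SeedSequence([seed, 1315423911])
    s_fate, s_jit, s_shape = [np.random.default_rng(s) for s in root_seq.spawn(3)]

    nodes = make_lineage(n_cells)
    leaves = [n for n, v in nodes.items() if v.get("leaf")]
    max_gen = max(v["generation"] for v in nodes.values())

    # fates: deterministic counts per class, randomly assigned to leaves
    counts = {c: int(round(f * len(leaves))) for c, f in class_fractions.items()}
    drift = len(leaves) - sum(counts.values())
    counts[max(counts, key=counts.get)] += drift
    order = s_fate.permutation(len(leaves))
    fates, i = {}, 0
    for cls, cnt in counts.items():
        for j in range(cnt):
            fates[leaves[order[i]]] = cls
            i += 1
    for n in nodes:
        if n not in fates:
            fates[n] = "progenitor"

    # lifespans: generation g lives in band [g, g+1) * T/(G+1); leaves to T
    T = float(n_timepoints)
    band = T / (max_gen + 1)
    spans = {}
    for name, v in nodes.items():
        g = v["generation"]
        start = g * band + (s_jit.uniform(-jitter, jitter) if g > 0 else 0.0)
        end = T if v.get("leaf") else (g + 1) * band + s_jit.uniform(-jitter, jitter)
        spans[name] = (start, max(end, start + time_step))

    labels = {name: i + 1 for i, name in enumerate(sorted(nodes))}
    radii = {name: max(6.0, radius * (1 + s_shape.uniform(-0.15, 0.15)))
             for name in sorted(nodes)}

    times = [t * time_step for t in range(int(np.floor(T / time_step)) + 1) if t * time_step < T]
    volumes: dict[float, LabeledVolume] = {}
    rows = []
    margin = 2
    slot = int(2 * np.ceil(radius * 1.5) + 2 * margin + 1)
    for tp in times:
        alive = sorted(n for n, (s, e) in spans.items() if s <= tp < e)
        if not alive:
            continue
        side = int(np.ceil(len(alive) ** (1 / 3)))
        shape = (side * slot,) * 3
        arr = np.zeros(shape, dtype=np.uint16)
        label_map = {}
        for k, name in enumerate(alive):
            cls = fates[name]
            kind, params = _CLASS_SHAPES.get(cls, ("sphere", {}))
            inst_seed = int(np.random.SeedSequence(
                [seed, labels[name], int(tp * 1000)]).generate_state(1)[0] % (2 ** 31))
            spec = ShapeSpec(kind=kind, radius=radii[name], params=params,
                             noise_amplitude=noise_amplitude, seed=inst_seed)
            ci, cj, ck = np.unravel_index(k, (side, side, side))
            center = (np.array([ci, cj, ck]) + 0.5) * slot
            cloud = make_shape(spec, center=tuple(center), cell_name=name,
                               embryo_id=embryo_id, timepoint=tp)
            arr[cloud.points[:, 0], cloud.points[:, 1], cloud.points[:, 2]] = labels[name]
            label_map[labels[name]] = name
            rows.append({"embryo": embryo_id, "cell": name, "time": tp,
                         "label": labels[name]})
        volumes[tp] = LabeledVolume(arr, embryo_id, tp, label_map)

    cell_table = pd.DataFrame(rows)
    fate_table = pd.DataFrame(
        [{"cell": n, "fate": fates[n]} for n in sorted(nodes)])
    params = {"n_cells": n_cells, "class_fractions": dict(class_fractions),
              "n_timepoints": n_timepoints, "jitter": jitter, "seed": seed,
              "time_step": time_step, "radius": radius,
              "noise_amplitude": noise_amplitude}
    return SyntheticEmbryo(embryo_id, volumes, cell_table, fate_table, params)


def make_population(n_embryos: int, seed: int = 0, **kwargs) -> list[SyntheticEmbryo]:
    """Independent jittered embryos sharing one lineage template."""
    seqs = np.random.SeedSequence([seed, 2654435769]).generate_state(n_embryos)
    return [make_embryo(seed=int(s % (2 ** 31)), embryo_id=f"sim{i:02d}", **kwargs)
            for i, s in enumerate(seqs)]
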