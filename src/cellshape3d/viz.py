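"""Lineage heat-trees and OBJ mesh export of spherical-grid shapes.

The heat-tree draws the (average) lineage with time running left to
right, one horizontal branch per cell, colored by an eigen-weight
component on a diverging blue-white-red map centered at zero (blue =
depression-dominant, red = protrusion-dominant, 0 = no deformation).
Static mode colors each minute of a branch separately; dynamic mode
gives each cell one color.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.collections import LineCollection
from matplotlib.colors import Normalize

from .grid import SphericalGrid
from .lineage import AverageLineage

GREY = (0.75, 0.75, 0.75, 1.0)


@dataclass
class TreePlotSpec:
    """Options for a lineage heat-tree rendering."""

    value_source: str = "static_per_minute"  # or "dynamic"
    component_index: int = 1
    color_limit: float | None = None  # symmetric about 0; None = data quantile
    cmap: str = "bwr"

    def __post_init__(self) -> None:
        if self.value_source not in ("static_per_minute", "dynamic"):
            raise ValueError("value_source must be static_per_minute or dynamic")
        if self.color_limit is not None and self.color_limit <= 0:
            raise ValueError("color_limit must be positive (symmetric about 0)")


def _leaf_positions(avg: AverageLineage) -> dict[str, float]:
    """y position per node: leaves in traversal order, parents centered."""
    pos: dict[str, float] = {}
    counter = [0.0]

    def walk(name: str) -> float:
        kids = avg.children(name)
        if not kids:
            pos[name] = counter[0]
            counter[0] += 1.0
        else:
            pos[name] = float(np.mean([walk(k) for k in kids]))
        return pos[name]

    for root in avg.roots():
        walk(root)
    return pos


def plot_lineage_heat(avg: AverageLineage, values: pd.DataFrame,
                      spec: TreePlotSpec, out_path: str | Path) -> Path:
    """Render the lineage tree colored by per-cell(-minute) values.

    ``values`` holds columns ``cell, value`` plus ``time`` for the
    static source.  Cells without values are drawn grey.  Layout is
    deterministic (alphabetical child order).
    """
    out_path = Path(out_path)
    pos = _leaf_positions(avg)
    if spec.color_limit is None:
        vmax = float(np.nanquantile(np.abs(values["value"]), 0.98)) or 1.0
    else:
        vmax = spec.color_limit
    norm = Normalize(-vmax, vmax)
    cmap = plt.get_cmap(spec.cmap)

    fig, ax = plt.subplots(figsize=(10, max(3, 0.22 * len(pos))))
    segments, colors = [], []
    for name, node in avg.nodes.items():
        y = pos[name]
        sub = values[values["cell"] == name]
        if spec.value_source == "dynamic":
            color = cmap(norm(float(sub["value"].mean()))) if len(sub) else GREY
            segments.append([(node.start, y), (node.end, y)])
            colors.append(color)
        else:
            if len(sub) == 0:
                segments.append([(node.start, y), (node.end, y)])
                colors.append(GREY)
            else:
                sub = sub.sort_values("time")
                t = sub["time"].to_numpy(dtype=float)
                v = sub["value"].to_numpy(dtype=float)
                edges = np.concatenate([[node.start], (t[1:] + t[:-1]) / 2,
                                        [node.end]])
                for j in range(len(t)):
                    segments.append([(edges[j], y), (edges[j + 1], y)])
                    colors.append(cmap(norm(v[j])))
        for kid in avg.children(name):
            segments.append([(node.end, y), (node.end, pos[kid])])
            colors.append((0.3, 0.3, 0.3, 1.0))
    ax.add_collection(LineCollection(segments, colors=colors, linewidths=2.5))
    ax.autoscale()
    ax.set_xlabel("time (min)")
    ax.set_yticks([])
    label = f"component {spec.component_index} weight"
    fig.colorbar(plt.cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, label=label)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def export_mesh(grid: SphericalGrid, out_path: str | Path) -> Path:
    """Write the grid surface as a watertight OBJ mesh.

    Vertices are r(theta_i, phi_j) * direction with the two pole rows
    fused to single vertices; quads between latitude rings are split
    into triangles and the poles are closed with triangle fans.
    """
    if np.any(grid.values <= 0):
        raise ValueError("mesh export requires strictly positive radii")
    rows, cols = grid.shape
    theta, phi = grid.theta_axis, grid.phi_axis
    verts = []
    north = grid.values[0].mean()
    south = grid.values[-1].mean()
    verts.append((north, 0.0, 0.0))            # +z pole, (z, y, x)
    for i in range(1, rows - 1):
        st, ct = np.sin(theta[i]), np.cos(theta[i])
        for j in range(cols):
            r = grid.values[i, j]
            verts.append((r * ct, r * st * np.sin(phi[j]), r * st * np.cos(phi[j])))
    verts.append((-south, 0.0, 0.0))
    n_south = len(verts)  # 1-based OBJ index of the south pole

    def ring(i: int, j: int) -> int:
        # 1-based OBJ index of interior row i (1..rows-2), column j
        return 2 + (i - 1) * cols + (j % cols)

    faces = []
    for j in range(cols):  # north fan
        faces.append((1, ring(1, j), ring(1, j + 1)))
    for i in range(1, rows - 2):
        for j in range(cols):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j + 1), ring(i + 1, j)
            faces.append((a, b, c))
            faces.append((a, c, d))
    for j in range(cols):  # south fan
        faces.append((n_south, ring(rows - 2, j + 1), ring(rows - 2, j)))

    out_path = Path(out_path)
    with out_path.open("w") as fh:
        for z, y, x in verts:
            fh.write(f"v {x:.8f} {y:.8f} {z:.8f}\n")
        for a, b, c in faces:
            fh.write(f"f {a} {b} {c}\n")
    return out_path
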