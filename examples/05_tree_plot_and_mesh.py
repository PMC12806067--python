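"""Render a lineage heat-tree and export a reconstructed cell as OBJ.

Writes two artifacts under ./scratch: a lineage tree colored by
eigengrid 1 per minute (blue = depression-dominant, red = protrusion)
and a triangulated mesh of one cell's spherical-grid surface.
"""

import warnings
from pathlib import Path

from cellshape3d import make_embryo
from cellshape3d.grid import unflatten
from cellshape3d.lineage import average_lineage, build_tree, static_on_tree
from cellshape3d.pipeline import embryo_features, fit_eigen_bases, weight_table
from cellshape3d.viz import TreePlotSpec, export_mesh, plot_lineage_heat

out = Path("scratch")
out.mkdir(exist_ok=True)

embryo = make_embryo(n_cells=12, n_timepoints=100, time_step=10, seed=6)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    tables = embryo_features(embryo)
    basis = fit_eigen_bases(tables, n_components=6, kinds=("grid",))["grid"]
weights = weight_table(tables, basis)

tree = build_tree(embryo.cell_table, fate_table=embryo.fate_table)
avg = average_lineage([tree])
values = static_on_tree(avg, weights, component_index=1)

png = plot_lineage_heat(avg, values, TreePlotSpec(component_index=1),
                        out / "lineage_tree.png")
print(f"wrote {png} ({png.stat().st_size} bytes): one branch per cell, "
      "colored by eigengrid 1 per minute")

row = tables.grid[len(tables.grid) // 2]
obj = export_mesh(unflatten(row), out / "cell.obj")
n_verts = sum(1 for line in obj.read_text().splitlines() if line.startswith("v "))
print(f"wrote {obj} with {n_verts} vertices (fused poles, watertight fans)")
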