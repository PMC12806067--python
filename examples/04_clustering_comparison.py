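"""Compare clustering of the three eigen features under random rotation.

Two deformation phenotypes are rendered in random orientations.  Grid
and coefficient features depend on orientation, so their clusters
smear; the per-degree power spectrum is rotation-invariant and keeps
the classes separable — the rationale for eigenspectrum features.
"""

import numpy as np

from cellshape3d import ShapeSpec, make_shape, project
from cellshape3d.cluster import compare_methods
from cellshape3d.pipeline import features_from_clouds, fit_eigen_bases

rng = np.random.default_rng(4)
clouds = []
for i in range(12):
    for kind, params in (("ring_depressed", {"depth": 0.35}),
                         ("lobed", {"amplitude": 0.25, "lobes": 3})):
        spec = ShapeSpec(kind=kind, radius=10, params=params,
                         rotation=tuple(rng.uniform(0, 360, size=3)),
                         noise_amplitude=0.02,
                         seed=int(rng.integers(2 ** 31)))
        clouds.append(make_shape(spec, cell_name=f"{kind[:4]}{i}"))

tables = features_from_clouds(clouds)
bases = fit_eigen_bases(tables, n_components=10)
weights = {kind: project(basis, tables.matrix(kind))
           for kind, basis in bases.items()}

scores = compare_methods(weights, methods=("kmeans", "ward", "average",
                                           "complete", "single"), seed=0)
print("silhouette scores (best k per method), higher = cleaner clusters:\n")
print(scores.drop(columns="inflated").to_string(float_format=lambda x: f"{x:5.2f}"))
print("\nthe eigenspectrum column should dominate: rotation cannot scramble "
      "per-degree power")
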