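"""Lineage trees, the average lineage, and threshold-based cell calling.

Worm lineage names are systematic: every daughter's name is its mother's
name plus one character (ABp -> ABpl), with the early founder relations
(P0 -> AB/P1, EMS -> MS/E, ...) given explicitly.  A per-embryo tree is
therefore recoverable from a cell table alone.  Trees of several embryos
are combined into an *average* lineage whose per-cell lifespan is the
across-embryo mean of first and last observation,

    Range(cell) = [ mean_i start_i, mean_i end_i ],

and whose per-minute feature value is the across-embryo mean of the
chosen eigen-weight component at that minute.  Cells whose first
eigen-weight stays large in absolute value after ~100 minutes of
development (the paper's stage clock: last 4-cell stage = 0 min) are
called as skin-like; precision/recall of the call is evaluated against a
user-supplied fate table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import FOUNDER_PARENTS

VIRTUAL_ROOT = "<root>"


@dataclass
class LineageNode:
    name: str
    parent: str | None
    start: float
    end: float
    fate: str | None = None


@dataclass
class LineageTree:
    """Per-embryo lineage: cell name -> node with lifespan and parent."""

    embryo_id: str
    nodes: dict[str, LineageNode] = field(default_factory=dict)

    def children(self, name: str) -> list[str]:
        return sorted(n for n, v in self.nodes.items() if v.parent == name)

    def roots(self) -> list[str]:
        return sorted(n for n, v in self.nodes.items()
                      if v.parent is None or v.parent == VIRTUAL_ROOT)


@dataclass
class AverageLineage:
    """Across-embryo averaged lineage.

    ``nodes[name]`` carries the averaged lifespan; ``n_embryos`` is the
    number of embryos combined (a cell present in fewer embryos is
    averaged over those containing it).
    """

    nodes: dict[str, LineageNode]
    n_embryos: int
    n_per_cell: dict[str, int] = field(default_factory=dict)

    def children(self, name: str) -> list[str]:
        return sorted(n for n, v in self.nodes.items() if v.parent == name)

    def roots(self) -> list[str]:
        return sorted(n for n, v in self.nodes.items()
                      if v.parent is None or v.parent == VIRTUAL_ROOT)


def _infer_parent(name: str, present: set[str],
                  founder_parents: dict[str, str]) -> str | None:
    """Longest proper name prefix present in the table, else founder map."""
    for cut in range(len(name) - 1, 0, -1):
        if name[:cut] in present:
            return name[:cut]
    anc = name
    while anc in founder_parents:
        anc = founder_parents[anc]
        if anc in present:
            return anc
    return None


def build_tree(cell_table: pd.DataFrame,
               founder_parents: dict[str, str] | None = None,
               fate_table: pd.DataFrame | None = None) -> LineageTree:
    """Build a lineage tree from an ``embryo,cell,time`` table.

    A cell's lifespan is [first, last] observed timepoint.  A cell whose
    parent cannot be resolved and that is not a founder is attached to a
    virtual root with a warning.
    """
    if founder_parents is None:
        founder_parents = FOUNDER_PARENTS
    embryos = cell_table["embryo"].unique()
    if len(embryos) != 1:
        raise ValueError(f"cell table spans {len(embryos)} embryos; expected 1")
    fates = {}
    if fate_table is not None:
        fates = dict(zip(fate_table["cell"], fate_table["fate"]))
    agg = cell_table.groupby("cell")["time"].agg(["min", "max"])
    present = set(agg.index)
    tree = LineageTree(str(embryos[0]))
    for name, row in agg.iterrows():
        parent = _infer_parent(str(name), present - {name}, founder_parents)
        if parent is None and str(name) not in founder_parents and len(str(name)) > 1:
            warnings.warn(f"cell {name} has no resolvable parent; "
                          "attached to virtual root", stacklevel=2)
            parent = VIRTUAL_ROOT
        tree.nodes[str(name)] = LineageNode(
            str(name), parent, float(row["min"]), float(row["max"]),
            fate=fates.get(str(name)))
    return tree


def average_lineage(trees: list[LineageTree]) -> AverageLineage:
    """Average per-cell lifespans across embryos.

    For each cell name, start and end are the arithmetic means over the
    embryos containing that cell; parent and fate are taken from any tree
    (they are name-determined).
    """
    if not trees:
        raise ValueError("need at least one tree")
    names = sorted({n for t in trees for n in t.nodes})
    nodes, n_per_cell = {}, {}
    for name in names:
        hits = [t.nodes[name] for t in trees if name in t.nodes]
        nodes[name] = LineageNode(
            name,
            hits[0].parent,
            float(np.mean([h.start for h in hits])),
            float(np.mean([h.end for h in hits])),
            fate=next((h.fate for h in hits if h.fate is not None), None),
        )
        n_per_cell[name] = len(hits)
    return AverageLineage(nodes, n_embryos=len(trees), n_per_cell=n_per_cell)


def static_on_tree(avg: AverageLineage, weights: pd.DataFrame,
                   component_index: int = 1,
                   clip_to_range: bool = True) -> pd.DataFrame:
    """Per-(cell, minute) across-embryo mean of one weight component.

    ``weights`` has columns ``embryo, cell, time, w1..wK``;
    ``component_index`` is 1-based (component 1 = largest variance).
    Rows outside a cell's averaged lifespan are dropped when
    ``clip_to_range`` (the averaged tree only carries values inside
    Range(cell)).  Cells in the tree without any records are omitted with
    a warning.
    """
    col = f"w{component_index}"
    if col not in weights.columns:
        raise KeyError(f"weights table has no column {col}")
    df = weights.groupby(["cell", "time"], as_index=False)[col].mean()
    df = df.rename(columns={col: "value"})
    df = df[df["cell"].isin(avg.nodes)]
    if clip_to_range:
        keep = np.zeros(len(df), dtype=bool)
        for i, (cell, t) in enumerate(zip(df["cell"], df["time"])):
            node = avg.nodes[cell]
            keep[i] = node.start - 1e-9 <= t <= node.end + 1e-9
        df = df[keep]
    missing = set(avg.nodes) - set(df["cell"])
    if missing:
        warnings.warn(f"{len(missing)} tree cells have no weight records",
                      stacklevel=2)
    return df.reset_index(drop=True)


def classify_by_threshold(values: pd.DataFrame, threshold: float,
                          min_time_minutes: float = 100.0) -> set[str]:
    """Cells whose mean |value| after ``min_time_minutes`` exceeds the threshold.

    ``values`` has columns ``cell, value`` and optionally ``time``:
    with a time column, only rows at time >= min_time are scored (cells
    with no such rows are negative); without one every cell is eligible.
    The absolute value is used — protrusion- and depression-dominant
    deformations both count.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    df = values.copy()
    if "time" in df.columns:
        df = df[df["time"] >= min_time_minutes]
    score = df.assign(absval=df["value"].abs()).groupby("cell")["absval"].mean()
    return set(score[score >= threshold].index)


def precision_recall(predicted: set[str], truth: set[str]) -> tuple[float, float]:
    """Precision and recall of a predicted cell set, in percent.

    With no predictions precision is undefined and returned as NaN with
    a warning.
    """
    if not truth:
        raise ValueError("truth set is empty")
    tp = len(predicted & truth)
    if not predicted:
        warnings.warn("no positive predictions; precision undefined", stacklevel=2)
        precision = float("nan")
    else:
        precision = 100.0 * tp / len(predicted)
    recall = 100.0 * tp / len(truth)
    return precision, recall


def threshold_sweep(values: pd.DataFrame, truth: set[str],
                    thresholds: list[float],
                    min_time_minutes: float = 100.0) -> pd.DataFrame:
    """Precision/recall table over a list of thresholds.

    The predicted set shrinks (weakly) as the threshold grows; precision
    need not be monotone.
    """
    if len(thresholds) == 0:
        raise ValueError("need at least one threshold")
    rows = []
    for t in thresholds:
        pred = classify_by_threshold(values, t, min_time_minutes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r = precision_recall(pred, truth)
        rows.append({"threshold": t, "n_predicted": len(pred),
                     "precision": p, "recall": r})
    return pd.DataFrame(rows)
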