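"""Lineage building, averaging, per-minute features and threshold calls."""

import numpy as np
import pandas as pd
import pytest

from cellshape3d.lineage import (average_lineage, build_tree,
                                 classify_by_threshold, precision_recall,
                                 static_on_tree, threshold_sweep)
from cellshape3d.synthetic import make_lineage, make_population


def table(rows):
    return pd.DataFrame(rows, columns=["embryo", "cell", "time", "label"])


class TestBuildTree:
    def test_prefix_parent_and_ranges(self):
        df = table([("e", "ABp", t, 1) for t in range(10, 21)]
                   + [("e", "ABpl", t, 2) for t in range(21, 41)])
        tree = build_tree(df)
        assert tree.nodes["ABpl"].parent == "ABp"
        assert (tree.nodes["ABp"].start, tree.nodes["ABp"].end) == (10, 20)
        assert (tree.nodes["ABpl"].start, tree.nodes["ABpl"].end) == (21, 40)

    def test_lone_founder_is_root(self):
        tree = build_tree(table([("e", "AB", 0, 1)]))
        assert tree.nodes["AB"].parent is None
        assert tree.roots() == ["AB"]

    def test_founder_chain_resolved_through_map(self):
        df = table([("e", "EMS", 0, 1), ("e", "E", 5, 2)])
        tree = build_tree(df)
        assert tree.nodes["E"].parent == "EMS"

    def test_orphan_attached_to_virtual_root_with_warning(self):
        df = table([("e", "Qxy", 0, 1)])
        with pytest.warns(UserWarning, match="parent"):
            tree = build_tree(df)
        assert tree.nodes["Qxy"].parent == "<root>"

    def test_generator_round_trip(self, small_embryo):
        tree = build_tree(small_embryo.cell_table,
                          fate_table=small_embryo.fate_table)
        truth = make_lineage(small_embryo.generator_params["n_cells"])
        for name, node in tree.nodes.items():
            assert node.parent == truth[name]["parent"]

    def test_multi_embryo_table_rejected(self):
        df = table([("e1", "AB", 0, 1), ("e2", "AB", 0, 1)])
        with pytest.raises(ValueError):
            build_tree(df)


class TestAverageLineage:
    def test_printed_mean_formula(self):
        t1 = build_tree(table([("e1", "AB", t, 1) for t in (10, 20)]))
        t2 = build_tree(table([("e2", "AB", t, 1) for t in (12, 24)]))
        avg = average_lineage([t1, t2])
        assert avg.nodes["AB"].start == 11
        assert avg.nodes["AB"].end == 22

    def test_single_tree_identity(self):
        t1 = build_tree(table([("e1", "AB", t, 1) for t in (5, 9)]))
        avg = average_lineage([t1])
        assert (avg.nodes["AB"].start, avg.nodes["AB"].end) == (5, 9)
        assert avg.n_embryos == 1

    def test_idempotent_on_identical_trees(self):
        t = build_tree(table([("e", "ABa", x, 1) for x in (3, 8)]
                             + [("e", "ABal", x, 2) for x in (9, 15)]))
        avg = average_lineage([t, t, t])
        for name in t.nodes:
            assert avg.nodes[name].start == t.nodes[name].start
            assert avg.nodes[name].end == t.nodes[name].end

    def test_cell_missing_from_some_embryos_averaged_over_present(self):
        t1 = build_tree(table([("e1", "AB", t, 1) for t in (0, 10)]))
        t2 = build_tree(table([("e2", "AB", t, 1) for t in (2, 12)]
                              + [("e2", "ABa", t, 2) for t in (13, 20)]))
        avg = average_lineage([t1, t2])
        assert avg.n_per_cell["ABa"] == 1
        assert avg.nodes["ABa"].start == 13

    def test_jittered_population_recovers_template(self):
        embryos = make_population(4, seed=5, n_cells=6, n_timepoints=40,
                                  time_step=5, radius=6, jitter=2.0)
        trees = [build_tree(e.cell_table) for e in embryos]
        avg = average_lineage(trees)
        template = make_lineage(6)
        for name, node in avg.nodes.items():
            g = template[name]["generation"]
            band = 40 / (max(t["generation"] for t in template.values()) + 1)
            # observed starts are jittered generation-band edges snapped to
            # the 5-minute sampling grid
            assert abs(node.start - g * band) <= 2.0 + 5.0


class TestStaticOnTree:
    @staticmethod
    def weights_df(rows):
        return pd.DataFrame(rows, columns=["embryo", "cell", "time", "w1"])

    @staticmethod
    def avg_for(cells):
        trees = []
        for emb in {e for e, *_ in cells}:
            trees.append(build_tree(table(
                [(e, c, t, 1) for e, c, t in cells if e == emb])))
        return average_lineage(trees)

    def test_single_embryo_passthrough(self):
        cells = [("e1", "ABa", 0.0), ("e1", "ABa", 1.0)]
        avg = self.avg_for(cells)
        w = self.weights_df([("e1", "ABa", 0.0, 2.0), ("e1", "ABa", 1.0, 4.0)])
        out = static_on_tree(avg, w, 1)
        assert list(out["value"]) == [2.0, 4.0]

    def test_two_embryo_mean(self):
        cells = [("e1", "ABpl", 100.0), ("e2", "ABpl", 100.0)]
        avg = self.avg_for(cells)
        w = self.weights_df([("e1", "ABpl", 100.0, 4.0),
                             ("e2", "ABpl", 100.0, 6.0)])
        out = static_on_tree(avg, w, 1)
        assert list(out["value"]) == [5.0]

    def test_matches_groupby_mean_oracle(self):
        rng = np.random.default_rng(0)
        rows, cells = [], []
        for e in ("e1", "e2", "e3"):
            for c in ("ABa", "ABp"):
                for t in range(5):
                    rows.append((e, c, float(t), rng.standard_normal()))
                    cells.append((e, c, float(t)))
        avg = self.avg_for(cells)
        w = self.weights_df(rows)
        out = static_on_tree(avg, w, 1).set_index(["cell", "time"])
        oracle = w.groupby(["cell", "time"])["w1"].mean()
        for key, val in oracle.items():
            assert np.isclose(out.loc[key, "value"], val)


class TestClassify:
    df = pd.DataFrame({"cell": ["a", "b", "c"], "time": [150.0, 50.0, 150.0],
                       "value": [130.0, 130.0, -125.0]})

    def test_value_above_threshold_after_min_time(self):
        assert "a" in classify_by_threshold(self.df, 120)

    def test_early_cell_excluded(self):
        assert "b" not in classify_by_threshold(self.df, 120)

    def test_absolute_value_used(self):
        assert "c" in classify_by_threshold(self.df, 120)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            classify_by_threshold(self.df, -1)


class TestPrecisionRecall:
    def test_all_predictions_correct_but_misses(self):
        pred = set(range(13))
        truth = set(range(20))
        p, r = precision_recall(pred, truth)
        assert p == 100.0
        assert r == 65.0

    def test_perfect(self):
        p, r = precision_recall({"a", "b"}, {"a", "b"})
        assert (p, r) == (100.0, 100.0)

    def test_matches_confusion_count_oracle(self):
        rng = np.random.default_rng(1)
        universe = list(range(50))
        for _ in range(10):
            pred = set(rng.choice(universe, 15, replace=False).tolist())
            truth = set(rng.choice(universe, 20, replace=False).tolist())
            p, r = precision_recall(pred, truth)
            tp = sum(1 for x in pred if x in truth)
            assert np.isclose(p, 100 * tp / len(pred))
            assert np.isclose(r, 100 * tp / len(truth))

    def test_no_predictions_precision_nan(self):
        with pytest.warns(UserWarning, match="undefined"):
            p, r = precision_recall(set(), {"a"})
        assert np.isnan(p)
        assert r == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            precision_recall({"a"}, set())


class TestThresholdSweep:
    values = pd.DataFrame({
        "cell": list("abcdef"),
        "time": [150.0] * 6,
        "value": [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]})
    truth = {"d", "e", "f"}

    def test_predicted_size_non_increasing(self):
        sweep = threshold_sweep(self.values, self.truth, [5, 15, 25, 35, 45, 55])
        assert (np.diff(sweep["n_predicted"]) <= 0).all()

    def test_zero_threshold_full_recall(self):
        sweep = threshold_sweep(self.values, self.truth, [0.0])
        assert sweep["recall"].iloc[0] == 100.0

    def test_planted_gap_gives_perfect_precision_regime(self):
        sweep = threshold_sweep(self.values, self.truth, [35.0])
        assert sweep["precision"].iloc[0] == 100.0
        assert sweep["recall"].iloc[0] == 100.0

    def test_empty_thresholds_rejected(self):
        with pytest.raises(ValueError):
            threshold_sweep(self.values, self.truth, [])
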