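"""PCA eigen-bases, projection contracts, dynamic features, interpolation."""

import numpy as np
import pandas as pd
import pytest

from cellshape3d.eigen import (EigenBasis, component_shape, dynamic_feature,
                               dynamic_table, fit_basis, interpolate_missing,
                               project, reconstruct)


@pytest.fixture
def toy_basis():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((40, 8))
    return fit_basis(X, 8, "grid"), X


class TestFitBasis:
    def test_constant_matrix_zero_variance(self):
        X = np.tile(np.arange(5.0), (10, 1))
        with pytest.warns(UserWarning, match="constant"):
            basis = fit_basis(X, 3, "grid")
        assert np.allclose(basis.explained_variance_ratio, 0)
        assert np.allclose(project(basis, X), 0)

    def test_planted_two_direction_variances(self):
        rng = np.random.default_rng(1)
        n, d = 2000, 20
        e1 = np.zeros(d); e1[0] = 1
        e2 = np.zeros(d); e2[1] = 1
        X = (rng.standard_normal(n)[:, None] * 3 * e1
             + rng.standard_normal(n)[:, None] * 1 * e2)
        basis = fit_basis(X, 2, "grid")
        assert abs(basis.explained_variance_ratio[0] - 0.9) < 0.02
        assert abs(basis.explained_variance_ratio[1] - 0.1) < 0.02

    def test_full_rank_projection_lossless(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 6))
        basis = fit_basis(X, 6, "grid")
        rec = reconstruct(basis, project(basis, X))
        assert np.allclose(rec, X, atol=1e-9)

    def test_components_orthonormal(self, toy_basis):
        basis, _ = toy_basis
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(basis.n_components), atol=1e-8)

    def test_ratios_non_increasing_and_bounded(self, toy_basis):
        basis, _ = toy_basis
        r = basis.explained_variance_ratio
        assert np.all(np.diff(r) <= 1e-12)
        assert np.all((r >= 0) & (r <= 1))
        assert r.sum() <= 1 + 1e-9

    def test_excessive_k_reduced_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((5, 100))
        with pytest.warns(UserWarning, match="reduced"):
            basis = fit_basis(X, 96, "grid")
        assert basis.n_components == 4

    def test_deterministic_sign_convention(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((50, 7))
        b1 = fit_basis(X, 5, "grid")
        b2 = fit_basis(X[::-1].copy(), 5, "grid")  # permuted rows, same subspace
        for k in range(5):
            assert abs(abs(b1.components[k] @ b2.components[k]) - 1) < 1e-8
            peak = np.argmax(np.abs(b1.components[k]))
            assert b1.components[k][peak] > 0


class TestProjectReconstruct:
    def test_mean_maps_to_zero(self, toy_basis):
        basis, _ = toy_basis
        assert np.allclose(project(basis, basis.mean), 0, atol=1e-12)

    def test_single_component_direction(self, toy_basis):
        basis, _ = toy_basis
        v = basis.mean + 3.0 * basis.components[0]
        w = project(basis, v)
        expected = np.zeros(basis.n_components)
        expected[0] = 3.0
        assert np.allclose(w, expected, atol=1e-9)

    def test_residual_is_out_of_span_component(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 10))
        basis = fit_basis(X, 4, "grid")
        v = rng.standard_normal(10)
        err = v - reconstruct(basis, project(basis, v))
        centered = v - basis.mean
        in_span = basis.components.T @ (basis.components @ centered)
        assert np.allclose(np.linalg.norm(err),
                           np.linalg.norm(centered - in_span), atol=1e-9)

    def test_zero_weights_give_mean(self, toy_basis):
        basis, _ = toy_basis
        assert np.allclose(reconstruct(basis, np.zeros(basis.n_components)),
                           basis.mean)

    def test_length_mismatch_rejected(self, toy_basis):
        basis, _ = toy_basis
        with pytest.raises(ValueError):
            project(basis, np.ones(basis.d + 1))
        with pytest.raises(ValueError):
            reconstruct(basis, np.ones(basis.n_components + 1))


class TestComponentShape:
    def test_grid_mean_shape(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0.8, 1.2, size=(20, 5565))
        basis = fit_basis(X, 3, "grid")
        g = component_shape(basis, 0, scale=0.0)
        assert g.shape == (53, 105)
        assert np.allclose(g.values.ravel(), basis.mean)

    def test_harmonic_mode_renderable(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 676)) * 0.01
        X[:, 0] += np.sqrt(4 * np.pi)
        basis = fit_basis(X, 3, "harmonic")
        coeffs = component_shape(basis, 1, scale=1.0)
        from cellshape3d.harmonics import inverse_transform

        g = inverse_transform(coeffs)
        assert np.all(np.isfinite(g.values))

    def test_planted_ring_mode_recovered(self):
        # population = unit sphere grids +- a mid-theta ring depression
        rng = np.random.default_rng(8)
        theta = np.linspace(0, np.pi, 53)
        ring = -np.exp(-(((theta - np.pi / 2) / 0.3) ** 2))  # depression
        profile = np.tile(ring[:, None], (1, 105)).ravel()
        X = np.empty((60, 5565))
        for i in range(60):
            depth = rng.uniform(0, 0.4)
            X[i] = 1.0 + depth * profile + 0.01 * rng.standard_normal(5565)
        basis = fit_basis(X, 5, "grid")
        comp = basis.components[0].reshape(53, 105)
        mid = np.abs(comp[22:31]).mean()
        off = np.abs(np.vstack([comp[:10], comp[-10:]])).mean()
        assert mid > 3 * off
        signs = np.sign(comp[22:31].ravel())
        assert abs(signs.sum()) > 0.95 * signs.size  # sign-coherent band

    def test_index_out_of_range(self, toy_basis):
        basis, _ = toy_basis
        with pytest.raises(IndexError):
            component_shape(basis, basis.n_components)


class TestDynamicFeature:
    def test_two_timepoint_mean(self):
        df = pd.DataFrame({"embryo": ["e", "e"], "cell": ["ABa", "ABa"],
                           "time": [1.0, 2.0], "w1": [2.0, 4.0]})
        dyn = dynamic_feature(df)
        assert np.allclose(dyn.weights, [3.0])
        assert dyn.n_timepoints == 2

    def test_single_timepoint_equals_static(self):
        df = pd.DataFrame({"embryo": ["e"], "cell": ["ABa"], "time": [1.0],
                           "w1": [5.0], "w2": [-1.0]})
        assert np.allclose(dynamic_feature(df).weights, [5.0, -1.0])

    def test_mixed_cells_rejected(self):
        df = pd.DataFrame({"embryo": ["e", "e"], "cell": ["ABa", "ABp"],
                           "time": [1, 1], "w1": [0, 0]})
        with pytest.raises(ValueError, match="mix"):
            dynamic_feature(df)

    def test_matches_componentwise_mean_oracle(self):
        rng = np.random.default_rng(9)
        W = rng.standard_normal((10, 4))
        df = pd.DataFrame(W, columns=["w1", "w2", "w3", "w4"])
        df["embryo"], df["cell"], df["time"] = "e", "ABa", np.arange(10.0)
        assert np.allclose(dynamic_feature(df).weights, W.mean(axis=0))

    def test_dynamic_table_groups_by_cell(self):
        df = pd.DataFrame({"embryo": ["e"] * 4, "cell": ["a", "a", "b", "b"],
                           "time": [0, 1, 0, 1], "w1": [1.0, 3.0, 10.0, 20.0]})
        out = dynamic_table(df).set_index("cell")
        assert out.loc["a", "w1"] == 2.0
        assert out.loc["b", "w1"] == 15.0
        assert out.loc["a", "n_timepoints"] == 2


class TestInterpolateMissing:
    def test_linear_midpoint(self):
        series = {1.0: np.array([0.0]), 3.0: np.array([4.0])}
        filled = interpolate_missing(series)
        assert np.allclose(filled[2.0], [2.0])

    def test_no_gaps_identity(self):
        series = {0.0: np.array([1.0]), 1.0: np.array([2.0])}
        assert interpolate_missing(series).keys() == series.keys()

    def test_multi_gap_matches_piecewise_linear_oracle(self):
        rng = np.random.default_rng(10)
        times = [0.0, 3.0, 4.0, 9.0]
        series = {t: rng.standard_normal(3) for t in times}
        filled = interpolate_missing(series)
        W = np.array([series[t] for t in times])
        for t in (1.0, 2.0, 5.0, 6.0, 7.0, 8.0):
            oracle = [np.interp(t, times, W[:, j]) for j in range(3)]
            assert np.allclose(filled[t], oracle)

    def test_boundary_gap_warns_and_stays_unfilled(self):
        series = {2.0: np.array([1.0]), 4.0: np.array([2.0])}
        with pytest.warns(UserWarning, match="outside"):
            filled = interpolate_missing(series, target_times=[0.0, 3.0])
        assert 0.0 not in filled
        assert 3.0 in filled


def test_basis_save_load_round_trip(tmp_path, toy_basis):
    basis, _ = toy_basis
    basis.save(tmp_path / "b.json")
    back = EigenBasis.load(tmp_path / "b.json")
    assert back.kind == basis.kind
    assert np.allclose(back.mean, basis.mean)
    assert np.allclose(back.components, basis.components)
    assert np.allclose(back.explained_variance_ratio,
                       basis.explained_variance_ratio)
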