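"""Constrained projection and the hierarchical cascade."""
import numpy as np
import pandas as pd
import pytest

from tmedecon import (
    ValidationError,
    aggregate_to_layer,
    constrained_projection,
    deconvolve,
    deconvolve_layer,
    simplex_grid_search,
)
from tmedecon.library import LayerLibrary


def _toy_library(X, classes=None, tag="T"):
    k = X.shape[1]
    classes = classes or [f"c{j}" for j in range(k)]
    return LayerLibrary(
        tag=tag,
        classes=tuple(classes),
        means=pd.DataFrame(
            X, index=[f"p{j}" for j in range(X.shape[0])], columns=classes
        ),
        markers=pd.DataFrame({"class": [], "rank": [], "probe_id": [], "direction": []}),
        focal_children=tuple(classes),
    )


def _y(lib, vec):
    return pd.Series(vec, index=lib.means.index)


class TestConstrainedProjection:
    def test_vertex_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 1, (20, 3))
        lib = _toy_library(X)
        res = constrained_projection(_y(lib, X[:, 1]), lib)
        np.testing.assert_allclose(res.weights, [0, 1, 0], atol=1e-8)
        assert res.residual_norm <= 1e-8

    def test_exact_interior_mixture(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (25, 2))
        lib = _toy_library(X)
        res = constrained_projection(_y(lib, 0.5 * X[:, 0] + 0.5 * X[:, 1]), lib)
        np.testing.assert_allclose(res.weights, [0.5, 0.5], atol=1e-8)

    def test_weights_nonnegative_and_sum_to_one(self):
        rng = np.random.default_rng(2)
        for k in (2, 3, 4):
            X = rng.uniform(0, 1, (30, k))
            lib = _toy_library(X)
            res = constrained_projection(_y(lib, rng.uniform(0, 1, 30)), lib)
            assert (res.weights >= 0).all()
            assert abs(res.weights.sum() - 1) <= 1e-6

    def test_noisy_mixture_matches_grid_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (30, 3))
        lib = _toy_library(X)
        w_true = np.array([0.6, 0.3, 0.1])
        y = X @ w_true + rng.normal(0, 0.02, 30)
        res = constrained_projection(_y(lib, y), lib)
        w_grid = simplex_grid_search(X, y, step=0.01)
        assert np.abs(res.weights.to_numpy() - w_grid).max() <= 0.01 + 1e-9

    def test_insufficient_probes_raises(self):
        X = np.random.default_rng(4).uniform(0, 1, (5, 3))
        lib = _toy_library(X)
        with pytest.raises(ValidationError, match="usable probes"):
            constrained_projection(_y(lib, X[:, 0]), lib)

    def test_collinear_columns_warn_but_solve(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(0, 1, 20)
        X = np.column_stack([col, col, rng.uniform(0, 1, 20)])
        lib = _toy_library(X)
        res = constrained_projection(_y(lib, col), lib)
        assert any("collinear" in w for w in res.warnings)
        assert abs(res.weights.sum() - 1) <= 1e-6
        assert res.residual_norm <= 1e-8

    def test_le_constraint_variant(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (20, 2))
        lib = _toy_library(X, classes=["a", "b"])
        # attenuated profile: NNLS total < 1, renormalized onto the simplex
        res = constrained_projection(_y(lib, 0.5 * X[:, 0]), lib, sum_constraint="le")
        np.testing.assert_allclose(res.weights, [1.0, 0.0], atol=1e-8)
        # an exact interior mixture is identical under both constraints
        y = 0.3 * X[:, 0] + 0.7 * X[:, 1]
        a = constrained_projection(_y(lib, y), lib, sum_constraint="eq")
        b = constrained_projection(_y(lib, y), lib, sum_constraint="le")
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-8)

    def test_slsqp_agrees_with_exact(self):
        rng = np.random.default_rng(6)
        X = rng.uniform(0, 1, (30, 4))
        y = X @ np.array([0.4, 0.3, 0.2, 0.1]) + rng.normal(0, 0.01, 30)
        lib = _toy_library(X)
        a = constrained_projection(_y(lib, y), lib, solver="exact")
        b = constrained_projection(_y(lib, y), lib, solver="slsqp")
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-5)


class TestDeconvolveLayer:
    def test_scaling_by_parent_mass(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, (20, 3))
        lib = _toy_library(X, classes=["a", "b", "other"])
        y = _y(lib, 0.25 * X[:, 0] + 0.75 * X[:, 1])
        out, _ = deconvolve_layer(y, lib, ("a", "b"), parent_mass=0.4)
        np.testing.assert_allclose([out["a"], out["b"]], [0.1, 0.3], atol=1e-6)

    def test_zero_parent_mass_annihilates(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0, 1, (20, 2))
        lib = _toy_library(X, classes=["a", "b"])
        out, _ = deconvolve_layer(_y(lib, X[:, 0]), lib, ("a", "b"), parent_mass=0.0)
        assert out == {"a": 0.0, "b": 0.0}

    def test_children_sum_to_parent_mass(self):
        rng = np.random.default_rng(9)
        X = rng.uniform(0, 1, (30, 3))
        lib = _toy_library(X)
        out, _ = deconvolve_layer(
            _y(lib, rng.uniform(0, 1, 30)), lib, tuple(lib.classes), parent_mass=0.37
        )
        assert abs(sum(out.values()) - 0.37) <= 1e-12

    def test_all_zero_focal_weights_split_equally(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0.2, 0.8, (20, 3))
        lib = _toy_library(X, classes=["a", "b", "winner"])
        out, warns = deconvolve_layer(_y(lib, X[:, 2]), lib, ("a", "b"), parent_mass=0.5)
        np.testing.assert_allclose([out["a"], out["b"]], [0.25, 0.25], atol=1e-9)
        assert any("equal split" in w for w in warns)


class TestDeconvolve:
    def test_layer6_has_17_cell_type_columns(self, deconv_result):
        assert deconv_result.tables[6].shape[1] == 17

    def test_layer1_is_tumor_vs_other(self, study, bundle):
        res = deconvolve(study["mix"], bundle, h=1)
        tbl = res.tables[1]
        assert list(tbl.columns) == ["Tumor", "Nontumor"]
        np.testing.assert_allclose(tbl.sum(axis=1), 1.0, atol=1e-12)

    def test_every_layer_is_a_simplex(self, deconv_result):
        for h, tbl in deconv_result.tables.items():
            assert (tbl.to_numpy() >= 0).all(), h
            np.testing.assert_allclose(tbl.sum(axis=1), 1.0, atol=1e-6)

    def test_hierarchical_conservation_exact(self, deconv_result, bundle):
        tree = bundle.tree
        for h in range(2, 7):
            rolled = aggregate_to_layer(deconv_result, tree, h, h - 1)
            stored = deconv_result.tables[h - 1]
            dev = np.abs(rolled[stored.columns].to_numpy() - stored.to_numpy()).max()
            assert dev <= 1e-12, h

    def test_aggregate_h6_to_h2_matches_stored(self, deconv_result, bundle):
        rolled = aggregate_to_layer(deconv_result, bundle.tree, 6, 2)
        stored = deconv_result.tables[2]
        np.testing.assert_allclose(
            rolled[stored.columns].to_numpy(), stored.to_numpy(), atol=1e-12
        )

    def test_aggregate_h2_to_h1_is_complement(self, deconv_result, bundle):
        rolled = aggregate_to_layer(deconv_result, bundle.tree, 2, 1)
        np.testing.assert_allclose(
            rolled["Nontumor"], 1.0 - rolled["Tumor"], atol=1e-12
        )

    def test_mass_preserved_under_aggregation(self, deconv_result, bundle):
        rolled = aggregate_to_layer(deconv_result, bundle.tree, 6, 3)
        np.testing.assert_allclose(rolled.sum(axis=1), 1.0, atol=1e-9)

    def test_sample_permutation_permutes_rows_only(self, study, bundle):
        mix = study["mix"]
        perm = list(mix.sample_ids[::-1])
        res_fwd = deconvolve(mix, bundle, h=3)
        res_rev = deconvolve(mix.select_samples(perm), bundle, h=3)
        pd.testing.assert_frame_equal(
            res_fwd.tables[3].loc[perm], res_rev.tables[3]
        )

    def test_bad_layer_raises(self, study, bundle):
        with pytest.raises(ValidationError, match="h must be"):
            deconvolve(study["mix"], bundle, h=7)

    def test_pure_reference_vertex_recovery(self, noise_free):
        from tmedecon import BetaMatrix

        arch = noise_free["archetypes"]
        tree = noise_free["bundle"].tree
        leaves = list(tree.leaves())
        vertices = BetaMatrix(
            arch[leaves].rename(columns=lambda c: f"v_{c}"), validate=False
        )
        res = deconvolve(vertices, noise_free["bundle"], h=6)
        for c in leaves:
            assert res.tables[6].loc[f"v_{c}", c] >= 0.99, c
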