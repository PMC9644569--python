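"""Layer-1 iDMC selection, direction transform and KDE purity estimation."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmedecon import (
    BetaMatrix,
    IDMCLibrary,
    ValidationError,
    estimate_purity,
    select_idmc,
    transform_idmc_betas,
)


def _bm(arr, probes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    probes = probes or [f"cg{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return BetaMatrix(pd.DataFrame(arr, index=probes, columns=samples))


def _lib(directions):
    entries = pd.DataFrame(
        {"direction": list(directions.values()), "p": 0.0, "mean_diff": 0.0},
        index=pd.Index(list(directions), name="probe_id"),
    )
    return IDMCLibrary(entries=entries, n_top=len(directions), var_threshold=0.005)


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of all label
    assignments (independent oracle; no ties assumed)."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n_x = len(x)
    obs = ranks[:n_x].sum()
    mu = n_x * (len(pooled) + 1) / 2.0
    stats = [
        np.sum(ranks[list(idx)])
        for idx in itertools.combinations(range(len(pooled)), n_x)
    ]
    stats = np.array(stats)
    return np.mean(np.abs(stats - mu) >= np.abs(obs - mu) - 1e-12)


class TestSelectIdmc:
    def test_matches_exact_enumeration_oracle(self):
        # 6 probes, 3 tumor / 3 normal, graded separations, no ties
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.4, (6, 6))
        shift = np.array([0.5, 0.4, 0.3, 0.2, 0.1, 0.05])
        vals = base.copy()
        vals[:, :3] += shift[:, None]  # tumor columns shifted per probe
        vals += rng.normal(0, 0.02, vals.shape)  # break ties between probes
        vals = np.clip(vals, 0, 1)
        tumor = _bm(vals[:, :3] + 0.0, samples=["t1", "t2", "t3"])
        normal = _bm(vals[:, 3:], samples=["n1", "n2", "n3"])

        lib = select_idmc(tumor, normal, n_top=6, var_threshold=0.0)

        oracle = []
        for i, probe in enumerate(tumor.probe_ids):
            p = exact_ranksum_p(vals[i, :3], vals[i, 3:])
            diff = vals[i, :3].mean() - vals[i, 3:].mean()
            oracle.append((p, -abs(diff), probe))
        expected = [probe for _, _, probe in sorted(oracle)]
        assert list(lib.probe_ids) == expected
        assert (lib.entries["direction"] == "hyper").all()

    def test_variance_filter_zero_candidates(self):
        tumor = _bm(np.full((5, 3), 0.5))
        normal = _bm(np.random.default_rng(1).uniform(0, 1, (5, 3)))
        with pytest.raises(ValidationError, match="zero candidates"):
            select_idmc(tumor, normal)

    def test_abundant_differential_gives_full_library(self, study):
        lib = select_idmc(study["tumor"], study["normal"])
        assert len(lib) == 1000

    def test_selected_probes_enriched_in_truly_differential(self, study):
        lib = select_idmc(study["tumor"], study["normal"])
        truly = set(study["differential"])
        frac = np.mean([p in truly for p in lib.probe_ids])
        assert frac >= 0.95

    def test_short_library_warns(self, study):
        with pytest.warns(UserWarning, match="shorter than n_top"):
            lib = select_idmc(study["tumor"], study["normal"], n_top=100000)
        assert len(lib) < 100000

    def test_direction_flip_symmetry(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.1, 0.9, (20, 8))
        vals[:10, :4] += 0.08  # tumor-hyper block
        vals = np.clip(vals, 0, 1)
        tumor, normal = _bm(vals[:, :4]), _bm(vals[:, 4:])
        flipped_t = BetaMatrix(1.0 - tumor.data)
        flipped_n = BetaMatrix(1.0 - normal.data)
        a = select_idmc(tumor, normal, n_top=20, var_threshold=0.0)
        b = select_idmc(flipped_t, flipped_n, n_top=20, var_threshold=0.0)
        assert list(a.probe_ids) == list(b.probe_ids)
        flipped = a.entries["direction"].map({"hyper": "hypo", "hypo": "hyper"})
        assert (b.entries["direction"] == flipped).all()

    def test_deterministic(self, study):
        a = select_idmc(study["tumor"], study["normal"])
        b = select_idmc(study["tumor"], study["normal"])
        assert list(a.probe_ids) == list(b.probe_ids)
        assert np.array_equal(a.entries["p"], b.entries["p"])


class TestTransform:
    def test_definition_and_boundary(self):
        lib = _lib({"h": "hyper", "l": "hypo", "z": "hypo"})
        out = transform_idmc_betas(pd.Series({"h": 0.8, "l": 0.2, "z": 1.0}), lib)
        assert out.tolist() == [0.8, 0.8, 0.0]

    def test_elementwise_matches_direct_recomputation(self):
        rng = np.random.default_rng(11)
        probes = [f"cg{i}" for i in range(10)]
        dirs = {p: ("hyper" if i % 2 else "hypo") for i, p in enumerate(probes)}
        betas = pd.Series(rng.uniform(0, 1, 10), index=probes)
        out = transform_idmc_betas(betas, _lib(dirs))
        expected = [b if dirs[p] == "hyper" else 1 - b for p, b in betas.items()]
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_missing_probes_skipped(self):
        lib = _lib({"a": "hyper", "b": "hypo", "c": "hyper"})
        out = transform_idmc_betas(pd.Series({"a": 0.3, "c": np.nan}), lib)
        assert out.tolist() == [0.3]

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_outputs_always_in_unit_interval(self, betas):
        probes = [f"cg{i}" for i in range(len(betas))]
        dirs = {p: ("hypo" if i % 3 else "hyper") for i, p in enumerate(probes)}
        out = transform_idmc_betas(pd.Series(betas, index=probes), _lib(dirs))
        assert (out >= 0).all() and (out <= 1).all()


class TestEstimatePurity:
    def test_point_mass(self):
        lib = _lib({f"cg{i}": "hyper" for i in range(12)})
        est = estimate_purity(pd.Series(0.6, index=lib.probe_ids), lib)
        assert abs(est.purity - 0.6) <= 0.001
        assert est.n_probes_used == 12

    def test_too_few_probes_raises(self):
        lib = _lib({f"cg{i}": "hyper" for i in range(12)})
        with pytest.raises(ValidationError, match="< 10"):
            estimate_purity(pd.Series(0.5, index=lib.probe_ids[:5]), lib)

    def test_generative_recovery_near_true_purity(self):
        # transformed values concentrated near p = 0.7 with noise sd 0.05
        rng = np.random.default_rng(21)
        lib = _lib({f"cg{i:04d}": "hyper" for i in range(1000)})
        vals = np.clip(0.7 + rng.normal(0, 0.05, 1000), 0, 1)
        est = estimate_purity(pd.Series(vals, index=lib.probe_ids), lib)
        assert abs(est.purity - 0.7) <= 0.05

    def test_monotone_in_true_purity(self):
        rng = np.random.default_rng(22)
        lib = _lib({f"cg{i:04d}": "hyper" for i in range(1000)})
        ests = []
        for p in (0.3, 0.8):
            vals = np.clip(p + rng.normal(0, 0.05, 1000), 0, 1)
            ests.append(estimate_purity(pd.Series(vals, index=lib.probe_ids), lib).purity)
        assert ests[0] < ests[1]

    def test_purity_always_in_unit_interval(self):
        rng = np.random.default_rng(23)
        lib = _lib({f"cg{i:03d}": "hyper" for i in range(100)})
        for loc in (0.0, 0.5, 1.0):
            vals = np.clip(loc + rng.normal(0, 0.1, 100), 0, 1)
            est = estimate_purity(pd.Series(vals, index=lib.probe_ids), lib)
            assert 0.0 <= est.purity <= 1.0

    def test_low_coverage_warning_attached(self):
        lib = _lib({f"cg{i:03d}": "hyper" for i in range(100)})
        sub = pd.Series(0.4, index=lib.probe_ids[:20])
        est = estimate_purity(sub, lib)
        assert any("50%" in w for w in est.warnings)

    def test_bimodal_density_flagged(self):
        rng = np.random.default_rng(24)
        lib = _lib({f"cg{i:04d}": "hyper" for i in range(1000)})
        vals = np.concatenate(
            [0.25 + rng.normal(0, 0.02, 500), 0.75 + rng.normal(0, 0.02, 500)]
        )
        est = estimate_purity(pd.Series(np.clip(vals, 0, 1), index=lib.probe_ids), lib)
        assert est.multimodal
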