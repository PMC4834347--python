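"""Bounded region, strength threshold, consistency set, separation search."""

import numpy as np
import pandas as pd
import pytest

from mmsig.cv import CVConfig, CVGridResult, TuningGrid
from mmsig.data import CohortDesign, FeatureMatrix, InputError
from mmsig.selection import (
    bounded_region,
    consistency_set,
    minimal_separating_subsets,
    strength_threshold,
    strong_set,
)
from oracles import brute_force_separating_subsets


def synthetic_grid_result(mean_auc, mean_active, mean_abs=None, sel_prop=None,
                          mean_coef=None, p=12):
    """Hand-assembled CVGridResult for exercising the selection layer."""
    mean_auc = np.asarray(mean_auc, float)
    G = mean_auc.size
    lams = tuple(10.0 ** -np.arange(1, G + 1))
    grid = TuningGrid((0.5,), lams)
    rng = np.random.default_rng(0)
    if mean_abs is None:
        mean_abs = rng.random((G, p))
    if sel_prop is None:
        sel_prop = rng.random((G, p))
    if mean_coef is None:
        mean_coef = rng.standard_normal((G, p))
    names = [f"VBM:f{j}" for j in range(p)]
    return CVGridResult(
        grid=grid,
        mean_auc=mean_auc,
        auc_per_iter=np.tile(mean_auc[:, None], (1, 3)),
        mean_active=np.asarray(mean_active, float),
        mean_abs_coef=np.asarray(mean_abs, float),
        selection_proportion=np.asarray(sel_prop, float),
        mean_sign=np.sign(mean_coef),
        mean_coef=np.asarray(mean_coef, float),
        n_fits=np.full(G, 6),
        n_failed=np.zeros(G, int),
        feature_names=names,
        modalities=np.asarray(["VBM"] * p, dtype=object),
        fold_assignments=np.zeros((3, 10), int),
        labels=np.array([1] * 6 + [0] * 4),
        seed=0,
        config=CVConfig(n_iter=3),
    )


class TestBoundedRegion:
    def test_trivial_bounds_keep_entire_grid(self):
        res = synthetic_grid_result([0.6, 0.7, 0.8], [5, 50, 500])
        region = bounded_region(res, p1=np.inf, q1=0.0)
        assert region.size == 3

    def test_unattainable_auc_bound_reports_frontier(self):
        res = synthetic_grid_result([0.6, 0.7], [5, 5])
        with pytest.raises(InputError, match="frontier"):
            bounded_region(res, p1=75, q1=0.99)

    def test_membership_matches_hand_filter(self):
        auc = [0.95, 0.85, 0.92, 0.99]
        active = [10, 10, 80, 40]
        res = synthetic_grid_result(auc, active)
        region = bounded_region(res, p1=75, q1=0.90)
        assert list(region.indices) == [0, 3]

    def test_shrinking_bounds_never_adds_members(self):
        rng = np.random.default_rng(1)
        res = synthetic_grid_result(rng.uniform(0.5, 1.0, 20),
                                    rng.uniform(0, 100, 20))
        loose = bounded_region(res, p1=90, q1=0.55)
        tight = bounded_region(res, p1=60, q1=0.7)
        assert set(tight.indices) <= set(loose.indices)


class TestStrengthThreshold:
    def test_ten_distinct_values_top_one_passes(self):
        v = np.arange(10.0)
        xi = strength_threshold(v, 0.10)
        assert xi == 9.0
        assert list(strong_set(v, 0.10)) == [9]

    def test_all_equal_values_all_pass(self):
        v = np.full(20, 3.3)
        xi = strength_threshold(v, 0.10)
        assert xi == 3.3
        assert strong_set(v, 0.10).size == 20

    def test_271_distinct_values_27_pass(self):
        rng = np.random.default_rng(2)
        v = rng.permutation(np.linspace(0.01, 5.0, 271))
        assert strong_set(v, 0.10).size == 27  # floor(0.10 · 271)

    def test_fewer_than_ten_features_rejected(self):
        with pytest.raises(InputError, match="10 features"):
            strength_threshold(np.arange(5.0))

    def test_all_zero_coefficients_degenerate_tie(self):
        v = np.zeros(30)
        assert strength_threshold(v) == 0.0
        assert strong_set(v).size == 30


class TestConsistencySet:
    def test_feature_in_every_strong_set_is_selected_at_100pct(self):
        p, G = 20, 5
        mean_abs = np.random.default_rng(3).random((G, p))
        mean_abs[:, 4] = 10.0  # dominant everywhere
        res = synthetic_grid_result(np.full(G, 0.95), np.full(G, 10),
                                    mean_abs=mean_abs, p=p)
        region = bounded_region(res, 75, 0.9)
        report = consistency_set(res, region, 0.10, 0.90)
        row = report.table.set_index("feature").loc["VBM:f4"]
        assert row["strength_pct"] == 100.0
        assert "VBM:f4" in report.consistency_features

    def test_boundary_fraction_below_tau_excluded(self):
        # feature strong in 89 of 100 points, tau_c = 0.90 -> excluded
        p, G = 20, 100
        rng = np.random.default_rng(4)
        mean_abs = rng.random((G, p)) * 0.1
        mean_abs[:89, 7] = 5.0
        mean_abs[:, 3] = 4.0  # always strong, fills the top slot elsewhere
        res = synthetic_grid_result(np.full(G, 0.95), np.full(G, 10),
                                    mean_abs=mean_abs, p=p)
        report = consistency_set(res, bounded_region(res, 75, 0.9), 0.10, 0.90)
        tab = report.table.set_index("feature")
        assert tab.loc["VBM:f7", "strength_pct"] == 89.0
        assert "VBM:f7" not in report.consistency_features
        assert "VBM:f3" in report.consistency_features

    def test_tau_limits_give_intersection_and_union(self):
        p, G = 15, 4
        rng = np.random.default_rng(5)
        mean_abs = rng.random((G, p))
        res = synthetic_grid_result(np.full(G, 0.95), np.full(G, 10),
                                    mean_abs=mean_abs, p=p)
        region = bounded_region(res, 75, 0.9)
        strong_sets = [set(strong_set(mean_abs[g], 0.10)) for g in range(G)]
        inter = set.intersection(*strong_sets)
        union = set.union(*strong_sets)
        c_inter = consistency_set(res, region, 0.10, 1.0)
        c_union = consistency_set(res, region, 0.10, 1e-9)
        idx = {f"VBM:f{j}" for j in inter}
        assert set(c_inter.consistency_features) == idx
        assert set(c_union.consistency_features) == {f"VBM:f{j}" for j in union}

    def test_direction_is_sign_of_region_average(self):
        p, G = 12, 3
        mean_coef = np.ones((G, p))
        mean_coef[:, 0] = -2.0
        res = synthetic_grid_result(np.full(G, 0.95), np.full(G, 5),
                                    mean_coef=mean_coef, p=p)
        report = consistency_set(res, bounded_region(res, 75, 0.9))
        tab = report.table.set_index("feature")
        assert tab.loc["VBM:f0", "direction"] == -1
        assert tab.loc["VBM:f5", "direction"] == 1


def fm_from_columns(cols: dict[str, np.ndarray]) -> FeatureMatrix:
    names = list(cols)
    vals = np.column_stack([cols[k] for k in names])
    return FeatureMatrix(vals, names, ["VBM"] * len(names))


class TestSeparationSearch:
    def test_single_feature_with_disjoint_ranges(self):
        y = np.array([1] * 5 + [0] * 5)
        rng = np.random.default_rng(6)
        fm = fm_from_columns({
            "VBM:gap": np.concatenate([rng.uniform(2, 3, 5), rng.uniform(0, 1, 5)]),
            "VBM:noise": rng.standard_normal(10),
        })
        res = minimal_separating_subsets(fm, CohortDesign(y), k_max=3)
        assert res.min_size == 1
        assert ("VBM:gap",) in res.subsets

    def test_no_subset_up_to_kmax_when_classes_interleave(self):
        # XOR-style construction: no linear separator in any subset
        y = np.array([1, 1, 0, 0])
        fm = fm_from_columns({
            "VBM:a": np.array([1.0, -1.0, 1.0, -1.0]),
            "VBM:b": np.array([1.0, -1.0, -1.0, 1.0]),
        })
        res = minimal_separating_subsets(fm, CohortDesign(y), k_max=2)
        assert res.min_size is None
        assert res.subsets == []

    def test_exact_pair_found_and_matches_brute_force(self):
        # no single feature separates, but (a, b) jointly does (y = sign(a+b))
        rng = np.random.default_rng(7)
        n = 16
        a = rng.uniform(-1, 1, n)
        b = rng.uniform(-1, 1, n)
        y = (a + b > 0).astype(int)
        # overlap each single coordinate across classes
        assert a[y == 1].min() < a[y == 0].max()
        assert b[y == 1].min() < b[y == 0].max()
        noise = rng.standard_normal(n) * 1e-3
        cols = {"VBM:a": a, "VBM:b": b, "VBM:noise": noise}
        fm = fm_from_columns(cols)
        design = CohortDesign(y)
        res = minimal_separating_subsets(fm, design, k_max=2)
        assert res.min_size == 2
        found = {tuple(sorted(s)) for s in res.subsets}
        brute = brute_force_separating_subsets(fm.values, y, None, 2)
        names = list(cols)
        brute_named = {tuple(sorted(names[i] for i in combo)) for combo in brute}
        assert found == brute_named
        assert ("VBM:a", "VBM:b") in found

    def test_covariates_participate_in_separator(self):
        # covariate alone separates: every 1-feature model then separates
        y = np.array([1] * 4 + [0] * 4)
        rng = np.random.default_rng(8)
        fm = fm_from_columns({"VBM:x": rng.standard_normal(8)})
        cov = pd.DataFrame({"age": np.concatenate([np.full(4, 80.0),
                                                   np.full(4, 50.0)])})
        res = minimal_separating_subsets(fm, CohortDesign(y, cov), k_max=1)
        assert res.min_size == 1

    def test_enumeration_guard(self):
        rng = np.random.default_rng(9)
        y = np.array([1] * 5 + [0] * 5)
        fm = FeatureMatrix(rng.standard_normal((10, 300)),
                           [f"VBM:f{j}" for j in range(300)], ["VBM"] * 300)
        with pytest.raises(InputError, match="guard"):
            minimal_separating_subsets(fm, CohortDesign(y), k_max=3,
                                       max_combinations=100)
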