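"""Iterated CV: grids, folds, AUC, sweep aggregation, ROC averaging."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score, roc_curve

from mmsig.cv import (
    CVConfig,
    CVGridResult,
    TuningGrid,
    average_roc,
    make_fold_iterations,
    roc_auc,
    run_iterated_cv,
)
from mmsig.data import CohortDesign, InputError
from mmsig.enet import EnetSpec
from oracles import auc_by_pair_count


class TestTuningGrid:
    def test_canonical_lambda_ladder_has_151_points(self):
        grid = TuningGrid.from_spec(51, 1e-5, 10.0, 25)
        assert len(grid.lams) == 151
        assert len(grid.alphas) == 51
        assert grid.lams[0] == pytest.approx(1e-5)
        assert grid.lams[-1] == pytest.approx(10.0)

    def test_points_per_decade_spacing(self):
        grid = TuningGrid.from_spec(3, 1e-3, 1.0, 4)
        assert len(grid.lams) == 13
        ratios = np.diff(np.log10(grid.lams))
        assert np.allclose(ratios, 0.25)

    def test_empty_or_invalid_grid_rejected(self):
        with pytest.raises(InputError):
            TuningGrid((), (0.1,))
        with pytest.raises(InputError):
            TuningGrid((0.5,), (0.0,))


class TestFolds:
    def test_default_yields_200_training_samples(self):
        y = np.array([1] * 28 + [0] * 14)
        folds = make_fold_iterations(y, n_iter=100, k=2, seed=0)
        assert folds.shape == (100, 42)
        assert 2 * 100 == 200

    def test_stratified_counts_28_14(self):
        y = np.array([1] * 28 + [0] * 14)
        folds = make_fold_iterations(y, n_iter=10, k=2, seed=1)
        for it in range(10):
            for f in (0, 1):
                sel = folds[it] == f
                assert y[sel].sum() == 14
                assert (1 - y[sel]).sum() == 7

    def test_same_seed_identical(self):
        y = np.array([1] * 10 + [0] * 10)
        a = make_fold_iterations(y, 5, 2, seed=7)
        b = make_fold_iterations(y, 5, 2, seed=7)
        assert np.array_equal(a, b)

    def test_class_too_small_to_stratify(self):
        y = np.array([1] * 20 + [0])
        with pytest.raises(InputError, match="stratify"):
            make_fold_iterations(y, 2, 2, seed=0)

    def test_every_subject_in_exactly_one_fold(self):
        y = np.array([1] * 12 + [0] * 9)
        folds = make_fold_iterations(y, 8, 3, seed=3)
        assert np.all(np.isin(folds, [0, 1, 2]))


class TestAuc:
    def test_perfectly_ordered_scores(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0

    def test_tie_correction_hand_case(self):
        # pairs: (0.2 vs 0.2) ties -> 1/2, (0.8 vs 0.2) wins -> 1; AUC = 1.5/2
        assert roc_auc([0.2, 0.2, 0.8], [0, 1, 1]) == pytest.approx(0.75)

    def test_matches_pair_count_and_sklearn(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            scores = np.round(rng.random(30), 1)  # induce ties
            labels = (rng.random(30) < 0.5).astype(int)
            if labels.min() == labels.max():
                continue
            ours = roc_auc(scores, labels)
            assert ours == pytest.approx(auc_by_pair_count(scores, labels))
            assert ours == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_increasing_transform(self):
        rng = np.random.default_rng(1)
        scores = rng.random(40)
        labels = (rng.random(40) < 0.4).astype(int)
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc(np.exp(5 * scores), labels)
        )

    def test_single_class_rejected(self):
        with pytest.raises(InputError):
            roc_auc([0.1, 0.2], [1, 1])


class TestAverageRoc:
    def test_identical_curves_average_to_themselves(self):
        fpr, tpr, _ = roc_curve([0, 0, 1, 1], [0.1, 0.6, 0.4, 0.9])
        grid, mean_tpr = average_roc([(fpr, tpr)] * 3)
        pos = np.searchsorted(fpr, grid, side="right") - 1
        assert np.allclose(mean_tpr, tpr[np.clip(pos, 0, len(fpr) - 1)])

    def test_degenerate_pair_averages_to_half(self):
        perfect = roc_curve([0, 1], [0.0, 1.0])[:2]
        worst = roc_curve([0, 1], [1.0, 0.0])[:2]
        grid, mean_tpr = average_roc([perfect, worst])
        interior = (grid > 0) & (grid < 1)
        assert np.allclose(mean_tpr[interior], 0.5)

    def test_trapezoid_area_close_to_mean_auc(self):
        rng = np.random.default_rng(2)
        curves, aucs = [], []
        for _ in range(5):
            scores = rng.random(60)
            labels = (rng.random(60) < 0.5).astype(int)
            fpr, tpr, _ = roc_curve(labels, scores)
            curves.append((fpr, tpr))
            aucs.append(roc_auc(scores, labels))
        grid, mean_tpr = average_roc(curves, n_grid=401)
        area = np.trapezoid(mean_tpr, grid)
        assert area == pytest.approx(np.mean(aucs), abs=0.01)


@pytest.fixture(scope="module")
def tiny_cv_result(request):
    small_cohort = request.getfixturevalue("small_cohort")
    grid = TuningGrid.from_spec(n_alpha=2, lam_min=1e-3, lam_max=1.0,
                                points_per_decade=1)
    return run_iterated_cv(
        small_cohort.features, small_cohort.design, grid,
        CVConfig(n_iter=5, seed=9), EnetSpec(max_iter=300),
    )


class TestIteratedCV:
    def test_deterministic_under_fixed_seed(self, small_cohort):
        grid = TuningGrid((0.5,), (0.05,))
        kw = dict(cv_cfg=CVConfig(n_iter=2, seed=4),
                  enet_spec=EnetSpec(max_iter=300))
        r1 = run_iterated_cv(small_cohort.features, small_cohort.design, grid, **kw)
        r2 = run_iterated_cv(small_cohort.features, small_cohort.design, grid, **kw)
        assert np.array_equal(r1.auc_per_iter, r2.auc_per_iter)
        assert np.array_equal(r1.mean_abs_coef, r2.mean_abs_coef)

    def test_parallel_jobs_reproduce_serial_results(self, small_cohort):
        grid = TuningGrid((0.5,), (0.05, 0.5))
        kw = dict(cv_cfg=CVConfig(n_iter=4, seed=6),
                  enet_spec=EnetSpec(max_iter=300))
        r1 = run_iterated_cv(small_cohort.features, small_cohort.design, grid,
                             n_jobs=1, **kw)
        r2 = run_iterated_cv(small_cohort.features, small_cohort.design, grid,
                             n_jobs=2, **kw)
        assert np.array_equal(r1.auc_per_iter, r2.auc_per_iter)
        assert np.array_equal(r1.selection_proportion, r2.selection_proportion)

    def test_pooled_scores_cover_every_subject(self, tiny_cv_result):
        assert tiny_cv_result.scores is not None
        assert np.all(np.isfinite(tiny_cv_result.scores))

    def test_ridge_points_keep_all_features(self, tiny_cv_result):
        alpha0 = tiny_cv_result.alpha_grid == 0.0
        p = len(tiny_cv_result.feature_names)
        assert np.allclose(tiny_cv_result.mean_active[alpha0], p)

    def test_selection_proportion_steps(self, tiny_cv_result):
        # 5 iterations × 2 folds = 10 fits: proportions are multiples of 1/10
        sp = tiny_cv_result.selection_proportion
        assert np.allclose(sp * 10, np.round(sp * 10))
        assert sp.min() >= 0 and sp.max() <= 1

    def test_planted_feature_dominates_with_strong_effect(self):
        # feature-channel check: no covariates, so the only signal is the
        # single planted effect (standardized difference 3.0)
        from mmsig.synthetic import EffectSpec, generate_cohort

        cohort = generate_cohort(
            p_by_block={"VBM": 40},
            effect=EffectSpec(planted_indices=(7,), effect_sizes=(3.0,),
                              n_planted=1),
            seed=21,
        )
        design = CohortDesign(cohort.design.labels, None,
                              cohort.design.subject_ids)
        grid = TuningGrid((0.5, 1.0), (1e-3, 1e-2))
        res = run_iterated_cv(cohort.features, design, grid,
                              CVConfig(n_iter=10, seed=2),
                              EnetSpec(max_iter=300))
        assert np.nanmax(res.mean_auc) >= 0.9
        for g in range(grid.n_points):
            assert np.argmax(res.mean_abs_coef[g]) == 7

    def test_null_labels_give_chance_auc(self, null_cohort):
        # one permutation's CV mean carries dataset-level variability (the
        # fit can latch onto chance correlations of this one cohort), so the
        # chance check averages over several independent permutations
        # and shrinkage on null data induces a small anti-learning bias, so
        # the band is wider than a naive per-iteration standard error
        grid = TuningGrid((0.5,), (0.05,))
        means = []
        for rep in range(6):
            rng = np.random.default_rng(100 + rep)
            perm = rng.permutation(null_cohort.design.labels)
            design = CohortDesign(perm, None, null_cohort.design.subject_ids)
            res = run_iterated_cv(null_cohort.features, design, grid,
                                  CVConfig(n_iter=10, seed=8 + rep),
                                  EnetSpec(max_iter=300))
            means.append(np.nanmean(res.auc_per_iter[0]))
        assert abs(np.mean(means) - 0.5) < 0.10

    def test_per_fold_pooling_option(self, small_cohort):
        grid = TuningGrid((0.5,), (0.05,))
        res = run_iterated_cv(
            small_cohort.features, small_cohort.design, grid,
            CVConfig(n_iter=3, seed=5, pooling="fold"),
            EnetSpec(max_iter=300),
        )
        assert np.all(np.isfinite(res.auc_per_iter))

    def test_round_trip_to_directory(self, tiny_cv_result, tmp_path):
        tiny_cv_result.to_dir(tmp_path / "cvgrid")
        back = CVGridResult.from_dir(tmp_path / "cvgrid")
        assert np.allclose(back.mean_auc, tiny_cv_result.mean_auc)
        assert np.allclose(back.mean_abs_coef, tiny_cv_result.mean_abs_coef,
                           atol=1e-12)
        assert back.feature_names == tiny_cv_result.feature_names
        assert np.array_equal(back.fold_assignments,
                              tiny_cv_result.fold_assignments)
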