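"""Nested CV machinery, algorithms, splitting, thresholding, lesioning."""

import numpy as np
import pytest
from scipy import stats

from traitscape.images import BrainMaps, scale_images
from traitscape.predictive import (
    CVSpec,
    fit_nested_cv,
    fit_pattern_model,
    lesion_evaluation,
    permutation_test_cv,
    stratified_split,
    threshold_pattern_weights,
    train_final_and_evaluate,
)
from traitscape.synthdata import generate_cohort

from .conftest import tiny_config


def make_maps(data, grid):
    return BrainMaps(
        data=np.asarray(data, float),
        voxel_coords=np.indices(grid).reshape(3, -1).T,
        grid_shape=grid,
    )


class TestStratifiedSplit:
    def test_deterministic(self, rng):
        y = rng.standard_normal(100)
        assert np.array_equal(stratified_split(y, 0.25, 7)[1], stratified_split(y, 0.25, 7)[1])

    def test_sizes_near_nominal(self, rng):
        y = rng.standard_normal(403)
        train, hold = stratified_split(y, 0.25, seed=0)
        assert abs(hold.size - round(0.25 * 403)) <= 3  # bin-wise rounding slack
        assert train.size + hold.size == 403

    def test_beats_unstratified_on_mean_match(self):
        rng = np.random.default_rng(11)
        y = rng.uniform(size=1000)
        train, hold = stratified_split(y, 0.25, seed=0, n_bins=20)
        gap = abs(y[train].mean() - y[hold].mean())
        random_gaps = []
        for _ in range(200):
            perm = rng.permutation(1000)
            random_gaps.append(abs(y[perm[250:]].mean() - y[perm[:250]].mean()))
        assert gap < np.quantile(random_gaps, 0.05)

    def test_fraction_validation(self, rng):
        with pytest.raises(ValueError):
            stratified_split(rng.standard_normal(50), 1.2, 0)


class TestPatternModelOracles:
    def test_pcr_all_components_equals_least_squares(self, rng):
        # with every component retained, PCR is OLS on the standardized data
        n, p = 40, 5
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + 0.1 * rng.standard_normal(n)
        model = fit_pattern_model(X, y, "pcr", hyper=p)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        beta, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), Xs]), y, rcond=None)
        assert np.allclose(model.weights, beta[1:], atol=1e-8)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(model.predict(X), Xs @ beta[1:] + beta[0], atol=1e-8)

    def test_linear_weights_reproduce_estimator_predictions(self, rng):
        X = rng.standard_normal((30, 10))
        y = rng.standard_normal(30)
        for algorithm, hyper in [("pls", 3), ("svr", 1.0)]:
            model = fit_pattern_model(X, y, algorithm, hyper)
            Xnew = rng.standard_normal((5, 10))
            direct = ((Xnew - model.train_mean) / model.train_sd) @ model.weights + model.intercept
            assert np.allclose(model.predict(Xnew), direct)

    def test_pcarf_component_rule(self, rng):
        # feature space reduced to the training-sample rank (one less than
        # the participant count, never more than the voxel count)
        X = rng.standard_normal((25, 60))
        model = fit_pattern_model(X, rng.standard_normal(25), "pcarf", None, rf_trees=10)
        assert model.estimator.named_steps["pca"].n_components_ == 24


class TestNestedCV:
    def test_structure_and_determinism(self, rng):
        X = rng.standard_normal((40, 12))
        y = rng.standard_normal(40)
        spec = CVSpec(outer_folds=5, inner_folds=3, repeats=2, seed=3)
        res1 = fit_nested_cv(X, y, "pls", spec, grid=[1, 2])
        res2 = fit_nested_cv(X, y, "pls", spec, grid=[1, 2])
        assert len(res1.fold_records) == 10  # repeats x outer folds
        assert np.array_equal(res1.predictions, res2.predictions)  # bit-reproducible
        assert res1.predictions.shape == (2, 40)  # every subject once per repeat
        assert np.all(np.isfinite(res1.predictions))

    def test_fold_predictions_are_functions_of_training_fold_only(self, rng):
        # reproduce one outer fold by hand: same split, same standardization,
        # same fit; the recorded test predictions must match exactly, which
        # also demonstrates the test fold's outcomes never enter training
        from sklearn.model_selection import KFold

        from traitscape.predictive import _fit_predict, _std_stats

        X = rng.standard_normal((30, 8))
        y = rng.standard_normal(30)
        spec = CVSpec(outer_folds=3, inner_folds=2, repeats=1, seed=9)
        res = fit_nested_cv(X, y, "pls", spec, grid=[2])
        kf = KFold(n_splits=3, shuffle=True, random_state=spec.seed % (2**31))
        tr, te = next(iter(kf.split(X)))
        mean, sd = _std_stats(X[tr])
        pred = _fit_predict("pls", 2, (X[tr] - mean) / sd, y[tr], (X[te] - mean) / sd, spec.seed, 10)
        assert np.allclose(res.predictions[0, te], pred)

    def test_simulated_signal_recovered(self):
        # smoke test: 100 observations, 20 predictive features
        rng = np.random.default_rng(42)
        X = rng.standard_normal((100, 20))
        y = X @ np.full(20, 0.25) + rng.standard_normal(100)
        spec = CVSpec(outer_folds=3, inner_folds=3, repeats=1, seed=0)
        res = fit_nested_cv(X, y, "pls", spec, grid=[2, 5])
        assert res.r_mean > 0.3
        out = permutation_test_cv(X, y, "pls", spec, n_perm=99, seed=1, grid=[2, 5])
        assert out["p"] < 0.05

    def test_constant_prediction_scores_zero_with_warning(self, rng):
        # a forest trained on a constant outcome predicts a constant
        X = rng.standard_normal((24, 4))
        y = np.full(24, 3.0)
        spec = CVSpec(outer_folds=3, inner_folds=2, repeats=1, seed=0, rf_trees=10)
        with pytest.warns(UserWarning, match="constant predictions"):
            res = fit_nested_cv(X, y, "pcarf", spec)
        assert np.all(res.fold_records["r"] == 0.0)


class TestPermutationTest:
    def test_strong_signal_reaches_floor_p(self, rng):
        X = rng.standard_normal((40, 6))
        y = X[:, 0]
        spec = CVSpec(outer_folds=3, inner_folds=2, repeats=1, seed=0)
        out = permutation_test_cv(X, y, "pls", spec, n_perm=99, seed=0, grid=[1])
        assert out["p"] == pytest.approx(1 / 100)

    def test_minimum_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            permutation_test_cv(rng.standard_normal((20, 4)), rng.standard_normal(20), n_perm=10)


class TestHoldoutEvaluation:
    def test_holdout_equal_to_training_is_rejected(self, rng):
        X = rng.standard_normal((30, 6))
        y = rng.standard_normal(30)
        with pytest.raises(ValueError, match="disjoint"):
            train_final_and_evaluate(X, y, X.copy(), y, "pls", 2)

    def test_preprocessing_provenance_mismatch_is_rejected(self, rng):
        maps_tr = scale_images(make_maps(rng.standard_normal((30, 8)), (2, 2, 2)), "center")
        maps_ho = make_maps(rng.standard_normal((10, 8)), (2, 2, 2))  # unscaled
        model = fit_pattern_model(maps_tr, rng.standard_normal(30), "pls", 2)
        with pytest.raises(ValueError, match="provenance"):
            model.predict(maps_ho)

    def test_planted_signal_scores_with_inference(self, rng):
        X = rng.standard_normal((120, 10))
        y = X[:, 0] * 0.8 + rng.standard_normal(120)
        inf, model = train_final_and_evaluate(X[:90], y[:90], X[90:], y[90:], "pls", 2)
        assert inf.r > 0.3
        assert inf.alternative == "greater"
        assert inf.bf10 > 1.0


class TestThresholding:
    def _planted(self, rng, n=40, grid=(8, 8, 8), cluster=60, clean=False):
        # truth: one contiguous 60-voxel block occupying the first grid rows,
        # every member voxel individually tracking the outcome
        V = int(np.prod(grid))
        X = rng.standard_normal((n, V))
        y = rng.standard_normal(n)
        w_true = np.zeros(V)
        w_true[:cluster] = 1.0
        X[:, :cluster] += y[:, None] / 0.3
        if clean:
            # off-cluster voxels carry exactly zero in-sample association,
            # so only the true cluster can survive
            off = slice(cluster, V)
            yc = y - y.mean()
            proj = yc @ (X[:, off] - X[:, off].mean(0)) / (yc @ yc)
            X[:, off] -= np.outer(yc, proj)
        return make_maps(X, grid), y, w_true

    def test_exact_cluster_survives(self, rng):
        maps, y, w_true = self._planted(rng, n=80, clean=True)
        out = threshold_pattern_weights(
            maps, y, "pls", 1, alpha=0.01, min_cluster=50, n_boot=100, seed=0
        )
        assert np.array_equal(out["surviving"], w_true.astype(bool))

    def test_min_cluster_larger_than_map_empties_result(self, rng):
        maps, y, _ = self._planted(rng)
        out = threshold_pattern_weights(
            maps, y, "pls", 1, alpha=0.05, min_cluster=10_000, n_boot=50, seed=0
        )
        assert out["n_surviving"] == 0
        assert np.all(out["weights"] == 0.0)

    def test_fdr_on_null_data_survives_nothing(self):
        empty = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            maps = make_maps(rng.standard_normal((30, 125)), (5, 5, 5))
            out = threshold_pattern_weights(
                maps, rng.standard_normal(30), "pls", 1,
                alpha=0.05, min_cluster=1, n_boot=60, method="fdr", seed=seed,
            )
            empty += out["n_surviving"] == 0
        assert empty >= 9

    def test_nonlinear_algorithm_rejected(self, rng):
        maps, y, _ = self._planted(rng, n=20, grid=(4, 4, 4), cluster=5)
        with pytest.raises(ValueError, match="linear"):
            threshold_pattern_weights(maps, y, "pcarf", None, n_boot=10)


class TestLesionEvaluation:
    @pytest.fixture(scope="class")
    def localized_cohort(self):
        # all trait signal inside the somatomotor network, strongly expressed
        config = tiny_config(
            beta_trait=2.0, trait_networks=(1,), trait_support=0.1, n_subjects=80
        )
        return generate_cohort(config)

    def test_lesioning_signal_network_destroys_performance(self, localized_cohort):
        cohort = localized_cohort
        # unscaled maps: image-wise centering would smear the (deliberately
        # unbalanced) localized signal into the row mean of every voxel;
        # score against the latent trait so questionnaire unreliability does
        # not cap the effect
        maps = scale_images(cohort.maps_for("scenes", "control"), "none")
        y = cohort.truth["latent_trait"]
        tr, ho = np.arange(60), np.arange(60, 80)
        r_full, table = lesion_evaluation(
            maps.select_obs(tr), y[tr], maps.select_obs(ho), y[ho],
            cohort.atlas, level="network", algorithm="pls", hyper=2,
        )
        drop = table.set_index("unit_name")
        assert r_full > 0.7
        assert drop.loc["somatomotor", "r_lesioned"] < 0.3  # signal carrier
        others = drop.drop("somatomotor")
        assert others["delta_r"].abs().median() < 0.15

    def test_zero_weight_variant_runs(self, localized_cohort):
        cohort = localized_cohort
        maps = scale_images(cohort.maps_for("scenes", "control"), "center")
        y = cohort.traits["vulnerability"].to_numpy()
        r_full, table = lesion_evaluation(
            maps.select_obs(np.arange(60)), y[:60],
            maps.select_obs(np.arange(60, 80)), y[60:],
            cohort.atlas, level="network", algorithm="pls", hyper=2,
            units=["visual"], retrain=False,
        )
        assert len(table) == 1 and np.isfinite(table["r_lesioned"].iloc[0])
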