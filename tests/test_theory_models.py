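"""Theory-driven battery: correlations, best-region discovery, networks, signatures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traitscape.images import BrainMaps
from traitscape.inference import holm_correct
from traitscape.parcellation import Atlas
from traitscape.predictive import CVSpec
from traitscape.theory_models import (
    SignatureMap,
    best_region_splithalf,
    network_models,
    region_pattern_predict,
    region_trait_correlations,
    signature_expression,
    spatial_similarity,
)


class TestRegionTraitCorrelations:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(30)
        table = region_trait_correlations(pd.DataFrame({"roi": x}), x)
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_holm_family(self, rng):
        table = region_trait_correlations(
            pd.DataFrame(rng.standard_normal((30, 3)), columns=list("abc")),
            rng.standard_normal(30),
            family_m=6,
        )
        expected = holm_correct(table["p"].to_numpy(), family_m=6)
        assert np.allclose(table["p_holm"], expected)

    def test_zero_variance_unit_flagged(self, rng):
        df = pd.DataFrame({"flat": np.ones(20), "ok": rng.standard_normal(20)})
        table = region_trait_correlations(df, rng.standard_normal(20))
        assert table.loc[table.unit == "flat", "note"].iloc[0] == "zero variance"
        assert np.isnan(table.loc[table.unit == "flat", "p_holm"].iloc[0])

    def test_familywise_error_rate_controlled(self):
        # 7 null networks, Holm at alpha = .05: any false rejection <= 5%
        hits = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.standard_normal((50, 7)))
            df.columns = [f"n{i}" for i in range(7)]
            table = region_trait_correlations(df, rng.standard_normal(50), family_m=7)
            hits += (table["p_holm"] < 0.05).any()
        assert hits / 500 <= 0.07  # 0.05 plus binomial slack at 500 draws


class TestSignatureExpression:
    def test_tiny_example(self):
        maps = BrainMaps(
            data=[[2.0, 1.0]], voxel_coords=[[0, 0, 0], [0, 0, 1]], grid_shape=(1, 1, 2)
        )
        sig = SignatureMap("toy", [1.0, -1.0])
        assert signature_expression(maps, sig)[0] == pytest.approx(1.0)

    def test_offset_invariance_for_zero_sum_weights(self, rng):
        data = rng.standard_normal((4, 6))
        coords = np.indices((1, 2, 3)).reshape(3, -1).T
        w = rng.standard_normal(6)
        w -= w.mean()  # zero-sum weights ignore global offsets
        sig = SignatureMap("zs", w)
        a = signature_expression(BrainMaps(data=data, voxel_coords=coords, grid_shape=(1, 2, 3)), sig)
        b = signature_expression(
            BrainMaps(data=data + 7.3, voxel_coords=coords, grid_shape=(1, 2, 3)), sig
        )
        assert np.allclose(a, b)

    def test_matches_explicit_summation(self, rng):
        # brute-force oracle on a 5,000-voxel case
        V = 5000
        data = rng.standard_normal((3, V))
        w = rng.standard_normal(V)
        coords = np.column_stack([np.arange(V), np.zeros(V, int), np.zeros(V, int)])
        maps = BrainMaps(data=data, voxel_coords=coords, grid_shape=(V, 1, 1))
        got = signature_expression(maps, SignatureMap("big", w))
        expected = [sum(w[v] * data[i, v] for v in range(V)) for i in range(3)]
        assert np.allclose(got, expected)

    def test_linearity(self, rng):
        V = 50
        coords = np.column_stack([np.arange(V), np.zeros(V, int), np.zeros(V, int)])
        x = rng.standard_normal((1, V))
        y = rng.standard_normal((1, V))
        sig = SignatureMap("lin", rng.standard_normal(V))
        mk = lambda d: BrainMaps(data=d, voxel_coords=coords, grid_shape=(V, 1, 1))
        lhs = signature_expression(mk(2.0 * x + 3.0 * y), sig)
        rhs = 2.0 * signature_expression(mk(x), sig) + 3.0 * signature_expression(mk(y), sig)
        assert np.allclose(lhs, rhs)

    def test_misalignment_raises(self, rng):
        maps = BrainMaps(
            data=rng.standard_normal((2, 4)),
            voxel_coords=np.indices((1, 2, 2)).reshape(3, -1).T,
            grid_shape=(1, 2, 2),
        )
        with pytest.raises(ValueError, match="voxels"):
            signature_expression(maps, SignatureMap("bad", np.ones(5)))


class TestSpatialSimilarity:
    def test_identity_and_sign(self, rng):
        a = rng.standard_normal(100)
        assert spatial_similarity(a, a) == pytest.approx(1.0)
        assert spatial_similarity(a, -a) == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self, rng):
        assert abs(spatial_similarity(rng.standard_normal(5000), rng.standard_normal(5000))) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spatial_similarity(np.ones(10), np.arange(10.0))


class TestBestRegionSplitHalf:
    def test_strong_signal_selected_and_confirmed(self):
        picks, confirms = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trait = rng.standard_normal(80)
            means = pd.DataFrame(rng.standard_normal((80, 6)), columns=[f"r{i}" for i in range(6)])
            means["r3"] = trait + 0.5 * rng.standard_normal(80)
            out = best_region_splithalf(means, trait, seed=seed)
            picks += out["selected"] == "r3"
            confirms += out["r_test"] > 0
        assert picks >= 18  # > 90% of seeds
        assert confirms >= 18

    def test_boundary_smallest_sample(self, rng):
        means = pd.DataFrame(rng.standard_normal((8, 2)), columns=["a", "b"])
        out = best_region_splithalf(means, rng.standard_normal(8), seed=0)
        assert out["n_test"] == 4


class TestNetworkModels:
    def test_regression_perfect_fit(self, rng):
        nets = pd.DataFrame(rng.standard_normal((40, 7)), columns=[f"n{i}" for i in range(7)])
        trait = 2.0 * nets["n0"] - 1.0 * nets["n3"]
        out = network_models(nets, trait, model="multiple_regression")
        assert out["r_squared"] == pytest.approx(1.0)

    def test_univariate_family_guard(self, rng):
        nets = pd.DataFrame(rng.standard_normal((30, 8)))
        nets.columns = [f"n{i}" for i in range(8)]
        with pytest.raises(ValueError, match="family"):
            network_models(nets, rng.standard_normal(30), model="univariate", family_m=7)

    def test_forest_beats_regression_on_interaction(self):
        # the non-linearity rationale: a threshold interaction of two networks
        rng = np.random.default_rng(3)
        nets = pd.DataFrame(rng.standard_normal((200, 7)), columns=[f"n{i}" for i in range(7)])
        trait = ((nets["n0"] > 0) ^ (nets["n1"] > 0)).astype(float) + 0.2 * rng.standard_normal(200)
        forest = network_models(nets, trait, model="random_forest_oob", n_perm=0, n_trees=200)
        from sklearn.linear_model import LinearRegression
        from sklearn.model_selection import cross_val_predict

        pred = cross_val_predict(LinearRegression(), nets, trait, cv=5)
        reg_r = stats.pearsonr(pred, trait).statistic
        assert forest["oob_r"] > reg_r

    def test_null_permutation_p_uniform(self):
        ps = []
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            nets = pd.DataFrame(rng.standard_normal((30, 7)), columns=[f"n{i}" for i in range(7)])
            out = network_models(
                nets, rng.standard_normal(30), model="random_forest_oob",
                n_perm=39, n_trees=30, seed=seed,
            )
            ps.append(out["perm_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRegionPatternPredict:
    def _maps(self, data, grid):
        return BrainMaps(
            data=data, voxel_coords=np.indices(grid).reshape(3, -1).T, grid_shape=grid
        )

    def test_planted_positive_weights_give_high_sign_consistency(self, rng):
        grid = (2, 2, 2)
        atlas = Atlas(region_of_voxel=[0] * 4 + [1] * 4, network_of_region=[0, 0])
        n = 60
        data = rng.standard_normal((n, 8))
        trait = data[:, :4].sum(axis=1) + 0.3 * rng.standard_normal(n)
        spec = CVSpec(outer_folds=3, inner_folds=3, repeats=1, seed=0)
        out = region_pattern_predict(self._maps(data, grid), atlas, 0, trait, spec)
        assert out.sign_consistency > 0.9
        assert out.r_mean > 0.5

    def test_single_voxel_region_matches_simple_regression(self, rng):
        # oracle: per-fold ordinary regression on the standardized voxel
        from sklearn.model_selection import KFold

        grid = (2, 2, 1)
        atlas = Atlas(region_of_voxel=[0, 1, 1, 1], network_of_region=[0, 0])
        n = 40
        data = rng.standard_normal((n, 4))
        trait = 0.8 * data[:, 0] + rng.standard_normal(n)
        spec = CVSpec(outer_folds=4, inner_folds=2, repeats=1, seed=5)
        out = region_pattern_predict(self._maps(data, grid), atlas, 0, trait, spec)
        x = data[:, 0]
        expected = np.empty(n)
        kf = KFold(n_splits=4, shuffle=True, random_state=spec.seed % (2**31))
        for tr, te in kf.split(x):
            mu, sd = x[tr].mean(), x[tr].std(ddof=1)
            xs_tr, xs_te = (x[tr] - mu) / sd, (x[te] - mu) / sd
            xc, yc = xs_tr - xs_tr.mean(), trait[tr] - trait[tr].mean()
            slope = float((xc * yc).sum() / (xc**2).sum())
            expected[te] = trait[tr].mean() + slope * (xs_te - xs_tr.mean())
        assert np.allclose(out.predictions[0], expected, atol=1e-8)
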