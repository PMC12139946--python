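"""Theory-driven brain-trait battery: regions, networks and signatures.

Three families of increasing complexity, mirroring how hypothesis-led
affective neuroscience interrogates a trait:

* region/network **mean-signal correlations** with Holm correction over an
  explicitly declared family size;
* **region-restricted multivariate prediction** (PLS within one region's
  voxels under the standard nested CV) plus a weight sign-consistency
  summary, and a data-driven **best-region split-half** test that selects
  the strongest region in one stratified half and confirms it in the other;
* **network models** (univariate, multiple regression, out-of-bag random
  forest with a permutation test) and **signature expression** (dot product
  of fixed published-style weight maps with person-wise images).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import BrainMaps
from .inference import (
    correlation_test,
    fisher_ci,
    holm_correct,
    permutation_pvalue,
)

__all__ = [
    "SignatureMap",
    "region_trait_correlations",
    "region_pattern_predict",
    "best_region_splithalf",
    "network_models",
    "signature_expression",
    "spatial_similarity",
]


@dataclass
class SignatureMap:
    """A fixed voxel weight vector whose expression is a dot product."""

    name: str
    weights: np.ndarray
    grid_shape: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1 or not np.all(np.isfinite(self.weights)):
            raise ValueError("signature weights must be a finite 1-D vector")

    def save(self, maps: BrainMaps, path) -> None:
        import nibabel as nib

        vol = np.zeros(maps.grid_shape, dtype=np.float32)
        i, j, k = maps.voxel_coords.T
        vol[i, j, k] = self.weights
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def region_trait_correlations(
    unit_means: pd.DataFrame,
    trait,
    family_m: int | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each unit's mean signal with a trait.

    One row per unit with r, two-sided p, Holm-adjusted p (over the family
    size the caller declares — e.g. six region tests or seven network tests,
    never inferred) and the 95% Fisher CI. Zero-variance units are flagged
    and excluded from the family, but still count toward ``family_m``.
    """
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if n < 4:
        raise ValueError("need n >= 4 per correlation")
    rows = []
    for name in unit_means.columns:
        x = unit_means[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append(
                {"unit": name, "r": np.nan, "p": np.nan, "note": "zero variance"}
            )
            continue
        res = stats.pearsonr(x, trait)
        lo, hi = fisher_ci(res.statistic, n)
        rows.append(
            {
                "unit": name,
                "r": float(res.statistic),
                "p": float(res.pvalue),
                "ci_lower": lo,
                "ci_upper": hi,
                "note": "",
            }
        )
    table = pd.DataFrame(rows)
    ok = table["p"].notna()
    m = family_m if family_m is not None else int(ok.sum())
    adjusted = np.full(len(table), np.nan)
    adjusted[ok.to_numpy()] = holm_correct(table.loc[ok, "p"].to_numpy(), family_m=m)
    table["p_holm"] = adjusted
    return table


def region_pattern_predict(
    maps: BrainMaps,
    atlas,
    region,
    trait,
    cv_spec=None,
):
    """Multivariate pattern prediction restricted to one region's voxels.

    Runs the standard nested cross-validation with PLS on the region's
    voxels only; the returned CVResult is augmented with
    ``sign_consistency``: the fraction of positive voxel weights in a final
    model refit on all observations, a measure of whether the
    activity-trait association has a consistent direction across the
    region. Component counts are capped at the region's voxel count.
    """
    from .predictive import CVSpec, fit_nested_cv, fit_pattern_model

    member = atlas.voxels_of(region, level="region")
    if member.sum() < 1:
        raise ValueError("region has no voxels")
    # a single-voxel region degrades gracefully to simple regression
    # (component counts are capped at the voxel count downstream)
    sub = maps.select_voxels(member, tag=f"region:{region}")
    spec = cv_spec if cv_spec is not None else CVSpec()
    result = fit_nested_cv(sub, trait, algorithm="pls", cv_spec=spec)
    hypers = [rec["hyper"] for rec in result.fold_records.to_dict("records")]
    best = max(set(hypers), key=hypers.count)
    model = fit_pattern_model(sub, trait, algorithm="pls", hyper=best)
    result.sign_consistency = float(np.mean(model.weights > 0))
    return result


def best_region_splithalf(
    region_means: pd.DataFrame,
    trait,
    seed: int = 0,
) -> dict:
    """Data-driven region discovery with split-half confirmation.

    The sample is split in half, stratified on the trait; the region with
    the strongest absolute correlation in the first half is selected and its
    correlation tested (two-sided) in the second half. Selection and test
    are independent, so the confirmatory p is valid despite the search.
    """
    from .predictive import _stratified_indices

    trait = np.asarray(trait, dtype=float)
    if region_means.shape[1] < 2:
        raise ValueError("need at least 2 regions")
    if trait.size < 8:
        raise ValueError("need n >= 8 for a split-half test")
    first, second = _stratified_indices(trait, holdout_fraction=0.5, seed=seed)
    X1 = region_means.iloc[first]
    best_r, best_unit = 0.0, region_means.columns[0]
    for name in region_means.columns:
        x = X1[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue
        r = stats.pearsonr(x, trait[first]).statistic
        if abs(r) > abs(best_r):
            best_r, best_unit = float(r), name
    x2 = region_means.iloc[second][best_unit].to_numpy(dtype=float)
    res = stats.pearsonr(x2, trait[second])
    return {
        "selected": best_unit,
        "r_select": best_r,
        "r_test": float(res.statistic),
        "p_test": float(res.pvalue),
        "n_test": int(len(second)),
    }


def network_models(
    network_means: pd.DataFrame,
    trait,
    model: str = "univariate",
    n_perm: int = 1000,
    n_trees: int = 500,
    family_m: int = 7,
    seed: int = 0,
):
    """Network-level models of a trait, in increasing complexity.

    ``univariate``: per-network correlations, Holm-corrected over the
    declared family. ``multiple_regression``: OLS of the trait on all
    network means with the overall F-test. ``random_forest_oob``: random
    forest whose performance is the correlation of out-of-bag predictions
    with the trait, tested by permuting the trait and refitting.
    """
    trait = np.asarray(trait, dtype=float)
    if model == "univariate":
        if network_means.shape[1] > family_m:
            raise ValueError("more networks than the declared family size")
        return region_trait_correlations(network_means, trait, family_m=family_m)

    if model == "multiple_regression":
        import statsmodels.api as sm

        X = sm.add_constant(network_means.to_numpy(dtype=float))
        fit = sm.OLS(trait, X).fit()
        return {
            "r_squared": float(fit.rsquared),
            "f_pvalue": float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else np.nan,
            "coef": fit.params[1:],
            "fit": fit,
        }

    if model == "random_forest_oob":
        from sklearn.ensemble import RandomForestRegressor

        if trait.size <= 20:
            raise ValueError("random forest OOB evaluation needs n > 20")
        X = network_means.to_numpy(dtype=float)
        rng = np.random.default_rng(seed)

        def oob_r(y, rs):
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                oob_score=True,
                bootstrap=True,
                random_state=rs,
                n_jobs=1,
            ).fit(X, y)
            pred = forest.oob_prediction_
            if np.ptp(pred) == 0:
                return 0.0
            return float(stats.pearsonr(pred, y).statistic)

        observed = oob_r(trait, seed)
        null = np.array(
            [oob_r(rng.permutation(trait), seed + 1 + b) for b in range(n_perm)]
        )
        return {
            "oob_r": observed,
            "perm_p": permutation_pvalue(observed, null),
            "n_perm": n_perm,
        }

    raise ValueError(f"unknown network model {model!r}")


def signature_expression(maps: BrainMaps, sig: SignatureMap) -> np.ndarray:
    """Per-observation signature expression: the dot product w . x."""
    if sig.weights.size != maps.n_voxels:
        raise ValueError(
            f"signature has {sig.weights.size} weights but maps have "
            f"{maps.n_voxels} voxels"
        )
    return maps.data @ sig.weights


def spatial_similarity(a, b) -> float:
    """Pearson correlation between two voxel weight vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("weight vectors must be aligned 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 voxels")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant weight vector: similarity undefined")
    return float(stats.pearsonr(a, b).statistic)
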