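"""Whole-brain predictive modelling with repeated nested cross-validation.

Four algorithms (PLS, principal-component regression, linear SVR, and
PCA-reduced random forest) predict a trait from voxel values. Model
selection and evaluation follow a repeated nested cross-validation: inner
folds tune the hyperparameter by the Pearson correlation of pooled
out-of-fold predictions, outer folds produce held-out predictions, and the
per-repeat performance is the correlation of the pooled out-of-fold
predictions with the trait. Voxel-wise standardization statistics are
computed inside each training fold only, so no information from evaluation
folds leaks into preprocessing or fitting.

Confirmatory machinery around the CV: a permutation test that re-runs the
full nested CV under trait permutations, a stratified train/hold-out split,
final-model hold-out evaluation with one-sided inference and a Bayes
factor, bootstrap thresholding of voxel weights, and virtual-lesion
re-evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .images import BrainMaps
from .inference import (
    CorrInference,
    DEFAULT_PRIOR_SCALE,
    correlation_bf,
    correlation_test,
    permutation_pvalue,
)
from .parcellation import Atlas, LesionResult, lesion

__all__ = [
    "ALGORITHMS",
    "CVSpec",
    "CVResult",
    "PatternModel",
    "stratified_split",
    "fit_pattern_model",
    "fit_nested_cv",
    "permutation_test_cv",
    "train_final_and_evaluate",
    "threshold_pattern_weights",
    "lesion_evaluation",
]

ALGORITHMS = ("pls", "pcr", "svr", "pcarf")
LINEAR_ALGORITHMS = ("pls", "pcr", "svr")


@dataclass
class CVSpec:
    """Cross-validation layout and hyperparameter grids.

    The default layout is 2 repeats x 5 outer folds x 5 inner folds with
    Pearson correlation as the selection and evaluation metric. Grids are
    per-algorithm lists; ``None`` uses the documented defaults (component
    counts {1, 2, 5, 10, 20} capped at half the training size for PLS/PCR,
    log-spaced C for the linear SVR with epsilon fixed at 0.1 SD of the
    trait, a single configuration for the PCA random forest). Fold
    assignment is random under ``seed``, not stratified.
    """

    outer_folds: int = 5
    inner_folds: int = 5
    repeats: int = 2
    seed: int = 0
    grids: dict | None = None
    rf_trees: int = 500

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.grids is not None and any(len(g) == 0 for g in self.grids.values()):
            raise ValueError("hyperparameter grids must be non-empty")

    def grid_for(self, algorithm: str, n_train: int, n_features: int) -> list:
        if self.grids and algorithm in self.grids:
            return list(self.grids[algorithm])
        if algorithm in ("pls", "pcr"):
            cap = max(1, min(n_train // 2, n_features))
            grid = [c for c in (1, 2, 5, 10, 20) if c <= cap]
            return grid or [1]
        if algorithm == "svr":
            return [10.0**k for k in range(-3, 3)]
        if algorithm == "pcarf":
            return [None]
        raise ValueError(f"unknown algorithm {algorithm!r}")


@dataclass
class CVResult:
    """Fold-wise and pooled nested-CV performance."""

    fold_records: pd.DataFrame  # columns repeat, fold, r, hyper
    predictions: np.ndarray  # (repeats, n) pooled out-of-fold predictions
    r_per_repeat: np.ndarray
    r_mean: float
    permutation_p: float | None = None
    sign_consistency: float | None = None


@dataclass
class PatternModel:
    """A trained predictive pattern with its preprocessing provenance.

    Linear algorithms expose a voxel weight vector (on the standardized
    voxel scale) and intercept; the PCA random forest keeps its fitted
    estimator. A model carries the training-fold voxel means/SDs, so it can
    only be applied to maps preprocessed the same way upstream.
    """

    algorithm: str
    hyper: object
    train_mean: np.ndarray
    train_sd: np.ndarray
    provenance: tuple[str, ...]
    trait_name: str = ""
    weights: np.ndarray | None = None
    intercept: float = 0.0
    estimator: object = None

    def predict(self, maps: BrainMaps | np.ndarray) -> np.ndarray:
        X = maps.data if isinstance(maps, BrainMaps) else np.asarray(maps, float)
        if X.shape[1] != self.train_mean.size:
            raise ValueError("voxel space does not match the training space")
        if isinstance(maps, BrainMaps):
            scale_tags = lambda prov: tuple(p for p in prov if p.startswith("scale:"))
            if scale_tags(maps.provenance) != scale_tags(self.provenance):
                raise ValueError(
                    "preprocessing provenance mismatch: the model was trained on "
                    f"{self.provenance} but got {tuple(maps.provenance)}"
                )
        Xs = (X - self.train_mean) / self.train_sd
        if self.weights is not None:
            return Xs @ self.weights + self.intercept
        return np.asarray(self.estimator.predict(Xs), float).ravel()

    # pattern "expression" is prediction up to the training affine map
    expression = predict

    def save(self, maps: BrainMaps, nifti_path, json_path) -> None:
        import json

        import nibabel as nib

        if self.weights is None:
            raise ValueError("only linear models have a weight image")
        vol = np.zeros(maps.grid_shape, dtype=np.float32)
        i, j, k = maps.voxel_coords.T
        vol[i, j, k] = self.weights
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(nifti_path))
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "algorithm": self.algorithm,
                    "hyper": self.hyper,
                    "intercept": self.intercept,
                    "trait": self.trait_name,
                    "provenance": list(self.provenance),
                },
                fh,
                indent=1,
            )


def _as_matrix(maps) -> np.ndarray:
    return maps.data if isinstance(maps, BrainMaps) else np.asarray(maps, dtype=float)


def _std_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def _make_estimator(algorithm, hyper, n_train, n_features, y_sd, seed, rf_trees):
    if algorithm == "pls":
        from sklearn.cross_decomposition import PLSRegression

        return PLSRegression(n_components=int(hyper), scale=False)
    if algorithm == "pcr":
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LinearRegression
        from sklearn.pipeline import make_pipeline

        k = min(int(hyper), n_train - 1, n_features)
        return make_pipeline(PCA(n_components=k, random_state=0), LinearRegression())
    if algorithm == "svr":
        from sklearn.svm import SVR

        return SVR(kernel="linear", C=float(hyper), epsilon=0.1 * y_sd)
    if algorithm == "pcarf":
        from sklearn.decomposition import PCA
        from sklearn.ensemble import RandomForestRegressor
        from sklearn.pipeline import make_pipeline

        # feature space reduced to the number of training participants
        k = min(n_train - 1, n_features)
        return make_pipeline(
            PCA(n_components=k, random_state=0),
            RandomForestRegressor(
                n_estimators=rf_trees, random_state=seed % (2**31), n_jobs=1
            ),
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _fit_predict(algorithm, hyper, Xtr, ytr, Xte, seed, rf_trees) -> np.ndarray:
    est = _make_estimator(
        algorithm, hyper, Xtr.shape[0], Xtr.shape[1], float(np.std(ytr)), seed, rf_trees
    )
    if algorithm == "pls":
        hyper_cap = min(int(hyper), Xtr.shape[0] - 1, Xtr.shape[1])
        est.set_params(n_components=hyper_cap)
    est.fit(Xtr, ytr)
    return np.asarray(est.predict(Xte), float).ravel()


def _safe_r(pred: np.ndarray, y: np.ndarray, context: str) -> float:
    if not np.all(np.isfinite(pred)) or np.ptp(pred) == 0 or np.ptp(y) == 0:
        warnings.warn(f"constant predictions in {context}; recording r = 0", stacklevel=2)
        return 0.0
    return float(stats.pearsonr(pred, y).statistic)


def stratified_split(
    trait,
    holdout_fraction: float = 0.25,
    seed: int = 0,
    n_bins: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Quantile-stratified train/hold-out split on a continuous trait.

    Observations are binned into trait quantiles and the requested fraction
    is drawn from each bin, so the hold-out trait distribution matches the
    training one. Rounding within bins can make the realized split deviate
    from the nominal fraction by an observation or two.
    """
    trait = np.asarray(trait, dtype=float)
    n = trait.size
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError("holdout_fraction must lie in (0, 1)")
    if n < 10:
        raise ValueError("stratified split requires n >= 10")
    return _stratified_indices(trait, holdout_fraction, seed, n_bins)


def _stratified_indices(trait, holdout_fraction, seed, n_bins=5):
    n = trait.size
    q = min(n_bins, max(2, n // 4))
    bins = pd.qcut(trait, q=q, labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    holdout = []
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        rng.shuffle(idx)
        k = int(round(holdout_fraction * idx.size))
        holdout.extend(idx[:k])
    holdout = np.sort(np.asarray(holdout, dtype=int))
    train = np.setdiff1d(np.arange(n), holdout)
    return train, holdout


def fit_pattern_model(
    maps,
    y,
    algorithm: str,
    hyper,
    trait_name: str = "",
    seed: int = 0,
    rf_trees: int = 500,
) -> PatternModel:
    """Fit one algorithm on the full training data and package it.

    Voxel standardization statistics come from these training maps; linear
    algorithms are reduced to an explicit voxel weight vector and intercept
    (on the standardized scale), so that expressions are plain dot products.
    """
    X = _as_matrix(maps)
    y = np.asarray(y, dtype=float)
    mean, sd = _std_stats(X)
    Xs = (X - mean) / sd
    est = _make_estimator(
        algorithm, hyper, X.shape[0], X.shape[1], float(np.std(y)), seed, rf_trees
    )
    if algorithm == "pls":
        est.set_params(n_components=min(int(hyper), X.shape[0] - 1, X.shape[1]))
    est.fit(Xs, y)
    prov = tuple(maps.provenance) if isinstance(maps, BrainMaps) else ()
    model = PatternModel(
        algorithm=algorithm,
        hyper=hyper,
        train_mean=mean,
        train_sd=sd,
        provenance=prov,
        trait_name=trait_name,
    )
    if algorithm in LINEAR_ALGORITHMS:
        # recover the weight vector by probing the fitted linear map
        p = X.shape[1]
        intercept = float(np.asarray(est.predict(np.zeros((1, p)))).ravel()[0])
        probe = np.asarray(est.predict(np.eye(p))).ravel() - intercept
        model.weights = probe
        model.intercept = intercept
    else:
        model.estimator = est
    return model


def fit_nested_cv(
    maps,
    y,
    algorithm: str = "pls",
    cv_spec: CVSpec | None = None,
    grid: list | None = None,
) -> CVResult:
    """Repeated nested cross-validation of one algorithm on one outcome.

    Inner folds select the hyperparameter by the Pearson correlation of
    pooled inner out-of-fold predictions (ties broken toward the simpler,
    earlier grid entry); outer folds yield held-out predictions. Voxel
    standardization is refit inside every training fold (outer and inner).
    Performance per repeat is the correlation of the pooled out-of-fold
    predictions with the outcome; fold-wise correlations of constant
    predictions are recorded as 0 with a warning.
    """
    from sklearn.model_selection import KFold

    spec = cv_spec or CVSpec()
    X = _as_matrix(maps)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("maps and outcome length differ")
    n = y.size
    records = []
    predictions = np.empty((spec.repeats, n))
    r_per_repeat = np.empty(spec.repeats)
    for rep in range(spec.repeats):
        outer = KFold(
            n_splits=spec.outer_folds,
            shuffle=True,
            random_state=(spec.seed + 7919 * rep) % (2**31),
        )
        for fold, (tr, te) in enumerate(outer.split(X)):
            mean, sd = _std_stats(X[tr])
            Xtr, ytr = (X[tr] - mean) / sd, y[tr]
            Xte = (X[te] - mean) / sd
            grid_f = grid if grid is not None else spec.grid_for(algorithm, tr.size, X.shape[1])
            if len(grid_f) == 1:
                best = grid_f[0]
            else:
                inner = KFold(
                    n_splits=spec.inner_folds,
                    shuffle=True,
                    random_state=(spec.seed + 7919 * rep + 104729 * (fold + 1)) % (2**31),
                )
                splits = list(inner.split(Xtr))
                best, best_r = grid_f[0], -np.inf
                for hyper in grid_f:
                    inner_pred = np.empty(tr.size)
                    for itr, ite in splits:
                        imean, isd = _std_stats(X[tr][itr])
                        inner_pred[ite] = _fit_predict(
                            algorithm,
                            hyper,
                            (X[tr][itr] - imean) / isd,
                            ytr[itr],
                            (X[tr][ite] - imean) / isd,
                            spec.seed,
                            spec.rf_trees,
                        )
                    if np.ptp(inner_pred) == 0:
                        r_inner = -np.inf
                    else:
                        r_inner = stats.pearsonr(inner_pred, ytr).statistic
                    if r_inner > best_r:  # strict: ties keep the simpler model
                        best, best_r = hyper, r_inner
            pred = _fit_predict(algorithm, best, Xtr, ytr, Xte, spec.seed, spec.rf_trees)
            predictions[rep, te] = pred
            records.append(
                {
                    "repeat": rep,
                    "fold": fold,
                    "r": _safe_r(pred, y[te], f"repeat {rep} fold {fold}"),
                    "hyper": best,
                }
            )
        r_per_repeat[rep] = _safe_r(predictions[rep], y, f"repeat {rep} pooled")
    return CVResult(
        fold_records=pd.DataFrame(records),
        predictions=predictions,
        r_per_repeat=r_per_repeat,
        r_mean=float(r_per_repeat.mean()),
    )


def permutation_test_cv(
    maps,
    y,
    algorithm: str = "pls",
    cv_spec: CVSpec | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    grid: list | None = None,
) -> dict:
    """Permutation test of the nested-CV correlation.

    The outcome is permuted and the full nested CV re-run per permutation;
    p = (1 + #{null r >= observed r}) / (1 + n_perm), one-tailed, because
    only positive correlations indicate successful prediction.
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    spec = cv_spec or CVSpec()
    y = np.asarray(y, dtype=float)
    observed = fit_nested_cv(maps, y, algorithm, spec, grid=grid).r_mean
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        null[b] = fit_nested_cv(maps, rng.permutation(y), algorithm, spec, grid=grid).r_mean
    return {
        "observed_r": observed,
        "p": permutation_pvalue(observed, null),
        "null": null,
        "n_perm": n_perm,
    }


def train_final_and_evaluate(
    maps_train,
    y_train,
    maps_holdout,
    y_holdout,
    algorithm: str,
    hyper,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    trait_name: str = "",
) -> tuple[CorrInference, PatternModel]:
    """Retrain the selected model on all training data and score the hold-out.

    Hold-out predictions are evaluated by a one-sided correlation test with
    Fisher CI and a one-sided default-prior Bayes factor. Passing the
    training set as its own hold-out is a contract violation and raises.
    """
    Xtr, Xho = _as_matrix(maps_train), _as_matrix(maps_holdout)
    if Xtr.shape == Xho.shape and (np.shares_memory(Xtr, Xho) or np.array_equal(Xtr, Xho)):
        raise ValueError("hold-out sample must be disjoint from the training sample")
    model = fit_pattern_model(maps_train, y_train, algorithm, hyper, trait_name)
    pred = model.predict(maps_holdout)
    inf = correlation_test(pred, np.asarray(y_holdout, float), alternative="greater")
    inf.bf10 = correlation_bf(inf.r, inf.n, "greater", prior_scale)
    inf.prior_scale = prior_scale
    return inf, model


def threshold_pattern_weights(
    maps_train: BrainMaps,
    y_train,
    algorithm: str,
    hyper,
    alpha: float = 0.05,
    min_cluster: int = 50,
    n_boot: int = 500,
    method: str = "alpha",
    seed: int = 0,
) -> dict:
    """Bootstrap thresholding of a linear pattern's voxel weights.

    Training subjects are resampled with replacement and the model refit;
    per-voxel z = bootstrap mean / bootstrap SD gives a two-sided normal p,
    thresholded at ``alpha`` (or by Benjamini-Hochberg FDR with
    ``method="fdr"``), after which connected components (6-connectivity on
    the 3-D grid) smaller than ``min_cluster`` voxels are removed.
    """
    if algorithm not in LINEAR_ALGORITHMS:
        raise ValueError("weight thresholding requires a linear algorithm")
    if n_boot < 2:
        raise ValueError("need at least 2 bootstrap samples")
    y = np.asarray(y_train, dtype=float)
    n, V = maps_train.n_obs, maps_train.n_voxels
    rng = np.random.default_rng(seed)
    W = np.empty((n_boot, V))
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        W[b] = fit_pattern_model(maps_train.select_obs(idx), y[idx], algorithm, hyper).weights
    sd = W.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, W.mean(axis=0) / sd, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    if method == "alpha":
        sig = p < alpha
    elif method == "fdr":
        from statsmodels.stats.multitest import multipletests

        sig = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        raise ValueError(f"unknown thresholding method {method!r}")
    vol = np.zeros(maps_train.grid_shape, dtype=bool)
    i, j, k = maps_train.voxel_coords.T
    vol[i, j, k] = sig
    labels, n_comp = ndimage.label(vol, structure=ndimage.generate_binary_structure(3, 1))
    keep_vol = np.zeros_like(vol)
    for comp in range(1, n_comp + 1):
        members = labels == comp
        if members.sum() >= min_cluster:
            keep_vol |= members
    surviving = keep_vol[i, j, k]
    full = fit_pattern_model(maps_train, y, algorithm, hyper)
    return {
        "weights": np.where(surviving, full.weights, 0.0),
        "surviving": surviving,
        "z": z,
        "p": p,
        "n_surviving": int(surviving.sum()),
    }


def lesion_evaluation(
    maps_train: BrainMaps,
    y_train,
    maps_holdout: BrainMaps,
    y_holdout,
    atlas: Atlas,
    level: str = "network",
    algorithm: str = "pls",
    hyper=5,
    units=None,
    retrain: bool = True,
) -> tuple[float, pd.DataFrame]:
    """Hold-out performance after virtually lesioning each region/network.

    ``retrain=True`` refits the model on the reduced voxel space (the
    stronger test of whether the removed unit is necessary); ``retrain=False``
    keeps the full model and only drops the unit's voxels at prediction
    time, equivalent to zeroing its weights. Returns the full-model hold-out
    correlation and one :class:`LesionResult` row per unit.
    """
    y_train = np.asarray(y_train, float)
    y_holdout = np.asarray(y_holdout, float)
    full = fit_pattern_model(maps_train, y_train, algorithm, hyper)
    r_full = _safe_r(full.predict(maps_holdout), y_holdout, "full model hold-out")
    names = atlas.region_names if level == "region" else atlas.network_names
    if units is None:
        units = range(len(names))
    rows = []
    for unit in units:
        uid = atlas.unit_id(unit, level)
        member = atlas.voxels_of(uid, level)
        tr_les, _ = lesion(maps_train, atlas, uid, level)
        ho_les, _ = lesion(maps_holdout, atlas, uid, level)
        if retrain:
            model = fit_pattern_model(tr_les, y_train, algorithm, hyper)
            pred = model.predict(ho_les)
        else:
            keep = ~member
            w = full.weights
            if w is None:
                raise ValueError("retrain=False requires a linear algorithm")
            Xs = (ho_les.data - full.train_mean[keep]) / full.train_sd[keep]
            pred = Xs @ w[keep] + full.intercept
        r_les = _safe_r(pred, y_holdout, f"lesion {level} {uid}")
        rows.append(
            LesionResult(
                level=level,
                unit=uid,
                unit_name=names[uid],
                n_voxels_removed=int(member.sum()),
                r_lesioned=r_les,
                delta_r=r_full - r_les,
            )
        )
    return r_full, pd.DataFrame([vars(r) for r in rows])
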