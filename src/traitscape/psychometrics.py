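"""Reliability, validity and within-person state decoding of a pattern.

A trained pattern is only useful as a person-level marker if its expression
is reliable (split-half across trials, Spearman-Brown corrected), valid
(converges with related traits, diverges from unrelated ones), and if its
between-person performance can be put in context with the much easier
within-person problem of tracking momentary affect across trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .images import BrainMaps
from .inference import spearman_brown
from .predictive import PatternModel, fit_pattern_model
from .synthdata import build_contrast

__all__ = [
    "ReliabilityResult",
    "split_half_reliability",
    "loo_validity",
    "within_person_decode",
]


@dataclass
class ReliabilityResult:
    scheme: str
    r_half: float
    r_corrected: float  # Spearman-Brown projection to full length
    n_subjects: int


def split_half_reliability(
    trial_maps: BrainMaps,
    pattern: PatternModel,
    scheme: str = "odd_even",
    seed: int | None = None,
) -> ReliabilityResult:
    """Split-half reliability of per-person pattern expression.

    Trials are split into two halves within each condition (deterministic
    odd/even trial index by default, or randomly under ``seed`` with
    ``scheme="random"``); each half is collapsed into a condition contrast,
    the pattern expression computed on both, and the across-subject
    correlation of the two half-expressions Spearman-Brown corrected.
    """
    meta = trial_maps.obs_meta
    if meta is None or "trial" not in meta:
        raise ValueError("trial maps need subject/condition/trial metadata")
    counts = meta.groupby("subject").size()
    if (counts < 4).any():
        raise ValueError("need at least 4 trials per subject")
    if scheme == "odd_even":
        half1 = (meta["trial"].to_numpy() % 2) == 0
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        half1 = np.zeros(len(meta), dtype=bool)
        for _, grp in meta.groupby(["subject", "condition"]):
            idx = grp.index.to_numpy()
            pick = rng.permutation(idx)[: idx.size // 2]
            half1[pick] = True
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    # subjects must have >= 1 trial per condition in each half; build_contrast
    # raises otherwise, so screen and warn-exclude here
    ok_subjects = []
    for subj, grp in meta.groupby("subject"):
        fine = True
        for half in (half1, ~half1):
            conds = set(grp.loc[half[grp.index.to_numpy()], "condition"])
            if conds != {"negative", "neutral"}:
                fine = False
        if fine:
            ok_subjects.append(subj)
        else:
            warnings.warn(f"subject {subj!r} lacks trials in one half; excluded")
    keep_rows = meta["subject"].isin(ok_subjects).to_numpy()
    sub = trial_maps.select_obs(np.flatnonzero(keep_rows))
    h1 = half1[keep_rows]
    expr1 = pattern.predict(build_contrast(sub, trial_mask=h1))
    expr2 = pattern.predict(build_contrast(sub, trial_mask=~h1))
    r_half = float(stats.pearsonr(expr1, expr2).statistic)
    return ReliabilityResult(
        scheme=scheme,
        r_half=r_half,
        r_corrected=spearman_brown(r_half),
        n_subjects=len(ok_subjects),
    )


def loo_validity(
    maps: BrainMaps,
    traits: pd.DataFrame,
    target: str,
    others: list[str],
    algorithm: str = "pls",
    hyper=5,
) -> pd.DataFrame:
    """Convergent/discriminant validity of leave-one-out pattern predictions.

    The target trait is predicted by leave-one-out cross-validation (model
    and voxel standardization refit on each n-1 subsample); the vector of
    left-out predictions is then correlated with the target (its entry is
    the model's cross-validated performance) and with every other listed
    trait. Roles are labelled target / other; interpretation as convergent
    or discriminant is the caller's.
    """
    n = maps.n_obs
    if n < 10:
        raise ValueError("leave-one-out validity needs n >= 10")
    cols = [target] + list(others)
    if traits[cols].isna().any().any():
        raise ValueError("traits used for validity must be complete")
    y = traits[target].to_numpy(dtype=float)
    preds = np.empty(n)
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        model = fit_pattern_model(maps.select_obs(rest), y[rest], algorithm, hyper)
        preds[i] = model.predict(maps.data[i : i + 1])[0]
    rows = []
    for name in cols:
        r = float(stats.pearsonr(preds, traits[name].to_numpy(dtype=float)).statistic)
        rows.append({"trait": name, "r": r, "role": "target" if name == target else "other"})
    return pd.DataFrame(rows)


def within_person_decode(
    trial_maps: BrainMaps,
    algorithm: str = "pls",
    hyper=5,
    n_folds: int = 5,
    rating_col: str = "rating",
) -> dict:
    """Within-person decoding of trial-wise affect ratings.

    Folds are split by subject (all trials of a subject share a fold) — the
    only leakage-free reading — and a pattern is trained on the training
    subjects' trial maps against their ratings. For each held-out subject,
    performance is the Pearson correlation between predicted and actual
    ratings across that subject's trials; the mean and SD across subjects
    are reported. Subjects with constant ratings are excluded with a
    warning.
    """
    from sklearn.model_selection import GroupKFold

    meta = trial_maps.obs_meta
    if meta is None or rating_col not in meta:
        raise ValueError("trial maps need per-trial ratings in obs_meta")
    if (meta.groupby("subject").size() < 5).any():
        raise ValueError("need at least 5 rated trials per subject")
    y = meta[rating_col].to_numpy(dtype=float)
    groups = meta["subject"].to_numpy()
    per_subject: dict[str, float] = {}
    for tr, te in GroupKFold(n_splits=n_folds).split(trial_maps.data, groups=groups):
        model = fit_pattern_model(trial_maps.select_obs(tr), y[tr], algorithm, hyper)
        pred = model.predict(trial_maps.data[te])
        for subj in np.unique(groups[te]):
            rows = groups[te] == subj
            if np.ptp(y[te][rows]) == 0:
                warnings.warn(f"subject {subj!r} has constant ratings; excluded")
                continue
            per_subject[subj] = float(stats.pearsonr(pred[rows], y[te][rows]).statistic)
    rs = np.array(list(per_subject.values()))
    return {
        "per_subject": pd.Series(per_subject, name="r"),
        "mean_r": float(rs.mean()),
        "sd_r": float(rs.std(ddof=1)),
        "n_subjects": rs.size,
    }
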