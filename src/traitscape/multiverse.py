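"""Multiverse analysis: staged design grids, sweep execution, meta-analysis.

The staged model search crosses defensible design choices into factorial
grids: stage 1 fixes the outcome (broad neuroticism) and algorithm (PLS)
and varies task (scenes vs faces), baseline (control-condition contrast vs
implicit baseline) and image-wise scaling (none / center / z-score) — 12
models; stage 2 expands to the 7 neuroticism scores and 3 linear algorithms
— 252 models; stage 3 further expands to 14 affectivity outcomes and adds
the PCA random forest and a full-sample option. The exact factorial
composition of the reference third stage is configuration, with a
documented default whose product is 1,176: the four algorithms crossed with
{training, full} sample except that the random forest runs on the training
sample only (7 algorithm x sample combinations x 12 base points x 14
outcomes).

Each executed design point contributes its 2 x 5 fold-wise cross-validated
correlations to a tidy table, which is then meta-analyzed: a bagged random
forest ranks design factors by permutation importance (RMSE increase), and
a crossed random-intercept variance decomposition attributes spread in
fold correlations to each factor. Both are descriptive, as the fold rows
are not independent.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .images import scale_images
from .predictive import CVSpec, fit_nested_cv
from .synthdata import FACETS, CohortData

__all__ = [
    "DesignPoint",
    "TASKS",
    "BASELINES",
    "SCALINGS",
    "STAGE2_OUTCOMES",
    "STAGE3_OUTCOMES",
    "build_design_grid",
    "run_multiverse",
    "design_importance",
    "variance_decomposition",
    "export_report",
]

TASKS = ("scenes", "faces")
BASELINES = ("control", "implicit")
SCALINGS = ("none", "center", "zscore")
DESIGN_FACTORS = ("task", "baseline", "scaling", "outcome", "algorithm", "sample")

STAGE2_OUTCOMES = ("neuroticism",) + FACETS  # 7 neuroticism scores
STAGE3_OUTCOMES = STAGE2_OUTCOMES + (
    "neuroticism_other",
    "neuroticism_combined",
    "negative_affect",
    "positive_affect",
    "stai",
    "bdi",
    "task_ratings",
)  # 14 affectivity outcomes

#: stage-3 algorithm x sample crossing (7 combinations, see module docstring)
STAGE3_ALGO_SAMPLE = tuple(
    itertools.product(("pls", "pcr", "svr"), ("training", "full"))
) + (("pcarf", "training"),)


@dataclass(frozen=True)
class DesignPoint:
    """One fully specified analysis in the multiverse."""

    stage: int
    task: str
    baseline: str
    scaling: str
    outcome: str
    algorithm: str
    sample: str = "training"

    def label(self) -> str:
        return "|".join(
            [self.task, self.baseline, self.scaling, self.outcome, self.algorithm, self.sample]
        )


def build_design_grid(
    stage: int,
    outcomes=None,
    tasks=TASKS,
    baselines=BASELINES,
    scalings=SCALINGS,
    algorithms=None,
    algo_sample=None,
) -> list[DesignPoint]:
    """Full factorial grid of design points for one stage.

    Stage 1: 2 tasks x 2 baselines x 3 scalings = 12 points (outcome fixed
    to broad neuroticism, algorithm to PLS, training sample). Stage 2:
    12 x 7 outcomes x 3 algorithms = 252. Stage 3 crosses the 12 base
    points with 14 outcomes and the configured algorithm x sample pairs
    (default product 1,176). Factor levels can be overridden; the product
    is whatever the overridden lists imply.
    """
    for name, levels, valid in (
        ("task", tasks, TASKS),
        ("baseline", baselines, BASELINES),
        ("scaling", scalings, SCALINGS),
    ):
        unknown = set(levels) - set(valid)
        if unknown:
            raise ValueError(f"unknown {name} level(s): {sorted(unknown)}")
    if stage == 1:
        outcomes = tuple(outcomes) if outcomes is not None else ("neuroticism",)
        pairs = (("pls", "training"),)
    elif stage == 2:
        outcomes = tuple(outcomes) if outcomes is not None else STAGE2_OUTCOMES
        algorithms = tuple(algorithms) if algorithms is not None else ("pls", "pcr", "svr")
        pairs = tuple((a, "training") for a in algorithms)
    elif stage == 3:
        outcomes = tuple(outcomes) if outcomes is not None else STAGE3_OUTCOMES
        pairs = tuple(algo_sample) if algo_sample is not None else STAGE3_ALGO_SAMPLE
    else:
        raise ValueError("stage must be 1, 2 or 3")
    return [
        DesignPoint(stage, t, b, s, o, alg, samp)
        for t, b, s, o, (alg, samp) in itertools.product(
            tasks, baselines, scalings, outcomes, pairs
        )
    ]


def _run_point(point: DesignPoint, cohort: CohortData, cv_spec: CVSpec, train_idx):
    maps = cohort.maps_for(point.task, point.baseline)
    if point.sample == "training":
        if train_idx is None:
            raise ValueError("a training index is required for sample='training'")
        maps = maps.select_obs(train_idx)
        y = cohort.traits[point.outcome].to_numpy(dtype=float)[train_idx]
    else:
        y = cohort.traits[point.outcome].to_numpy(dtype=float)
    maps = scale_images(maps, point.scaling)
    result = fit_nested_cv(maps, y, algorithm=point.algorithm, cv_spec=cv_spec)
    rows = result.fold_records.copy()
    rows["mean_r"] = result.r_mean
    return rows


def run_multiverse(
    grid: list[DesignPoint],
    cohort: CohortData,
    cv_spec: CVSpec | None = None,
    train_idx=None,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """Execute every design point and collect fold-wise correlations.

    Returns a tidy table with one row per (design point x repeat x outer
    fold). All points share the CV seed policy, so identical points give
    identical results and execution order does not matter. A failing point
    is logged and marked, never aborting the sweep.
    """
    if not grid:
        raise ValueError("empty design grid")
    spec = cv_spec or CVSpec()

    def one(point):
        try:
            rows = _run_point(point, cohort, spec, train_idx)
            rows["failed"] = False
        except Exception as exc:  # noqa: BLE001 - isolate per-point failures
            warnings.warn(f"design point {point.label()} failed: {exc}")
            rows = pd.DataFrame(
                {"repeat": [np.nan], "fold": [np.nan], "r": [np.nan],
                 "hyper": [None], "mean_r": [np.nan], "failed": [True]}
            )
        for k, v in asdict(point).items():
            rows[k] = v
        return rows

    if n_jobs != 1:
        from joblib import Parallel, delayed

        parts = Parallel(n_jobs=n_jobs)(delayed(one)(p) for p in grid)
    else:
        parts = [one(p) for p in grid]
    return pd.concat(parts, ignore_index=True)


def _failed_rows(table: pd.DataFrame) -> pd.Series:
    if "failed" in table.columns:
        return table["failed"].astype(bool)
    return pd.Series(False, index=table.index)


def design_importance(
    table: pd.DataFrame,
    factors=None,
    n_trees: int = 1000,
    seed: int = 0,
) -> pd.Series:
    """Permutation-based design-factor importance from a bagged forest.

    Fold correlations are regressed on one-hot design factors with a random
    forest of bagged trees; a factor's importance is the mean increase in
    root-mean-squared error when its columns are permuted (jointly), a
    descriptive ranking of how much each choice moves performance. Factors
    with a single level have importance exactly 0.
    """
    from sklearn.ensemble import RandomForestRegressor

    factors = list(factors) if factors is not None else [
        f for f in DESIGN_FACTORS if f in table.columns
    ]
    data = table.loc[~_failed_rows(table)]
    y = data["r"].to_numpy(dtype=float)
    X = pd.get_dummies(data[factors].astype(str), dtype=float)
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    base_rmse = float(np.sqrt(np.mean((forest.predict(X) - y) ** 2)))
    rng = np.random.default_rng(seed)
    out = {}
    for f in factors:
        if data[f].nunique() < 2:
            out[f] = 0.0
            continue
        Xp = X.copy()
        cols = [c for c in X.columns if c.startswith(f + "_")]
        perm = rng.permutation(len(Xp))
        Xp[cols] = X[cols].to_numpy()[perm]
        rmse = float(np.sqrt(np.mean((forest.predict(Xp) - y) ** 2)))
        out[f] = rmse - base_rmse
    imp = pd.Series(out, name="rmse_increase").sort_values(ascending=False)
    imp.attrs["oob_r2"] = float(forest.oob_score_)
    return imp


def variance_decomposition(table: pd.DataFrame, factors=None) -> pd.Series:
    """Crossed random-intercept decomposition of fold-correlation variance.

    Each design factor is treated as a random grouping of the fold
    correlations and the model is fit by REML with all factors crossed;
    reported is the SD attributable to each factor plus the residual SD.
    Factors that are constant or perfectly confounded with another factor
    are rejected.
    """
    import statsmodels.formula.api as smf

    factors = list(factors) if factors is not None else [
        f for f in DESIGN_FACTORS if f in table.columns
    ]
    data = table.loc[~_failed_rows(table), factors + ["r"]].copy()
    factors = [f for f in factors if data[f].nunique() >= 2]
    if not factors:
        raise ValueError("no design factor with >= 2 levels")
    for f1, f2 in itertools.combinations(factors, 2):
        tab = pd.crosstab(data[f1], data[f2])
        if (tab > 0).sum().sum() == max(tab.shape):
            raise ValueError(f"factors {f1!r} and {f2!r} are confounded, not crossed")
    if float(np.var(data["r"])) == 0.0:
        return pd.Series({**{f: 0.0 for f in factors}, "residual": 0.0}, name="sd")
    data["_g"] = 1  # single group: all effects enter as crossed variance components
    vcf = {f: f"0 + C({f})" for f in factors}
    model = smf.mixedlm("r ~ 1", data=data, groups="_g", vc_formula=vcf, re_formula="0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True, method="lbfgs", maxiter=200)
    out = {f: float(np.sqrt(max(fit.vcomp[i], 0.0))) for i, f in enumerate(sorted(vcf))}
    out["residual"] = float(np.sqrt(fit.scale))
    return pd.Series(out, name="sd")


_HTML_TEMPLATE = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Multiverse results</title>
<style>body{{font-family:sans-serif}}table{{border-collapse:collapse}}
td,th{{border:1px solid #999;padding:2px 6px;font-size:12px}}</style>
<script>
function filt() {{
  var sels = document.querySelectorAll("select"), rows = document.querySelectorAll("tbody tr");
  rows.forEach(function(tr) {{
    var show = true;
    sels.forEach(function(s) {{
      var v = s.value, col = parseInt(s.dataset.col);
      if (v !== "all" && tr.children[col].textContent !== v) show = false;
    }});
    tr.style.display = show ? "" : "none";
  }});
}}
</script></head><body>
<h2>Multiverse fold-wise correlations</h2>
<div>{filters}</div>
{table}
</body></html>"""


def export_report(table: pd.DataFrame, csv_path, html_path=None) -> None:
    """Write the tidy fold-level table to CSV and a filterable HTML view."""
    table.to_csv(csv_path, index=False)
    if html_path is None:
        return
    cols = list(table.columns)
    filters = []
    for f in DESIGN_FACTORS:
        if f not in cols:
            continue
        opts = "".join(
            f'<option value="{v}">{v}</option>' for v in sorted(table[f].astype(str).unique())
        )
        filters.append(
            f'{f}: <select data-col="{cols.index(f)}" onchange="filt()">'
            f'<option value="all">all</option>{opts}</select>'
        )
    html = _HTML_TEMPLATE.format(
        filters=" ".join(filters), table=table.to_html(index=False)
    )
    with open(html_path, "w") as fh:
        fh.write(html)
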