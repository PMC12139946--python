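"""Frequentist and Bayesian inference for Pearson correlations.

Prediction performance throughout the pipeline is expressed as a Pearson
correlation between predicted and observed scores, so every confirmatory
question reduces to inference on a correlation coefficient: a (usually
one-sided) t-test, a Fisher-z confidence interval, and a Bayes factor that
quantifies evidence for a positive correlation against the null.

The Bayes factor follows the standard default-prior test for correlations:
a stretched-beta prior on the population correlation rho in (-1, 1) with
shape 1/kappa (so kappa = 1 is uniform and smaller kappa concentrates mass
near zero), truncated to rho > 0 for the one-sided test, integrated against
the exact sampling density of the observed correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, special, stats

__all__ = [
    "CorrInference",
    "DEFAULT_PRIOR_SCALE",
    "PRINTED_BF_PRIOR_SCALE",
    "correlation_test",
    "correlation_bf",
    "calibrate_prior_scale",
    "fisher_ci",
    "holm_correct",
    "power_correlation",
    "spearman_brown",
    "permutation_pvalue",
]

#: "Medium" prior scale of the default Bayesian correlation test: the
#: stretched beta(3, 3). This is the package-wide default.
DEFAULT_PRIOR_SCALE = 1.0 / 3.0

#: Prior scale calibrated so that the one-sided BF10 at r = .19, n = 102
#: reproduces 2.53 exactly from the two-decimal inputs (see
#: :func:`calibrate_prior_scale`; with kappa = 1/3 the same inputs give
#: 2.50, the difference being attributable to rounding of r).
PRINTED_BF_PRIOR_SCALE = 0.32491


@dataclass
class CorrInference:
    """Inference summary for a single Pearson correlation.

    Attributes
    ----------
    r : float
        Sample Pearson correlation.
    n : int
        Number of paired observations.
    alternative : str
        ``"greater"`` (one-sided, positive) or ``"two-sided"``.
    p : float
        p-value of the t-test under ``alternative``.
    ci_level : float
        Confidence level of the (always two-sided) Fisher-z interval.
    ci_lower, ci_upper : float
    bf10 : float or None
        Bayes factor alternative : null, if computed.
    prior_scale : float or None
        Stretched-beta scale kappa used for ``bf10``.
    """

    r: float
    n: int
    alternative: str
    p: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    bf10: float | None = None
    prior_scale: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError(f"correlation out of range: {self.r}")


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Two-sided Fisher-z confidence interval for a Pearson correlation.

    atanh(r) +- z_(1-alpha/2) / sqrt(n - 3), mapped back through tanh.
    Degenerate at |r| = 1, where the interval collapses to the point.
    """
    if n < 4:
        raise ValueError("Fisher interval requires n >= 4")
    if abs(r) >= 1.0:
        return (r, r)
    z = math.atanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / math.sqrt(n - 3)
    return (math.tanh(z - half), math.tanh(z + half))


def correlation_test(
    x,
    y,
    alternative: str = "greater",
    ci_level: float = 0.95,
) -> CorrInference:
    """t-test and Fisher-z CI for the Pearson correlation of ``x`` and ``y``.

    One-tailed tests are the default because only positive correlations
    between predictions and observed scores indicate successful prediction;
    the confidence interval is reported two-sided at ``ci_level`` regardless
    of the test's sidedness.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = x.size
    if n < 4:
        raise ValueError("correlation test requires n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    if alternative not in ("greater", "two-sided", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    res = stats.pearsonr(x, y, alternative=alternative)
    lo, hi = fisher_ci(res.statistic, n, ci_level)
    return CorrInference(
        r=float(res.statistic),
        n=n,
        alternative=alternative,
        p=float(res.pvalue),
        ci_level=ci_level,
        ci_lower=lo,
        ci_upper=hi,
    )


def _log_lik_ratio(rho: np.ndarray, r: float, n: int) -> np.ndarray:
    """log f(r | rho, n) - log f(r | 0, n) for the exact sampling density.

    Uses the classical exact density of the sample correlation from a
    bivariate normal, whose rho-dependent part is
    (1-rho^2)^((n-1)/2) * (1-rho*r)^(3/2-n) * 2F1(1/2, 1/2; n-1/2; (1+rho*r)/2).
    """
    rho = np.asarray(rho, dtype=float)
    hyp = special.hyp2f1(0.5, 0.5, n - 0.5, (1.0 + rho * r) / 2.0)
    hyp0 = special.hyp2f1(0.5, 0.5, n - 0.5, 0.5)
    with np.errstate(divide="ignore"):
        out = (
            0.5 * (n - 1) * np.log1p(-rho**2)
            + (1.5 - n) * np.log1p(-rho * r)
            + np.log(hyp)
            - np.log(hyp0)
        )
    return out


def _stretched_beta_logpdf(rho: np.ndarray, kappa: float) -> np.ndarray:
    """Log density of the stretched beta(1/kappa, 1/kappa) on (-1, 1)."""
    a = 1.0 / kappa
    rho = np.asarray(rho, dtype=float)
    return (
        (1.0 - 2.0 * a) * math.log(2.0)
        - special.betaln(a, a)
        + (a - 1.0) * np.log1p(-rho**2)
    )


def correlation_bf(
    r: float,
    n: int,
    alternative: str = "greater",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> float:
    """Bayes factor BF10 for a Pearson correlation by numerical integration.

    The marginal likelihood under the alternative integrates the exact
    reduced likelihood of the observed ``r`` over a stretched-beta
    (1/kappa, 1/kappa) prior on rho, truncated to (0, 1) for
    ``alternative="greater"`` (or (-1, 0) for ``"less"``), and is divided by
    the likelihood at rho = 0.

    Parameters
    ----------
    r : observed Pearson correlation, |r| < 1.
    n : number of paired observations, >= 4.
    alternative : "greater", "less" or "two-sided".
    prior_scale : stretched-beta scale kappa in (0, 1].
    """
    if not abs(r) < 1:
        raise ValueError("|r| must be < 1 for the Bayes factor")
    if n < 4:
        raise ValueError("Bayes factor requires n >= 4")
    if not 0 < prior_scale <= 1:
        raise ValueError("prior_scale kappa must be in (0, 1]")
    bounds = {"greater": (0.0, 1.0), "less": (-1.0, 0.0), "two-sided": (-1.0, 1.0)}
    try:
        lo, hi = bounds[alternative]
    except KeyError:
        raise ValueError(f"unknown alternative {alternative!r}") from None
    # prior mass in the integration window (1/2 for one-sided, 1 two-sided)
    mass = 0.5 if alternative != "two-sided" else 1.0

    def integrand(rho):
        return math.exp(
            _log_lik_ratio(rho, r, n) + _stretched_beta_logpdf(rho, prior_scale)
        )

    value, err = integrate.quad(integrand, lo, hi, limit=200)
    bf = value / mass
    if not np.isfinite(bf) or (bf > 0 and err / max(value, 1e-300) > 1e-6):
        raise RuntimeError(
            f"Bayes factor integration did not converge: value={value}, err={err}"
        )
    return bf


def calibrate_prior_scale(
    r: float,
    n: int,
    target_bf: float,
    alternative: str = "greater",
    bracket: tuple[float, float] = (0.05, 1.0),
) -> float:
    """Solve for the prior scale kappa at which BF10(r, n) equals ``target_bf``.

    Printed Bayes factors are computed from unrounded correlations, so no
    kappa need reproduce them exactly from rounded inputs; this helper finds
    the kappa that does, for documentation and sensitivity analysis. The BF
    is monotone decreasing in kappa for r > 0, so bisection is safe.
    """
    f = lambda k: correlation_bf(r, n, alternative, k) - target_bf
    return float(optimize.brentq(f, *bracket, xtol=1e-6))


def holm_correct(p_values, family_m: int | None = None) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sorted ascending, p_(i) is multiplied by (m - i), the running maximum is
    enforced (monotonicity) and values are capped at 1. ``family_m`` lets
    the caller declare a family larger than the number of p-values actually
    supplied (tests that were part of the declared family but excluded, e.g.
    for zero variance, still count toward the correction).
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p values must be 1-D")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    k = p.size
    m = k if family_m is None else int(family_m)
    if m < k:
        raise ValueError("declared family cannot be smaller than the tests supplied")
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(k)
    running = 0.0
    for i, idx in enumerate(order):
        running = max(running, (m - i) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def power_correlation(
    n: int,
    rho: float,
    alpha: float = 0.05,
    alternative: str = "greater",
) -> float:
    """Power of the correlation test via the Fisher-z approximation.

    One-sided positive: Phi( atanh(rho) * sqrt(n-3) - z_(1-alpha) ).
    Two-sided uses |rho| and z_(1-alpha/2) (the minor opposite-tail mass is
    neglected, as usual for this approximation).
    """
    if n < 4:
        raise ValueError("power requires n >= 4")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    delta = math.atanh(abs(rho) if alternative == "two-sided" else rho)
    crit = stats.norm.ppf(1 - (alpha / 2 if alternative == "two-sided" else alpha))
    return float(stats.norm.cdf(delta * math.sqrt(n - 3) - crit))


def spearman_brown(r_half: float) -> float:
    """Project a split-half correlation to full test length: 2r / (1 + r)."""
    if r_half <= -1.0 or r_half > 1.0:
        raise ValueError("split-half correlation must lie in (-1, 1]")
    return 2.0 * r_half / (1.0 + r_half)


def permutation_pvalue(observed: float, null_values) -> float:
    """One-sided permutation p-value with the add-one convention.

    p = (1 + #{null >= observed}) / (1 + n_permutations).
    """
    null_values = np.asarray(null_values, dtype=float)
    return float((1 + np.sum(null_values >= observed)) / (1 + null_values.size))
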