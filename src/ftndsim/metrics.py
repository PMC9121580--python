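"""Monte Carlo performance measures and the power-based sample sizes.

Per replication the estimand is either the mean total FTND score or the
slope of the total score regressed on "Is smoking allowed in your home?".
Bias is ``theta_hat - theta`` against the same replication's pre-missingness
value; percent bias divides by theta.  Precision is summarised as the
percent bias of the model-based SE against the empirical SE (the SD of the
estimates over the cell's replications), and all replication-level measures
are summarised by their mean and a 95% Monte Carlo interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError, UndefinedEstimateError

ESTIMANDS = ("mean_ftnd", "regression_coefficient")
#: |theta| below this guard leaves percent bias undefined for a replication
PERCENT_BIAS_GUARD = 1e-8
CLINICAL_BIAS_POINTS = 1.0


@dataclass(frozen=True)
class Estimate:
    """One replication's estimate: value, model-based SE and subjects used."""

    estimand: str
    value: float
    model_se: float
    n_used: int


@dataclass(frozen=True)
class TruthPair:
    """The pre-missingness value of an estimand from the same dataset."""

    estimand: str
    value: float


def mean_and_se(totals: np.ndarray) -> Estimate:
    """Mean of the non-missing totals with SE = SD(n-1) / sqrt(n_used)."""
    totals = np.asarray(totals, dtype=float)
    usable = totals[~np.isnan(totals)]
    if usable.size < 2:
        raise UndefinedEstimateError("fewer than 2 non-missing totals")
    return Estimate(
        "mean_ftnd",
        float(usable.mean()),
        float(usable.std(ddof=1) / math.sqrt(usable.size)),
        int(usable.size),
    )


def ols_simple(totals: np.ndarray, x: np.ndarray) -> Estimate:
    """OLS slope (with intercept) of the totals on a covariate.

    Fit on subjects with non-missing totals; the SE is the classical OLS
    slope standard error.
    """
    totals = np.asarray(totals, dtype=float)
    x = np.asarray(x, dtype=float)
    keep = ~np.isnan(totals)
    y, xv = totals[keep], x[keep]
    if y.size < 3:
        raise UndefinedEstimateError("fewer than 3 non-missing totals")
    if np.ptp(xv) == 0:
        raise UndefinedEstimateError("covariate constant among scored subjects")
    fit = stats.linregress(xv, y)
    return Estimate("regression_coefficient", float(fit.slope), float(fit.stderr), int(y.size))


def bias_and_percent(
    estimate: Estimate, truth: TruthPair, guard: float = PERCENT_BIAS_GUARD
) -> tuple[float, float]:
    """``theta_hat - theta`` and ``100 * (theta_hat - theta) / theta``.

    Percent bias is NaN (undefined, still recorded) when |theta| <= guard.
    """
    if estimate.estimand != truth.estimand:
        raise ConfigurationError("estimate and truth refer to different estimands")
    if not np.isfinite(truth.value):
        raise ConfigurationError("truth must be finite")
    bias = estimate.value - truth.value
    percent = 100.0 * bias / truth.value if abs(truth.value) > guard else np.nan
    return bias, percent


def monte_carlo_ci(
    values: np.ndarray, method: str = "percentile", level: float = 0.95
) -> tuple[float, float]:
    """95% Monte Carlo interval of per-replication values.

    The default summarises the replication distribution by its 2.5th and
    97.5th percentiles (linear interpolation); ``method="normal"`` gives the
    normal-theory interval for the mean instead.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < 2:
        raise UndefinedEstimateError("need at least 2 finite values for a CI")
    if method == "percentile":
        tail = 100.0 * (1.0 - level) / 2.0
        lo, hi = np.percentile(vals, [tail, 100.0 - tail])
    elif method == "normal":
        z = stats.norm.ppf(0.5 + level / 2.0)
        half = z * vals.std(ddof=1) / math.sqrt(vals.size)
        lo, hi = vals.mean() - half, vals.mean() + half
    else:
        raise ConfigurationError(f"unknown CI method {method!r}")
    return float(lo), float(hi)


def se_bias_summary(
    model_ses: np.ndarray, estimates: np.ndarray, ci_method: str = "percentile"
) -> tuple[float, float, tuple[float, float]]:
    """Percent bias of the model SE against the cell's empirical SE.

    The empirical SE is the SD of the estimates over replications; each
    replication contributes ``100 * (model_se - empirical_se) /
    empirical_se``, and the mean and Monte Carlo CI of those values are
    returned together with the empirical SE itself.
    """
    ses = np.asarray(model_ses, dtype=float)
    est = np.asarray(estimates, dtype=float)
    keep = ~(np.isnan(ses) | np.isnan(est))
    ses, est = ses[keep], est[keep]
    if est.size < 2:
        raise UndefinedEstimateError("need at least 2 replications")
    empirical_se = float(est.std(ddof=1))
    if empirical_se == 0:
        raise UndefinedEstimateError("empirical SE is zero")
    percent = 100.0 * (ses - empirical_se) / empirical_se
    return empirical_se, float(percent.mean()), monte_carlo_ci(percent, ci_method)


def power_sample_size(d: float, power: float = 0.80, alpha: float = 0.05) -> int:
    """Smallest even total N for a two-sided two-sample t-test.

    Uses exact noncentral-t power with equal group sizes; the integer search
    starts from the normal-approximation solution.
    """
    if d <= 0 or not 0 < power < 1 or not 0 < alpha < 1:
        raise ConfigurationError("require d > 0 and power, alpha in (0, 1)")

    def achieved(n_per_group: int) -> float:
        df = 2 * n_per_group - 2
        if df < 1:
            return 0.0
        ncp = d * math.sqrt(n_per_group / 2.0)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))

    z = stats.norm.ppf
    n = max(2, math.ceil(2.0 * (z(1.0 - alpha / 2.0) + z(power)) ** 2 / d**2))
    while achieved(n) < power:
        n += 1
    while n > 2 and achieved(n - 1) >= power:
        n -= 1
    return 2 * n


def flag_clinical_bias(summary, threshold: float = CLINICAL_BIAS_POINTS):
    """Mark mean-FTND rows whose |mean bias| reaches the clinical threshold.

    One point on the 0-10 scale can move a smoker between dependence
    categories, so it is treated as the clinically important bias level.
    Returns a copy of the summary table with a ``clinically_important``
    column (NA for other estimands).
    """
    out = summary.copy()
    is_mean = out["estimand"] == "mean_ftnd"
    flags = np.abs(out["mean_bias"]) >= threshold
    out["clinically_important"] = np.where(is_mean, flags, None)
    return out


def summarize_replications(
    theta_hat: np.ndarray,
    model_se: np.ndarray,
    bias: np.ndarray,
    percent_bias: np.ndarray,
    ci_method: str = "percentile",
) -> dict:
    """Aggregate one cell x method x estimand block of replication records."""
    theta_hat = np.asarray(theta_hat, dtype=float)
    defined = ~np.isnan(theta_hat)
    out = {
        "n_replications": int(theta_hat.size),
        "n_undefined": int((~defined).sum()),
    }
    if defined.sum() < 2:
        for key in (
            "mean_bias",
            "mean_percent_bias",
            "percent_bias_ci_low",
            "percent_bias_ci_high",
            "empirical_se",
            "mean_model_se",
            "mean_percent_se_bias",
            "se_bias_ci_low",
            "se_bias_ci_high",
        ):
            out[key] = np.nan
        return out
    bias = np.asarray(bias, dtype=float)[defined]
    pct = np.asarray(percent_bias, dtype=float)[defined]
    ses = np.asarray(model_se, dtype=float)[defined]
    out["mean_bias"] = float(np.mean(bias))
    out["mean_percent_bias"] = float(np.nanmean(pct)) if np.any(~np.isnan(pct)) else np.nan
    try:
        lo, hi = monte_carlo_ci(pct, ci_method)
    except UndefinedEstimateError:
        lo = hi = np.nan
    out["percent_bias_ci_low"], out["percent_bias_ci_high"] = lo, hi
    try:
        emp, mean_pct_se, (se_lo, se_hi) = se_bias_summary(
            ses, theta_hat[defined], ci_method
        )
    except UndefinedEstimateError:
        emp = mean_pct_se = se_lo = se_hi = np.nan
    out["empirical_se"] = emp
    out["mean_model_se"] = float(np.nanmean(ses))
    out["mean_percent_se_bias"] = mean_pct_se
    out["se_bias_ci_low"], out["se_bias_ci_high"] = se_lo, se_hi
    return out
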