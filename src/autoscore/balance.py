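"""Propensity scores, matching weights, and covariate balance diagnostics.

Group membership (high = 1, low = 0) is modeled by logistic regression on
the clinical confounders; categorical covariates are expanded to indicator
variables with the first level as reference. The matching weights (MW)
emulate 1:1 pair matching by weighting:

    w = min(e, 1 - e) / e        for high-group samples,
    w = min(e, 1 - e) / (1 - e)  for low-group samples,

so a sample whose group is on the minority side of its propensity gets
weight exactly 1. Balance is assessed with the standardized difference

    d = (mean_high - mean_low) / sqrt((var_high + var_low) / 2),

weighted after MW, with |d| < 0.1 as the balance criterion; a categorical
covariate reports the maximum |d| over its indicator levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

logger = logging.getLogger("autoscore")

PROPENSITY_CLIP = 1e-6

#: default confounder list for the tumor-cohort analysis
DEFAULT_COVARIATES = ("age", "gender", "purity", "race", "histological_type", "stage")


@dataclass
class BalanceResult:
    """Propensities, MW weights and before/after balance diagnostics."""

    propensity: pd.Series
    weight: pd.Series
    std_diff_before: pd.Series
    std_diff_after: pd.Series
    balanced: bool
    threshold: float = 0.1


def _design_matrix(samples: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    missing = [c for c in covariates if c not in samples.columns]
    if missing:
        raise ValueError(f"covariates absent from sample table: {missing}")
    cov = samples[list(covariates)].copy()
    keep = []
    for c in covariates:
        if cov[c].nunique(dropna=True) < 2:
            logger.warning("covariate %r has a single level; dropped from propensity model", c)
        else:
            keep.append(c)
    cov = cov[keep]
    numeric = cov.select_dtypes(include=[np.number])
    categorical = cov.drop(columns=numeric.columns)
    parts = [numeric.astype(float)]
    if categorical.shape[1]:
        parts.append(
            pd.get_dummies(categorical.astype("object"), drop_first=True, dtype=float)
        )
    X = pd.concat(parts, axis=1)
    return X


def fit_propensity(
    samples: pd.DataFrame,
    group: pd.Series,
    covariates: list[str] | None = None,
) -> tuple[pd.Series, sm.Logit]:
    """Fit e(x) = P(high | covariates) by logistic regression.

    Returns fitted probabilities clipped to [1e-6, 1 - 1e-6] and the
    statsmodels results object (for coefficients and standard errors).
    Samples with any missing covariate are dropped complete-case with a
    logged count.
    """
    covariates = list(covariates or [c for c in DEFAULT_COVARIATES if c in samples.columns])
    y = group.reindex(samples.index)
    mask = y.isin(["high", "low"])
    samples = samples.loc[mask]
    y = (y.loc[mask] == "high").astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need >= 2 samples in each of the high and low groups")
    X = _design_matrix(samples, covariates)
    complete = X.notna().all(axis=1)
    if (~complete).any():
        logger.warning("fit_propensity: dropped %d samples with missing covariates", int((~complete).sum()))
        X, y = X.loc[complete], y.loc[complete]
    Xc = sm.add_constant(X, has_constant="add")
    try:
        import warnings

        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and raised as a ValueError below
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError or numerical failure
        raise ValueError(
            f"propensity model failed ({exc}); consider removing a separating covariate"
        ) from exc
    raw = res.predict(Xc)
    if np.max(np.abs(raw - y)) < 1e-8:
        raise ValueError("perfect separation detected; consider removing a separating covariate")
    e = pd.Series(np.clip(raw, PROPENSITY_CLIP, 1 - PROPENSITY_CLIP), index=X.index)
    if (raw <= PROPENSITY_CLIP).any() or (raw >= 1 - PROPENSITY_CLIP).any():
        logger.warning("fit_propensity: propensity clipping active for extreme samples")
    return e, res


def matching_weights(e: pd.Series, group: pd.Series) -> pd.Series:
    """MW weights: min(e, 1-e)/e for high samples, min(e, 1-e)/(1-e) for low."""
    e = pd.Series(e)
    g = group.reindex(e.index)
    if ((e <= 0) | (e >= 1)).any():
        raise ValueError("propensities must lie strictly in (0, 1)")
    bad = set(g.unique()) - {"high", "low"}
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}")
    m = np.minimum(e, 1 - e)
    w = np.where(g == "high", m / e, m / (1 - e))
    return pd.Series(w, index=e.index)


def _weighted_mean_var(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    sw = w.sum()
    if sw <= 0:
        raise ValueError("total weight must be positive")
    m = float(np.sum(w * x) / sw)
    denom = sw - np.sum(w**2) / sw  # reliability-weights unbiased denominator
    if denom <= 0:
        return m, 0.0
    v = float(np.sum(w * (x - m) ** 2) / denom)
    return m, v


def standardized_difference(
    values: pd.Series,
    group: pd.Series,
    weights: pd.Series | None = None,
) -> float:
    """Standardized mean difference between high and low groups.

    Numeric covariates use the pooled-variance formula; a categorical
    covariate is expanded to level indicators and reports max |d| (signed
    by the maximizing level). Zero pooled variance with unequal means
    yields signed infinity with a warning.
    """
    g = group.reindex(values.index)
    mask = g.isin(["high", "low"]) & values.notna()
    values, g = values.loc[mask], g.loc[mask]
    if weights is not None:
        w = weights.reindex(values.index).to_numpy(dtype=float)
    else:
        w = np.ones(len(values))
    if (g == "high").sum() == 0 or (g == "low").sum() == 0:
        raise ValueError("both groups must be non-empty")

    if not pd.api.types.is_numeric_dtype(values):
        dummies = pd.get_dummies(values.astype("object"), dtype=float)
        ds = [
            standardized_difference(dummies[c], g, weights=pd.Series(w, index=values.index))
            for c in dummies.columns
        ]
        return ds[int(np.argmax([abs(d) for d in ds]))]

    x = values.to_numpy(dtype=float)
    hi, lo = (g == "high").to_numpy(), (g == "low").to_numpy()
    mh, vh = _weighted_mean_var(x[hi], w[hi])
    ml, vl = _weighted_mean_var(x[lo], w[lo])
    pooled = (vh + vl) / 2.0
    if pooled == 0:
        if mh == ml:
            return 0.0
        logger.warning("standardized_difference: zero pooled variance with unequal means")
        return float(np.sign(mh - ml) * np.inf)
    return float((mh - ml) / np.sqrt(pooled))


def balance_table(
    samples: pd.DataFrame,
    group: pd.Series,
    weights: pd.Series,
    covariates: list[str],
) -> pd.DataFrame:
    """Per-covariate standardized differences before and after weighting."""
    rows = []
    for c in covariates:
        rows.append(
            {
                "covariate": c,
                "d_before": standardized_difference(samples[c], group),
                "d_after": standardized_difference(samples[c], group, weights=weights),
            }
        )
    return pd.DataFrame(rows)


def check_balance(result: BalanceResult, threshold: float = 0.1) -> bool:
    """True iff every post-weighting |d| is below the threshold."""
    return bool((result.std_diff_after.abs() < threshold).all())


class PropensityBalancer(BaseEstimator):
    """Estimator computing MW weights and balance diagnostics.

    Parameters
    ----------
    covariates : list of str or None
        Confounders to balance; None uses every default confounder present.
    threshold : float, default 0.1
        |standardized difference| bound declaring a covariate balanced.

    Attributes (after ``fit(X=sample table, y=group labels)``)
    ----------
    propensity_ : Series, weights_ : Series
    std_diff_before_, std_diff_after_ : Series per covariate
    balanced_ : bool
    model_result_ : statsmodels results (coefficients, SEs)
    """

    def __init__(self, covariates: list[str] | None = None, threshold: float = 0.1):
        self.covariates = covariates
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y: pd.Series) -> "PropensityBalancer":
        covs = list(self.covariates or [c for c in DEFAULT_COVARIATES if c in X.columns])
        y = pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y
        e, res = fit_propensity(X, y, covs)
        w = matching_weights(e, y)
        table = balance_table(X.loc[e.index], y, w, covs)
        self.propensity_ = e
        self.weights_ = w
        self.model_result_ = res
        self.std_diff_before_ = table.set_index("covariate")["d_before"]
        self.std_diff_after_ = table.set_index("covariate")["d_after"]
        self.balanced_ = bool(self.std_diff_after_.abs().max() < self.threshold)
        return self

    def result(self) -> BalanceResult:
        if not hasattr(self, "weights_"):
            raise ValueError("PropensityBalancer is not fitted")
        return BalanceResult(
            propensity=self.propensity_,
            weight=self.weights_,
            std_diff_before=self.std_diff_before_,
            std_diff_after=self.std_diff_after_,
            balanced=self.balanced_,
            threshold=self.threshold,
        )
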