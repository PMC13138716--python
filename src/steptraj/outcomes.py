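"""Weight-loss outcome definition, tabulation and logistic modelling.

The study outcome is a relative weight loss of at least 3% between the two
checkups.  Odds ratios for each trajectory class against the FLAT reference
come from a multivariable logistic regression (maximum likelihood via
iteratively reweighted least squares) adjusted for age, sex, mean daily
steps (per 1,000), smoking and medication use; confidence intervals and
p-values use the Wald statistic.  A sensitivity variant refits on the
medication-free subset with the medication term dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z975 = 1.959963984540054

DEFAULT_COVARIATES = ("age", "sex", "mean_steps_k", "smoking", "medication")

__all__ = [
    "EstimationError",
    "OutcomeModelResult",
    "weight_loss_flag",
    "summarize_outcomes",
    "fit_logistic",
    "sensitivity_no_medication",
]


class EstimationError(RuntimeError):
    """Logistic fit failed (non-convergence or separation)."""


@dataclass
class OutcomeModelResult:
    """Per-term estimates of the weight-loss logistic model.

    ``table`` has one row per term: coef, se, odds_ratio, ci_low, ci_high,
    p_value (Wald, two-sided, 95% normal-quantile intervals).
    """

    table: pd.DataFrame
    n: int
    converged: bool
    loglik: float

    def term(self, name: str) -> pd.Series:
        return self.table.set_index("term").loc[name]


def weight_loss_flag(pre_weight, post_weight, threshold: float = 0.03):
    """1 iff relative loss (pre - post)/pre >= threshold (inclusive)."""
    pre = np.asarray(pre_weight, dtype=float)
    post = np.asarray(post_weight, dtype=float)
    if (pre <= 0).any():
        raise ValueError("pre_weight must be positive")
    flag = ((pre - post) / pre >= threshold).astype(int)
    return int(flag) if flag.ndim == 0 else flag


def _pct_half_up(count: int, n: int) -> float:
    if n == 0:
        return float("nan")
    raw = Decimal(100 * count) / Decimal(n)
    return float(raw.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize_outcomes(rows: pd.DataFrame, class_col: str = "class_label",
                       outcome_col: str = "outcome") -> pd.DataFrame:
    """Per-class and overall n, >=3%-loss count, and one-decimal percentage."""
    if rows.empty:
        raise ValueError("cannot summarize an empty cohort")
    out = []
    for label, grp in rows.groupby(class_col, sort=True):
        n = len(grp)
        k = int(grp[outcome_col].sum())
        out.append({"class_label": label, "n": n, "n_loss": k,
                    "pct_loss": _pct_half_up(k, n)})
    n = len(rows)
    k = int(rows[outcome_col].sum())
    out.append({"class_label": "Overall", "n": n, "n_loss": k,
                "pct_loss": _pct_half_up(k, n)})
    return pd.DataFrame(out)


def _design(rows: pd.DataFrame, class_col: str, reference: str,
            covariates) -> tuple:
    labels = sorted(set(rows[class_col]) - {reference})
    cols = {"const": np.ones(len(rows))}
    for lab in labels:
        cols[f"class[{lab}]"] = (rows[class_col] == lab).to_numpy(dtype=float)
    for cov in covariates:
        cols[cov] = rows[cov].to_numpy(dtype=float)
    return pd.DataFrame(cols, index=rows.index)


def fit_logistic(rows: pd.DataFrame, class_col: str = "class_label",
                 reference: str = "FLAT",
                 covariates=DEFAULT_COVARIATES,
                 outcome_col: str = "outcome") -> OutcomeModelResult:
    """Adjusted odds ratios of >=3% weight loss by trajectory class.

    Classes are dummy-coded against ``reference``; covariate columns are
    used as given (mean steps should already be per 1,000).  Complete-case:
    rows with missing values in any used column are dropped.
    """
    used = [outcome_col, class_col] + list(covariates)
    data = rows[used].dropna()
    y = data[outcome_col].to_numpy(dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise EstimationError("outcome has no events or no non-events")
    X = _design(data, class_col, reference, covariates)
    try:
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation raises inside statsmodels
        raise EstimationError(f"logistic fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", False):
        worst = X.columns[np.argmax(np.abs(res.params))]
        raise EstimationError(f"logistic fit did not converge (term {worst})")
    se = np.asarray(res.bse, dtype=float)
    if not np.isfinite(se).all() or (se > 1e3).any():
        worst = X.columns[int(np.argmax(se))]
        raise EstimationError(f"separation suspected for term {worst}")
    coef = np.asarray(res.params, dtype=float)
    table = pd.DataFrame({
        "term": X.columns,
        "coef": coef,
        "se": se,
        "odds_ratio": np.exp(coef),
        "ci_low": np.exp(coef - Z975 * se),
        "ci_high": np.exp(coef + Z975 * se),
        "p_value": 2.0 * (1.0 - _norm_cdf(np.abs(coef / se))),
    })
    return OutcomeModelResult(table=table, n=len(data),
                              converged=True, loglik=float(res.llf))


def _norm_cdf(x):
    from scipy.stats import norm

    return norm.cdf(x)


def sensitivity_no_medication(rows: pd.DataFrame, **kwargs) -> OutcomeModelResult:
    """Refit on medication-free participants, dropping the medication term."""
    sub = rows[rows["medication"] == 0]
    if sub.empty:
        raise EstimationError("no medication-free participants in the cohort")
    covariates = kwargs.pop("covariates", DEFAULT_COVARIATES)
    covariates = tuple(c for c in covariates if c != "medication")
    return fit_logistic(sub, covariates=covariates, **kwargs)
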