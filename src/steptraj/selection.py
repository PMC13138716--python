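"""Class-number selection and trajectory archetype labeling.

A candidate number of classes G is *admissible* when every fitted class
holds at least 5% of participants by modal assignment and every class's
mean posterior probability among its assigned members is at least 0.90.
Among admissible candidates the model with the smallest BIC wins; an exact
BIC tie goes to the smaller G (parsimony).

Fitted mean curves receive a human-readable archetype label from their
shape over the study window: FLAT when the curve's relative range is small,
otherwise UP / DOWN / UP_DOWN / DOWN_UP from the signs of the endpoint
slopes.  DOWN_UP never occurred in the motivating cohort but the rule must
cover every quadratic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lcmm import LcmmFit, SeriesSet, class_mean, fit_lcmm

ARCHETYPE_LABELS = ("UP", "DOWN", "UP_DOWN", "DOWN_UP", "FLAT")

__all__ = [
    "SelectionCriteria",
    "SelectionError",
    "SelectionResult",
    "admissible",
    "select_G",
    "label_archetype",
    "label_classes",
]


@dataclass(frozen=True)
class SelectionCriteria:
    min_class_share: float = 0.05
    min_mean_posterior: float = 0.90
    g_min: int = 1
    g_max: int = 5

    def __post_init__(self):
        if not 0 < self.min_class_share < 1:
            raise ValueError("min_class_share must be in (0, 1)")
        if not 0 < self.min_mean_posterior <= 1:
            raise ValueError("min_mean_posterior must be in (0, 1]")
        if not 1 <= self.g_min <= self.g_max:
            raise ValueError("need 1 <= g_min <= g_max")


class SelectionError(RuntimeError):
    """No candidate G satisfied the admissibility conditions."""

    def __init__(self, message, table=None):
        super().__init__(message)
        self.table = table


@dataclass
class SelectionResult:
    fit: LcmmFit
    n_classes: int
    table: pd.DataFrame


def admissible(fit: LcmmFit, criteria: SelectionCriteria) -> bool:
    """True iff every class meets the share and mean-posterior conditions."""
    shares = fit.class_shares()
    if (shares < criteria.min_class_share).any():
        return False
    mp = np.asarray(fit.mean_posterior, dtype=float)
    if np.isnan(mp).any() or (mp < criteria.min_mean_posterior).any():
        return False
    return True


def select_G(series, criteria: SelectionCriteria = SelectionCriteria(),
             seed: int = 0, **fit_kwargs) -> SelectionResult:
    """Fit every G in the candidate range and pick the admissible minimum-BIC
    model; the returned table reports every candidate."""
    if not isinstance(series, SeriesSet):
        series = SeriesSet.from_frame(series)
    rows = []
    best = None
    for g in range(criteria.g_min, criteria.g_max + 1):
        child_seed = int(np.random.SeedSequence(
            [int(seed), g]).generate_state(1)[0] % 2**31)
        fit = fit_lcmm(series, g, seed=child_seed, **fit_kwargs)
        ok = admissible(fit, criteria)
        rows.append({
            "G": g,
            "loglik": fit.loglik,
            "bic": fit.bic,
            "min_share": float(fit.class_shares().min()),
            "min_mean_posterior": float(np.nanmin(fit.mean_posterior))
            if not np.isnan(fit.mean_posterior).all() else float("nan"),
            "admissible": ok,
            "converged": fit.converged,
        })
        if ok and (best is None or fit.bic < best.bic):
            best = fit
    table = pd.DataFrame(rows)
    if best is None:
        raise SelectionError("no admissible class number in the search range",
                             table=table)
    return SelectionResult(fit=best, n_classes=best.n_classes, table=table)


def label_archetype(beta_g, T: int, flat_tolerance: float = 0.10) -> str:
    """Archetype of one quadratic mean curve over weeks 1..T.

    FLAT when (max - min) / mean level < ``flat_tolerance``; otherwise the
    endpoint slopes s(1) and s(T) of the quadratic decide the trend.
    """
    if T < 2:
        raise ValueError("need T >= 2 to label a trajectory")
    b0, b1, b2 = (float(x) for x in np.asarray(beta_g, dtype=float))
    grid = np.arange(1.0, T + 1.0)
    values = class_mean((b0, b1, b2), grid)
    level = abs(float(np.mean(values)))
    rng = float(values.max() - values.min())
    if level > 0 and rng / level < flat_tolerance:
        return "FLAT"
    s_start = b1 + 2.0 * b2 * 1.0
    s_end = b1 + 2.0 * b2 * T
    if s_start >= 0 and s_end >= 0:
        return "UP"
    if s_start <= 0 and s_end <= 0:
        return "DOWN"
    if s_start > 0 > s_end:
        return "UP_DOWN"
    return "DOWN_UP"


def label_classes(fit: LcmmFit, T: int = 52,
                  flat_tolerance: float = 0.10) -> list:
    """One archetype label per fitted class, in the fit's class order.

    ``T`` is the study window in weeks (default one year).
    """
    return [label_archetype(fit.params.beta[g], T, flat_tolerance)
            for g in range(fit.n_classes)]
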