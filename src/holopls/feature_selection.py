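"""Stepwise linear-regression feature selection with partial-F entry/removal.

Forward step: among excluded variables, the one with the smallest
partial-F p-value enters if that p-value is <= p_enter.  Backward step:
any included variable whose partial-F p-value is >= p_remove leaves
(worst first).  The procedure iterates to a fixed point; ties are broken
by column order, making the trace fully deterministic.

The response is regressed with ordinary linear regression even when it is
binary — this mirrors the protocol being reproduced and is deliberately
not "upgraded" to logistic regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["StepwiseStep", "StepwiseTrace", "stepwise_select"]


@dataclass(frozen=True)
class StepwiseStep:
    action: str  # "enter" | "remove"
    variable: str
    r_squared: float
    adjusted_r_squared: float


@dataclass
class StepwiseTrace:
    steps: list[StepwiseStep] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "iteration": i + 1,
                "action": s.action,
                "variable": s.variable,
                "R2": s.r_squared,
                "adjusted_R2": s.adjusted_r_squared,
            }
            for i, s in enumerate(self.steps)
        ]


def _fit_rss(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of OLS with intercept."""
    A = np.column_stack([np.ones(len(y)), X]) if X.shape[1] else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    return float(resid @ resid)


def _r2_stats(X: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n, p = X.shape
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = _fit_rss(X, y)
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    denom = n - p - 1
    adj = 1.0 - (1.0 - r2) * (n - 1) / denom if denom > 0 else float("nan")
    return r2, adj


def _partial_f_pvalue(X_reduced: np.ndarray, X_full: np.ndarray, y: np.ndarray) -> float:
    """p-value of the F-test comparing the full model against reduced (1 df)."""
    n = len(y)
    p_full = X_full.shape[1]
    df2 = n - p_full - 1
    if df2 <= 0:
        return float("nan")
    rss_r = _fit_rss(X_reduced, y)
    rss_f = _fit_rss(X_full, y)
    if rss_f <= 0:
        return 0.0
    f = (rss_r - rss_f) / (rss_f / df2)
    f = max(f, 0.0)
    return float(stats.f.sf(f, 1, df2))


def stepwise_select(
    X: np.ndarray,
    y: np.ndarray,
    columns: list[str] | None = None,
    p_enter: float = 0.02,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> tuple[list[str], StepwiseTrace]:
    """Stepwise selection over named columns of X against response y.

    Returns the selected variable names (in final model order) and the
    full enter/remove trace with per-step R² and adjusted R².
    """
    if not p_enter < p_remove:
        raise ValueError("require p_enter < p_remove")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("X must be (n, p) with n matching y")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    n, p = X.shape
    if columns is None:
        columns = [f"x{j}" for j in range(p)]
    if len(columns) != p:
        raise ValueError("columns must name every predictor")

    included: list[int] = []
    trace = StepwiseTrace()

    for _ in range(max_steps):
        changed = False

        # forward: candidate with the smallest partial-F p-value
        if n > len(included) + 2:
            best_j, best_p = None, None
            X_cur = X[:, included]
            for j in range(p):
                if j in included:
                    continue
                pval = _partial_f_pvalue(X_cur, X[:, included + [j]], y)
                if np.isnan(pval):
                    continue
                if best_p is None or pval < best_p:
                    best_j, best_p = j, pval
            if best_j is not None and best_p <= p_enter:
                included.append(best_j)
                r2, adj = _r2_stats(X[:, included], y)
                trace.steps.append(StepwiseStep("enter", columns[best_j], r2, adj))
                changed = True
        else:
            logger.info("stepwise: n too small to enter further variables (n=%d, p=%d)", n, len(included))

        # backward: remove worst included variable with p >= p_remove
        while len(included) > 0:
            worst_j, worst_p = None, None
            for j in included:
                reduced = [i for i in included if i != j]
                pval = _partial_f_pvalue(X[:, reduced], X[:, included], y)
                if np.isnan(pval):
                    continue
                if worst_p is None or pval > worst_p:
                    worst_j, worst_p = j, pval
            if worst_j is None or worst_p < p_remove:
                break
            included.remove(worst_j)
            r2, adj = _r2_stats(X[:, included], y)
            trace.steps.append(StepwiseStep("remove", columns[worst_j], r2, adj))
            changed = True

        if not changed:
            break
    else:
        logger.warning("stepwise: max_steps reached before fixed point")

    return [columns[j] for j in included], trace
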