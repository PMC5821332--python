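"""Ecological inference stack: rank correlation, normality gate, and
hierarchical (block-entry) regression with R²-change F tests.

The analysis is ecological — units are jurisdictions, not individuals —
and mirrors the two-step design used for state-level maternity outcomes:

* Spearman's rho between integration scores / midwifery access measures
  and outcome rates (rank-based because outcome rates at the state level
  are typically non-normal, while composite scores tend to pass a
  Shapiro–Wilk gate);
* hierarchical OLS in which % non-Hispanic Black births enters in block 1
  and the integration score in block 2, the increment in R² tested with
  the F-change statistic.

Spearman's rho is computed by hand (Pearson correlation of average ranks,
t-approximation p-value) so its behaviour — tie handling, p-value
convention, exact permutation option — is fully specified; scipy supplies
only distribution tail probabilities and the Shapiro–Wilk statistic.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .profiles import MissScore
from .workforce import (
    OUTCOME_NAMES,
    StateVitalRecord,
    access_proportions,
)

__all__ = [
    "CorrelationResult",
    "HierarchicalFit",
    "AnalysisError",
    "average_ranks",
    "spearman_rho",
    "normality_check",
    "correlation_table",
    "ols_fit",
    "hierarchical_r2_change",
    "residual_diagnostics",
    "EXPOSURES",
]

#: Exposure columns of the correlation table (mirror the published layout):
#: composite score, % of births midwife-attended in hospital, % midwife-led
#: in community settings.
EXPOSURES = ("miss_total", "pct_midwife_hospital", "pct_midwife_community")


class AnalysisError(Exception):
    """Undefined or ill-posed statistical computation."""


@dataclass
class CorrelationResult:
    label_x: str
    label_y: str
    n: int
    rho: float
    p_two_tailed: float
    sig_flag: str  # "ns", "p<0.05", "p<0.01"


@dataclass
class HierarchicalFit:
    """Block-entry regression result.

    ``r2_block1`` is the variance explained by the block-1 predictors
    alone; ``delta_r2`` the increment when block 2 enters; ``f_change``
    and ``p_change`` test that increment on F(q, n - p_full - 1).
    """

    outcome: str
    n: int
    r2_block1: float
    r2_total: float
    delta_r2: float
    f_change: float
    p_change: float
    coefficients: dict[str, float]
    std_residuals: np.ndarray
    fitted: np.ndarray


def _sig_flag(p: float) -> str:
    if p < 0.01:
        return "p<0.01"
    if p < 0.05:
        return "p<0.05"
    return "ns"


def average_ranks(x: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with ties sharing the mean of the ranks they span."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise AnalysisError("cannot rank an empty vector")
    order = np.argsort(x, kind="stable")
    ranks = np.empty(x.size, dtype=float)
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0  # mean of ranks i+1..j+1
        i = j + 1
    return ranks


def _rank_pearson(rx: np.ndarray, ry: np.ndarray) -> float:
    dx = rx - rx.mean()
    dy = ry - ry.mean()
    den = math.sqrt(float(dx @ dx) * float(dy @ dy))
    if den == 0.0:
        raise AnalysisError("correlation undefined for a constant vector")
    return float(dx @ dy) / den


def spearman_rho(
    x: Sequence[float],
    y: Sequence[float],
    *,
    label_x: str = "x",
    label_y: str = "y",
    method: str = "t",
) -> CorrelationResult:
    """Spearman's rho with a two-tailed p-value.

    rho is the Pearson correlation of average ranks. ``method='t'``
    (default) uses t = rho * sqrt((n-2)/(1-rho²)) on n-2 df; rho = ±1
    yields p = 0. ``method='exact'`` enumerates all permutations of one
    margin (n ≤ 8) for an exact two-tailed permutation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be equal-length 1-d vectors")
    n = x.size
    if n < 3:
        raise AnalysisError(f"need n >= 3 pairs, got {n}")
    rx, ry = average_ranks(x), average_ranks(y)
    rho = _rank_pearson(rx, ry)
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    elif method == "exact":
        if n > 8:
            raise AnalysisError("exact permutation p-value limited to n <= 8")
        observed = abs(rho)
        hits = total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rank_pearson(rx, np.array(perm))) >= observed - 1e-12:
                hits += 1
        p = hits / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(
        label_x=label_x, label_y=label_y, n=n, rho=rho,
        p_two_tailed=float(p), sig_flag=_sig_flag(float(p)),
    )


def normality_check(x: Sequence[float], alpha: float = 0.05):
    """Shapiro–Wilk test; returns ``(W, p, is_normal)``.

    ``is_normal`` is True when p > alpha, the gate used to decide whether
    a variable may be treated as normally distributed (composite scores
    usually pass; state-level outcome rates usually do not, motivating
    rank correlation).
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= x.size <= 5000:
        raise AnalysisError(f"Shapiro–Wilk needs 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise AnalysisError("Shapiro–Wilk undefined for a constant vector")
    w, p = stats.shapiro(x)
    return float(w), float(p), bool(p > alpha)


# ---------------------------------------------------------------------------
# correlation table

def _exposure_values(
    score: MissScore, record: StateVitalRecord
) -> dict[str, float]:
    props = access_proportions(record)
    return {
        "miss_total": score.total,
        "pct_midwife_hospital": 100.0 * sum(
            props[(g, "hospital")] for g in ("CNM_CM", "CPM_other")
        ),
        "pct_midwife_community": 100.0 * props[("all_midwife", "community")],
    }


def correlation_table(
    scores: Iterable[MissScore],
    records: Iterable[StateVitalRecord],
    outcomes: Sequence[str] = OUTCOME_NAMES,
) -> list[CorrelationResult]:
    """One Spearman correlation per (exposure x outcome) cell.

    Scores and vital records are joined on jurisdiction;
    pairwise-complete deletion applies per cell (NaN outcome rates are
    dropped and the per-cell n recorded). Cells with fewer than 3 complete
    pairs raise, naming the cell.
    """
    by_state = {r.jurisdiction: r for r in records}
    joined = [(s, by_state[s.jurisdiction]) for s in scores
              if s.jurisdiction in by_state]
    if len(joined) < 3:
        raise AnalysisError(
            f"join yields only {len(joined)} jurisdictions; need >= 3"
        )
    expo = {
        name: np.array([_exposure_values(s, r)[name] for s, r in joined])
        for name in EXPOSURES
    }
    results = []
    for name in EXPOSURES:
        for outcome in outcomes:
            yvals = np.array(
                [r.outcomes.get(outcome, math.nan) for _, r in joined]
            )
            keep = ~np.isnan(yvals) & ~np.isnan(expo[name])
            if keep.sum() < 3:
                raise AnalysisError(
                    f"cell ({name}, {outcome}): only {int(keep.sum())} "
                    "complete pairs"
                )
            results.append(
                spearman_rho(
                    expo[name][keep], yvals[keep],
                    label_x=name, label_y=outcome,
                )
            )
    return results


# ---------------------------------------------------------------------------
# regression

def ols_fit(design: np.ndarray, y: np.ndarray):
    """Least squares on an explicit design matrix (intercept included by
    the caller). Returns ``(coefficients, r2, residuals)``.

    Rank-deficient designs raise rather than silently pseudo-inverting.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise AnalysisError("design must be n x p with y of length n")
    n, p = X.shape
    if n <= p:
        raise AnalysisError(f"need n > p, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        raise AnalysisError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    ss_res = float(resid @ resid)
    dy = y - y.mean()
    ss_tot = float(dy @ dy)
    if ss_tot == 0.0:
        raise AnalysisError("R² undefined: response is constant")
    r2 = 1.0 - ss_res / ss_tot
    return beta, r2, resid


def _as_matrix(block, n: int) -> np.ndarray:
    b = np.asarray(block, dtype=float)
    if b.ndim == 1:
        b = b.reshape(-1, 1)
    if b.shape[0] != n:
        raise AnalysisError("block length does not match response length")
    return b


def hierarchical_r2_change(
    y: Sequence[float],
    block1,
    block2,
    *,
    outcome: str = "y",
    names1: Sequence[str] | None = None,
    names2: Sequence[str] | None = None,
) -> HierarchicalFit:
    """Two-block hierarchical OLS with the R²-change F test.

    Fits ``y ~ 1 + block1`` then ``y ~ 1 + block1 + block2``.
    With q block-2 columns and p_full total (non-intercept) predictors,

        F_change = (ΔR² / q) / ((1 − R²_total) / (n − p_full − 1))

    and p_change is its upper tail on F(q, n − p_full − 1).
    ``std_residuals`` are full-model residuals divided by their sample
    standard deviation (ddof=1).
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    b1 = _as_matrix(block1, n)
    b2 = _as_matrix(block2, n)
    q = b2.shape[1]
    p_full = b1.shape[1] + q
    intercept = np.ones((n, 1))
    X1 = np.hstack([intercept, b1])
    X2 = np.hstack([intercept, b1, b2])
    _, r2_1, _ = ols_fit(X1, y)
    if np.linalg.matrix_rank(X2) == np.linalg.matrix_rank(X1):
        # block 2 spans nothing beyond block 1 (e.g. a duplicated
        # predictor): the nested models coincide, so the increment is zero
        beta1, _, resid = ols_fit(X1, y)
        beta = np.concatenate([beta1, np.zeros(q)])
        r2_full = r2_1
    else:
        beta, r2_full, resid = ols_fit(X2, y)
    # adding predictors cannot reduce R²; guard the float epsilon case
    r2_full = max(r2_full, r2_1)
    delta = r2_full - r2_1
    df2 = n - p_full - 1
    if df2 <= 0:
        raise AnalysisError("no residual degrees of freedom for F-change")
    if r2_full >= 1.0:
        f_change = math.inf if delta > 0 else 0.0
    else:
        f_change = (delta / q) / ((1.0 - r2_full) / df2)
    p_change = float(stats.f.sf(f_change, q, df2)) if math.isfinite(
        f_change
    ) else 0.0
    if f_change == 0.0:
        p_change = 1.0
    names1 = list(names1 or [f"b1_x{i}" for i in range(b1.shape[1])])
    names2 = list(names2 or [f"b2_x{i}" for i in range(q)])
    coef = dict(zip(["intercept"] + names1 + names2, map(float, beta)))
    sd = float(resid.std(ddof=1))
    std_resid = resid / sd if sd > 0 else resid * 0.0
    return HierarchicalFit(
        outcome=outcome, n=n, r2_block1=r2_1, r2_total=r2_full,
        delta_r2=delta, f_change=float(f_change), p_change=p_change,
        coefficients=coef, std_residuals=std_resid, fitted=X2 @ beta,
    )


def residual_diagnostics(fit: HierarchicalFit, alpha: float = 0.05) -> dict:
    """Assumption checks on a fitted model.

    Returns the Shapiro–Wilk p on standardized residuals (normality), the
    Pearson correlation between standardized fitted values and
    standardized residuals (zero by OLS orthogonality when an intercept is
    present), and pass flags at ``alpha``.
    """
    resid = np.asarray(fit.std_residuals, dtype=float)
    if resid.size < 3:
        raise AnalysisError("need >= 3 residuals for diagnostics")
    _, shapiro_p, normal_ok = normality_check(resid, alpha=alpha)
    fitted = np.asarray(fit.fitted, dtype=float)
    fz = (fitted - fitted.mean())
    rz = resid - resid.mean()
    den = math.sqrt(float(fz @ fz) * float(rz @ rz))
    corr = float(fz @ rz) / den if den > 0 else 0.0
    return {
        "shapiro_p": shapiro_p,
        "residuals_normal": normal_ok,
        "fitted_residual_corr": corr,
        "linearity_ok": abs(corr) < 1e-8,
    }
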