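"""Correlation and stepwise-regression links between SOC and soil physics.

Pairwise-complete Pearson correlations describe the marginal
association of SOC with stones, texture fractions and bulk density;
forward stepwise regression with backward elimination partitions the
explainable variance into sequential R^2 increments at entry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DomainError, InsufficientDataError


@dataclass(frozen=True)
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame  #: complete pairs per cell


def pearson_matrix(table: pd.DataFrame, variables) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation matrix with two-sided p-values.

    Zero-variance variables yield NaN entries (with a warning) rather
    than an error.  The diagonal r is 1 with p = 0.
    """
    variables = list(variables)
    k = len(variables)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            a = table[variables[i]].to_numpy(float)
            b = table[variables[j]].to_numpy(float)
            ok = ~np.isnan(a) & ~np.isnan(b)
            n[i, j] = n[j, i] = int(ok.sum())
            if n[i, j] < 3:
                raise InsufficientDataError(
                    f"fewer than 3 complete pairs for "
                    f"({variables[i]}, {variables[j]})"
                )
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                continue
            a, b = a[ok], b[ok]
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"zero variance in ({variables[i]}, {variables[j]}); "
                    "correlation undefined", stacklevel=2,
                )
                continue
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(variables)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


@dataclass(frozen=True)
class StepwiseResult:
    """Forward-stepwise model summary.

    ``explained_variance`` holds the sequential R^2 increments (in %)
    of the selected variables in entry order; they sum to 100 x the
    final unadjusted R^2.
    """

    variables: tuple[str, ...]
    coefficients: dict[str, float]  #: includes "const"
    explained_variance: tuple[float, ...]
    r2: float
    adj_r2: float
    mse: float
    entry_p: tuple[float, ...]


def _fit_ols(y, x_df):
    design = sm.add_constant(x_df, has_constant="add")
    return sm.OLS(y, design, missing="drop").fit()


def stepwise_regression(
    y,
    candidates: pd.DataFrame,
    alpha_in: float = 0.05,
    alpha_out: float = 0.10,
    *,
    condition_limit: float = 1e10,
) -> StepwiseResult:
    """Forward selection with backward elimination.

    At each step the candidate with the smallest partial-F p-value
    enters if p <= alpha_in; any included variable whose p rises above
    alpha_out is then removed; iteration stops when no change occurs.
    Candidates that would make the design numerically collinear
    (condition number above ``condition_limit``) are skipped with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    if not 0 < alpha_in <= 1 or not 0 < alpha_out <= 1:
        raise DomainError("alpha_in and alpha_out must lie in (0, 1]")
    names = list(candidates.columns)
    if len(y) <= len(names) + 2:
        raise InsufficientDataError(
            f"need n > p + 2 (n={len(y)}, p={len(names)})"
        )

    included: list[str] = []
    entry_p: dict[str, float] = {}
    while True:
        changed = False
        # forward step
        best_name, best_p = None, None
        for name in names:
            if name in included:
                continue
            trial = candidates[included + [name]]
            design = sm.add_constant(trial, has_constant="add")
            cond = np.linalg.cond(np.asarray(design, dtype=float))
            if cond > condition_limit:
                warnings.warn(
                    f"candidate {name!r} skipped: collinear design "
                    f"(condition number {cond:.2g})", stacklevel=2,
                )
                continue
            fit = _fit_ols(y, trial)
            p_val = float(fit.pvalues[name])
            if best_p is None or p_val < best_p:
                best_name, best_p = name, p_val
        if best_name is not None and best_p <= alpha_in:
            included.append(best_name)
            entry_p[best_name] = best_p
            changed = True
        # backward step
        while included:
            fit = _fit_ols(y, candidates[included])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > alpha_out:
                included.remove(worst)
                changed = True
            else:
                break
        if not changed:
            break

    if included:
        final = _fit_ols(y, candidates[included])
        coef = {k: float(v) for k, v in final.params.items()}
        r2, adj_r2 = float(final.rsquared), float(final.rsquared_adj)
        mse = float(final.mse_resid)
    else:
        coef = {"const": float(np.nanmean(y))}
        r2 = adj_r2 = 0.0
        mse = float(np.nanvar(y, ddof=1))

    # sequential R^2 increments of the final variables, in entry order
    increments = []
    prev_r2 = 0.0
    for i in range(1, len(included) + 1):
        fit_i = _fit_ols(y, candidates[included[:i]])
        increments.append(100.0 * (float(fit_i.rsquared) - prev_r2))
        prev_r2 = float(fit_i.rsquared)

    return StepwiseResult(
        variables=tuple(included),
        coefficients=coef,
        explained_variance=tuple(increments),
        r2=r2,
        adj_r2=adj_r2,
        mse=mse,
        entry_p=tuple(entry_p[v] for v in included),
    )
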