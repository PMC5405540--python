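"""SNP -> mediator regression (path a) and covariate screening.

``fit_linear`` is ordinary least squares of a mediator on the coded SNP
plus covariates, reporting per-term effect sizes with normal-approximation
95% CIs.  ``screen_covariates`` implements the conventional three-stage
reduction of a candidate confounder battery: univariate screen, backward
stepwise selection by information criterion, and iterative
variance-inflation-factor pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .cox import Z95

__all__ = ["LinearFit", "fit_linear", "screen_covariates"]

log = logging.getLogger(__name__)


@dataclass
class LinearFit:
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    ci95: np.ndarray  # (p, 2)
    p_values: np.ndarray
    residual_variance: float
    n_used: int

    def coef(self, term: str) -> float:
        return float(self.coefficients[self.terms.index(term)])

    def se(self, term: str) -> float:
        return float(self.standard_errors[self.terms.index(term)])


def fit_linear(outcome, design, terms: list[str] | None = None, add_intercept: bool = True) -> LinearFit:
    """OLS of a mediator on a design matrix.

    CIs are estimate +/- 1.96 SE (normal approximation; indistinguishable
    from t at cohort sample sizes).  Raises on rank-deficient designs,
    naming the collinear columns.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if isinstance(design, pd.DataFrame) and terms is None:
        terms = list(design.columns)
    if terms is None:
        terms = [f"x{j}" for j in range(X.shape[1])]
    terms = list(terms)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        terms = ["const"] + terms
    n, p = X.shape
    if n <= p:
        raise ValueError(f"n={n} too small for {p} terms")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns by checking rank drop on removal
        guilty = [
            terms[j]
            for j in range(p)
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise ValueError(f"singular design; collinear terms: {guilty}")
    res = sm.OLS(y, X).fit()
    coefs = res.params
    se = res.bse
    ci = np.column_stack([coefs - Z95 * se, coefs + Z95 * se])
    return LinearFit(
        terms=terms,
        coefficients=np.asarray(coefs),
        standard_errors=np.asarray(se),
        ci95=ci,
        p_values=np.asarray(res.pvalues),
        residual_variance=float(res.mse_resid),
        n_used=n,
    )


def _aic(y, X) -> float:
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit().aic


def screen_covariates(
    table: pd.DataFrame,
    candidates: list[str],
    outcome: str,
    univariate_p: float = 0.20,
    vif_max: float = 10.0,
) -> tuple[list[str], pd.DataFrame]:
    """Three-stage covariate reduction against one outcome.

    1. univariate screen: keep candidates with OLS slope p < 0.20;
    2. backward stepwise by AIC on the survivors;
    3. iterative VIF pruning: repeatedly drop the worst VIF > 10.

    Returns the selected list and a log DataFrame with one row per
    candidate and per stage recording the action and the statistic.
    Duplicated/collinear columns (infinite VIF) fall at stage 3.
    """
    if not candidates:
        raise ValueError("no candidate covariates supplied")
    y = table[outcome].to_numpy(dtype=float)
    logrows = []

    survivors = []
    for c in candidates:
        x = table[c].to_numpy(dtype=float)
        if np.std(x) == 0:
            logrows.append({"stage": "univariate", "variable": c, "action": "dropped", "stat": np.nan, "why": "constant"})
            continue
        res = sm.OLS(y, sm.add_constant(x)).fit()
        p = float(res.pvalues[1])
        keep = p < univariate_p
        logrows.append(
            {"stage": "univariate", "variable": c, "action": "kept" if keep else "dropped",
             "stat": p, "why": f"p {'<' if keep else '>='} {univariate_p}"}
        )
        if keep:
            survivors.append(c)

    current = list(survivors)
    improved = True
    while improved and len(current) > 1:
        improved = False
        base = _aic(y, table[current].to_numpy(dtype=float))
        best_drop, best_aic = None, base
        for c in current:
            rest = [v for v in current if v != c]
            a = _aic(y, table[rest].to_numpy(dtype=float))
            if a < best_aic - 1e-9:
                best_drop, best_aic = c, a
        if best_drop is not None:
            current.remove(best_drop)
            logrows.append({"stage": "stepwise", "variable": best_drop, "action": "dropped",
                            "stat": best_aic, "why": f"AIC {best_aic:.2f} < {base:.2f}"})
            improved = True
    for c in current:
        logrows.append({"stage": "stepwise", "variable": c, "action": "kept", "stat": np.nan, "why": "in final AIC model"})

    while len(current) > 1:
        X = sm.add_constant(table[current].to_numpy(dtype=float))
        with np.errstate(divide="ignore"):
            vifs = np.array(
                [variance_inflation_factor(X, j + 1) for j in range(len(current))]
            )
        worst = int(np.nanargmax(vifs))
        if not np.isfinite(vifs[worst]) or vifs[worst] > vif_max:
            c = current.pop(worst)
            logrows.append({"stage": "vif", "variable": c, "action": "dropped",
                            "stat": float(vifs[worst]), "why": f"VIF > {vif_max}"})
        else:
            break
    for c in current:
        logrows.append({"stage": "vif", "variable": c, "action": "kept", "stat": np.nan, "why": f"VIF <= {vif_max}"})

    if not current:
        log.warning("covariate screening removed every candidate")
    return current, pd.DataFrame(logrows)
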