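"""Mediation decomposition of a SNP–cancer effect through a glycemic trait.

Two complementary quantifications of the mediated (indirect) pathway:

* difference in hazard ratios — the SNP's HR from a covariate-adjusted Cox
  model without the mediator (total effect C) versus with it (direct
  effect C'); the proportion mediated is the percentage change of the HR
  relative to the total excess HR,
  100 * |HR_total - HR_direct| / (HR_total - 1);
* product of coefficients — the SNP->mediator OLS slope (a) times the
  mediator->outcome Cox log-hazard coefficient (b), with a percentile
  bootstrap (subjects resampled with replacement, both stages refit) for
  its confidence interval.

On the log-hazard scale a*b approximates ln(HR_total) - ln(HR_direct);
under hazard-ratio non-collapsibility the two agree only approximately
even without confounding, tightly so for rare outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .apath import fit_linear
from .cox import ConvergenceError, CoxFit, fit_cox

__all__ = [
    "MediationResult",
    "estimate_total_direct",
    "proportion_mediated",
    "format_proportion_mediated",
    "product_indirect",
    "bootstrap_indirect",
    "mediate",
]

log = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """One SNP x mediator x stratum mediation decomposition."""

    snp_id: str
    mediator: str
    stratum: str
    hr_total: float
    hr_total_ci95: tuple[float, float]
    hr_direct: float
    hr_direct_ci95: tuple[float, float]
    indirect_ab: float
    indirect_ci95: tuple[float, float]
    indirect_significant: bool
    proportion_mediated_pct: float | None  # None encodes "N/A (>100%)"
    n_used: int
    n_events: int
    n_boot: int
    seed: int | None

    @property
    def proportion_mediated_label(self) -> str:
        return format_proportion_mediated(self.proportion_mediated_pct)


def _design(table: pd.DataFrame, cols: list[str]) -> np.ndarray:
    return table[cols].to_numpy(dtype=float)


def estimate_total_direct(
    table: pd.DataFrame,
    snp: str,
    mediator: str,
    covariates: list[str],
    time_col: str = "followup_years",
    event_col: str = "event_breast",
) -> tuple[CoxFit, CoxFit]:
    """Fit the total-effect and direct-effect Cox models.

    The two fits differ only by the mediator term; the SNP coefficient in
    each gives HR_total (C) and HR_direct (C').
    """
    if mediator in covariates:
        raise ValueError("mediator must not appear among the covariates")
    cols_total = [snp] + list(covariates)
    cols_direct = [snp, mediator] + list(covariates)
    t = table[time_col].to_numpy(dtype=float)
    e = table[event_col].to_numpy(dtype=float)
    fit_total = fit_cox(t, e, _design(table, cols_total), terms=cols_total)
    fit_direct = fit_cox(t, e, _design(table, cols_direct), terms=cols_direct)
    return fit_total, fit_direct


def proportion_mediated(hr_total: float, hr_direct: float) -> float | None:
    """Percentage change in the SNP HR upon adding the mediator, relative
    to the total excess HR: 100 * |HR_total - HR_direct| / (HR_total - 1).

    For protective SNPs (HR_total < 1) the denominator is still
    HR_total - 1 and the absolute value is taken of the whole ratio.
    Returns None when the proportion exceeds 100% (reported as
    "N/A (>100%)").  HR_total == 1 is undefined.
    """
    if hr_total <= 0 or hr_direct <= 0:
        raise ValueError("hazard ratios must be positive")
    if hr_total == 1.0:
        raise ZeroDivisionError("proportion mediated undefined at HR_total = 1")
    pct = 100.0 * abs((hr_total - hr_direct) / (hr_total - 1.0))
    if pct > 100.0:
        return None
    return pct


def format_proportion_mediated(pct: float | None) -> str:
    return "N/A (>100%)" if pct is None else f"{pct:.1f}%"


def product_indirect(a: float, b: float) -> float:
    """Indirect effect size a*b on the log-hazard scale."""
    return a * b


def _ab_once(table, snp, mediator, covariates, time_col, event_col):
    acols = [snp] + list(covariates)
    afit = fit_linear(table[mediator].to_numpy(dtype=float), _design(table, acols), terms=acols)
    bcols = [snp, mediator] + list(covariates)
    bfit = fit_cox(
        table[time_col].to_numpy(dtype=float),
        table[event_col].to_numpy(dtype=float),
        _design(table, bcols),
        terms=bcols,
    )
    return afit.coef(snp), bfit.coef(mediator)


def bootstrap_indirect(
    table: pd.DataFrame,
    snp: str,
    mediator: str,
    covariates: list[str],
    time_col: str = "followup_years",
    event_col: str = "event_breast",
    n_boot: int = 1000,
    seed: int | None = None,
    max_failure_rate: float = 0.10,
) -> dict:
    """Percentile-bootstrap CI for the indirect effect a*b.

    Subjects are resampled with replacement; both the a-path OLS and the
    b-path Cox model are refit on every replicate and the products'
    2.5/97.5 percentiles form the CI.  Significance = CI excludes zero.
    Aborts if more than ``max_failure_rate`` of replicates fail to
    converge.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    a_hat, b_hat = _ab_once(table, snp, mediator, covariates, time_col, event_col)
    point = product_indirect(a_hat, b_hat)

    rng = np.random.default_rng(seed)
    n = len(table)
    # flat arrays for the resampling loop: OLS by lstsq, Cox by the engine
    snp_v = table[snp].to_numpy(dtype=float)
    med_v = table[mediator].to_numpy(dtype=float)
    t_v = table[time_col].to_numpy(dtype=float)
    e_v = table[event_col].to_numpy(dtype=float)
    cov_m = _design(table, list(covariates)) if covariates else np.empty((n, 0))
    ones = np.ones(n)
    bterms = [snp, mediator] + list(covariates)
    products = np.empty(n_boot)
    failures = 0
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        Xa = np.column_stack([ones, snp_v[idx], cov_m[idx]])
        try:
            coef_a = np.linalg.lstsq(Xa, med_v[idx], rcond=None)[0][1]
            Xb = np.column_stack([snp_v[idx], med_v[idx], cov_m[idx]])
            bfit = fit_cox(t_v[idx], e_v[idx], Xb, terms=bterms)
            products[r] = coef_a * bfit.coef(mediator)
        except (ConvergenceError, ValueError, np.linalg.LinAlgError):
            products[r] = np.nan
            failures += 1
        if failures > max_failure_rate * n_boot:
            raise RuntimeError(
                f"bootstrap aborted: {failures} of {r + 1} replicates failed to converge"
            )
    ok = products[~np.isnan(products)]
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return {
        "indirect": point,
        "a": a_hat,
        "b": b_hat,
        "ci95": (float(lo), float(hi)),
        "significant": bool(lo > 0 or hi < 0),
        "n_boot": n_boot,
        "n_failed": failures,
        "seed": seed,
    }


def mediate(
    table: pd.DataFrame,
    snp: str,
    mediator: str,
    covariates: list[str],
    time_col: str = "followup_years",
    event_col: str = "event_breast",
    stratum: str = "all",
    n_boot: int = 1000,
    seed: int | None = None,
) -> MediationResult:
    """Full decomposition for one SNP x mediator x stratum cell."""
    fit_total, fit_direct = estimate_total_direct(
        table, snp, mediator, covariates, time_col, event_col
    )
    hr_t = fit_total.hazard_ratio(snp)
    hr_d = fit_direct.hazard_ratio(snp)
    i_t = fit_total.terms.index(snp)
    i_d = fit_direct.terms.index(snp)
    boot = bootstrap_indirect(
        table, snp, mediator, covariates, time_col, event_col, n_boot=n_boot, seed=seed
    )
    try:
        pm = proportion_mediated(hr_t, hr_d)
    except ZeroDivisionError:
        pm = None
    return MediationResult(
        snp_id=snp,
        mediator=mediator,
        stratum=stratum,
        hr_total=hr_t,
        hr_total_ci95=tuple(fit_total.hr_ci95[i_t]),
        hr_direct=hr_d,
        hr_direct_ci95=tuple(fit_direct.hr_ci95[i_d]),
        indirect_ab=boot["indirect"],
        indirect_ci95=boot["ci95"],
        indirect_significant=boot["significant"],
        proportion_mediated_pct=pm,
        n_used=fit_total.n_used,
        n_events=fit_total.n_events,
        n_boot=n_boot,
        seed=seed,
    )
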