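"""Obesity / lifestyle stratification and cross-stratum interaction tests.

The cohort is dichotomized on one of five effect modifiers — BMI (30
kg/m2), waist circumference (88 cm), waist-to-hip ratio (0.85),
recreational physical activity (10 MET-h/week) and dietary fat (40% of
calories) — and the mediation decomposition is repeated within each
stratum.  Effect modification is tested in a pooled Cox model with a
SNP x stratum product term.

Boundary membership follows the published dichotomies: BMI 30 is obese;
waist 88 and w/h 0.85 are non-obese (favorable); MET 10 is favorable;
40% fat is unfavorable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import fit_cox
from .mediation import MediationResult, mediate

__all__ = [
    "StratumSpec",
    "InteractionResult",
    "STRATA_PRESETS",
    "assign_strata",
    "interaction_test",
    "run_stratified_mediation",
]

log = logging.getLogger(__name__)

_VARIABLES = ("bmi", "waist", "whr", "met_hours", "pct_fat_calories")


@dataclass(frozen=True)
class StratumSpec:
    """A dichotomizing rule: variable, cutoff, and which side is 'unfavorable'.

    ``unfavorable_side`` is ``"at-or-above"``, ``"above"`` or ``"below"``
    and names the side assigned the unfavorable (obese / inactive /
    high-fat) label.
    """

    variable: str
    cutoff: float
    unfavorable_side: str
    labels: tuple[str, str]  # (favorable, unfavorable)

    def __post_init__(self):
        if self.variable not in _VARIABLES:
            raise ValueError(f"variable must be one of {_VARIABLES}")
        if self.unfavorable_side not in ("above", "at-or-above", "below"):
            raise ValueError("unfavorable_side must be above / at-or-above / below")
        if self.labels[0] == self.labels[1]:
            raise ValueError("stratum labels must differ")
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")


#: The five published dichotomies, keyed by variable.
STRATA_PRESETS: dict[str, StratumSpec] = {
    "bmi": StratumSpec("bmi", 30.0, "at-or-above", ("BMI<30", "BMI>=30")),
    "waist": StratumSpec("waist", 88.0, "above", ("waist<=88", "waist>88")),
    "whr": StratumSpec("whr", 0.85, "above", ("w/h<=0.85", "w/h>0.85")),
    "met_hours": StratumSpec("met_hours", 10.0, "below", ("MET>=10", "MET<10")),
    "pct_fat_calories": StratumSpec(
        "pct_fat_calories", 40.0, "at-or-above", ("fat<40%", "fat>=40%")
    ),
}

#: Effect-modifier variables adjusted as covariates when not themselves the
#: stratifying variable (physical activity, BMI and w/h ratio); when
#: stratifying by waist the w/h ratio is additionally left out.
_MODIFIER_COVARIATES = ("met_hours", "bmi", "whr")


def assign_strata(table: pd.DataFrame, spec: StratumSpec) -> pd.Series:
    """Binary labels for one dichotomy: 1 = unfavorable side, NaN = missing.

    Missing values are excluded with a logged count.
    """
    if spec.variable not in table.columns:
        raise KeyError(f"column {spec.variable!r} not in cohort table")
    v = table[spec.variable].to_numpy(dtype=float)
    if spec.unfavorable_side == "at-or-above":
        unf = v >= spec.cutoff
    elif spec.unfavorable_side == "above":
        unf = v > spec.cutoff
    else:
        unf = v < spec.cutoff
    out = np.where(unf, 1.0, 0.0)
    miss = np.isnan(v)
    if miss.any():
        log.info("%s: %d subject(s) missing, excluded from stratification",
                 spec.variable, int(miss.sum()))
        out = np.where(miss, np.nan, out)
    return pd.Series(out, index=table.index, name=f"stratum_{spec.variable}")


@dataclass
class InteractionResult:
    """Product-term test of effect modification from a pooled Cox model."""

    snp_id: str
    stratum_variable: str
    effect_size: float  # SNP x stratum log-hazard coefficient
    se: float
    p_value: float
    n_used: int


def interaction_test(
    table: pd.DataFrame,
    snp: str,
    stratum_labels: pd.Series,
    covariates: list[str],
    time_col: str = "followup_years",
    event_col: str = "event_breast",
    stratum_variable: str = "stratum",
) -> InteractionResult:
    """Wald test of the SNP x stratum product term in a pooled Cox model.

    The model contains the SNP, the stratum indicator, their product and
    the covariates; the reported effect size is the product-term
    log-hazard coefficient.
    """
    lab = np.asarray(stratum_labels, dtype=float)
    keep = ~np.isnan(lab)
    sub = table.loc[keep]
    lab = lab[keep]
    ev = sub[event_col].to_numpy(dtype=float)
    for side in (0.0, 1.0):
        if ev[lab == side].sum() < 1:
            raise ValueError(f"stratum {side:g} of {stratum_variable} has no events")
    snp_v = sub[snp].to_numpy(dtype=float)
    X = np.column_stack(
        [snp_v, lab, snp_v * lab]
        + [sub[c].to_numpy(dtype=float) for c in covariates]
    )
    terms = [snp, "stratum", f"{snp}:stratum"] + list(covariates)
    fit = fit_cox(sub[time_col].to_numpy(dtype=float), ev, X, terms=terms)
    j = terms.index(f"{snp}:stratum")
    return InteractionResult(
        snp_id=snp,
        stratum_variable=stratum_variable,
        effect_size=float(fit.coefficients[j]),
        se=float(fit.standard_errors[j]),
        p_value=float(fit.p_values[j]),
        n_used=fit.n_used,
    )


def covariate_roster(
    base_covariates: list[str], stratifying_variable: str
) -> list[str]:
    """Covariates for one stratum analysis.

    The non-evaluated effect modifiers (physical activity, BMI, w/h
    ratio) join the base covariates; when stratifying by waist
    circumference, w/h ratio is not adjusted.
    """
    extra = [v for v in _MODIFIER_COVARIATES if v != stratifying_variable]
    if stratifying_variable == "waist":
        extra = [v for v in extra if v != "whr"]
    return list(base_covariates) + extra


def run_stratified_mediation(
    table: pd.DataFrame,
    snps: list[str],
    mediators: list[str],
    covariates: list[str],
    strata: list[StratumSpec] | None = None,
    time_col: str = "followup_years",
    event_col: str = "event_breast",
    n_boot: int = 1000,
    seed: int | None = None,
) -> tuple[list[MediationResult], list[InteractionResult], pd.DataFrame]:
    """Full SNP x mediator x stratum cross of mediation decompositions.

    Each stratum is analyzed separately with the covariate roster rule
    above; one interaction test per SNP x stratum variable is run on the
    pooled data.  Per-cell failures are logged and skipped, not fatal.
    Deterministic under a fixed master seed (cell seeds are spawned from
    it in a fixed order).

    Returns (mediation results, interaction results, covariate audit log).
    """
    if strata is None:
        strata = list(STRATA_PRESETS.values())
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    results: list[MediationResult] = []
    interactions: list[InteractionResult] = []
    audit = []
    for spec in strata:
        labels = assign_strata(table, spec)
        covs = covariate_roster(covariates, spec.variable)
        audit.append(
            {"stratum_variable": spec.variable, "covariates": ",".join(covs)}
        )
        for snp in snps:
            try:
                interactions.append(
                    interaction_test(
                        table, snp, labels, covs, time_col, event_col,
                        stratum_variable=spec.variable,
                    )
                )
            except (ValueError, RuntimeError) as exc:
                log.warning("interaction %s x %s failed: %s", snp, spec.variable, exc)
            for mediator in mediators:
                for side, name in ((0.0, spec.labels[0]), (1.0, spec.labels[1])):
                    cell_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                    sub = table.loc[labels == side]
                    try:
                        results.append(
                            mediate(
                                sub, snp, mediator, covs, time_col, event_col,
                                stratum=f"{spec.variable}:{name}",
                                n_boot=n_boot, seed=cell_seed,
                            )
                        )
                    except (ValueError, RuntimeError) as exc:
                        log.warning(
                            "mediation %s x %s x %s failed: %s", snp, mediator, name, exc
                        )
    return results, interactions, pd.DataFrame(audit)
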