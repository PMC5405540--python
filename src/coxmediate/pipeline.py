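"""End-to-end pipeline: simulate/load -> QC -> a-path -> Cox -> mediation.

A run is driven by one :class:`RunConfig` (built in code or loaded from
YAML) and a master seed; it emits four artifacts into the output
directory:

* ``descriptive.tsv``   — stratified baseline table with group-comparison
  p-values (rank-sum for continuous, chi-square for categorical);
* ``apath.tsv``         — SNP x mediator effect sizes with 95% CIs;
* ``mediation.tsv``     — SNP x mediator x stratum total/direct HRs,
  bootstrap indirect effects, proportion-mediated notes and interaction
  footnotes;
* ``manifest.json``     — seed, config hash, package version, exclusion
  accounting.

Identical config + seed gives byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .apath import fit_linear
from .genotype import code_genotype, qc_filter, read_genotypes
from .mediation import format_proportion_mediated
from .strata import STRATA_PRESETS, assign_strata, run_stratified_mediation
from .synthetic import SimulationConfig, assemble_cohort
from .traits import ensure_homa_ir

__all__ = ["RunConfig", "run", "describe_cohort", "load_config"]

log = logging.getLogger(__name__)

DEFAULT_COVARIATES = [
    "age", "education_high", "family_history_dm", "hypertension", "smoking_current",
]


@dataclass
class RunConfig:
    """Validated description of one pipeline run."""

    seed: int
    simulation: SimulationConfig | None = None
    phenotype_path: str | None = None
    genotype_path: str | None = None
    genotype_format: str = "dosage-matrix"
    outcome: str = "breast"
    snps: list[str] | None = None
    mediators: list[str] = field(default_factory=lambda: ["glucose", "insulin", "homa_ir"])
    genetic_model: str = "additive"
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    strata: list[str] = field(default_factory=lambda: list(STRATA_PRESETS))
    n_boot: int = 1000
    min_followup_years: float = 1.0

    def __post_init__(self):
        has_sim = self.simulation is not None
        has_paths = self.phenotype_path is not None
        if has_sim == has_paths:
            raise ValueError("exactly one of simulation / phenotype_path is required")
        if self.seed is None:
            raise ValueError("a master seed is required")
        if self.outcome not in ("breast", "crc"):
            raise ValueError("outcome must be 'breast' or 'crc'")
        if self.genetic_model not in ("additive", "dominant"):
            raise ValueError("genetic_model must be 'additive' or 'dominant'")
        unknown = [s for s in self.strata if s not in STRATA_PRESETS]
        if unknown:
            raise ValueError(f"unknown strata: {unknown}")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            sim.setdefault("seed", d.get("seed"))
            sim.setdefault("outcome", d.get("outcome", "breast"))
            d["simulation"] = SimulationConfig.from_dict(sim)
        return cls(**d)

    def to_canonical_json(self) -> str:
        d = self.__dict__.copy()
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        return json.dumps(d, sort_keys=True, default=str)


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh))


def describe_cohort(table: pd.DataFrame, stratum_labels: pd.Series,
                    variables: list[str] | None = None) -> pd.DataFrame:
    """Baseline characteristics by stratum, with group-comparison tests.

    Continuous variables: median (range) per stratum, Wilcoxon rank-sum
    p.  Binary variables: n (%) per stratum, chi-square p.  Constant
    variables get an undefined-p flag.  Significance flagged at 0.05.
    """
    lab = np.asarray(stratum_labels, dtype=float)
    keep = ~np.isnan(lab)
    df = table.loc[keep]
    lab = lab[keep]
    if variables is None:
        variables = [
            c for c in df.columns
            if c not in ("subject_id",) and pd.api.types.is_numeric_dtype(df[c])
        ]
    rows = []
    for v in variables:
        x = df[v].to_numpy(dtype=float)
        g0, g1 = x[lab == 0], x[lab == 1]
        binary = set(np.unique(x[~np.isnan(x)])) <= {0.0, 1.0}
        if np.nanstd(x) == 0:
            rows.append({"variable": v, "favorable": f"{np.nanmedian(g0):.3g}",
                         "unfavorable": f"{np.nanmedian(g1):.3g}",
                         "p": np.nan, "flag": "constant (p undefined)"})
            continue
        if binary:
            tab = np.array([
                [np.sum(g0 == 0), np.sum(g0 == 1)],
                [np.sum(g1 == 0), np.sum(g1 == 1)],
            ])
            p = float(stats.chi2_contingency(tab, correction=False)[1])
            s0 = f"{int(tab[0, 1])} ({100 * tab[0, 1] / max(len(g0), 1):.1f}%)"
            s1 = f"{int(tab[1, 1])} ({100 * tab[1, 1] / max(len(g1), 1):.1f}%)"
        else:
            p = float(stats.ranksums(g0, g1).pvalue)
            s0 = f"{np.nanmedian(g0):.3g} ({np.nanmin(g0):.3g}-{np.nanmax(g0):.3g})"
            s1 = f"{np.nanmedian(g1):.3g} ({np.nanmin(g1):.3g}-{np.nanmax(g1):.3g})"
        rows.append({"variable": v, "favorable": s0, "unfavorable": s1,
                     "p": p, "flag": "*" if p < 0.05 else ""})
    return pd.DataFrame(rows)


def _load_or_simulate(config: RunConfig):
    exclusions = {}
    if config.simulation is not None:
        cohort = assemble_cohort(config.simulation)
        table = cohort.data
        snp_defs = cohort.snps
        qc_report = None
    else:
        table = pd.read_csv(config.phenotype_path, sep="\t")
        snp_defs = []
        qc_report = None
        if config.genotype_path is not None:
            from .synthetic import default_snp_panel

            panel = read_genotypes(
                config.genotype_path, default_snp_panel(), format=config.genotype_format
            )
            panel, qc_report = qc_filter(panel)
            snp_defs = panel.snps
            geno = panel.dosages.reset_index(drop=True)
            table = pd.concat([table.reset_index(drop=True), geno], axis=1)
    snp_ids = config.snps or [s.snp_id for s in snp_defs]
    return table, snp_ids, qc_report, exclusions


def run(config: RunConfig, out_dir) -> dict:
    """Execute the full pipeline; returns a result bundle (also on disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    event_col = f"event_{config.outcome}"

    table, snp_ids, qc_report, exclusions = _load_or_simulate(config)
    n_input = len(table)
    table = ensure_homa_ir(table)

    short = table["followup_years"] < config.min_followup_years
    exclusions["followup_lt_1yr"] = int(short.sum())
    table = table.loc[~short]

    needed = list(dict.fromkeys(
        snp_ids + config.mediators + config.covariates
        + ["followup_years", event_col]
        + [STRATA_PRESETS[s].variable for s in config.strata]
    ))
    missing_any = table[needed].isna().any(axis=1)
    exclusions["missing_values"] = int(missing_any.sum())
    table = table.loc[~missing_any].reset_index(drop=True)
    exclusions["analyzed"] = len(table)

    if config.genetic_model == "dominant":
        for s in snp_ids:
            table[s] = code_genotype(table[s].to_numpy(dtype=float), "dominant")

    # 1. descriptive table stratified by BMI obesity
    bmi_labels = assign_strata(table, STRATA_PRESETS["bmi"])
    desc = describe_cohort(table, bmi_labels)
    desc.to_csv(out / "descriptive.tsv", sep="\t", index=False, float_format="%.4g")

    # 2. a-path effect tables (whole cohort, adjusted for covariates)
    arows = []
    for snp in snp_ids:
        for mediator in config.mediators:
            cols = [snp] + config.covariates
            fit = fit_linear(
                table[mediator].to_numpy(dtype=float),
                table[cols].to_numpy(dtype=float),
                terms=cols,
            )
            j = fit.terms.index(snp)
            arows.append({
                "snp_id": snp, "mediator": mediator,
                "effect_size": fit.coefficients[j],
                "se": fit.standard_errors[j],
                "ci_low": fit.ci95[j, 0], "ci_high": fit.ci95[j, 1],
                "p": fit.p_values[j], "n": fit.n_used,
            })
    apath_tab = pd.DataFrame(arows)
    apath_tab.to_csv(out / "apath.tsv", sep="\t", index=False, float_format="%.6g")

    # 3. stratified mediation tables with interaction footnotes
    specs = [STRATA_PRESETS[s] for s in config.strata]
    med_results, inter_results, audit = run_stratified_mediation(
        table, snp_ids, config.mediators, config.covariates, specs,
        event_col=event_col, n_boot=config.n_boot, seed=config.seed,
    )
    mrows = [{
        "snp_id": m.snp_id, "mediator": m.mediator, "stratum": m.stratum,
        "hr_direct": m.hr_direct,
        "hr_direct_ci": f"{m.hr_direct_ci95[0]:.3f}-{m.hr_direct_ci95[1]:.3f}",
        "indirect_ab": m.indirect_ab,
        "indirect_ci": f"{m.indirect_ci95[0]:.4f}-{m.indirect_ci95[1]:.4f}",
        "indirect_significant": m.indirect_significant,
        "hr_total": m.hr_total,
        "hr_total_ci": f"{m.hr_total_ci95[0]:.3f}-{m.hr_total_ci95[1]:.3f}",
        "proportion_mediated": format_proportion_mediated(m.proportion_mediated_pct),
        "n": m.n_used, "events": m.n_events,
    } for m in med_results]
    med_tab = pd.DataFrame(mrows)
    with open(out / "mediation.tsv", "w") as fh:
        med_tab.to_csv(fh, sep="\t", index=False, float_format="%.4f")
        fh.write("# interaction tests (pooled Cox product term)\n")
        for it in inter_results:
            fh.write(
                f"# {it.snp_id} x {it.stratum_variable}: effect size "
                f"{it.effect_size:.2f}, p-value {it.p_value:.2f}\n"
            )
    audit.to_csv(out / "covariate_audit.tsv", sep="\t", index=False)
    if qc_report is not None:
        qc_report.to_csv(out / "genotype_qc.tsv", sep="\t", index=False, float_format="%.4g")

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "outcome": config.outcome,
        "config_sha256": hashlib.sha256(config.to_canonical_json().encode()).hexdigest(),
        "n_input": n_input,
        "exclusions": exclusions,
        "n_mediation_cells": len(med_results),
        "n_interaction_tests": len(inter_results),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "descriptive": desc,
        "apath": apath_tab,
        "mediation": med_tab,
        "mediation_results": med_results,
        "interactions": inter_results,
        "manifest": manifest,
    }
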