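"""Genotype input, quality control and coding.

Reads dosage data from a minimal VCF (GT, optional DS) or a plain
tab-delimited dosage matrix, orients every site to the panel's effect
allele, applies the standard per-SNP QC screen (missing call rate < 2%,
Hardy–Weinberg equilibrium p >= 1e-4 by 1-df chi-square on hard calls),
and produces additive (0–2 allele count) or dominant (carrier indicator)
codings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SnpDef

__all__ = [
    "GenotypePanel",
    "AlleleOrientationError",
    "read_genotypes",
    "hwe_chisq",
    "qc_filter",
    "code_genotype",
]

log = logging.getLogger(__name__)


class AlleleOrientationError(ValueError):
    """A site's allele pair matches neither orientation of its definition."""


@dataclass
class GenotypePanel:
    """SNP definitions plus a subjects x SNPs dosage matrix (NaN = missing)."""

    snps: list[SnpDef]
    dosages: pd.DataFrame  # columns = snp_ids, index = sample ids
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        ids = [s.snp_id for s in self.snps]
        if list(self.dosages.columns) != ids:
            raise ValueError("dosage columns must match SNP definitions in order")
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | ((vals >= 0) & (vals <= 2))
        if not ok.all():
            raise ValueError("dosages must lie in [0, 2] where present")
        if not self.sample_ids:
            self.sample_ids = list(self.dosages.index.astype(str))

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    def effect_allele_freqs(self) -> pd.Series:
        """Estimated effect-allele frequency: mean(dosage)/2 per SNP."""
        return self.dosages.mean(skipna=True) / 2.0


def _orient(dosage, ref, alt, snp: SnpDef):
    """Return dosage counting the effect allele; flip 2-d if REF/ALT are
    swapped relative to the SNP definition."""
    if (ref, alt) == (snp.other_allele, snp.effect_allele):
        return dosage, False
    if (ref, alt) == (snp.effect_allele, snp.other_allele):
        return 2.0 - dosage, True
    raise AlleleOrientationError(
        f"{snp.snp_id}: file alleles {ref}/{alt} match neither orientation of "
        f"{snp.other_allele}/{snp.effect_allele}"
    )


def _read_vcf(path, snp_defs):
    from cyvcf2 import VCF

    defs = {s.snp_id: s for s in snp_defs}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols = {}
    order = []
    for var in vcf:
        sid = var.ID
        if sid not in defs:
            continue
        snp = defs[sid]
        if len(var.ALT) != 1:
            raise ValueError(f"{sid}: only biallelic sites are supported")
        ds = var.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotypes, dtype=object)
            d = np.array(
                [np.nan if g[0] < 0 else float(g[0] + g[1]) for g in var.genotypes]
            )
        d, flipped = _orient(d, var.REF, var.ALT[0], snp)
        if flipped:
            log.info("%s: REF/ALT swapped relative to effect allele; dosage flipped", sid)
        cols[sid] = d
        order.append(sid)
    missing = set(defs) - set(order)
    if missing:
        log.warning("VCF lacks %d panel SNP(s): %s", len(missing), sorted(missing))
    snps = [defs[s] for s in order]
    df = pd.DataFrame(cols, index=samples)[order]
    return GenotypePanel(snps=snps, dosages=df, sample_ids=samples)


def _read_dosage_matrix(path, snp_defs):
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas reports the line
        raise ValueError(f"malformed dosage matrix {path}: {exc}") from exc
    defs = {s.snp_id: s for s in snp_defs}
    order = [c for c in df.columns if c in defs]
    if not order:
        raise ValueError("dosage matrix shares no rsID with the SNP panel")
    df = df[order].astype(float)
    snps = [defs[s] for s in order]
    return GenotypePanel(snps=snps, dosages=df, sample_ids=list(df.index.astype(str)))


def read_genotypes(path, snp_defs: list[SnpDef], format: str = "vcf") -> GenotypePanel:
    """Read a genotype file and orient dosages to each SNP's effect allele.

    ``format`` is ``"vcf"`` (VCF v4.2; DS preferred, GT fallback) or
    ``"dosage-matrix"`` (tab-delimited, first column sample ID, header of
    rsIDs; dosages already effect-allele oriented).
    """
    if format == "vcf":
        return _read_vcf(path, snp_defs)
    if format == "dosage-matrix":
        return _read_dosage_matrix(path, snp_defs)
    raise ValueError(f"unknown genotype format {format!r}")


def hwe_chisq(dosage: np.ndarray) -> tuple[float, float]:
    """1-df chi-square Hardy–Weinberg test on hard calls.

    Continuous dosages are rounded to the nearest genotype before
    counting.  Returns (chi2, p); monomorphic sites give (0, 1).
    """
    d = np.asarray(dosage, dtype=float)
    d = d[~np.isnan(d)]
    hard = np.clip(np.rint(d), 0, 2).astype(int)
    n = len(hard)
    if n == 0:
        return 0.0, 1.0
    counts = np.bincount(hard, minlength=3).astype(float)
    p = (counts[1] + 2 * counts[2]) / (2 * n)
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    panel: GenotypePanel,
    max_missing: float = 0.02,
    hwe_p_min: float = 1e-4,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Drop SNPs failing the missingness or HWE screen; report all metrics.

    The report has one row per input SNP: missing call rate, estimated
    effect-allele frequency, HWE chi-square and p, and the retained flag.
    An empty post-filter panel is a logged warning, not an error.
    """
    if not panel.snps:
        raise ValueError("empty genotype panel")
    rows = []
    keep = []
    for snp in panel.snps:
        d = panel.dosages[snp.snp_id].to_numpy(dtype=float)
        miss = float(np.isnan(d).mean())
        eaf = float(np.nanmean(d) / 2.0) if not np.all(np.isnan(d)) else np.nan
        chi2, p = hwe_chisq(d)
        ok = miss < max_missing and p >= hwe_p_min
        reason = []
        if miss >= max_missing:
            reason.append(f"missing {miss:.3f} >= {max_missing}")
        if p < hwe_p_min:
            reason.append(f"HWE p {p:.2e} < {hwe_p_min}")
        rows.append(
            {
                "snp_id": snp.snp_id,
                "missing_rate": miss,
                "eaf": eaf,
                "hwe_chi2": chi2,
                "hwe_p": p,
                "retained": ok,
                "reason": "; ".join(reason),
            }
        )
        if ok:
            keep.append(snp)
    report = pd.DataFrame(rows)
    if not keep:
        log.warning("QC removed every SNP from the panel")
        return GenotypePanel(snps=[], dosages=panel.dosages.iloc[:, :0], sample_ids=panel.sample_ids), report
    kept_ids = [s.snp_id for s in keep]
    return (
        GenotypePanel(snps=keep, dosages=panel.dosages[kept_ids], sample_ids=panel.sample_ids),
        report,
    )


def code_genotype(dosage, model: str = "additive", carrier_threshold: float = 0.5):
    """Code dosages for modelling.

    additive: the dosage itself (effect-allele count).  dominant: carrier
    indicator, 1 iff dosage >= carrier_threshold (default 0.5, so any
    appreciable imputed dose counts as carrying).  Missing stays NaN.
    """
    d = np.asarray(dosage, dtype=float)
    if np.nanmin(d) < 0 or np.nanmax(d) > 2:
        raise ValueError("dosages must lie in [0, 2]")
    if model == "additive":
        return d.copy()
    if model == "dominant":
        out = np.where(d >= carrier_threshold, 1.0, 0.0)
        out = np.where(np.isnan(d), np.nan, out)
        return out
    raise ValueError(f"unknown genetic model {model!r}")
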