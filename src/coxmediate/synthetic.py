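"""Synthetic cohort generator.

Emulates a postmenopausal cohort with the causal structure the mediation
analysis assumes: biallelic SNPs under Hardy–Weinberg equilibrium at
European-like frequencies, glycemic mediators (fasting glucose mg/dl,
fasting insulin uIU/ml, derived HOMA-IR) that depend on obesity stratum and
on genotype through per-allele effects (path a), and exponential
proportional-hazards event times (path b plus any direct genetic effect)
with administrative censoring.

Default calibration targets: median glucose 92 (non-obese) / 97 (obese)
mg/dl, median insulin 5.5 / 9.8 uIU/ml, obesity prevalence ~32%, and a
cumulative cancer incidence of roughly 5% (non-obese) and 8% (obese) over
16 years of follow-up.

Every stochastic operation takes an explicit seed, or derives one
deterministically from the config master seed via ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .traits import homa_ir

__all__ = [
    "SnpDef",
    "SimulationConfig",
    "Cohort",
    "default_snp_panel",
    "default_config",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_survival",
    "assemble_cohort",
    "write_phenotypes",
    "write_dosage_matrix",
    "write_vcf",
]


@dataclass(frozen=True)
class SnpDef:
    """A biallelic SNP: identifier, nearest gene, alleles and frequency.

    ``effect_allele_freq`` is the population frequency of the effect
    (dosage-counted) allele.
    """

    snp_id: str
    gene_label: str
    effect_allele: str
    other_allele: str
    effect_allele_freq: float

    def __post_init__(self):
        if not 0.0 <= self.effect_allele_freq <= 1.0:
            raise ValueError(
                f"{self.snp_id}: effect allele frequency "
                f"{self.effect_allele_freq} outside [0, 1]"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")


def default_snp_panel() -> list[SnpDef]:
    """Sixteen glucose-metabolism SNPs with European-like allele frequencies.

    The panel covers the fasting-glucose and fasting-insulin loci
    established by large GWAS meta-analyses (G6PC2, GCKR, GCK, DGKB,
    ADRA2A, FADS1, CRY2, SLC30A8, IGF1, MTNR1B, ADCY5, MADD, SLC2A2,
    GLIS3, PROX1, C2CD4B).  Frequencies are approximate European values
    and are configuration defaults, not estimates.
    """
    rows = [
        ("rs560887", "G6PC2", "T", "C", 0.30),
        ("rs780094", "GCKR", "C", "T", 0.61),
        ("rs4607517", "GCK", "G", "A", 0.84),
        ("rs2191349", "DGKB/TMEM195", "G", "T", 0.47),
        ("rs10885122", "ADRA2A", "G", "T", 0.87),
        ("rs174550", "FADS1", "T", "C", 0.64),
        ("rs11605924", "CRY2", "C", "A", 0.49),
        ("rs11558471", "SLC30A8", "A", "G", 0.68),
        ("rs35767", "IGF1", "A", "G", 0.15),
        ("rs10830963", "MTNR1B", "G", "C", 0.27),
        ("rs11708067", "ADCY5", "A", "G", 0.78),
        ("rs7944584", "MADD", "A", "T", 0.75),
        ("rs11920090", "SLC2A2", "T", "A", 0.87),
        ("rs7034200", "GLIS3", "A", "C", 0.49),
        ("rs340874", "PROX1", "C", "T", 0.52),
        ("rs11071657", "C2CD4B", "A", "G", 0.63),
    ]
    return [SnpDef(*r) for r in rows]


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    ``a_effects`` maps snp_id -> mediator shift (mg/dl glucose per effect
    allele); ``gamma_direct_loghr`` maps snp_id -> direct log-hazard per
    allele.  ``b_loghr`` is the log-hazard per mg/dl of glucose entering
    the linear predictor as a raw (uncentered) term, so the default
    ``baseline_rate`` already absorbs exp(b * typical glucose).
    """

    n_subjects: int = 5379
    seed: int = 2017
    snps: list[SnpDef] = field(default_factory=default_snp_panel)
    a_effects: dict[str, float] = field(default_factory=dict)
    obesity_prevalence: float = 0.317
    trait_params: dict = field(default_factory=lambda: {
        "glucose": {  # truncated normal, mg/dl
            "non_obese": {"median": 92.0, "sd": 13.0},
            "obese": {"median": 97.0, "sd": 16.0},
            "floor": 40.0,
        },
        "insulin": {  # log-normal, uIU/ml
            "non_obese": {"median": 5.5, "sigma": 0.55},
            "obese": {"median": 9.8, "sigma": 0.50},
        },
    })
    b_loghr: float = 0.01
    gamma_direct_loghr: dict[str, float] = field(default_factory=dict)
    obesity_loghr: float = 0.45
    baseline_rate: float = 0.00127
    admin_censor_years: float = 16.0
    outcome: str = "breast"
    weibull_shape: float = 1.0
    continuous_dosage: bool = False
    covariate_specs: dict = field(default_factory=lambda: {
        "age": {"kind": "normal", "mean": 67.0, "sd": 7.0,
                "lo": 50.0, "hi": 79.0, "loghr": 0.02},
        "education_high": {"kind": "bernoulli", "p": 0.63, "loghr": 0.0},
        "family_history_dm": {"kind": "bernoulli", "p": 0.29, "loghr": 0.0},
        "hypertension": {"kind": "bernoulli", "p": 0.31, "loghr": 0.0},
        "smoking_current": {"kind": "bernoulli", "p": 0.07, "loghr": 0.0},
    })

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be positive")
        if not 0.0 <= self.obesity_prevalence <= 1.0:
            raise ValueError("obesity_prevalence must lie in [0, 1]")
        if self.outcome not in ("breast", "crc"):
            raise ValueError("outcome must be 'breast' or 'crc'")
        if not self.a_effects:
            # focal SNP carries a strong mediated effect; background SNPs weak
            self.a_effects = {s.snp_id: 0.5 for s in self.snps}
            self.a_effects["rs560887"] = 2.0
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_id values must be unique within the panel")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snps"] = [asdict(s) for s in self.snps]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "snps" in d:
            d["snps"] = [SnpDef(**s) if isinstance(s, dict) else s for s in d["snps"]]
        return cls(**d)


@dataclass
class Cohort:
    """A generated cohort: phenotypes plus the parameters that made it."""

    data: pd.DataFrame
    snps: list[SnpDef]
    truth: dict

    @property
    def n(self) -> int:
        return len(self.data)

    def dosage_columns(self) -> list[str]:
        return [s.snp_id for s in self.snps]


def default_config(**overrides) -> SimulationConfig:
    """The packaged default configuration (calibration described above)."""
    return SimulationConfig(**overrides)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def simulate_genotypes(snp: SnpDef, n: int, seed, continuous: bool = False) -> np.ndarray:
    """Draw n dosages for one SNP under Hardy–Weinberg equilibrium.

    Hard calls 0/1/2 with probabilities (1-p)^2, 2p(1-p), p^2.  With
    ``continuous=True`` a small Gaussian smear (sd 0.1) emulates imputed
    dosages, clipped to [0, 2].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    p = snp.effect_allele_freq
    rng = _rng(seed)
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    d = rng.choice([0.0, 1.0, 2.0], size=n, p=probs)
    if continuous:
        d = np.clip(d + rng.normal(0.0, 0.1, size=n), 0.0, 2.0)
    return d


def simulate_traits(
    dosages: pd.DataFrame | np.ndarray,
    obesity_flags: np.ndarray,
    config: SimulationConfig,
    seed=None,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (glucose, insulin) given genotypes and obesity stratum.

    Glucose: stratum-median truncated normal plus the centered genetic
    contribution sum_j a_j (d_j - 2 p_j).  Centering keeps the stratum
    medians at their calibration targets whatever the panel's allele
    frequencies; per-allele contrasts (path a) are unaffected.  Insulin:
    stratum log-normal, genetics-free by default.  HOMA-IR is always
    derived, never drawn.
    """
    obesity_flags = np.asarray(obesity_flags)
    if isinstance(dosages, pd.DataFrame):
        snp_ids = list(dosages.columns)
        D = dosages.to_numpy(dtype=float)
    else:
        D = np.atleast_2d(np.asarray(dosages, dtype=float))
        if D.shape[0] != len(obesity_flags) and D.shape[1] == len(obesity_flags):
            D = D.T
        snp_ids = [s.snp_id for s in config.snps[: D.shape[1]]]
    n = len(obesity_flags)
    if D.shape[0] != n:
        raise ValueError("dosages and obesity_flags are not conformable")

    freqs = {s.snp_id: s.effect_allele_freq for s in config.snps}
    genetic = np.zeros(n)
    for j, sid in enumerate(snp_ids):
        a = config.a_effects.get(sid, 0.0)
        if a:
            genetic += a * (D[:, j] - 2 * freqs.get(sid, 0.0))

    gp = config.trait_params["glucose"]
    ip = config.trait_params["insulin"]
    rng = _rng(seed if seed is not None else config.seed)

    base = np.where(obesity_flags == 1, gp["obese"]["median"], gp["non_obese"]["median"])
    sd = np.where(obesity_flags == 1, gp["obese"]["sd"], gp["non_obese"]["sd"])
    glucose = base + genetic
    if noise:
        glucose = glucose + rng.normal(0.0, 1.0, n) * sd
    glucose = np.maximum(glucose, gp.get("floor", 40.0))

    med = np.where(obesity_flags == 1, ip["obese"]["median"], ip["non_obese"]["median"])
    sig = np.where(obesity_flags == 1, ip["obese"]["sigma"], ip["non_obese"]["sigma"])
    if noise:
        insulin = med * np.exp(rng.normal(0.0, 1.0, n) * sig)
    else:
        insulin = med.astype(float).copy()
    return glucose, insulin


def simulate_survival(
    linear_predictor: np.ndarray,
    baseline_rate: float,
    admin_censor_years: float,
    seed,
    weibull_shape: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-transform proportional-hazards event times.

    Latent time solves the cumulative hazard equation
    ``(rate * T)^shape * exp(eta) = -ln U``; shape 1 (default) is the
    exponential special case T = -ln(U) / (rate * exp(eta)).  Follow-up is
    min(T, censor) with event = 1 iff T <= censor.
    """
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    if admin_censor_years <= 0:
        raise ValueError("admin_censor_years must be positive")
    eta = np.asarray(linear_predictor, dtype=float)
    rng = _rng(seed)
    u = rng.uniform(size=eta.shape)
    latent = (-np.log(u) / np.exp(eta)) ** (1.0 / weibull_shape) / baseline_rate
    event = (latent <= admin_censor_years).astype(int)
    followup = np.minimum(latent, admin_censor_years)
    # guard against zero follow-up from numerically tiny latent times
    followup = np.maximum(followup, 1e-9)
    return followup, event


def _draw_covariates(n, specs, rng):
    cols = {}
    for name, spec in specs.items():
        if spec["kind"] == "normal":
            v = rng.normal(spec["mean"], spec["sd"], n)
            v = np.clip(v, spec.get("lo", -np.inf), spec.get("hi", np.inf))
        elif spec["kind"] == "bernoulli":
            v = rng.binomial(1, spec["p"], n).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {spec['kind']!r}")
        cols[name] = v
    return cols


def _draw_adiposity(n, obese, rng):
    """BMI, waist, waist-to-hip and lifestyle variables by obesity stratum."""
    bmi = np.where(
        obese == 1,
        30.0 + 0.5 + np.abs(rng.normal(0.0, 3.5, n)),
        30.0 - 0.5 - np.abs(rng.normal(0.0, 4.0, n)),
    )
    bmi = np.clip(bmi, 16.0, 60.0)
    waist = np.where(obese == 1, rng.normal(100.0, 10.0, n), rng.normal(81.0, 8.0, n))
    waist = np.clip(waist, 50.0, 192.0)
    whr = np.where(obese == 1, rng.normal(0.849, 0.06, n), rng.normal(0.798, 0.06, n))
    whr = np.clip(whr, 0.34, 1.9)
    # calibrated so P(MET >= 10) ~ 49% non-obese / 32% obese
    met_med = np.where(obese == 1, 6.5, 9.8)
    met = met_med * np.exp(rng.normal(0.0, 1.0, n) * 0.9)
    fat = np.where(obese == 1, rng.normal(35.4, 7.0, n), rng.normal(33.0, 7.0, n))
    fat = np.clip(fat, 5.0, 75.0)
    return bmi, waist, whr, met, fat


def assemble_cohort(config: SimulationConfig) -> Cohort:
    """Generate a complete cohort under one configuration.

    Deterministic given ``config.seed``: every sub-generator receives a
    child seed spawned from the master ``SeedSequence``.
    """
    n = config.n_subjects
    ss = np.random.SeedSequence(config.seed)
    keys = ["obesity", "covariates", "adiposity", "traits", "survival", "genotypes"]
    child = dict(zip(keys, ss.spawn(len(keys))))

    obese = _rng(child["obesity"]).binomial(1, config.obesity_prevalence, n)

    geno_seeds = child["genotypes"].spawn(len(config.snps))
    dosages = {
        s.snp_id: simulate_genotypes(s, n, gs, continuous=config.continuous_dosage)
        for s, gs in zip(config.snps, geno_seeds)
    }
    D = pd.DataFrame(dosages)

    glucose, insulin = simulate_traits(D, obese, config, seed=child["traits"])
    homa = homa_ir(glucose, insulin)

    cov_rng = _rng(child["covariates"])
    covs = _draw_covariates(n, config.covariate_specs, cov_rng)
    bmi, waist, whr, met, fat = _draw_adiposity(n, obese, _rng(child["adiposity"]))

    eta = config.b_loghr * glucose + config.obesity_loghr * obese
    for sid, g in config.gamma_direct_loghr.items():
        if g:
            eta = eta + g * D[sid].to_numpy()
    for name, spec in config.covariate_specs.items():
        lh = spec.get("loghr", 0.0)
        if lh:
            center = spec.get("mean", spec.get("p", 0.0))
            eta = eta + lh * (covs[name] - center)

    followup, event = simulate_survival(
        eta,
        config.baseline_rate,
        config.admin_censor_years,
        child["survival"],
        weibull_shape=config.weibull_shape,
    )

    df = pd.DataFrame({"subject_id": [f"S{i:06d}" for i in range(n)]})
    for sid in D.columns:
        df[sid] = D[sid]
    df["glucose"] = glucose
    df["insulin"] = insulin
    df["homa_ir"] = homa
    df["bmi"] = bmi
    df["waist"] = waist
    df["whr"] = whr
    df["met_hours"] = met
    df["pct_fat_calories"] = fat
    df["obese"] = obese
    for name, v in covs.items():
        df[name] = v
    df["followup_years"] = followup
    df["event_breast"] = event if config.outcome == "breast" else 0
    df["event_crc"] = event if config.outcome == "crc" else 0

    truth = {
        "a_effects": dict(config.a_effects),
        "b_loghr": config.b_loghr,
        "gamma_direct_loghr": dict(config.gamma_direct_loghr),
        "obesity_loghr": config.obesity_loghr,
        "baseline_rate": config.baseline_rate,
        "obesity_prevalence": config.obesity_prevalence,
        "outcome": config.outcome,
        "seed": config.seed,
    }
    return Cohort(data=df, snps=list(config.snps), truth=truth)


# ---------------------------------------------------------------------------
# writers

def write_phenotypes(cohort: Cohort, path) -> None:
    """Tab-delimited phenotype table with a header row (dosages included)."""
    cohort.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_dosage_matrix(cohort_or_df, path, snp_ids=None) -> None:
    """Plain dosage matrix: sample ID column then one column per rsID."""
    if isinstance(cohort_or_df, Cohort):
        df = cohort_or_df.data
        snp_ids = snp_ids or cohort_or_df.dosage_columns()
    else:
        df = cohort_or_df
        if snp_ids is None:
            raise ValueError("snp_ids required with a bare DataFrame")
    out = df[["subject_id"] + list(snp_ids)].rename(columns={"subject_id": "sample_id"})
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_vcf(cohort: Cohort, path, contig: str = "1") -> None:
    """Minimal VCF v4.2: GT hard calls, DS carries the (possibly
    continuous) effect-allele dosage.  ALT is the effect allele, so DS
    counts ALT copies.  Placeholder positions; the analysis is
    position-free."""
    df = cohort.data
    samples = df["subject_id"].tolist()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for i, snp in enumerate(cohort.snps):
            d = df[snp.snp_id].to_numpy(dtype=float)
            hard = np.clip(np.rint(d), 0, 2).astype(int)
            gt = np.choose(hard, ["0/0", "0/1", "1/1"])
            cells = [f"{g}:{x:.6f}" for g, x in zip(gt, d)]
            fh.write(
                f"{contig}\t{1000 * (i + 1)}\t{snp.snp_id}\t{snp.other_allele}\t"
                f"{snp.effect_allele}\t.\tPASS\t.\tGT:DS\t" + "\t".join(cells) + "\n"
            )
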