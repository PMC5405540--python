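# Methods

## Model and estimands

Let D be the effect-allele dosage of one SNP, M a glycemic mediator
(fasting glucose in mg/dl, fasting insulin in μIU/ml, or HOMA-IR =
glucose × insulin / 405), T the time from enrollment to cancer or
censoring in years, and Z a covariate vector. Two proportional-hazards
models are fit by partial likelihood:

    h(t | D, Z)    = h0(t) exp(C·D + ζ'Z)          (total)
    h(t | D, M, Z) = h0'(t) exp(C'·D + b·M + ζ''Z)  (direct)

C and C′ are reported as hazard ratios per allele. The a-path is ordinary
least squares of M on D and Z; the indirect effect is the product a·b on
the log-hazard scale, with a percentile bootstrap (subjects resampled with
replacement; both stages refit per replicate; 2.5/97.5 percentiles) for
its interval. The proportion mediated is the percentage change of the SNP
HR upon adjusting for M, relative to the total excess HR:
100 · |HR_total − HR_direct| / (HR_total − 1), with the same formula and an
overall absolute value for protective SNPs (HR_total < 1), and cells above
100% rendered "N/A (>100%)".

Assumptions: no unmeasured exposure–outcome, exposure–mediator or
mediator–outcome confounding given Z; no exposure–mediator interaction
(none is modelled); proportional hazards for every term (checked, below).
Because the hazard ratio is non-collapsible, ln C − ln C′ and a·b estimate
the same pathway but agree only approximately; the discrepancy shrinks as
the outcome becomes rare, and the test suite bounds the relative gap at
25% for <10% incidence at n = 10000. Counterfactual (natural-effect)
estimands are deliberately out of scope.

## Cox engine

Newton–Raphson maximization of the partial likelihood with the Efron tie
approximation (Breslow optional; the two are verified to agree to 1e-10
when event times are distinct). Convergence when the largest coefficient
update falls below 1e-8, at most 50 iterations, with step-halving so the
partial log-likelihood never decreases. Coefficients diverging past |β| >
50 raise a monotone-likelihood (separation) error naming the term.
Standard errors come from the inverse observed information; CIs and
p-values are Wald. Columns are internally centered for conditioning
(coefficients are shift-invariant). The proportional-hazards check
computes per-event Schoenfeld residuals, scales by the averaged risk-set
covariance, and correlates with the rank of event time (rho); per-term
1-df and global chi-square score tests follow the Grambsch–Therneau form
with the rank transform. Type-I error of the global test is verified at
4–7% over 500 proportional-hazards replicates.

## a-path and covariate screening

OLS through statsmodels with normal-approximation CIs (estimate ± 1.96 SE;
indistinguishable from t at cohort n). Covariate reduction follows the
conventional three stages: univariate screen at p < 0.20, backward
stepwise by AIC, then iterative VIF pruning at VIF > 10. All three
thresholds are arguments; the defaults are the field's conventions, since
no sharper prescription exists for this procedure.

## Stratification and interaction

Five dichotomies with fixed boundary membership: BMI ≥ 30 obese; waist >
88 cm obese (88 itself non-obese); w/h > 0.85 obese; MET ≥ 10 favorable;
fat ≥ 40% of calories unfavorable. Within-stratum analyses adjust for the
non-evaluated effect modifiers (physical activity, BMI, w/h ratio) as
covariates, except that w/h is dropped when stratifying by waist (the two
are near-collinear measures of central adiposity); a covariate audit log
records the roster per cell. Effect modification is tested by the Wald
p-value of a SNP × stratum product term in a pooled Cox model — the
convention that yields a log-hazard-scale interaction effect size. A
difference-of-coefficients test across separately fitted strata is the
documented alternative; it is asymptotically equivalent under equal
baseline hazards. No multiple-testing adjustment is applied anywhere, by
design; two-tailed α = 0.05 throughout.

## Synthetic cohort generator

What it emulates: a postmenopausal cohort of default size 5379 with ~32%
obesity; 16 biallelic SNPs in Hardy–Weinberg equilibrium at European-like
frequencies (hard calls by default; a Gaussian-smear continuous-dosage
option emulates imputation); glycemic traits by obesity stratum — glucose
truncated normal (medians 92/97 mg/dl, sd 13/16, floor 40), insulin
log-normal (medians 5.5/9.8 μIU/ml, log-sd 0.55/0.50, right-skewed as
observed ranges suggest); HOMA-IR always derived, never drawn; a reduced
covariate battery (age, education, family history of diabetes,
hypertension, current smoking) plus adiposity/lifestyle variables with
stratum-dependent distributions calibrated to the published
dichotomy prevalences; exponential event times via inverse transform
(Weibull shape exposed) with administrative censoring at 16 years and a
baseline rate of 0.00127/yr yielding ~5%/8% non-obese/obese cumulative
incidence.

Two deliberate modelling choices:

- The genetic trait contribution is centered, M = stratum baseline +
  Σ a_j (d_j − 2p_j) + noise, so stratum medians stay at their calibration
  targets for any panel; per-allele contrasts — the a-path — are
  unaffected.
- The linear predictor uses the raw mediator term b·M (not centered), so
  the event count is monotone in b under common random numbers; the
  default baseline rate absorbs exp(b · typical glucose).

What it does not emulate: linkage disequilibrium (SNPs are independent, as
they are analyzed marginally), competing risks (one outcome per run; the
other outcome column is zero), assay measurement error, the full
29-covariate battery, informative censoring, or any obesity–genotype
dependence (allele frequencies are identical across strata). Passing
tests therefore demonstrate correctness of the estimators under the
stated causal structure, not robustness to those real-data features.

Default a-effects give the focal SNP rs560887 a = 2 mg/dl per allele and
background SNPs 0.5; the default b is 0.01 log-hazard per mg/dl of
glucose and all direct effects γ are 0, so the default cohort carries a
small, fully mediated genetic signal. Obesity contributes 0.45 log-hazard
directly (plus its pathway through glucose), reproducing the 5%→8%
incidence contrast.

All randomness flows from one master seed through
`numpy.random.SeedSequence` spawning, in a fixed order; identical
config + seed reproduces cohorts and report tables byte for byte.

## Numerical and procedural details

- Dominant coding thresholds continuous dosages at 0.5 (any appreciable
  imputed dose counts as carrier); additive coding is the dosage itself.
- HWE QC uses the 1-df chi-square on hard calls (continuous dosages
  rounded), threshold p ≥ 1e-4; missingness threshold 2%. An exact test is
  a noted alternative but the chi-square matches the screening convention
  and is stable at these n.
- Allele orientation: a site whose REF/ALT pair is swapped relative to the
  panel definition is flipped (dosage → 2 − dosage) with a logged note;
  a pair matching neither orientation is an error naming the site.
- Subjects followed under 1 year are excluded at the pipeline stage (not
  inside the engine), with counts reconciled in the run manifest.
- Bootstrap: percentile intervals (BCa noted as an option), subjects
  resampled unstratified; a run aborts if more than 10% of replicates fail
  to converge. Default 1000 replicates in the pipeline; heavy simulation
  tests use 200.
- Degenerate inputs: rank-deficient designs raise errors naming the
  collinear terms; HR_total = 1 makes the proportion mediated undefined
  (division by zero) and is reported as such.

## Problem sizes used by the test suite

Oracle and invariance checks run at n ≤ 6–6000 in seconds. Calibration
checks use: 500 OLS replicates at n = 2000 (CI coverage 93–97%); 500
proportional-hazards replicates at n = 500 (Schoenfeld type-I 4–7%); 200
outer replicates at n = 1500 with 200 bootstrap draws (indirect-effect
type-I ≈ 95% coverage of 0); 25 replicates at n = 5000 (power ≥ 80% under
a = 2, b = 0.02); 10 replicates at n = 10000 (difference/product
consistency); simulator calibration at n = 20000. These sizes were chosen
to keep Monte-Carlo error comfortably inside each test's tolerance.

## Known limitations

The percentage-change proportion is unstable when HR_total ≈ 1 and is not
comparable across strata with different baseline risks; the indirect a·b
treats the mediator model as linear and homoscedastic; non-collapsibility
means the two mediation routes differ systematically (if slightly) even
in the rare-event limit; and the pooled product-term interaction model
assumes shared baseline hazards across strata.
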