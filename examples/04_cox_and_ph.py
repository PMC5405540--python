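"""Fit a Cox proportional-hazards model and test the PH assumption.

The generator is proportional-hazards by construction, so the Schoenfeld
rank test should not signal a violation beyond its 5% type-I rate.
"""

from coxmediate import SimulationConfig, assemble_cohort, fit_cox, schoenfeld_test
from coxmediate.synthetic import default_snp_panel

df = assemble_cohort(
    SimulationConfig(n_subjects=6000, seed=4, snps=default_snp_panel()[:1],
                     baseline_rate=0.004)
).data

terms = ["glucose", "obese", "age"]
X = df[terms].to_numpy()
fit = fit_cox(df["followup_years"], df["event_breast"], X, terms=terms)
for j, t in enumerate(fit.terms):
    print(f"{t:>8}: HR {fit.hr[j]:.4f} (95% CI {fit.hr_ci95[j,0]:.4f}-{fit.hr_ci95[j,1]:.4f})"
          f"  p={fit.p_values[j]:.3g}")
print(f"events {fit.n_events}/{fit.n_used}, converged in {fit.iterations} iterations")

ph = schoenfeld_test(fit, df["followup_years"], df["event_breast"], X)
for j, t in enumerate(ph.terms):
    print(f"PH check {t:>8}: rho={ph.rho[j]:+.3f}, p={ph.p[j]:.2f}")
print(f"global PH p = {ph.global_p:.2f}")
# Glucose carries the generating log-hazard 0.01/mg-dl (HR ~1.010); the PH
# p-values should be unremarkable since hazards are proportional by design.
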