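"""Write genotypes to a minimal VCF, read them back, and run the QC screen.

QC drops SNPs with missing call rate >= 2% or Hardy-Weinberg chi-square
p < 1e-4 (hard calls, 1 df); the report lists every SNP's metrics.
"""

import tempfile
from pathlib import Path

import numpy as np

from coxmediate import SimulationConfig, assemble_cohort, qc_filter, read_genotypes
from coxmediate.synthetic import default_snp_panel, write_vcf

cohort = assemble_cohort(
    SimulationConfig(n_subjects=2000, seed=2, snps=default_snp_panel()[:4])
)
with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "panel.vcf"
    write_vcf(cohort, vcf)
    panel = read_genotypes(vcf, cohort.snps, format="vcf")

# inject a failing SNP: 5% missing calls
panel.dosages.iloc[:100, 0] = np.nan
filtered, report = qc_filter(panel)

print(report.to_string(index=False))
print(f"\nretained {len(filtered.snps)} of {len(panel.snps)} SNPs")
# The first SNP fails the missingness screen; the rest pass with HWE p >> 1e-4
# and estimated effect-allele frequencies near their generating values.
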