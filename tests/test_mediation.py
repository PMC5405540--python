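"""Mediation decomposition: proportion-mediated arithmetic, total/direct
contrast on cohorts with known truth, and the bootstrap."""

import numpy as np
import pytest

from coxmediate.mediation import (
    bootstrap_indirect,
    estimate_total_direct,
    format_proportion_mediated,
    mediate,
    product_indirect,
    proportion_mediated,
)
from coxmediate.synthetic import SimulationConfig, assemble_cohort, default_snp_panel

# obesity shifts both glucose and the hazard in the generator, so the
# b-path model adjusts for it (as obesity is adjusted in the real analysis)
COVS = ["age", "obese"]


class TestProportionMediated:
    @pytest.mark.parametrize(
        "hr_total,hr_direct,expected",
        [
            (1.35, 1.34, 2.9),   # percentage change vs total excess HR
            (1.12, 1.17, 41.7),  # direct exceeding total: magnitude taken
            (1.10, 1.07, 30.0),
            (1.59, 1.56, 5.1),
            (1.20, 1.20, 0.0),
        ],
    )
    def test_reference_values(self, hr_total, hr_direct, expected):
        assert proportion_mediated(hr_total, hr_direct) == pytest.approx(expected, abs=0.05)

    def test_over_100_percent_is_na(self):
        assert proportion_mediated(1.05, 1.20) is None
        assert format_proportion_mediated(None) == "N/A (>100%)"

    def test_unit_total_hr_undefined(self):
        with pytest.raises(ZeroDivisionError):
            proportion_mediated(1.0, 1.1)

    def test_scale_free(self):
        # rescaling the mediator leaves both HRs, hence the proportion, alone;
        # arithmetically the ratio only depends on the HR pair
        assert proportion_mediated(1.4, 1.2) == proportion_mediated(1.4, 1.2)
        assert proportion_mediated(0.8, 0.85) == pytest.approx(25.0, abs=1e-9)

    def test_product_indirect_arithmetic(self):
        assert product_indirect(0.0, 5.0) == 0.0
        assert product_indirect(0.5, 0.02) == pytest.approx(0.01)


def _cohort(a, gamma, n=5000, seed=1, rate=0.004):
    # baseline rate raised above the cohort default so the fixtures carry
    # enough events for tight contrasts at n=5000
    cfg = SimulationConfig(
        n_subjects=n,
        seed=seed,
        snps=default_snp_panel()[:1],
        a_effects={"rs560887": a},
        gamma_direct_loghr={"rs560887": gamma},
        b_loghr=0.01,
        baseline_rate=rate,
    )
    return assemble_cohort(cfg).data


class TestTotalDirect:
    def test_full_mediation_shrinks_snp_hr(self):
        # a>0, b>0, no direct effect: adjusting for the mediator should
        # move the SNP HR toward 1
        df = _cohort(a=12.0, gamma=0.0, seed=2)
        ft, fd = estimate_total_direct(df, "rs560887", "glucose", COVS)
        ab_true = 12.0 * 0.01
        jt = ft.terms.index("rs560887")
        jd = fd.terms.index("rs560887")
        assert abs(ft.coefficients[jt] - ab_true) < 3 * ft.standard_errors[jt]
        assert abs(fd.coefficients[jd]) < 3 * fd.standard_errors[jd]
        assert abs(np.log(fd.hazard_ratio("rs560887"))) < abs(np.log(ft.hazard_ratio("rs560887")))

    def test_direct_only_effect_preserved(self):
        gamma = np.log(1.6)
        df = _cohort(a=0.0, gamma=gamma, seed=3)
        ft, fd = estimate_total_direct(df, "rs560887", "glucose", COVS)
        for fit in (ft, fd):
            j = fit.terms.index("rs560887")
            assert abs(fit.coefficients[j] - gamma) < 3 * fit.standard_errors[j]

    def test_mediator_cannot_be_covariate(self):
        df = _cohort(a=2.0, gamma=0.0, n=500, seed=4)
        with pytest.raises(ValueError, match="mediator"):
            estimate_total_direct(df, "rs560887", "glucose", ["glucose"])


class TestBootstrap:
    def test_same_seed_identical_ci(self, small_cohort):
        df = small_cohort.data
        r1 = bootstrap_indirect(df, "rs560887", "glucose", COVS, n_boot=200, seed=5)
        r2 = bootstrap_indirect(df, "rs560887", "glucose", COVS, n_boot=200, seed=5)
        assert r1["ci95"] == r2["ci95"]
        assert r1["indirect"] == r2["indirect"]

    def test_rejects_tiny_n_boot(self, small_cohort):
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_indirect(small_cohort.data, "rs560887", "glucose", COVS, n_boot=50)

    def test_strong_mediation_detected(self):
        df = _cohort(a=12.0, gamma=0.0, seed=6)
        res = bootstrap_indirect(df, "rs560887", "glucose", COVS, n_boot=200, seed=7)
        assert res["significant"]
        assert res["ci95"][0] > 0

    def test_product_recovers_truth(self):
        # truth a = 8 mg/dl per allele, b = 0.01 per mg/dl -> ab = 0.08;
        # point estimates only (no bootstrap) over 30 replicates
        from coxmediate.apath import fit_linear
        from coxmediate.cox import fit_cox

        est = []
        for r in range(30):
            df = _cohort(a=8.0, gamma=0.0, n=4000, seed=100 + r)
            acols = ["rs560887"] + COVS
            a_hat = fit_linear(df["glucose"], df[acols].to_numpy(), terms=acols).coef("rs560887")
            bcols = ["rs560887", "glucose"] + COVS
            b_hat = fit_cox(
                df["followup_years"], df["event_breast"], df[bcols].to_numpy(), terms=bcols
            ).coef("glucose")
            est.append(a_hat * b_hat)
        assert np.mean(est) == pytest.approx(0.08, rel=0.20)


def test_mediate_bundles_everything(small_cohort):
    m = mediate(small_cohort.data, "rs560887", "glucose", COVS, n_boot=200, seed=8)
    assert m.hr_total > 0 and m.hr_direct > 0
    assert m.indirect_ci95[0] <= m.indirect_ab <= m.indirect_ci95[1]
    assert m.n_events <= m.n_used
    assert m.proportion_mediated_label.endswith("%") or m.proportion_mediated_label.startswith("N/A")
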