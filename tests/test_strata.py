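"""Stratification presets, boundary membership, interaction tests and the
stratified mediation cross."""

import numpy as np
import pandas as pd
import pytest

from coxmediate.strata import (
    STRATA_PRESETS,
    StratumSpec,
    assign_strata,
    covariate_roster,
    interaction_test,
    run_stratified_mediation,
)
from coxmediate.synthetic import SimulationConfig, assemble_cohort, default_snp_panel


class TestAssignStrata:
    @pytest.mark.parametrize(
        "variable,value,expected_unfavorable",
        [
            ("bmi", 30.0, 1),            # BMI 30 is obese
            ("bmi", 29.99, 0),
            ("waist", 88.0, 0),          # waist <= 88 is non-obese
            ("waist", 88.01, 1),
            ("whr", 0.85, 0),            # w/h <= 0.85 is non-obese
            ("whr", 0.851, 1),
            ("met_hours", 10.0, 0),      # MET >= 10 is favorable
            ("met_hours", 9.99, 1),
            ("pct_fat_calories", 40.0, 1),  # >= 40% fat is unfavorable
            ("pct_fat_calories", 39.99, 0),
        ],
    )
    def test_boundary_membership(self, variable, value, expected_unfavorable):
        df = pd.DataFrame({variable: [value]})
        lab = assign_strata(df, STRATA_PRESETS[variable])
        assert lab.iloc[0] == expected_unfavorable

    def test_partition_with_missing_logged(self):
        df = pd.DataFrame({"bmi": [25.0, 35.0, np.nan, 31.0]})
        lab = assign_strata(df, STRATA_PRESETS["bmi"])
        assert np.nansum(lab == 0) + np.nansum(lab == 1) == 3
        assert np.isnan(lab.iloc[2])

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            StratumSpec("cholesterol", 1.0, "above", ("a", "b"))
        with pytest.raises(ValueError):
            StratumSpec("bmi", 30.0, "above", ("same", "same"))

    def test_obese_stratum_has_higher_glucose(self, default_cohort):
        df = default_cohort.data
        lab = assign_strata(df, STRATA_PRESETS["bmi"])
        assert df.glucose[lab == 1].median() > df.glucose[lab == 0].median()


class TestCovariateRoster:
    def test_modifiers_adjusted_when_not_stratified(self):
        base = ["age"]
        assert set(covariate_roster(base, "bmi")) == {"age", "met_hours", "whr"}
        assert set(covariate_roster(base, "met_hours")) == {"age", "bmi", "whr"}
        assert set(covariate_roster(base, "pct_fat_calories")) == {"age", "met_hours", "bmi", "whr"}

    def test_whr_dropped_when_stratifying_by_waist(self):
        roster = covariate_roster(["age"], "waist")
        assert "whr" not in roster
        assert set(roster) == {"age", "met_hours", "bmi"}


def _interaction_cohort(loghr0, loghr1, n=6000, seed=5):
    """Cohort with a SNP whose log-HR differs by obesity stratum."""
    rng = np.random.default_rng(seed)
    snp = rng.binomial(2, 0.3, n).astype(float)
    stratum = rng.binomial(1, 0.4, n).astype(float)
    eta = np.where(stratum == 1, loghr1, loghr0) * snp
    latent = rng.exponential(1.0 / (0.01 * np.exp(eta)))
    c = np.full(n, 16.0)
    return pd.DataFrame(
        {
            "snp": snp,
            "stratum_var": stratum,
            "age": rng.normal(67, 7, n),
            "followup_years": np.minimum(latent, c),
            "event_breast": (latent <= c).astype(float),
        }
    )


class TestInteraction:
    def test_null_product_term_near_zero(self):
        df = _interaction_cohort(np.log(1.3), np.log(1.3))
        res = interaction_test(df, "snp", df["stratum_var"], ["age"])
        assert abs(res.effect_size) < 3 * res.se

    def test_recovers_differential_effect(self):
        df = _interaction_cohort(0.0, np.log(1.6))
        res = interaction_test(df, "snp", df["stratum_var"], ["age"])
        assert abs(res.effect_size - np.log(1.6)) < 3 * res.se
        assert res.p_value < 0.05

    def test_permuted_labels_calibrate_at_5pct(self):
        df = _interaction_cohort(np.log(1.4), np.log(1.4), n=3000)
        rng = np.random.default_rng(9)
        rej = 0
        reps = 100
        for _ in range(reps):
            perm = pd.Series(rng.permutation(df["stratum_var"].to_numpy()))
            res = interaction_test(df, "snp", perm, ["age"])
            rej += res.p_value < 0.05
        assert 0.0 <= rej / reps <= 0.11

    def test_empty_stratum_rejected(self):
        df = _interaction_cohort(0.0, 0.0, n=200)
        all_one = pd.Series(np.ones(len(df)))
        with pytest.raises(ValueError, match="no events"):
            interaction_test(df, "snp", all_one, ["age"])


class TestStratifiedCross:
    @pytest.fixture(scope="class")
    def cross(self):
        cfg = SimulationConfig(
            n_subjects=3000, seed=77, snps=default_snp_panel()[:2],
            baseline_rate=0.004,
        )
        table = assemble_cohort(cfg).data
        return run_stratified_mediation(
            table,
            snps=["rs560887", "rs780094"],
            mediators=["glucose", "homa_ir"],
            covariates=["age"],
            strata=[STRATA_PRESETS["bmi"]],
            n_boot=200,
            seed=123,
        )

    def test_cell_count(self, cross):
        results, interactions, audit = cross
        # 2 SNPs x 2 mediators x 2 strata sides
        assert len(results) == 8
        assert len(interactions) == 2
        assert audit.loc[0, "stratum_variable"] == "bmi"

    def test_roster_audit_matches_rule(self, cross):
        _, _, audit = cross
        covs = audit.loc[0, "covariates"].split(",")
        assert "met_hours" in covs and "whr" in covs and "bmi" not in covs

    def test_deterministic_under_master_seed(self):
        cfg = SimulationConfig(
            n_subjects=1500, seed=78, snps=default_snp_panel()[:1], baseline_rate=0.004
        )
        table = assemble_cohort(cfg).data
        kwargs = dict(
            snps=["rs560887"], mediators=["glucose"], covariates=["age"],
            strata=[STRATA_PRESETS["bmi"]], n_boot=200, seed=5,
        )
        r1, _, _ = run_stratified_mediation(table, **kwargs)
        r2, _, _ = run_stratified_mediation(table, **kwargs)
        assert [m.indirect_ci95 for m in r1] == [m.indirect_ci95 for m in r2]
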