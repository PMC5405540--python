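import numpy as np
import pandas as pd
import pytest

from coxmediate import SimulationConfig, assemble_cohort, default_snp_panel


@pytest.fixture(scope="session")
def small_cohort():
    """Two-SNP cohort with a strong mediated path for mediation tests."""
    panel = default_snp_panel()[:2]
    cfg = SimulationConfig(
        n_subjects=3000,
        seed=42,
        snps=panel,
        a_effects={"rs560887": 2.0, "rs780094": 0.0},
        gamma_direct_loghr={},
    )
    return assemble_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-panel cohort at the default calibration."""
    cfg = SimulationConfig(n_subjects=5379, seed=7)
    return assemble_cohort(cfg)


def simulate_ph_data(rng, n, beta, rate=0.05, censor=(1.0, 16.0)):
    """Exponential PH data with standard-normal covariates; returns
    (time, event, X)."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = rng.normal(size=(n, beta.size))
    eta = X @ beta
    latent = rng.exponential(1.0 / (rate * np.exp(eta)))
    c = rng.uniform(*censor, size=n)
    time = np.minimum(latent, c)
    event = (latent <= c).astype(float)
    return time, event, X
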