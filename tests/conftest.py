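import numpy as np
import pandas as pd
import pytest

from collidermr.simulate import (
    SimulationConfig,
    simulate_mediation_cohort,
    simulate_two_exposure_cohort,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def strong_two_exposure():
    """One strong-instrument, no-pleiotropy two-exposure cohort."""
    cfg = SimulationConfig(
        n_individuals=4000,
        n_snps_per_exposure=20,
        gamma_scale=0.25,
        beta_x1=1.0,
        beta_x2=0.5,
        confounder_effects=(0.5, 0.5, 0.5),
        seed=7,
    )
    geno, cohort, truth = simulate_two_exposure_cohort(cfg)
    return geno, cohort, truth


@pytest.fixture(scope="session")
def strong_mediation():
    """One strong-instrument mediation cohort with true pi_m = 0.5."""
    cfg = SimulationConfig(
        n_individuals=5000,
        n_snps_per_exposure=15,
        gamma_scale=0.25,
        beta_xy_direct=0.2,
        beta_xm=0.5,
        beta_my=0.4,
        confounder_effects=(0.3, 0.3, 0.3),
        seed=11,
    )
    geno, cohort, truth = simulate_mediation_cohort(cfg)
    return geno, cohort, truth


def snp_columns(geno, ids):
    """Dosage sub-matrix for a list of variant ids."""
    return geno.values(list(ids))
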