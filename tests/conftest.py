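import numpy as np
import pandas as pd
import pytest

from scexome import ErrorRates, SimConfig, simulate_observations, \
    simulate_population, simulate_tissue_normal


@pytest.fixture(scope="session")
def study_rates():
    """The study's error operating point: ADO 0.41, FDR 6.7e-5."""
    return ErrorRates(ado_het=0.41, fdr=6.7e-5)


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_tumor_cells=12, n_normal_cells=5,
                     n_ancestral_muts=6, n_cloneB_muts=3, n_cloneC_muts=4,
                     n_neutral_tail_muts=30, n_germline_het_sites=400,
                     n_hom_background_sites=600, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_population(small_config)


@pytest.fixture(scope="session")
def small_obs(small_truth):
    return simulate_observations(small_truth)


@pytest.fixture(scope="session")
def small_tissue(small_truth):
    return simulate_tissue_normal(small_truth)


@pytest.fixture(scope="session")
def noise_free_config():
    return SimConfig(n_tumor_cells=10, n_normal_cells=4,
                     n_ancestral_muts=5, n_cloneB_muts=2, n_cloneC_muts=3,
                     n_neutral_tail_muts=15, n_germline_het_sites=200,
                     n_hom_background_sites=200, ado_het=0.0, ado_hom=0.0,
                     fdr_per_site=0.0, per_read_error=0.0,
                     coverage_fraction=1.0, seed=5)


@pytest.fixture(scope="session")
def noise_free_truth(noise_free_config):
    return simulate_population(noise_free_config)


@pytest.fixture(scope="session")
def noise_free_obs(noise_free_truth):
    return simulate_observations(noise_free_truth)
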