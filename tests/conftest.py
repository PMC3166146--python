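import math

import numpy as np
import pytest

from cissat import SimulationConfig, simulate_cohort
from cissat.simulate import DEFAULT_PATTERN_PROBS


def null_pattern_probs() -> dict[str, float]:
    probs = {p: 0.0 for p in DEFAULT_PATTERN_PROBS}
    probs["none"] = 1.0
    return probs


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Desk-size cohort with the default effect architecture."""
    return SimulationConfig(n_individuals=120, n_snps=300, n_transcripts=40,
                            chrom_length_bp=5_000_000, seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def strong_config() -> SimulationConfig:
    """Near-noiseless cohort: every causal effect is detectable and the
    lead SNP should coincide with the causal SNP (no LD, huge effects)."""
    return SimulationConfig(n_individuals=60, n_snps=200, n_transcripts=30,
                            chrom_length_bp=5_000_000, ld_rho=0.0,
                            effect_mu=math.log(2.0), effect_sigma=0.05,
                            noise_sd=1e-6, seed=11)


@pytest.fixture(scope="session")
def strong_cohort(strong_config):
    return simulate_cohort(strong_config)


@pytest.fixture(scope="session")
def null_config() -> SimulationConfig:
    """Cohort with no cis effects at all (every transcript pure noise)."""
    return SimulationConfig(n_individuals=200, n_snps=500, n_transcripts=100,
                            chrom_length_bp=12_500_000, ld_rho=0.0,
                            pattern_probs=null_pattern_probs(), seed=5)


@pytest.fixture(scope="session")
def null_cohort(null_config):
    return simulate_cohort(null_config)
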