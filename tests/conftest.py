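import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hlamm.hla import LOCI, AlleleSequenceStore, Genotype, Haplotype, HLAAllele
from hlamm.predictors import MockBindingPredictor
from hlamm.synthetic import (
    SimulationConfig,
    generate_allele_universe,
    generate_cohort,
    generate_ems3d_table,
    generate_haplotype_table,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_allele(name, seq, split=None, locus=None):
    from hlamm.hla import locus_of

    return HLAAllele(locus or locus_of(name), name, seq, split)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=11, n_patients=80)


@pytest.fixture(scope="session")
def universe(sim_config):
    return generate_allele_universe(sim_config)


@pytest.fixture(scope="session")
def haplotypes(universe, sim_config):
    return generate_haplotype_table(universe, sim_config)


@pytest.fixture(scope="session")
def ems3d(universe, sim_config):
    return generate_ems3d_table(universe, sim_config)


@pytest.fixture(scope="session")
def predictor(sim_config):
    return MockBindingPredictor(seed=sim_config.seed)


@pytest.fixture(scope="session")
def cohort(universe, haplotypes, ems3d, sim_config, predictor):
    return generate_cohort(universe, haplotypes, ems3d, sim_config, predictor)


@pytest.fixture(scope="session")
def genotype_pair(universe, haplotypes):
    """A (donor, recipient) genotype pair guaranteed to carry mismatches."""
    donor = Genotype.from_haplotypes(haplotypes[0], haplotypes[1])
    recipient = Genotype.from_haplotypes(haplotypes[2], haplotypes[3])
    return donor, recipient
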