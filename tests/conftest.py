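import numpy as np
import pytest

from polygs import simpop


@pytest.fixture(scope="session")
def small_config():
    """A compact polycross: 12 mothers x 6 fathers, clean observations."""
    return simpop.SimConfig(
        n_mothers=12,
        n_polymix_fathers=6,
        n_shared_parents=1,
        offspring_per_mother=10,
        n_snp=300,
        n_sites=2,
        n_blocks=2,
        contamination_rate=0.0,
        genotyping_error_rate=0.0,
        missing_rate=0.0,
        trait_specs=(simpop.TraitSpec("t", 0.3, 0.7, 100.0, 20.0),),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_polycross(small_config):
    parents = simpop.simulate_parents(small_config)
    offspring, ped = simpop.simulate_polycross(parents, small_config)
    return parents, offspring, ped


@pytest.fixture(scope="session")
def small_phenotypes(small_config, small_polycross):
    _, offspring, _ = small_polycross
    arch = simpop.build_architecture(offspring, small_config)
    traits, truth = simpop.simulate_phenotypes(
        offspring, arch, small_config, return_truth=True
    )
    return traits, truth, arch
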