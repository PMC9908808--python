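import numpy as np
import pytest

from promotermine.candidate_mining import mine_candidates
from promotermine.strength_quant import quantify_plate
from promotermine.synthetic_data import (
    SimConfig,
    generate_expression,
    generate_genome,
    generate_plate_reader,
)


@pytest.fixture(scope="session")
def config0():
    """Default study world, zero measurement noise."""
    return SimConfig(seed=1, fluor_cv=0.0, titer_cv=0.0)


@pytest.fixture(scope="session")
def world0(config0):
    return generate_genome(config0)


@pytest.fixture(scope="session")
def expression0(world0, config0):
    return generate_expression(world0, config0)


@pytest.fixture(scope="session")
def plate0(world0, config0):
    return generate_plate_reader(world0, config0)


@pytest.fixture(scope="session")
def profiles0(plate0):
    return quantify_plate(plate0)


@pytest.fixture(scope="session")
def candidates0(world0, expression0, config0):
    return mine_candidates(
        world0.genome, world0.genes, expression0, top_n=config0.top_n
    )


@pytest.fixture(scope="session")
def noisy_config():
    """Default study world with plate noise at the study's replicate CV."""
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def noisy_world(noisy_config):
    return generate_genome(noisy_config)


@pytest.fixture(scope="session")
def noisy_plate(noisy_world, noisy_config):
    return generate_plate_reader(noisy_world, noisy_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
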