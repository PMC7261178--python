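import pytest

import ighvkit as ik
from ighvkit.usage import CollapseMap


@pytest.fixture(scope="session")
def db():
    return ik.default_reference()


@pytest.fixture(scope="session")
def cmap(db):
    return CollapseMap.for_database(db)


@pytest.fixture(scope="session")
def zero_noise_cohort(db):
    """Small error-free, mutation-free cohort with full ground truth."""
    config = ik.SimConfig(
        germline_db=db,
        n_individuals=6,
        depth=ik.DepthLaw(kind="fixed", depth=600),
        mutation_probs=(1.0,),
        error_rate=0.0,
        seed=11,
    )
    table, truth = ik.simulate_cohort(config)
    return config, table, truth


@pytest.fixture(scope="session")
def noisy_cohort(db):
    """Cohort with mutations and uniform sequencing error."""
    config = ik.SimConfig(
        germline_db=db,
        n_individuals=4,
        depth=ik.DepthLaw(kind="fixed", depth=500),
        error_rate=0.005,
        seed=23,
    )
    table, truth = ik.simulate_cohort(config)
    return config, table, truth
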