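import numpy as np
import pytest

from cometdr.embedding import ConceptEmbedding, PatientTimeline
from cometdr.synthetic import SyntheticConfig, generate_cohorts


@pytest.fixture(scope="session")
def small_cohorts():
    """A small but fully structured (pretrain, discovery, validation) triple."""
    config = SyntheticConfig(
        seed=7,
        n_pretrain=80,
        n_discovery=60,
        n_discovery_cases=9,
        n_validation=70,
        n_validation_cases=10,
        n_concepts=60,
        n_proteins=40,
        n_days=20,
        n_effect_concepts=8,
        n_effect_proteins=6,
        n_rooted_proteins=3,
    )
    return generate_cohorts(config)


@pytest.fixture
def toy_timeline():
    return PatientTimeline(
        person_id=1,
        days=[(0, [10, 11]), (3, [12]), (7, [10, 12, 13, 13])],
        index_date=7,
    )


@pytest.fixture
def tiny_embedding():
    rng = np.random.default_rng(0)
    vectors = {c: rng.standard_normal(4) for c in (10, 11, 12, 13)}
    return ConceptEmbedding(dimension=4, vectors=vectors)
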