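import pytest

from fanmem import (
    SGNSConfig,
    build_activation_table,
    build_classic_design,
    build_semantic_design,
    synth_clustered_space,
    to_training_pairs,
    train_ensemble,
)
from fanmem.fan_design import DEFAULT_LOCATION_LEXICON, DEFAULT_PERSON_LEXICON


@pytest.fixture(scope="session")
def classic_design():
    design = build_classic_design(DEFAULT_PERSON_LEXICON,
                                  DEFAULT_LOCATION_LEXICON,
                                  varied_category="location", rng_seed=3)
    design.validate()
    return design


@pytest.fixture(scope="session")
def classic_models(classic_design):
    pairs = to_training_pairs(classic_design)
    return train_ensemble(pairs, SGNSConfig())


@pytest.fixture(scope="session")
def classic_activations(classic_design, classic_models):
    return build_activation_table(classic_models, classic_design)


@pytest.fixture(scope="session")
def synthetic_space():
    return synth_clustered_space(rng_seed=5)


@pytest.fixture(scope="session")
def semantic_design(synthetic_space):
    _, groups = synthetic_space
    design = build_semantic_design(
        [g for g in groups if g.category == "person"],
        [g for g in groups if g.category == "location"],
        varied_category="person", rng_seed=5)
    design.validate()
    return design
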