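import pytest

from clinorm import (
    LearnConfig,
    SynthConfig,
    generate,
    learn_by_semantic_type,
    learn_from_training,
)


@pytest.fixture(scope="session")
def synth():
    """One synthetic world shared across the suite (fixed seed)."""
    return generate(SynthConfig(random_seed=7))


@pytest.fixture(scope="session")
def learn_cfg():
    return LearnConfig(random_seed=7)


@pytest.fixture(scope="session")
def type_patterns(synth, learn_cfg):
    return learn_by_semantic_type(synth.lexicon, learn_cfg)


@pytest.fixture(scope="session")
def training_patterns(synth, learn_cfg):
    return learn_from_training(synth.lexicon, synth.training_mentions,
                               learn_cfg)


@pytest.fixture(scope="session")
def all_patterns(type_patterns, training_patterns):
    return type_patterns.merged_with(training_patterns)
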