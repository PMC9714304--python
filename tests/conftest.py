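import numpy as np
import pytest

from kiwiner.corpus_io import Lexicon
from kiwiner.synthetic import SynthSpec, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small seeded synthetic world + corpus shared across tests."""
    spec = SynthSpec(
        n_common_words=40,
        n_domain_words=20,
        n_sentences=300,
        mean_sentence_words=5.0,
        seed=11,
    )
    world, corpus = generate(spec)
    return spec, world, corpus


@pytest.fixture(scope="session")
def detection_synth():
    """The default-sized synthetic corpus used for detection recall checks."""
    spec = SynthSpec(seed=1)
    world, corpus = generate(spec)
    return spec, world, corpus


@pytest.fixture()
def example_lexicon():
    """The plant-disease worked-example lexicon."""
    return Lexicon({"植物": 5, "病害": 3, "植物病害": 2, "病": 4})


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
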