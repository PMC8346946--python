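import numpy as np
import pytest

from glyphcomplexity import GeneratorSpec, build_half_table, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Small default-structure synthetic corpus shared across tests."""
    spec = GeneratorSpec(
        n_families=3, scripts_per_family=3, chars_per_script=8, seed=5
    )
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def small_half_table(small_corpus):
    return build_half_table(small_corpus.glyphs, small_corpus.inventory)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
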