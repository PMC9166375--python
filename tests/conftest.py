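import numpy as np
import pytest

from docsubre.fixtures import GeneratorSpec, generate_documents, word_vectors_text
from docsubre.path_encoder import (EncoderConfig, EncoderParams,
                                   load_word_vectors)


@pytest.fixture(scope="session")
def gen_spec():
    return GeneratorSpec(n_docs=30, seed=42)


@pytest.fixture(scope="session")
def corpus(gen_spec):
    """(docs, parses_by_doc, locus map) for a small synthetic corpus."""
    return generate_documents(gen_spec)


@pytest.fixture(scope="session")
def word_table(gen_spec):
    return load_word_vectors(word_vectors_text(gen_spec, 24))


@pytest.fixture
def small_params(word_table):
    # function-scoped: several tests overwrite weights in place
    rng = np.random.default_rng(0)
    return EncoderParams.create(EncoderConfig.small(), word_table, rng)


PUBTATOR_ONE = (
    "101|t|Aspirin study\n"
    "101|a|Aspirin induces severe rash . Patients were monitored .\n"
    "101\t0\t7\tAspirin\tChemical\tMESH:C001\n"
    "101\t14\t21\tAspirin\tChemical\tMESH:C001\n"
    "101\t37\t41\trash\tDisease\tMESH:D001\n"
    "101\tCID\tMESH:C001\tMESH:D001\n"
)


@pytest.fixture
def pubtator_one():
    return PUBTATOR_ONE
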