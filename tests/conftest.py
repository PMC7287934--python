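import numpy as np
import pytest

from retroseq.data import Corpus, Reaction
from retroseq.synth import GeneratorConfig, generate_corpora


@pytest.fixture(scope="session")
def tiny_corpora():
    """A small synthetic corpus pair shared by read-only tests."""
    return generate_corpora(
        GeneratorConfig(n_large=600, n_small=150, fragment_pool_size=60, seed=11)
    )


@pytest.fixture(scope="session")
def tiny_large(tiny_corpora):
    return tiny_corpora[0]


@pytest.fixture(scope="session")
def tiny_small(tiny_corpora):
    return tiny_corpora[1]


def make_corpus(lines, name="fixture"):
    """Build a corpus from raw reaction-SMILES lines."""
    from retroseq.data import parse_reaction_line

    return Corpus(
        [parse_reaction_line(l, i + 1) for i, l in enumerate(lines)], name=name
    )
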