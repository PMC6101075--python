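import numpy as np
import pytest

from bbgru.parse import ParseGraph
from bbgru.synth import SynthConfig, generate_corpus, write_corpus


@pytest.fixture
def running_example_graph() -> ParseGraph:
    """The running instance 'contains bacterium at environment with human':
    a prepositional chain hanging off the bacterium mention, governed by
    the verb 'contains'."""
    return ParseGraph(
        surface=["contains", "bacterium", "at", "environment", "with", "human"],
        stem=["contain", "bacterium", "at", "environment", "with", "human"],
        pos=["VBZ", "NNP", "IN", "NN", "IN", "NNP"],
        chunk=["B-VP", "B-NP", "B-PP", "B-NP", "B-PP", "B-NP"],
        entity=["O", "B-Bacteria", "O", "O", "O", "B-Habitat"],
        head=[0, 1, 2, 3, 4, 5],
        deplabel=["root", "dobj", "prep", "pobj", "prep", "pobj"],
    )


@pytest.fixture(scope="session")
def small_corpus_dir(tmp_path_factory):
    """A small deterministic synthetic corpus on disk (12 docs, seed 7)."""
    d = tmp_path_factory.mktemp("corpus")
    docs = generate_corpus(SynthConfig(n_docs=12, sentences_per_doc=5, seed=7))
    write_corpus(docs, d)
    return d


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
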