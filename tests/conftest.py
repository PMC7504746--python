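import numpy as np
import pytest

from lwas import (EntityLexicon, IBC_ANNOTATIONS, IBC_LEXICON, IBC_PAIRS,
                  TrainConfig, build_corpus, load_annotations, load_pairs,
                  packaged_data, train_embeddings)
from lwas.embedding import EmbeddingModel, Vocabulary
from lwas.synthetic_corpus import (GeneratorConfig, generate_abstracts,
                                   generate_world)


@pytest.fixture(scope="session")
def ibc_lexicon():
    return EntityLexicon.from_tsv(packaged_data(IBC_LEXICON))


@pytest.fixture(scope="session")
def ibc_refset():
    return load_pairs(packaged_data(IBC_PAIRS))


@pytest.fixture(scope="session")
def ibc_annotations():
    return load_annotations(packaged_data(IBC_ANNOTATIONS))


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down planted world: quick to generate and train on."""
    return GeneratorConfig(
        n_groups=3,
        diseases_per_group=3,
        drugs_per_disease=2,
        n_abstracts=300,
        background_vocab_size=100,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_corpus(small_world, small_config):
    docs = generate_abstracts(small_world, small_config)
    return build_corpus(docs, small_world.lexicon)


@pytest.fixture(scope="session")
def small_model(small_corpus):
    return train_embeddings(small_corpus,
                            TrainConfig(dim=20, epochs=5, seed=7))


def model_from_matrix(tokens: list[str], matrix: np.ndarray) -> EmbeddingModel:
    """Hand-built model for geometry tests (counts are irrelevant)."""
    vocab = Vocabulary({t: 1 for t in tokens})
    ordered = np.asarray([matrix[tokens.index(t)] for t in vocab.tokens],
                         dtype=float)
    return EmbeddingModel(vocab, ordered, np.zeros_like(ordered),
                          TrainConfig(dim=matrix.shape[1]))
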