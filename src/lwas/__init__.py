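"""lwas: literature-wide association studies for drug repurposing.

Embeds drug and disease terms from a biomedical text corpus into a shared
vector space, ranks diseases similar to a target disease, and proposes the
known drugs of those similar diseases as repurposing candidates.
"""

from importlib import resources

from .corpus_prep import (EntityLexicon, LexiconEntry, RawDocument,
                          SentenceCorpus, build_corpus, clean_text,
                          entity_token, hyphenate_entities, split_sentences,
                          tokenize)
from .embedding import (EmbeddingModel, MissingTermError, TrainConfig,
                        Vocabulary, build_vocabulary, corpus_loss, cosine,
                        train_embeddings)
from .reference_set import (Drug, DrugDiseasePair, ReferenceSet,
                            ReferenceSetError, disease_token_map,
                            drugs_for_disease, filter_to_vocabulary,
                            load_pairs, save_pairs)
from .repurposing import (CandidateDrug, EvaluationCounts, PipelineConfig,
                          PipelineError, RepurposingResult, SimilarDisease,
                          annotate_candidates, load_annotations,
                          propose_drugs, run_pipeline, similar_diseases)
from .similarity_map import Map2D, export_map, project_2d, trustworthiness
from .synthetic_corpus import (GeneratorConfig, PlantedWorld,
                               evaluate_recovery, generate_abstracts,
                               generate_world)

__version__ = "0.1.0"


def packaged_data(name: str):
    """Path to a packaged fixture table (reference pairs, lexicon,
    annotations for the worked inflammatory-breast-cancer example)."""
    return resources.files("lwas.data") / name


IBC_PAIRS = "ibc_reference_pairs.tsv"
IBC_LEXICON = "ibc_lexicon.tsv"
IBC_ANNOTATIONS = "ibc_annotations.tsv"
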