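"""Repurposing inference: similar diseases → candidate drugs → evaluation.

Given a trained embedding, the target disease's nearest disease neighbors
(by cosine in the full embedding space) are ranked, the known drugs of those
diseases are pooled from the reference set, deduplicated, and — when an
annotation table is supplied — tallied against PubMed / ClinicalTrials.gov
support columns.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .corpus_prep import (EntityLexicon, RawDocument, build_corpus,
                          read_documents)
from .embedding import EmbeddingModel, TrainConfig, train_embeddings
from .reference_set import (ReferenceSet, disease_token_map,
                            filter_to_vocabulary, load_pairs)

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarDisease",
    "CandidateDrug",
    "EvaluationCounts",
    "PipelineConfig",
    "PipelineError",
    "RepurposingResult",
    "similar_diseases",
    "propose_drugs",
    "annotate_candidates",
    "load_annotations",
    "run_pipeline",
]


@dataclass(frozen=True)
class SimilarDisease:
    disease_id: str
    disease_token: str
    similarity: float


@dataclass
class CandidateDrug:
    drug_id: str
    drug_name: str
    supporting_diseases: list[tuple[str, float]]
    rank_score: float


@dataclass
class EvaluationCounts:
    n_candidates: int
    n_pubmed_supported: int
    n_clinicaltrials: int
    n_novel: int  # negative in both sources


def similar_diseases(
    model: EmbeddingModel,
    target_token: str,
    disease_tokens: Mapping[str, str],
    k: int,
    lexicon: EntityLexicon | None = None,
) -> list[SimilarDisease]:
    """Top-*k* diseases by cosine similarity to the target token.

    *disease_tokens* maps corpus tokens to disease IDs.  The target itself
    and any synonym token sharing its canonical ID in the lexicon are
    excluded (e.g. an abbreviation and its spelled-out form count as one
    disease).  When one disease is embedded under several tokens, its best
    scoring token represents it.  Ties break lexicographically on token.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    target_vec = model.vector(target_token)  # raises MissingTermError if OOV

    excluded = {target_token}
    if lexicon is not None:
        cid = lexicon.canonical_id(target_token)
        if cid is not None:
            excluded |= lexicon.tokens_for_id(cid)

    best: dict[str, SimilarDisease] = {}
    for token in sorted(disease_tokens):
        if token in excluded or token not in model:
            continue
        sim = model.similarity(target_token, token)
        did = disease_tokens[token]
        cur = best.get(did)
        if cur is None or sim > cur.similarity:
            best[did] = SimilarDisease(did, token, sim)
    ranked = sorted(best.values(),
                    key=lambda s: (-s.similarity, s.disease_token))
    del target_vec
    return ranked[:k]


def propose_drugs(
    similar: Sequence[SimilarDisease], refset: ReferenceSet
) -> list[CandidateDrug]:
    """Pool and deduplicate the known drugs of the similar diseases.

    One candidate per unique drug ID; rank_score is the maximum similarity
    among its supporting diseases.  Sorted by descending rank_score, ties
    broken alphabetically by drug name.
    """
    by_id: dict[str, CandidateDrug] = {}
    for sd in similar:
        for drug in sorted(refset.drugs_for_disease(sd.disease_id)):
            cand = by_id.get(drug.drug_id)
            if cand is None:
                cand = CandidateDrug(drug.drug_id, drug.name, [], float("-inf"))
                by_id[drug.drug_id] = cand
            cand.supporting_diseases.append((sd.disease_id, sd.similarity))
            cand.rank_score = max(cand.rank_score, sd.similarity)
    return sorted(by_id.values(), key=lambda c: (-c.rank_score, c.drug_name))


ANNOTATION_COLUMNS = ["drug_name", "pubmed", "clinicaltrials"]


def load_annotations(path: str | Path) -> pd.DataFrame:
    """Read a drug annotation table (yes/no per evidence source)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table missing columns {missing}")
    return table


def _as_bool(value: object) -> bool:
    text = str(value).strip().casefold()
    if text in ("yes", "y", "true", "1"):
        return True
    if text in ("no", "n", "false", "0"):
        return False
    raise ValueError(f"annotation value {value!r} is not yes/no")


def annotate_candidates(
    candidates: Sequence[CandidateDrug], annotations: pd.DataFrame
) -> EvaluationCounts:
    """Tally candidate support by exact case-folded drug-name match.

    Candidates absent from the table count as negative in both sources (and
    are logged); duplicate annotation rows for one drug are an error.
    """
    names = annotations["drug_name"].map(lambda s: str(s).strip().casefold())
    if names.duplicated().any():
        dupes = sorted(names[names.duplicated()].unique())
        raise ValueError(f"duplicate annotation rows for {dupes}")
    table = {
        name: (_as_bool(pm), _as_bool(ct))
        for name, pm, ct in zip(names, annotations["pubmed"],
                                annotations["clinicaltrials"])
    }
    n_pm = n_ct = n_novel = n_missing = 0
    for cand in candidates:
        pm, ct = table.get(cand.drug_name.strip().casefold(), (False, False))
        if cand.drug_name.strip().casefold() not in table:
            n_missing += 1
            logger.warning("no annotation row for %s; counted negative",
                           cand.drug_name)
        n_pm += pm
        n_ct += ct
        n_novel += (not pm) and (not ct)
    if n_missing:
        logger.info("%d candidates had no annotation row", n_missing)
    return EvaluationCounts(
        n_candidates=len(candidates),
        n_pubmed_supported=n_pm,
        n_clinicaltrials=n_ct,
        n_novel=n_novel,
    )


# --------------------------------------------------------------------------
# end-to-end pipeline


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs.

    ``documents`` may be a path or an in-memory list of RawDocument;
    ``target`` is the target disease's corpus token (hyphenated uppercase).
    """

    documents: str | Path | list[RawDocument] | None = None
    lexicon: str | Path | EntityLexicon | None = None
    pairs: str | Path | ReferenceSet | None = None
    target: str | None = None
    k: int = 18
    train: TrainConfig = field(default_factory=TrainConfig)
    annotations: str | Path | pd.DataFrame | None = None
    out_dir: str | Path | None = None

    def validate(self) -> None:
        for name in ("documents", "lexicon", "pairs", "target"):
            if getattr(self, name) is None:
                raise ValueError(f"pipeline configuration missing field {name!r}")


@dataclass
class RepurposingResult:
    similar: list[SimilarDisease]
    candidates: list[CandidateDrug]
    counts: EvaluationCounts | None
    vocab_size: int
    n_sentences: int

    def candidate_names(self) -> list[str]:
        return [c.drug_name for c in self.candidates]


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> RepurposingResult:
    """prepare → train → rank diseases → propose drugs → annotate → export."""
    with _stage("configuration"):
        config.validate()

    with _stage("prepare"):
        lexicon = (config.lexicon if isinstance(config.lexicon, EntityLexicon)
                   else EntityLexicon.from_tsv(config.lexicon))
        docs = (config.documents if isinstance(config.documents, list)
                else read_documents(config.documents))
        corpus = build_corpus(docs, lexicon)

    with _stage("train"):
        model = train_embeddings(corpus, config.train)

    with _stage("reference_set"):
        refset = (config.pairs if isinstance(config.pairs, ReferenceSet)
                  else load_pairs(config.pairs))
        refset, report = filter_to_vocabulary(refset, model.vocabulary, lexicon)
        tokens = disease_token_map(refset, lexicon)

    with _stage("similar_diseases"):
        similar = similar_diseases(model, config.target, tokens,
                                   config.k, lexicon)

    with _stage("propose_drugs"):
        candidates = propose_drugs(similar, refset)

    counts = None
    if config.annotations is not None:
        with _stage("annotate"):
            ann = (config.annotations
                   if isinstance(config.annotations, pd.DataFrame)
                   else load_annotations(config.annotations))
            counts = annotate_candidates(candidates, ann)

    result = RepurposingResult(
        similar=similar,
        candidates=candidates,
        counts=counts,
        vocab_size=len(model.vocabulary),
        n_sentences=len(corpus),
    )

    if config.out_dir is not None:
        with _stage("export"):
            export_result(result, model, config, Path(config.out_dir))
    return result


def export_result(
    result: RepurposingResult,
    model: EmbeddingModel,
    config: PipelineConfig,
    out_dir: Path,
) -> None:
    """Write the candidate report, similar-disease list and run log."""
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "candidates.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug_id\tdrug_name\trank_score\tsupporting_diseases\n")
        for c in result.candidates:
            support = ";".join(f"{d}:{s:.6f}" for d, s in c.supporting_diseases)
            fh.write(f"{c.drug_id}\t{c.drug_name}\t{c.rank_score:.6f}\t{support}\n")
    with open(out_dir / "similar_diseases.tsv", "w", encoding="utf-8") as fh:
        fh.write("disease_id\tdisease_token\tsimilarity\n")
        for s in result.similar:
            fh.write(f"{s.disease_id}\t{s.disease_token}\t{s.similarity:.6f}\n")
    log = {
        "target": config.target,
        "k": config.k,
        "train": asdict(config.train),
        "vocab_size": result.vocab_size,
        "n_sentences": result.n_sentences,
        "n_similar": len(result.similar),
        "n_candidates": len(result.candidates),
    }
    if result.counts is not None:
        log["evaluation"] = asdict(result.counts)
        (out_dir / "evaluation.json").write_text(json.dumps(asdict(result.counts)))
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    model.save(out_dir / "model")
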