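"""Known drug–disease indication pairs linking drug space and disease space.

The reference set (DrugBank + KEGG style) is what turns "diseases similar to
the target" into candidate drugs: once similar diseases are ranked, their
known drugs are collected from these pairs.  IDs follow the DrugBank
(``DBnnnnn``) and KEGG disease (``Hnnnnn``) accession formats.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

from .corpus_prep import EntityLexicon, entity_token
from .embedding import Vocabulary

logger = logging.getLogger(__name__)

DRUG_ID_RE = re.compile(r"^DB\d{5}$")
DISEASE_ID_RE = re.compile(r"^H\d{5}$")
SOURCES = ("drugbank", "kegg", "other")

PAIR_COLUMNS = ["drug_id", "drug_name", "disease_id", "disease_name", "source"]


class ReferenceSetError(ValueError):
    pass


class Drug(NamedTuple):
    drug_id: str
    name: str


@dataclass(frozen=True)
class DrugDiseasePair:
    drug_id: str
    drug_name: str
    disease_id: str
    disease_name: str
    source: str = "other"

    def __post_init__(self) -> None:
        if not DRUG_ID_RE.match(self.drug_id):
            raise ReferenceSetError(f"malformed drug ID {self.drug_id!r}")
        if not DISEASE_ID_RE.match(self.disease_id):
            raise ReferenceSetError(f"malformed disease ID {self.disease_id!r}")
        if not self.drug_name or not self.disease_name:
            raise ReferenceSetError("empty drug or disease name")
        if self.source not in SOURCES:
            raise ReferenceSetError(f"unknown source {self.source!r}")


@dataclass
class FilterReport:
    n_drugs: int
    n_diseases: int
    n_pairs: int


@dataclass
class ReferenceSet:
    """Deduplicated pairs plus disease→drugs and drug→diseases indices."""

    pairs: list[DrugDiseasePair]
    n_duplicates: int = 0
    _by_disease: dict[str, set[Drug]] = field(init=False, repr=False)
    _by_drug: dict[str, set[str]] = field(init=False, repr=False)
    _disease_names: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[DrugDiseasePair] = []
        dups = 0
        for p in self.pairs:
            key = (p.drug_id, p.disease_id)
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            unique.append(p)
        if dups:
            logger.info("collapsed %d duplicate pairs", dups)
        self.pairs = unique
        self.n_duplicates += dups
        self._by_disease = {}
        self._by_drug = {}
        self._disease_names = {}
        for p in self.pairs:
            self._by_disease.setdefault(p.disease_id, set()).add(
                Drug(p.drug_id, p.drug_name))
            self._by_drug.setdefault(p.drug_id, set()).add(p.disease_id)
            self._disease_names.setdefault(p.disease_id, p.disease_name)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def disease_ids(self) -> set[str]:
        return set(self._by_disease)

    @property
    def drug_ids(self) -> set[str]:
        return set(self._by_drug)

    def disease_name(self, disease_id: str) -> str:
        return self._disease_names[disease_id]

    def drugs_for_disease(self, disease_id: str) -> set[Drug]:
        """The drugs paired with *disease_id*; empty set if unknown."""
        return set(self._by_disease.get(disease_id, set()))

    def diseases_for_drug(self, drug_id: str) -> set[str]:
        return set(self._by_drug.get(drug_id, set()))


def load_pairs(path: str | Path) -> ReferenceSet:
    """Load a TSV of pairs; duplicates collapse with a logged count.

    Malformed rows raise :class:`ReferenceSetError` naming the line number;
    an empty file (or header-only file) is an error.
    """
    pairs: list[DrugDiseasePair] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != PAIR_COLUMNS:
            raise ReferenceSetError(
                f"unexpected header {header!r} in {path}; expected {PAIR_COLUMNS}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ReferenceSetError(
                    f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
            try:
                pairs.append(DrugDiseasePair(*fields))
            except ReferenceSetError as err:
                raise ReferenceSetError(f"{path}:{lineno}: {err}") from None
    if not pairs:
        raise ReferenceSetError(f"no pairs in {path}")
    return ReferenceSet(pairs)


def _entity_tokens(name: str, canonical_id: str,
                   lexicon: EntityLexicon | None) -> set[str]:
    """Corpus tokens under which an entity may be embedded: its own
    hyphenated name plus any lexicon synonyms sharing the canonical ID."""
    tokens = {entity_token(name)}
    if lexicon is not None:
        tokens |= lexicon.tokens_for_id(canonical_id)
    return tokens


def filter_to_vocabulary(
    refset: ReferenceSet,
    vocab: Vocabulary,
    lexicon: EntityLexicon | None = None,
) -> tuple[ReferenceSet, FilterReport]:
    """Keep pairs whose drug AND disease have an embedded token.

    An entity counts as embedded if any of its surface tokens (hyphenated
    name or lexicon synonym with the same canonical ID) is in *vocab*.
    Idempotent; output is never larger than the input.
    """
    kept = [
        p for p in refset.pairs
        if any(t in vocab for t in _entity_tokens(p.drug_name, p.drug_id, lexicon))
        and any(t in vocab for t in
                _entity_tokens(p.disease_name, p.disease_id, lexicon))
    ]
    out = ReferenceSet(kept)
    report = FilterReport(
        n_drugs=len(out.drug_ids),
        n_diseases=len(out.disease_ids),
        n_pairs=len(out),
    )
    logger.info(
        "vocabulary filter: %d/%d pairs, %d drugs, %d diseases survive",
        report.n_pairs, len(refset), report.n_drugs, report.n_diseases)
    return out, report


def drugs_for_disease(refset: ReferenceSet, disease_id: str) -> set[Drug]:
    return refset.drugs_for_disease(disease_id)


def save_pairs(refset: ReferenceSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in refset.pairs:
            fh.write(f"{p.drug_id}\t{p.drug_name}\t{p.disease_id}\t"
                     f"{p.disease_name}\t{p.source}\n")


def disease_token_map(
    refset: ReferenceSet, lexicon: EntityLexicon | None = None
) -> dict[str, str]:
    """Map corpus tokens to disease IDs for every disease in the set."""
    mapping: dict[str, str] = {}
    for did in refset.disease_ids:
        for tok in _entity_tokens(refset.disease_name(did), did, lexicon):
            mapping[tok] = did
    return mapping
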