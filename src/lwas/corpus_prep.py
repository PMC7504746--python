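"""Corpus preparation: cleaning, sentence splitting, and entity hyphenation.

Raw abstracts are normalised to uppercase, punctuation-free text; multiword
drug and disease names from an entity lexicon are collapsed into single
hyphenated tokens (e.g. ``INFLAMMATORY-BREAST-CANCER``) so that downstream
word embeddings treat each biomedical entity as one vocabulary item.
"""

from __future__ import annotations

import json
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: Sentence-terminal marks kept as standalone tokens until sentence splitting.
TERMINAL_MARKS = frozenset({".", "?", "!"})

#: Punctuation replaced by a space.  Hyphens in raw text are punctuation too:
#: after cleaning, "-" only ever appears as the joiner introduced by
#: :func:`hyphenate_entities`, so entity tokens are unambiguous.
_PUNCT = set(string.punctuation)

#: Tokens (uppercase, already cleaned) after which a period does NOT end a
#: sentence: single letters ("E." of "E. coli"), common abbreviations.
ABBREVIATIONS = frozenset(
    [*string.ascii_uppercase, "FIG", "FIGS", "VS", "AL", "ET", "SPP", "NO",
     "DR", "CA", "APPROX", "EG", "IE"]
)


@dataclass(frozen=True)
class RawDocument:
    """One input record: an abstract with an opaque identifier."""

    doc_id: str
    text: str


@dataclass(frozen=True)
class LexiconEntry:
    surface_form: str
    canonical_id: str
    entity_type: str  # "drug" or "disease"

    @property
    def token(self) -> str:
        """The corpus token this entry maps to (hyphenated uppercase form)."""
        return entity_token(self.surface_form)


class EntityLexicon:
    """Drug/disease surface forms mapped to canonical IDs.

    Matching is case-insensitive over token sequences.  A canonical ID may
    own several surface forms (synonyms such as an abbreviation and the
    spelled-out name).
    """

    def __init__(self, entries: Iterable[LexiconEntry]):
        self.entries: list[LexiconEntry] = list(entries)
        seen: set[tuple[str, str]] = set()
        for e in self.entries:
            if not e.surface_form.strip():
                raise ValueError("empty surface form in lexicon")
            if e.entity_type not in ("drug", "disease"):
                raise ValueError(f"unknown entity type {e.entity_type!r}")
            key = (e.token, e.entity_type)
            if key in seen:
                raise ValueError(f"duplicate lexicon entry {key}")
            seen.add(key)
        # token-sequence -> joined token, for the gazetteer matcher
        self._sequences: dict[tuple[str, ...], str] = {}
        for e in self.entries:
            words = tuple(_entity_words(e.surface_form))
            self._sequences[words] = "-".join(words)
        self._max_len = max((len(s) for s in self._sequences), default=0)
        self._by_token: dict[str, LexiconEntry] = {e.token: e for e in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[LexiconEntry]:
        return iter(self.entries)

    def entry_for_token(self, token: str) -> LexiconEntry | None:
        return self._by_token.get(token)

    def canonical_id(self, token: str) -> str | None:
        e = self._by_token.get(token)
        return e.canonical_id if e else None

    def tokens_for_id(self, canonical_id: str) -> set[str]:
        """All surface tokens sharing one canonical ID (synonym set)."""
        return {e.token for e in self.entries if e.canonical_id == canonical_id}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EntityLexicon":
        """Load a ``surface_form<TAB>canonical_id<TAB>entity_type`` table."""
        entries = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["surface_form", "canonical_id", "entity_type"]:
                raise ValueError(f"unexpected lexicon header {header!r} in {path}")
            for line in fh:
                if not line.strip():
                    continue
                surface, cid, etype = line.rstrip("\n").split("\t")[:3]
                entries.append(LexiconEntry(surface, cid, etype))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("surface_form\tcanonical_id\tentity_type\n")
            for e in self.entries:
                fh.write(f"{e.surface_form}\t{e.canonical_id}\t{e.entity_type}\n")


def _entity_words(surface_form: str) -> list[str]:
    """Cleaned word sequence of a lexicon surface form (no terminal marks)."""
    return [t for t in clean_text(surface_form).split() if t not in TERMINAL_MARKS]


def entity_token(surface_form: str) -> str:
    """Corpus token for an entity name: cleaned words joined by hyphens."""
    return "-".join(_entity_words(surface_form))


def clean_text(text: str) -> str:
    """Uppercase *text* and strip punctuation.

    Sentence-terminal marks (``. ? !``) followed by whitespace or end of
    string are preserved as standalone tokens for :func:`split_sentences`;
    every other punctuation character, including hyphens, becomes a space.
    Whitespace runs collapse to single spaces.  Idempotent and total.
    """
    out: list[str] = []
    n = len(text)
    for i, ch in enumerate(text):
        if ch in TERMINAL_MARKS:
            nxt = text[i + 1] if i + 1 < n else " "
            if nxt.isspace() or i + 1 == n:
                out.append(f" {ch} ")
            else:
                out.append(" ")
        elif ch in _PUNCT:
            out.append(" ")
        else:
            out.append(ch.upper())
    return " ".join("".join(out).split())


def split_sentences(text: str) -> list[str]:
    """Split cleaned text into sentences on standalone terminal marks.

    A period is not a boundary when the preceding token is a known
    abbreviation (``E.``, ``FIG.``, ``VS.`` ...).  Terminal marks are removed
    from the output; token order is preserved across the split.
    """
    tokens = text.split()
    sentences: list[str] = []
    current: list[str] = []
    for tok in tokens:
        if tok in TERMINAL_MARKS:
            if tok == "." and current and current[-1] in ABBREVIATIONS:
                continue  # abbreviation guard: swallow the mark, keep going
            if current:
                sentences.append(" ".join(current))
                current = []
        else:
            current.append(tok)
    if current:
        sentences.append(" ".join(current))
    return sentences


def tokenize(sentence: str) -> list[str]:
    return sentence.split()


def hyphenate_entities(tokens: Sequence[str], lexicon: EntityLexicon) -> list[str]:
    """Replace maximal multiword lexicon matches with hyphen-joined tokens.

    Greedy leftmost-longest gazetteer matching over the token sequence;
    matches of length 1 and non-matching tokens pass through unchanged.
    """
    seqs = lexicon._sequences
    max_len = lexicon._max_len
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        matched = False
        for length in range(min(max_len, n - i), 1, -1):
            window = tuple(tokens[i : i + length])
            if window in seqs:
                out.append(seqs[window])
                i += length
                matched = True
                break
        if not matched:
            out.append(tokens[i])
            i += 1
    return out


@dataclass
class SentenceCorpus:
    """Tokenised sentences with per-sentence document provenance."""

    sentences: list[list[str]] = field(default_factory=list)
    doc_ids: list[str] = field(default_factory=list)
    n_documents: int = 0
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if len(self.sentences) != len(self.doc_ids):
            raise ValueError("sentences and doc_ids lengths differ")

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[list[str]]:
        return iter(self.sentences)

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def save(self, out_dir: str | Path) -> None:
        """Write one sentence per line plus a JSON sidecar with counts."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "corpus.txt", "w", encoding="utf-8") as fh:
            for sent in self.sentences:
                fh.write(" ".join(sent) + "\n")
        with open(out / "corpus.json", "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "documents": self.n_documents,
                    "sentences": len(self.sentences),
                    "tokens": self.n_tokens,
                    "skipped_documents": self.n_skipped,
                    "doc_ids": self.doc_ids,
                },
                fh,
            )

    @classmethod
    def load(cls, out_dir: str | Path) -> "SentenceCorpus":
        out = Path(out_dir)
        with open(out / "corpus.txt", encoding="utf-8") as fh:
            sentences = [line.split() for line in fh if line.strip()]
        meta_path = out / "corpus.json"
        if meta_path.exists():
            meta = json.loads(meta_path.read_text())
            doc_ids = meta.get("doc_ids", [""] * len(sentences))
            n_docs = meta.get("documents", 0)
            n_skipped = meta.get("skipped_documents", 0)
        else:
            doc_ids, n_docs, n_skipped = [""] * len(sentences), 0, 0
        return cls(sentences, doc_ids, n_docs, n_skipped)


def build_corpus(
    docs: Iterable[RawDocument], lexicon: EntityLexicon
) -> SentenceCorpus:
    """clean → split → tokenize → hyphenate, per document, with provenance.

    Documents with a missing/None text field are skipped and counted.
    """
    corpus = SentenceCorpus()
    for doc in docs:
        corpus.n_documents += 1
        if getattr(doc, "text", None) is None:
            corpus.n_skipped += 1
            logger.warning("skipping document %s: missing text", doc.doc_id)
            continue
        for sent in split_sentences(clean_text(doc.text)):
            tokens = hyphenate_entities(tokenize(sent), lexicon)
            if tokens:
                corpus.sentences.append(tokens)
                corpus.doc_ids.append(doc.doc_id)
    if corpus.n_skipped:
        logger.info("skipped %d malformed documents", corpus.n_skipped)
    return corpus


def read_documents(path: str | Path) -> list[RawDocument]:
    """Read abstracts from a TSV (``doc_id<TAB>text``, with header) or, if
    the first line has no tab, plain text with one document per line."""
    docs: list[RawDocument] = []
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if "\t" in first:
            cols = first.rstrip("\n").split("\t")
            has_header = cols[0].lower() in ("doc_id", "id")
            if not has_header:
                doc_id, text = first.rstrip("\n").split("\t", 1)
                docs.append(RawDocument(doc_id, text))
            for line in fh:
                if not line.strip():
                    continue
                doc_id, text = line.rstrip("\n").split("\t", 1)
                docs.append(RawDocument(doc_id, text))
        else:
            if first.strip():
                docs.append(RawDocument("doc0", first.rstrip("\n")))
            for i, line in enumerate(fh, start=1):
                if line.strip():
                    docs.append(RawDocument(f"doc{i}", line.rstrip("\n")))
    return docs
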