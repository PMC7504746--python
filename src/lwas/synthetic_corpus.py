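"""Synthetic abstract corpora with planted disease groups and known drugs.

Every stage of the pipeline can be validated without external text: the
generator plants groups of diseases that share a theme vocabulary, assigns
each disease one or more drugs, and emits abstracts whose sentences mix
theme words, disease mentions and drug mentions from the abstract's group.
Same-group diseases therefore share context distributions — exactly the
co-occurrence structure the embedding method assumes — and the ground truth
(group mates, drug indications) is known by construction.

Sentences are a mixture-of-pools sampler, not a grammar: distributional
similarity is all the embedding consumes.  Disease names cycle through one-,
two- and three-word patterns to exercise multiword hyphenation, every third
disease gets an abbreviation synonym, and the last drug of each group's
first disease is shared with the next group to exercise candidate
deduplication.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus_prep import EntityLexicon, LexiconEntry, RawDocument, entity_token
from .reference_set import DrugDiseasePair, ReferenceSet

__all__ = [
    "GeneratorConfig",
    "PlantedWorld",
    "generate_world",
    "generate_abstracts",
    "evaluate_recovery",
]


@dataclass
class GeneratorConfig:
    """Study conditions for the planted world.

    Defaults: 10 groups × 3 diseases × 2 drugs, 2,000 abstracts of 4–8
    sentences, theme-dominant sentences (half the token positions draw from
    the group's theme pool, a fifth mention a group disease, a tenth a drug
    of that disease, the rest background noise).
    """

    n_groups: int = 10
    diseases_per_group: int = 3
    drugs_per_disease: int = 2
    n_abstracts: int = 2000
    sentences_per_abstract: tuple[int, int] = (4, 8)
    sentence_length: tuple[int, int] = (8, 12)
    theme_pool_size: int = 20
    background_vocab_size: int = 500
    p_disease_mention: float = 0.2
    p_drug_mention: float = 0.1
    p_theme_word: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "diseases_per_group", "drugs_per_disease",
                     "n_abstracts", "theme_pool_size", "background_vocab_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        probs = (self.p_disease_mention, self.p_drug_mention, self.p_theme_word)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("mention probabilities must lie in [0, 1]")
        if sum(probs) > 1.0:
            raise ValueError("mention probabilities sum past 1")
        if self.sentences_per_abstract[0] > self.sentences_per_abstract[1]:
            raise ValueError("invalid sentences_per_abstract range")
        if self.theme_pool_size < 1:
            raise ValueError("theme pool smaller than 1")


@dataclass(frozen=True)
class PlantedDisease:
    disease_id: str
    name: str
    group: int
    synonyms: tuple[str, ...] = ()

    @property
    def token(self) -> str:
        return entity_token(self.name)


@dataclass
class PlantedWorld:
    """Ground truth: groups, diseases, drugs, theme pools, background."""

    config: GeneratorConfig
    diseases: list[PlantedDisease]
    drugs: dict[str, list[tuple[str, str]]]  # disease_id -> [(drug_id, name)]
    theme_pools: list[list[str]]             # per group
    background: list[str]
    lexicon: EntityLexicon = field(repr=False, default=None)  # type: ignore[assignment]
    refset: ReferenceSet = field(repr=False, default=None)    # type: ignore[assignment]

    def group_members(self, group: int) -> list[PlantedDisease]:
        return [d for d in self.diseases if d.group == group]

    def group_mates(self, disease_id: str) -> set[str]:
        """True similar-disease set: same-group diseases, self excluded."""
        target = next(d for d in self.diseases if d.disease_id == disease_id)
        return {d.disease_id for d in self.group_members(target.group)
                if d.disease_id != disease_id}

    def expected_drugs(self, disease_ids: Sequence[str]) -> set[str]:
        """Union of planted drug IDs over the given diseases."""
        out: set[str] = set()
        for did in disease_ids:
            out |= {drug_id for drug_id, _ in self.drugs[did]}
        return out


_NAME_PATTERNS = (
    lambda base: f"{base}OSIS",                 # single word
    lambda base: f"MORBUS {base}",              # two words
    lambda base: f"CHRONIC {base} SYNDROME",    # three words
)


def generate_world(config: GeneratorConfig) -> PlantedWorld:
    """Build the planted world, its entity lexicon and its reference pairs.

    Deterministic in config.seed (the world layout is in fact a pure
    function of the counts; randomness only enters abstract generation).
    """
    diseases: list[PlantedDisease] = []
    drugs: dict[str, list[tuple[str, str]]] = {}
    entries: list[LexiconEntry] = []
    pairs: list[DrugDiseasePair] = []

    drug_serial = 0
    disease_serial = 0
    first_disease_last_drug: dict[int, tuple[str, str]] = {}
    for g in range(config.n_groups):
        for d in range(config.diseases_per_group):
            disease_serial += 1
            did = f"H9{disease_serial:04d}"
            base = f"QV{g}X{d}"
            name = _NAME_PATTERNS[d % 3](base)
            synonyms = (f"{base}AB",) if d % 3 == 2 else ()
            disease = PlantedDisease(did, name, g, synonyms)
            diseases.append(disease)
            entries.append(LexiconEntry(name, did, "disease"))
            for syn in synonyms:
                entries.append(LexiconEntry(syn, did, "disease"))

            dlist: list[tuple[str, str]] = []
            for _k in range(config.drugs_per_disease):
                # share one drug with the previous group's first disease
                if (d == 0 and _k == config.drugs_per_disease - 1
                        and g > 0 and config.drugs_per_disease > 1):
                    dlist.append(first_disease_last_drug[g - 1])
                else:
                    drug_serial += 1
                    dlist.append((f"DB9{drug_serial:04d}",
                                  f"RX{g}G{d}N{_k}"))
            if d == 0:
                first_disease_last_drug[g] = dlist[-1]
            drugs[did] = dlist
            for drug_id, drug_name in dlist:
                pairs.append(DrugDiseasePair(drug_id, drug_name, did, name,
                                             "other"))

    seen_drugs: set[str] = set()
    for did, dlist in drugs.items():
        for drug_id, drug_name in dlist:
            if drug_id not in seen_drugs:
                seen_drugs.add(drug_id)
                entries.append(LexiconEntry(drug_name, drug_id, "drug"))

    theme_pools = [
        [f"T{g}W{j}" for j in range(config.theme_pool_size)]
        for g in range(config.n_groups)
    ]
    background = [f"B{j:04d}" for j in range(config.background_vocab_size)]

    world = PlantedWorld(
        config=config,
        diseases=diseases,
        drugs=drugs,
        theme_pools=theme_pools,
        background=background,
        lexicon=EntityLexicon(entries),
        refset=ReferenceSet(pairs),
    )
    return world


def generate_abstracts(
    world: PlantedWorld,
    config: GeneratorConfig | None = None,
    null_shuffle: bool = False,
    seed: int | None = None,
) -> list[RawDocument]:
    """Emit abstracts whose sentences mix the assigned group's pools.

    Each abstract is assigned a group uniformly at random; each sentence
    position independently draws a theme word, a disease mention (a group
    disease's name or synonym), a drug mention (a drug of that disease), or
    a background token at the configured probabilities.  With
    ``null_shuffle=True`` every mention position draws its group
    independently at random, severing the planted co-occurrence structure
    while preserving marginal token frequencies — the chance-level control.
    """
    config = config or world.config
    rng = np.random.default_rng(config.seed if seed is None else seed)
    docs: list[RawDocument] = []
    n_groups = config.n_groups
    s_lo, s_hi = config.sentences_per_abstract
    l_lo, l_hi = config.sentence_length
    p_dis, p_drug, p_theme = (config.p_disease_mention, config.p_drug_mention,
                              config.p_theme_word)

    for a in range(config.n_abstracts):
        group = int(rng.integers(n_groups))
        sentences: list[str] = []
        for _s in range(int(rng.integers(s_lo, s_hi + 1))):
            words: list[str] = []
            for _pos in range(int(rng.integers(l_lo, l_hi + 1))):
                g = int(rng.integers(n_groups)) if null_shuffle else group
                u = rng.random()
                if u < p_theme:
                    pool = world.theme_pools[g]
                    words.append(pool[int(rng.integers(len(pool)))])
                elif u < p_theme + p_dis:
                    members = world.group_members(g)
                    dis = members[int(rng.integers(len(members)))]
                    forms = (dis.name,) + dis.synonyms
                    words.append(forms[int(rng.integers(len(forms)))])
                elif u < p_theme + p_dis + p_drug:
                    members = world.group_members(g)
                    dis = members[int(rng.integers(len(members)))]
                    dlist = world.drugs[dis.disease_id]
                    words.append(dlist[int(rng.integers(len(dlist)))][1])
                else:
                    words.append(
                        world.background[int(rng.integers(len(world.background)))])
            sentences.append(" ".join(w.lower() for w in words) + ".")
        docs.append(RawDocument(f"abs{a}", " ".join(sentences)))
    return docs


def evaluate_recovery(
    predicted: Sequence[str], truth: set[str] | Sequence[str]
) -> tuple[float, float]:
    """Set precision and recall of predicted IDs against planted truth."""
    truth_set = set(truth)
    if not truth_set:
        raise ValueError("empty truth set")
    pred_set = set(predicted)
    if not pred_set:
        return 0.0, 0.0
    tp = len(pred_set & truth_set)
    return tp / len(pred_set), tp / len(truth_set)
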