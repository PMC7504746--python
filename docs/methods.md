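# Methods

## Text normalisation

`clean_text` uppercases and replaces every ASCII punctuation character with a
space, with one exception: a sentence-terminal `.`, `?` or `!` followed by
whitespace (or end of text) is kept as a standalone token until sentence
splitting. Hyphens in raw text are punctuation — they are spaced out — so
after cleaning, `-` occurs only as the joiner that entity hyphenation
introduces, making hyphenated entity tokens unambiguous. The function is
idempotent and total.

Sentence splitting breaks on standalone terminal marks, guarded by a small
abbreviation list (all single letters plus FIG, FIGS, VS, AL, ET, SPP, NO,
DR, CA, APPROX, EG, IE) so that "E. coli" does not split. No published
splitting rule exists for this pipeline's source data — only sentence counts
— so the rule is ours and is deliberately simple and documented rather than
inferred. Numerals are retained as tokens: identifiers such as HER2 carry
signal. Stopwords are not filtered.

Entity hyphenation is greedy leftmost-longest gazetteer matching over token
sequences, case-insensitive (the lexicon's surface forms are normalised by
the same cleaning rule). Only matches of two or more tokens are joined;
single-word entities and non-entities pass through unchanged, so a run with
an empty lexicon is the identity on the token stream.

## Embedding model

The trainer is a from-scratch word2vec: a two-layer linear network with
input matrix `W_in` (the vectors the rest of the pipeline consumes) and
output matrix `W_out`, optimised by per-example SGD on the negative-sampling
log-loss. CBOW (predict the center token from the mean of its context
vectors) is the default; skip-gram (predict each context token from the
center) is selectable. Choices, all overridable in `TrainConfig`:

| parameter | default | rationale |
|---|---|---|
| `dim` | 150 | standard size for biomedical corpora of this scale |
| `window` | 5 | ±5 tokens within one sentence |
| `min_count` | 1 | embed every token; reference sets are filtered to the vocabulary afterwards |
| `negative` | 5 | classic negative-sample count |
| `epochs` | 5 | ecosystem default |
| `initial_lr` → `final_lr` | 0.025 → 1e-4 | linear anneal over `epochs × corpus tokens` |
| `subsample_threshold` | 1e-3 | frequent-word subsampling, `min(1, √(t/f) + t/f)` |
| noise distribution | unigram^0.75 | standard for negative sampling |
| dynamic window | uniform 1..window | matches the reference recipe |

`W_in` initialises uniform in ±0.5/dim from a seeded generator; `W_out`
starts at zero. The inner loop is numba-compiled and single-threaded:
identical (corpus, config, seed) triples give bitwise-identical vectors.
There is no parallel mode. The per-example loss and analytic gradients are
duplicated as plain numpy (`example_loss_and_grads`) so the compiled kernel's
arithmetic is checkable against central-difference numerical gradients; the
test suite holds both architectures to relative error < 1e-4.

Note on subsampling and small fixtures: on a corpus with only a handful of
token types, every type's frequency exceeds 1e-3 and subsampling discards
most of the signal. Tests that engineer exact context structure on tiny
vocabularies therefore set `subsample_threshold=0`; realistic corpora (and
the synthetic generator's defaults, with ~800 types) are unaffected.

## Similarity maps

`project_2d` delegates to scikit-learn's t-SNE with PCA initialisation,
perplexity 30 and 1,000 iterations by default, and a fixed seed — PCA init
removes one source of run-to-run variance, making layouts reproducible.
t-SNE distances are not metrically meaningful, so the map is diagnostic
only: neighborhoods for candidate selection are always computed by cosine in
the original embedding space. Projection fidelity is quantified by
trustworthiness
T(k) = 1 − 2/(nk(2n − 3k − 1)) Σᵢ Σ_{j∈Uᵢ(k)} (r(i,j) − k),
implemented in-package and verified in tests against both a brute-force
evaluation of the formula and scikit-learn's independent implementation.

## Reference set and inference

Indication pairs use DrugBank-style (`DBnnnnn`) and KEGG-style (`Hnnnnn`)
accessions, validated on load with row-level error reporting; duplicate
(drug, disease) pairs collapse with a logged count. Entity names resolve to
corpus tokens by the same hyphenation rule as corpus preparation, so the
reference set and the vocabulary can never disagree on surface form. A
disease known under several names (an abbreviation and its expansion) may
own several lexicon rows with one canonical ID; vocabulary filtering keeps a
pair if *any* surface token is embedded.

`similar_diseases` ranks diseases by cosine to the target token, excluding
the target and every token sharing its canonical ID (returning a synonym of
the target as its own "similar disease" would be vacuous). When a disease is
embedded under several tokens its best-scoring token represents it. The
neighborhood is cosine k-NN in the full embedding space with configurable k;
how the original visual analysis bounded its neighborhood (fixed k, cluster
boundary, or threshold) is not recoverable, so k-NN is the reproducible
default and the 2D map is never consulted.

`propose_drugs` pools the known drugs of the similar diseases, one candidate
per unique drug ID, with `rank_score = max` supporting similarity — a single
strongly similar indication is stronger evidence than a high average over
weak ones — and alphabetical tie-breaks. `annotate_candidates` matches drug
names case-insensitively against the annotation table; candidates missing
from the table count as negative in both evidence sources (logged), and
duplicate rows are an error. "Novel" means negative in both PubMed and
ClinicalTrials.gov columns.

## Synthetic planted worlds

The generator emulates the one property the method actually consumes:
same-group diseases share context distributions. Each of `n_groups` groups
owns a theme vocabulary (20 words), `diseases_per_group` diseases (names
cycle through one-, two- and three-word patterns to exercise hyphenation;
every third disease gets an abbreviation synonym) and `drugs_per_disease`
drugs per disease, with one drug per group shared into the next group to
exercise deduplication. Abstracts (2,000 by default, 4–8 sentences of 8–12
tokens) are each assigned a group; every token position draws a theme word
(p=0.5), a disease mention (p=0.2), a drug of that disease (p=0.1) or a
background token (500-word pool) — theme-dominant sentences, chosen once so
that group structure is clearly expressed but mentions stay sparse, as in
real abstracts. Text is emitted lowercase with sentence-terminal periods so
the cleaning stages do real work.

The null control redraws the group *independently per token position*,
which severs both theme–disease and disease–disease co-occurrence while
preserving marginal token frequencies; an earlier per-sentence shuffle was
rejected because same-group diseases still co-occurred within sentences and
recovery stayed at ceiling.

What the generator does not emulate: realistic biomedical language,
abstract-length distributions, polysemy, or entity-mention noise
(misspellings, nested entities). Passing recovery tests therefore shows the
pipeline recovers planted distributional structure, not that it reaches any
particular accuracy on real literature.

## Problem sizes and numerical notes

The recovery study trains dim-50 embeddings for 10 epochs on ~120k-token
corpora over five seeds plus five null runs (seconds per run after JIT
compilation); unit tests use a 3-group world with 300 abstracts and dim 20.
Cosine similarity raises on zero vectors rather than returning 0; nearest
neighbors break ties lexicographically; t-SNE requires ≥3 points and
perplexity < n; trustworthiness requires 1 ≤ k < n/2. Training on a corpus
whose sentences all have fewer than two kept tokens leaves the (finite)
initial vectors untouched rather than erroring.
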