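import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lwas.corpus_prep import SentenceCorpus
from lwas.embedding import (EmbeddingModel, MissingTermError, TrainConfig,
                            Vocabulary, build_vocabulary, corpus_loss, cosine,
                            example_loss_and_grads, train_embeddings)

from conftest import model_from_matrix


def make_corpus(sentences):
    return SentenceCorpus(sentences, [""] * len(sentences))


class TestVocabulary:
    def test_min_count_one_keeps_all(self):
        vocab = build_vocabulary(make_corpus([["A", "A", "B"], ["A"]]), 1)
        assert set(vocab.tokens) == {"A", "B"}
        assert vocab.count("A") == 3

    def test_min_count_filters(self):
        vocab = build_vocabulary(make_corpus([["A", "A", "B"], ["A"]]), 2)
        assert set(vocab.tokens) == {"A"}

    def test_counts_match_brute_force_tally(self):
        rng = np.random.default_rng(5)
        sentences = [[f"W{rng.integers(20)}" for _ in range(10)]
                     for _ in range(50)]
        vocab = build_vocabulary(make_corpus(sentences), 1)
        tally = {}
        for sent in sentences:
            for tok in sent:
                tally[tok] = tally.get(tok, 0) + 1
        assert {t: vocab.count(t) for t in vocab.tokens} == tally

    def test_empty_corpus_errors(self):
        with pytest.raises(ValueError, match="empty corpus"):
            build_vocabulary(make_corpus([]), 1)

    def test_indices_dense_and_bijective(self):
        vocab = build_vocabulary(make_corpus([["C", "A", "B", "A"]]), 1)
        assert sorted(vocab.index.values()) == list(range(len(vocab)))
        for tok, i in vocab.index.items():
            assert vocab.tokens[i] == tok


class TestGradients:
    """Analytic gradients of the negative-sampling loss vs central
    differences, for both architectures and negative counts 1 and 5."""

    @pytest.mark.parametrize("architecture", ["cbow", "skipgram"])
    @pytest.mark.parametrize("negative", [1, 5])
    def test_matches_numerical_gradient(self, architecture, negative):
        rng = np.random.default_rng(42)
        V, D = 5, 4
        w_in = rng.normal(0.0, 0.5, (V, D))
        w_out = rng.normal(0.0, 0.5, (V, D))
        center, context = 0, [1, 2, 3]
        negatives = list(rng.integers(0, V, negative))
        _, g_in, g_out = example_loss_and_grads(
            w_in, w_out, center, context, negatives, architecture)

        eps = 1e-6
        for which, analytic in (("in", g_in), ("out", g_out)):
            base = w_in if which == "in" else w_out
            numeric = np.zeros_like(base)
            for i in range(V):
                for j in range(D):
                    plus, minus = base.copy(), base.copy()
                    plus[i, j] += eps
                    minus[i, j] -= eps
                    args_p = (plus, w_out) if which == "in" else (w_in, plus)
                    args_m = (minus, w_out) if which == "in" else (w_in, minus)
                    lp, _, _ = example_loss_and_grads(
                        *args_p, center, context, negatives, architecture)
                    lm, _, _ = example_loss_and_grads(
                        *args_m, center, context, negatives, architecture)
                    numeric[i, j] = (lp - lm) / (2 * eps)
            rel = np.abs(analytic - numeric).max() / np.abs(numeric).max()
            assert rel < 1e-4


class TestTraining:
    def test_deterministic_for_fixed_seed(self):
        sentences = [["A", "B", "C", "D"], ["B", "C", "E"], ["A", "E", "D"]] * 10
        cfg = TrainConfig(dim=8, epochs=3, seed=5)
        m1 = train_embeddings(make_corpus(sentences), cfg)
        m2 = train_embeddings(make_corpus(sentences), cfg)
        assert m1.vocabulary.tokens == m2.vocabulary.tokens
        assert np.array_equal(m1.input_vectors, m2.input_vectors)
        assert np.array_equal(m1.context_vectors, m2.context_vectors)

    def test_single_sentence_corpus_trains(self):
        model = train_embeddings(make_corpus([["A", "B", "C"]]),
                                 TrainConfig(dim=4, epochs=1, seed=0))
        assert np.isfinite(model.input_vectors).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(dim=0)
        with pytest.raises(ValueError):
            TrainConfig(window=0)
        with pytest.raises(ValueError):
            TrainConfig(architecture="glove")

    @pytest.mark.parametrize("architecture", ["cbow", "skipgram"])
    def test_loss_decreases_from_initialization(self, architecture):
        rng = np.random.default_rng(2)
        pool = [f"W{i}" for i in range(30)]
        sentences = [list(rng.choice(pool, size=8)) for _ in range(80)]
        corpus = make_corpus(sentences)
        cfg = TrainConfig(dim=12, epochs=5, seed=2, architecture=architecture,
                          subsample_threshold=0.0)
        trained = train_embeddings(corpus, cfg)
        init = EmbeddingModel(
            trained.vocabulary,
            np.random.default_rng(cfg.seed).uniform(
                -0.5 / cfg.dim, 0.5 / cfg.dim,
                trained.input_vectors.shape),
            np.zeros_like(trained.context_vectors),
            cfg,
        )
        assert corpus_loss(trained, corpus, 0) <= corpus_loss(init, corpus, 0)

    def test_shared_context_tokens_end_up_similar(self):
        """Two tokens planted in interchangeable contexts must be closer to
        each other than to a token from a disjoint context pool, in at least
        19 of 20 seeded runs.  Subsampling is off: on a 19-type corpus every
        token counts as frequent and would be discarded."""
        pool_ab = [f"P{i}" for i in range(8)]
        pool_c = [f"Q{i}" for i in range(8)]
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            sentences = []
            for _ in range(150):
                tok = ["A", "B"][int(rng.integers(2))]
                ctx = list(rng.choice(pool_ab, size=6))
                sentences.append(ctx[:3] + [tok] + ctx[3:])
                ctx = list(rng.choice(pool_c, size=6))
                sentences.append(ctx[:3] + ["C"] + ctx[3:])
            model = train_embeddings(
                make_corpus(sentences),
                TrainConfig(dim=16, epochs=5, seed=seed,
                            subsample_threshold=0.0))
            sim_ab = model.similarity("A", "B")
            if sim_ab > max(model.similarity("A", "C"),
                            model.similarity("B", "C")):
                wins += 1
        assert wins >= 19

    def test_save_load_round_trip(self, tmp_path, small_model):
        small_model.save(tmp_path / "model")
        again = EmbeddingModel.load(tmp_path / "model")
        assert again.vocabulary.tokens == small_model.vocabulary.tokens
        np.testing.assert_array_equal(again.input_vectors,
                                      small_model.input_vectors)
        np.testing.assert_array_equal(again.context_vectors,
                                      small_model.context_vectors)


class TestLookupAndSimilarity:
    def test_vector_has_configured_dim(self, small_model):
        tok = small_model.vocabulary.tokens[0]
        assert small_model.vector(tok).shape == (20,)

    def test_missing_term_error_names_token(self, small_model):
        with pytest.raises(MissingTermError, match="NO-SUCH-TERM"):
            small_model.vector("NO-SUCH-TERM")

    def test_cosine_self_is_one(self):
        x = np.array([1.0, 2.0, -3.0])
        assert cosine(x, x) == pytest.approx(1.0)

    def test_cosine_orthogonal_is_zero(self):
        assert cosine(np.array([1.0, 0.0]), np.array([0.0, 1.0])) == \
            pytest.approx(0.0)

    def test_cosine_formula(self):
        assert cosine(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == \
            pytest.approx(0.7071, abs=1e-4)

    def test_cosine_zero_vector_errors(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine(np.zeros(3), np.ones(3))

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.lists(st.floats(-10, 10), min_size=3, max_size=3),
        st.floats(0.01, 100),
        st.floats(0.01, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_cosine_scale_invariant(self, u, v, a, b):
        u, v = np.array(u), np.array(v)
        if np.linalg.norm(u) < 1e-6 or np.linalg.norm(v) < 1e-6:
            return
        assert cosine(a * u, b * v) == pytest.approx(cosine(u, v), abs=1e-9)


class TestNearestNeighbors:
    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(9)
        tokens = [f"T{i:02d}" for i in range(30)]
        model = model_from_matrix(tokens, rng.normal(size=(30, 6)))
        for query in ("T00", "T15", "T29"):
            got = model.nearest_neighbors(query, k=30)
            expected = sorted(
                ((t, cosine(model.vector(query), model.vector(t)))
                 for t in tokens if t != query),
                key=lambda ts: (-ts[1], ts[0]))
            assert [t for t, _ in got] == [t for t, _ in expected]
            np.testing.assert_allclose([s for _, s in got],
                                       [s for _, s in expected], atol=1e-12)

    def test_query_never_in_own_list(self, small_model):
        tok = small_model.vocabulary.tokens[0]
        result = small_model.nearest_neighbors(tok, k=len(small_model.vocabulary))
        assert tok not in [t for t, _ in result]

    def test_k_larger_than_candidates_returns_all(self):
        rng = np.random.default_rng(0)
        model = model_from_matrix(["A", "B", "C"], rng.normal(size=(3, 4)))
        assert len(model.nearest_neighbors("A", k=10)) == 2

    def test_restrict_to_limits_candidates(self):
        rng = np.random.default_rng(1)
        model = model_from_matrix(list("ABCDE"), rng.normal(size=(5, 4)))
        got = model.nearest_neighbors("A", k=5, restrict_to={"B", "D"})
        assert {t for t, _ in got} == {"B", "D"}

    def test_oov_query_errors(self, small_model):
        with pytest.raises(MissingTermError):
            small_model.nearest_neighbors("NOPE", k=1)
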