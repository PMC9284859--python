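import numpy as np
import pytest

from premnlp.corpus import EmbeddingTable
from premnlp.topics import (
    UNASSIGNED,
    Stratum,
    StratumTooSmall,
    StratumTopicModel,
    assign_topics,
    fit_nmf,
    select_k,
    topic_coherence,
    topic_descriptors,
)


def planted_matrix(seed=0, n=60, m=30, k=3):
    """Block-separable nonnegative X = W0 @ H0 with known rank."""
    rng = np.random.default_rng(seed)
    W0 = np.zeros((n, k))
    H0 = np.zeros((k, m))
    for j in range(k):
        W0[j * (n // k) : (j + 1) * (n // k), j] = rng.uniform(0.5, 1.5, n // k)
        H0[j, j * (m // k) : (j + 1) * (m // k)] = rng.uniform(0.5, 1.5, m // k)
    return W0 @ H0


class TestFitNMF:
    def test_planted_factors_recovered(self):
        X = planted_matrix()
        W, H, info = fit_nmf(X, k=3, seed=0)
        rel = np.linalg.norm(X - W @ H) / np.linalg.norm(X)
        assert rel < 0.05
        assert (W >= 0).all() and (H >= 0).all()

    def test_zero_matrix(self):
        W, H, info = fit_nmf(np.zeros((4, 5)), k=2)
        assert not W.any() and not H.any()
        assert info["residuals"][-1] == 0.0

    def test_deterministic(self):
        X = planted_matrix(seed=1)
        W1, H1, _ = fit_nmf(X, k=3, seed=5)
        W2, H2, _ = fit_nmf(X, k=3, seed=5)
        np.testing.assert_array_equal(W1, W2)
        np.testing.assert_array_equal(H1, H2)

    def test_k_too_large(self):
        with pytest.raises(ValueError):
            fit_nmf(np.ones((3, 4)), k=4)

    def test_negative_entry_rejected(self):
        X = np.ones((4, 4))
        X[0, 0] = -1
        with pytest.raises(ValueError):
            fit_nmf(X, k=2)

    def test_residuals_non_increasing(self):
        X = planted_matrix(seed=2)
        _, _, info = fit_nmf(X, k=3)
        res = info["residuals"]
        assert all(a >= b - 1e-9 for a, b in zip(res, res[1:]))

    def test_comparable_to_reference_implementation(self):
        """Reconstruction error within 10% of sklearn's NMF on the same
        problem (independent solver as cross-check)."""
        from sklearn.decomposition import NMF

        X = planted_matrix(seed=3)
        W, H, _ = fit_nmf(X, k=3)
        ours = np.linalg.norm(X - W @ H)
        ref = NMF(n_components=3, init="nndsvda", max_iter=400, random_state=0)
        Wr = ref.fit_transform(X)
        theirs = np.linalg.norm(X - Wr @ ref.components_)
        assert ours <= max(theirs * 1.1, 0.05 * np.linalg.norm(X))


def embeddings_from(vectors):
    return EmbeddingTable({w: np.asarray(v, float) for w, v in vectors.items()})


class TestCoherence:
    def test_identical_vectors_give_one(self):
        emb = embeddings_from({"a": [1, 0], "b": [1, 0], "c": [1, 0]})
        assert topic_coherence(["a", "b", "c"], emb) == pytest.approx(1.0)

    def test_orthogonal_pair_gives_zero(self):
        emb = embeddings_from({"a": [1, 0], "b": [0, 1]})
        assert topic_coherence(["a", "b"], emb) == pytest.approx(0.0)

    def test_sixty_degrees_gives_half(self):
        emb = embeddings_from({"a": [1, 0], "b": [0.5, np.sqrt(3) / 2]})
        assert topic_coherence(["a", "b"], emb) == pytest.approx(0.5)

    def test_permutation_invariant_and_bounded(self):
        rng = np.random.default_rng(0)
        emb = embeddings_from(
            {f"w{i}": rng.normal(size=5) for i in range(10)}
        )
        terms = [f"w{i}" for i in range(10)]
        c1 = topic_coherence(terms, emb)
        c2 = topic_coherence(terms[::-1], emb)
        assert c1 == pytest.approx(c2)
        assert -1.0 <= c1 <= 1.0

    def test_ngram_embedded_as_mean(self):
        emb = embeddings_from({"a": [1, 0], "b": [0, 1], "c": [1, 0]})
        # "a b" embeds as normalized mean -> 45 degrees from both axes
        got = topic_coherence(["a b", "c"], emb)
        assert got == pytest.approx(np.cos(np.pi / 4))

    def test_unembeddable_terms_warn_and_zero(self):
        emb = embeddings_from({"a": [1, 0]})
        with pytest.warns(UserWarning):
            assert topic_coherence(["x", "y"], emb) == 0.0


class TestSelectK:
    def test_tie_prefers_smaller_k(self):
        # embeddings in which every word is identical: all coherences 1
        emb = embeddings_from({f"w{i}": [1.0, 0.0] for i in range(6)})
        X = planted_matrix(seed=4, n=12, m=6, k=2)
        vocab = [f"w{i}" for i in range(6)]
        k, *_ , log = select_k(X, vocab, emb, k_range=range(2, 5), seed=0)
        assert max(log.values()) == pytest.approx(log[k])
        assert all(log[k] >= v - 1e-12 for v in log.values())
        assert k == min(kk for kk, v in log.items() if v >= max(log.values()) - 1e-12)

    def test_k_range_clipped_to_matrix(self):
        emb = embeddings_from({f"w{i}": [1.0, 0.0] for i in range(8)})
        rng = np.random.default_rng(0)
        X = rng.uniform(size=(6, 8))
        vocab = [f"w{i}" for i in range(8)]
        _, _, _, _, log = select_k(X, vocab, emb, k_range=range(2, 16), seed=0)
        assert max(log) == 6  # clipped to n_docs

    def test_too_small_stratum_signals_skip(self):
        emb = embeddings_from({"a": [1, 0]})
        with pytest.raises(StratumTooSmall):
            select_k(np.ones((2, 3)), ["a", "b", "c"], emb)


class TestAssignTopics:
    def test_argmax(self):
        assert assign_topics(np.array([[0.9, 0.1]]))[0] == 0

    def test_zero_row_unassigned(self):
        out = assign_topics(np.array([[0.0, 0.0], [0.2, 0.8]]))
        assert out[0] == UNASSIGNED and out[1] == 1

    def test_tie_lowest_index(self):
        assert assign_topics(np.array([[0.4, 0.4]]))[0] == 0

    def test_conservation(self):
        rng = np.random.default_rng(1)
        W = rng.uniform(size=(40, 3))
        W[rng.choice(40, 5, replace=False)] = 0.0
        a = assign_topics(W)
        counts = [(a == j).sum() for j in range(3)]
        assert sum(counts) + (a == UNASSIGNED).sum() == 40


class TestDescriptors:
    def test_subsequence_removed(self):
        vocab = ["went very well", "went well", "friendly", "info"]
        h = np.array([4.0, 3.0, 2.0, 1.0])
        desc = topic_descriptors(h, vocab)
        assert "went very well" in desc
        assert "went well" not in desc

    def test_fewer_survivors_than_show(self):
        vocab = ["aaa bbb ccc", "aaa bbb", "ddd"]
        h = np.array([3.0, 2.0, 1.0])
        desc = topic_descriptors(h, vocab, show=5)
        assert desc == ["aaa bbb ccc", "ddd"]

    def test_longest_first(self):
        vocab = ["alpha", "beta gamma delta"]
        h = np.array([5.0, 1.0])
        assert topic_descriptors(h, vocab) == ["beta gamma delta", "alpha"]

    def test_no_contiguous_subsequence_pairs_retained(self):
        rng = np.random.default_rng(0)
        words = ["aa", "bb", "cc", "dd"]
        for _ in range(50):
            vocab = sorted(
                {
                    " ".join(
                        words[rng.integers(4)] for _ in range(rng.integers(1, 4))
                    )
                    for _ in range(12)
                }
            )
            h = rng.uniform(size=len(vocab))
            desc = topic_descriptors(h, vocab)
            toks = [tuple(t.split()) for t in desc]
            for a in toks:
                for b in toks:
                    if a is b or len(a) >= len(b):
                        continue
                    contiguous = any(
                        b[i : i + len(a)] == a for i in range(len(b) - len(a) + 1)
                    )
                    assert not contiguous, (a, b)

    def test_zero_row_warns_empty(self):
        with pytest.warns(UserWarning):
            assert topic_descriptors(np.zeros(3), ["a", "b", "c"]) == []

    def test_top_terms_weight_ties_lexicographic(self):
        vocab = ["zz", "aa", "mm"]
        h = np.array([1.0, 1.0, 1.0])
        desc = topic_descriptors(h, vocab, top_terms=2)
        assert desc == ["aa", "mm"]


class TestStratumModel:
    def test_fit_returns_consistent_results(self):
        rng = np.random.default_rng(0)
        emb = embeddings_from(
            {f"w{i}": rng.normal(size=8) for i in range(12)}
        )
        X = planted_matrix(seed=5, n=24, m=12, k=3)
        vocab = [f"w{i}" for i in range(12)]
        keys = tuple((f"r{i}", "Q1") for i in range(24))
        model = StratumTopicModel(
            Stratum("Q1", "positive", keys), X, vocab, emb, k_range=range(2, 7)
        )
        res = model.fit(seed=3)
        assert sum(res.topic_counts) + res.n_unassigned == len(keys)
        assert res.W.shape == (24, res.k)
        assert res.k in range(2, 7)
        assert set(res.coherence_by_k) == set(range(2, 7))
        assert len(res.descriptors) == res.k
        manifest = res.manifest()
        assert manifest["k"] == res.k
        assert "summary" not in manifest
        assert "selected k" in res.summary()

    def test_neutral_stratum_rejected(self):
        with pytest.raises(ValueError):
            Stratum("Q1", "neutral", (("r1", "Q1"),))
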