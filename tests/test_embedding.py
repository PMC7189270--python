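import numpy as np
import pytest

from eventemb.embedding import (
    EventEmbedding,
    SkipGramParams,
    load_word2vec_text,
    train_embedding,
)
from eventemb.event_graph import build_event_graph
from eventemb.sampling import SamplingConfig, sample_environments
from eventemb.synthetic import make_planted_communities, make_random_events


def toy_corpus(n_sentences=1000, seed=0):
    """Three tokens: A and B always co-occur, C only ever with itself-ish
    filler D, so A-B should embed closer than A-C."""
    rng = np.random.default_rng(seed)
    corpus = []
    for _ in range(n_sentences):
        if rng.random() < 0.5:
            corpus.append(["A", "B", "B", "A"])
        else:
            corpus.append(["C", "D", "D", "C"])
    return corpus


@pytest.fixture(scope="module")
def small_embedding():
    corpus = toy_corpus(200)
    return train_embedding(corpus, 16, SkipGramParams(epochs=3, seed=1))


class TestTrainEmbedding:
    def test_vector_shapes(self, small_embedding):
        assert small_embedding.dimension == 16
        for tok in small_embedding.tokens:
            assert small_embedding.vector(tok).shape == (16,)

    def test_every_corpus_token_embedded(self):
        tn = make_random_events(8, 30, 10, seed=0)
        g = build_event_graph(tn)
        envs, skipped = sample_environments(g, SamplingConfig(seed=0))
        emb = train_embedding(envs, 4, SkipGramParams(epochs=1, seed=0))
        for env in envs:
            assert env.center in emb

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_embedding([], 8)

    def test_bad_dimension_rejected(self):
        with pytest.raises(ValueError):
            train_embedding(toy_corpus(10), 0)

    def test_deterministic_under_seed(self):
        params = SkipGramParams(epochs=2, seed=7)
        e1 = train_embedding(toy_corpus(100), 8, params)
        e2 = train_embedding(toy_corpus(100), 8, params)
        np.testing.assert_array_equal(e1.matrix, e2.matrix)

    def test_seed_changes_vectors(self):
        e1 = train_embedding(toy_corpus(100), 8, SkipGramParams(epochs=2, seed=1))
        e2 = train_embedding(toy_corpus(100), 8, SkipGramParams(epochs=2, seed=2))
        assert not np.allclose(e1.matrix, e2.matrix)

    def test_cooccurring_tokens_closer_majority_vote(self):
        wins = 0
        for seed in range(10):
            emb = train_embedding(toy_corpus(1000, seed), 8, SkipGramParams(seed=seed))
            close = emb.euclidean_distance("A", "B")
            far = emb.euclidean_distance("A", "C")
            wins += close < far
        assert wins > 5

    def test_numpy_fallback_kernel(self, monkeypatch):
        import eventemb.embedding as mod

        monkeypatch.setattr(mod, "_HAVE_NUMBA", False)
        emb = mod.train_embedding(toy_corpus(200), 8, SkipGramParams(epochs=2, seed=3))
        assert emb.matrix.shape == (4, 8)
        assert np.isfinite(emb.matrix).all()
        close = emb.euclidean_distance("A", "B")
        far = emb.euclidean_distance("A", "C")
        assert close < far

    def test_untied_variant_trains(self):
        emb = train_embedding(
            toy_corpus(50), 4, SkipGramParams(epochs=1, seed=0, tied_weights=False)
        )
        assert emb.matrix.shape == (4, 4)


class TestEuclideanDistance:
    def test_self_distance_zero(self, small_embedding):
        assert small_embedding.euclidean_distance("A", "A") == 0.0

    def test_symmetry(self, small_embedding):
        assert small_embedding.euclidean_distance("A", "C") == pytest.approx(
            small_embedding.euclidean_distance("C", "A")
        )

    def test_three_four_five(self):
        emb = EventEmbedding(2, ["p", "q"], np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert emb.euclidean_distance("p", "q") == pytest.approx(5.0)

    def test_missing_token_raises(self, small_embedding):
        with pytest.raises(KeyError):
            small_embedding.vector("missing")


class TestWord2VecFormat:
    def test_round_trip(self, tmp_path, small_embedding):
        path = tmp_path / "emb.txt"
        small_embedding.save_word2vec_text(path)
        loaded = load_word2vec_text(path)
        assert loaded.tokens == small_embedding.tokens
        np.testing.assert_allclose(loaded.matrix, small_embedding.matrix, rtol=1e-5)

    def test_header_format(self, tmp_path, small_embedding):
        path = tmp_path / "emb.txt"
        small_embedding.save_word2vec_text(path)
        header = path.read_text().split("\n")[0]
        assert header == f"{len(small_embedding.tokens)} 16"


class TestEmbeddingGeometry:
    """Directional claims, asserted on means over several seeds."""

    def test_disjoint_communities_separate(self):
        intra_all, inter_all = [], []
        for seed in range(5):
            planted = make_planted_communities(2, 8, 10, p_in=0.3, p_out=0.0, seed=seed)
            tn = planted.network
            g = build_event_graph(tn)
            envs, _ = sample_environments(g, SamplingConfig(seed=seed))
            emb = train_embedding(envs, 8, SkipGramParams(epochs=3, seed=seed))
            evs = [e for e in tn.events if e in emb]
            X = np.stack([emb.vector(e) for e in evs])
            lab = np.array([planted.event_labels[e] for e in evs])
            from scipy.spatial.distance import pdist, squareform

            D = squareform(pdist(X))
            iu = np.triu_indices(len(evs), 1)
            same = (lab[:, None] == lab[None, :])[iu]
            intra_all.append(D[iu][same].mean())
            inter_all.append(D[iu][~same].mean())
        assert np.mean(intra_all) < np.mean(inter_all)

    def test_linked_events_closer_than_random_pairs(self):
        rng = np.random.default_rng(0)
        linked_means, random_means = [], []
        for seed in range(5):
            tn = make_random_events(12, 120, 30, seed=seed)
            g = build_event_graph(tn)
            envs, _ = sample_environments(g, SamplingConfig(seed=seed))
            emb = train_embedding(envs, 8, SkipGramParams(epochs=3, seed=seed))
            evs = [e for e in tn.events if e in emb]
            linked = [
                emb.euclidean_distance(edge.src, edge.dst)
                for edge in g.edges
                if edge.src in emb and edge.dst in emb
            ]
            idx = rng.integers(0, len(evs), size=(500, 2))
            rand = [
                emb.euclidean_distance(evs[a], evs[b]) for a, b in idx if a != b
            ]
            linked_means.append(np.mean(linked))
            random_means.append(np.mean(rand))
        assert np.mean(linked_means) < np.mean(random_means)
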