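import numpy as np
import pytest

from eventemb.event_graph import build_event_graph
from eventemb.sampling import SamplingConfig, sample_environments, sampling_probabilities
from eventemb.synthetic import make_random_events
from eventemb.temporal_io import Event, TemporalNetwork


@pytest.fixture
def two_neighbor_graph():
    # center (a,b,1); predecessor (a,c,0) at gap 1 (w_path 0.5);
    # successor (b,c,4) at gap 3 (w_path 0.25)
    tn = TemporalNetwork([Event(0, "a", "c"), Event(1, "a", "b"), Event(4, "b", "c")])
    return tn, build_event_graph(tn)


class TestSamplingConfig:
    @pytest.mark.parametrize("bad", [{"alpha": -0.1}, {"alpha": 1.1}, {"nb": 0}, {"s": 0}, {"mode": "x"}])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(ValueError):
            SamplingConfig(**bad)


class TestSamplingProbabilities:
    def test_single_neighbor_prob_one(self):
        tn = TemporalNetwork([Event(0, "a", "b"), Event(1, "b", "c")])
        g = build_event_graph(tn)
        for alpha in (0.0, 0.3, 1.0):
            probs = sampling_probabilities(g, tn.events[0], alpha)
            assert probs == {tn.events[1]: pytest.approx(1.0)}

    def test_alpha_one_uses_w_path_only(self, two_neighbor_graph):
        tn, g = two_neighbor_graph
        center = tn.events[1]
        probs = sampling_probabilities(g, center, alpha=1.0)
        # w_path 0.5 (gap 1) vs 0.25 (gap 2) -> 2/3 vs 1/3
        assert probs[tn.events[0]] == pytest.approx(2 / 3)
        assert probs[tn.events[2]] == pytest.approx(1 / 3)

    def test_mixed_alpha_hand_computed(self):
        # center X=(a,b,1); neighbors P=(a,c,0) gap 1 and S=(a,c,2) gap 1.
        # both on link (a,c): w_path = (0.5, 0.5), w_co identical -> p = (0.5, 0.5)
        tn = TemporalNetwork([Event(0, "a", "c"), Event(1, "a", "b"), Event(2, "a", "c")])
        g = build_event_graph(tn)
        probs = sampling_probabilities(g, tn.events[1], alpha=0.5)
        assert probs[tn.events[0]] == pytest.approx(0.5)
        assert probs[tn.events[2]] == pytest.approx(0.5)

    def test_mixed_alpha_asymmetric_weights(self, monkeypatch):
        """Hand evaluation of the mixing rule on injected weights:
        (w_path, w_co) = (0.5, 1) and (0.5, 3) at alpha=0.5
        -> p = (0.5*0.5 + 0.5*0.25, 0.5*0.5 + 0.5*0.75) = (0.375, 0.625)."""
        tn = TemporalNetwork([Event(0, "a", "c"), Event(1, "a", "b"), Event(2, "b", "c")])
        g = build_event_graph(tn)
        center = tn.events[1]
        nb = [(tn.events[0], 0.5, 1), (tn.events[2], 0.5, 3)]
        monkeypatch.setattr(g, "neighborhood", lambda e, mode="combined": nb)
        probs = sampling_probabilities(g, center, alpha=0.5)
        assert probs[tn.events[0]] == pytest.approx(0.375)
        assert probs[tn.events[2]] == pytest.approx(0.625)

    def test_empty_neighborhood_returns_empty(self):
        tn = TemporalNetwork([Event(0, "a", "b"), Event(1, "c", "d")])
        g = build_event_graph(tn)
        assert sampling_probabilities(g, tn.events[0], 0.5) == {}

    def test_zero_w_co_uniform_fallback(self, two_neighbor_graph):
        tn, g = two_neighbor_graph
        # links (a,c) and (b,c) never co-fire with (a,b) -> all w_co = 0
        probs = sampling_probabilities(g, tn.events[1], alpha=0.0)
        assert probs[tn.events[0]] == pytest.approx(0.5)
        assert probs[tn.events[2]] == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha", [0.0, 0.25, 0.5, 1.0])
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_probabilities_sum_to_one(self, alpha, seed):
        tn = make_random_events(8, 40, 15, seed=seed)
        g = build_event_graph(tn)
        for e in tn.events:
            probs = sampling_probabilities(g, e, alpha)
            if probs:
                assert sum(probs.values()) == pytest.approx(1.0, abs=1e-12)

    def test_affine_in_alpha(self):
        tn = make_random_events(8, 40, 15, seed=11)
        g = build_event_graph(tn)
        e = next(e for e in tn.events if len(g.neighborhood(e)) >= 2)
        p0 = sampling_probabilities(g, e, 0.0)
        p1 = sampling_probabilities(g, e, 1.0)
        pm = sampling_probabilities(g, e, 0.3)
        for ev in p0:
            assert pm[ev] == pytest.approx(0.3 * p1[ev] + 0.7 * p0[ev])


class TestSampleEnvironments:
    def test_counts_and_lengths(self):
        tn = make_random_events(6, 20, 8, seed=0)
        g = build_event_graph(tn)
        cfg = SamplingConfig(nb=4, s=7, seed=1)
        envs, skipped = sample_environments(g, cfg)
        non_isolated = len(tn.events) - len(skipped)
        assert len(envs) == 4 * non_isolated
        assert all(len(env.context) == 7 for env in envs)

    def test_single_neighbor_fills_context(self):
        tn = TemporalNetwork([Event(0, "a", "b"), Event(1, "b", "c")])
        g = build_event_graph(tn)
        envs, _ = sample_environments(g, SamplingConfig(nb=2, s=5, seed=0))
        for env in envs:
            assert len(set(env.context)) == 1

    def test_deterministic_under_seed(self):
        tn = make_random_events(8, 30, 10, seed=2)
        g = build_event_graph(tn)
        cfg = SamplingConfig(seed=123)
        envs1, _ = sample_environments(g, cfg)
        envs2, _ = sample_environments(g, cfg)
        assert [e.tokens for e in envs1] == [e.tokens for e in envs2]

    def test_context_members_are_first_neighbors(self):
        tn = make_random_events(8, 30, 10, seed=3)
        g = build_event_graph(tn)
        envs, _ = sample_environments(g, SamplingConfig(seed=0))
        for env in envs:
            neighbors = {n[0] for n in g.neighborhood(env.center)}
            assert set(env.context) <= neighbors

    def test_predecessors_only_never_future(self):
        tn = make_random_events(8, 40, 12, seed=4)
        g = build_event_graph(tn)
        envs, _ = sample_environments(g, SamplingConfig(mode="predecessors_only", seed=0))
        for env in envs:
            assert all(c.t < env.center.t for c in env.context)

    def test_empirical_frequencies_match_probabilities(self):
        tn = TemporalNetwork(
            [Event(0, "a", "c"), Event(1, "a", "b"), Event(2, "a", "c"), Event(4, "b", "c")]
        )
        g = build_event_graph(tn)
        center = tn.events[1]
        probs = sampling_probabilities(g, center, alpha=0.7)
        assert len(probs) >= 2
        cfg = SamplingConfig(alpha=0.7, nb=2000, s=10, seed=9)
        envs, _ = sample_environments(g, cfg)
        draws = [c for env in envs if env.center == center for c in env.context]
        n = len(draws)
        assert n == 20000
        for ev, p in probs.items():
            freq = sum(d == ev for d in draws) / n
            assert abs(freq - p) <= 4 * np.sqrt(p * (1 - p) / n)
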