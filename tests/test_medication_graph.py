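import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import medsim as m
from medsim.medication_graph import DEFAULT_CONFIG, extract_med_pairs

from conftest import brute_force_path, random_agent_graph

ZERO_DELTA = np.zeros(5)


def _rec(agent, strength=100.0, dose=1.0, freq=2.0, sunit="mg", dunit="tablet"):
    return m.MedicationRecord(agent, strength, sunit, dose, dunit, freq)


class TestEdgeWeight:
    def test_zero_lambda_passes_score_through(self):
        assert m.edge_weight([(3.0, ZERO_DELTA)], m.LambdaWeights()) == 3.0

    def test_saturated_adjustment_clips_at_smax(self):
        lam = m.LambdaWeights(lambda0=100.0)
        assert m.edge_weight([(4.5, ZERO_DELTA)], lam) == 5.0

    def test_observation_set_is_averaged(self):
        obs = [(2.0, ZERO_DELTA), (4.0, ZERO_DELTA)]
        assert m.edge_weight(obs, m.LambdaWeights()) == 3.0

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError):
            m.edge_weight([], m.LambdaWeights())

    def test_weight_floor_applied(self):
        lam = m.LambdaWeights(lambda0=-100.0)
        w = m.edge_weight([(0.0, ZERO_DELTA)], lam)
        assert w == DEFAULT_CONFIG.weight_floor


class TestBuildGraph:
    def test_single_pair_graph(self):
        g = m.build_graph([(_rec("a"), _rec("b"), 4.0)], m.LambdaWeights())
        assert g.nodes == {"a", "b"}
        assert g.weight("a", "b") == 4.0

    def test_co_occurrence_rule(self):
        g = m.build_graph(
            [(_rec("a"), _rec("b"), 4.0), (_rec("b"), _rec("c"), 3.0)],
            m.LambdaWeights(),
        )
        assert g.weight("a", "c") is None
        assert m.path_similarity(g, "a", "c").found

    def test_duplicate_pairs_collapse_to_one_averaged_edge(self):
        g = m.build_graph(
            [(_rec("a"), _rec("b"), 2.0), (_rec("b"), _rec("a"), 4.0)],
            m.LambdaWeights(),
        )
        assert len(g.edges) == 1
        assert g.weight("a", "b") == 3.0
        assert g.n_obs[("a", "b")] == 2

    def test_self_pairs_excluded_from_edges(self):
        g = m.build_graph([(_rec("a"), _rec("a"), 5.0)], m.LambdaWeights())
        assert "a" in g.nodes and not g.edges


class TestPathSimilarity:
    def test_direct_edge_is_identity(self):
        g = m.build_graph([(_rec("a"), _rec("b"), 4.0)], m.LambdaWeights())
        res = m.path_similarity(g, "a", "b")
        assert res.found and res.s_hat == 4.0

    def test_two_hop_parallel_resistance(self):
        g = m.build_graph(
            [(_rec("a"), _rec("b"), 4.0), (_rec("b"), _rec("c"), 4.0)],
            m.LambdaWeights(),
        )
        res = m.path_similarity(g, "a", "c")
        assert res.s_hat == pytest.approx(2.0)  # 1/(1/4 + 1/4)
        assert res.path == ("a", "b", "c")

    def test_disconnected_components_not_found(self):
        g = m.build_graph(
            [(_rec("a"), _rec("b"), 4.0), (_rec("c"), _rec("d"), 3.0)],
            m.LambdaWeights(),
        )
        assert not m.path_similarity(g, "a", "c").found

    def test_self_query_rejected(self):
        g = m.build_graph([(_rec("a"), _rec("b"), 4.0)], m.LambdaWeights())
        with pytest.raises(ValueError):
            m.path_similarity(g, "a", "a")

    def test_matches_brute_force_on_random_graphs(self):
        """Dijkstra equals exhaustive simple-path enumeration, and the
        aggregate never exceeds the smallest weight on the chosen path."""
        rng = np.random.default_rng(123)
        checked = 0
        for _ in range(60):
            g, names = random_agent_graph(rng)
            a, b = rng.choice(names, size=2, replace=False)
            expected = brute_force_path(g, a, b)
            res = m.path_similarity(g, a, b)
            if expected is None:
                assert not res.found
                continue
            checked += 1
            exp_res, _, exp_path = expected
            assert res.found
            assert res.path == exp_path
            assert res.s_hat == pytest.approx(1.0 / exp_res, rel=1e-12)
            min_w = min(
                g.weight(u, v) for u, v in zip(res.path, res.path[1:])
            )
            assert res.s_hat <= min_w + 1e-12
        assert checked > 20

    def test_appending_edges_never_increases_similarity(self):
        """Dissimilarity cannot be restored: a longer chain of the same
        weights scores lower."""
        lam = m.LambdaWeights()
        prev = None
        for n in range(2, 7):
            pairs = [
                (_rec(f"n{i}"), _rec(f"n{i+1}"), 3.0) for i in range(n - 1)
            ]
            g = m.build_graph(pairs, lam)
            s = m.path_similarity(g, "n0", f"n{n-1}").s_hat
            if prev is not None:
                assert s < prev
            prev = s


class TestPredictPair:
    def test_zero_lambda_returns_path_similarity(self):
        g = m.build_graph([(_rec("a"), _rec("b"), 3.0)], m.LambdaWeights())
        s = m.predict_pair(g, m.LambdaWeights(), _rec("a"), _rec("b"))
        assert s == pytest.approx(3.0)

    def test_clips_at_smin(self):
        lam = m.LambdaWeights(lambda0=100.0)  # tanh ≈ 1 both directions
        g = m.build_graph([(_rec("a"), _rec("b"), 0.2)], m.LambdaWeights())
        s = m.predict_pair(g, lam, _rec("a"), _rec("b"))
        assert s == 0.0

    def test_inverse_transform_round_trip(self):
        """With one observation and the same Δ at inference, the edge
        adjustment and the inference adjustment cancel exactly."""
        lam = m.LambdaWeights(0.1, (1e-5, 0.2, 0.1, 0.3, 0.05))
        rec_a = _rec("a", strength=100.0, dose=1.0, freq=2.0)
        rec_b = _rec("b", strength=110.0, dose=2.0, freq=3.0, dunit="capsule")
        s_obs = 2.5  # adjustment keeps s inside (0, 5): no clipping
        g = m.build_graph([(rec_a, rec_b, s_obs)], lam)
        s = m.predict_pair(g, lam, rec_a, rec_b)
        assert s == pytest.approx(s_obs, abs=1e-9)

    def test_same_agent_pair_uses_max_similarity(self):
        g = m.build_graph([(_rec("a"), _rec("b"), 3.0)], m.LambdaWeights())
        s = m.predict_pair(g, m.LambdaWeights(), _rec("a"), _rec("a"))
        assert s == 5.0

    def test_unseen_agent_returns_none_by_default(self):
        g = m.build_graph([(_rec("a"), _rec("b"), 3.0)], m.LambdaWeights())
        assert m.predict_pair(g, m.LambdaWeights(), _rec("x"), _rec("y")) is None

    def test_disconnected_fallback_value_used(self):
        cfg = m.GraphConfig(disconnected_fallback=2.5)
        g = m.build_graph([(_rec("a"), _rec("b"), 3.0)], m.LambdaWeights(), cfg)
        s = m.predict_pair(g, m.LambdaWeights(), _rec("x"), _rec("y"), cfg)
        assert s == 2.5


@settings(max_examples=60, deadline=None)
@given(
    s=st.floats(0, 5, allow_nan=False),
    lam0=st.floats(-3, 3, allow_nan=False),
    lams=st.tuples(*[st.floats(-1, 1, allow_nan=False)] * 5),
    strengths=st.tuples(
        st.floats(0, 500, allow_nan=False), st.floats(0, 500, allow_nan=False)
    ),
)
def test_scores_always_in_range_property(s, lam0, lams, strengths):
    """edge_weight and predict_pair always land in [0, 5]."""
    lam = m.LambdaWeights(lam0, lams)
    rec_a = _rec("a", strength=strengths[0])
    rec_b = _rec("b", strength=strengths[1], dose=2.0, freq=4.0)
    g = m.build_graph([(rec_a, rec_b, s)], lam)
    w = g.weight("a", "b")
    assert 0 <= w <= 5
    pred = m.predict_pair(g, lam, rec_a, rec_b)
    assert 0 <= pred <= 5


def _synth_med_pairs(seed=0, n_pairs=120, n_agents=10, noise_sd=0.2,
                     lambda_true=None):
    kwargs = {} if lambda_true is None else {"lambda_true": lambda_true}
    cfg = m.SynthConfig(
        n_agents=n_agents, n_pairs=n_pairs, med_fraction=1.0,
        noise_sd=noise_sd, seed=seed, **kwargs,
    )
    corpus, truth = m.generate_corpus(cfg)
    _, med_pairs = extract_med_pairs(corpus)
    return corpus, truth, med_pairs


class TestRandomWalkFit:
    def test_trace_strictly_decreasing_and_deterministic(self):
        _, _, med_pairs = _synth_med_pairs(seed=1)
        lam1, trace1 = m.random_walk_fit(med_pairs, m.LambdaWeights(), seed=9)
        lam2, trace2 = m.random_walk_fit(med_pairs, m.LambdaWeights(), seed=9)
        assert lam1 == lam2
        assert trace1 == trace2
        assert all(b < a for a, b in zip(trace1, trace1[1:]))

    def test_noise_free_zero_lambda_never_degrades(self):
        """When the data were generated with λ* = 0 and no noise, the walk
        can only keep improvements over the λ = 0 start."""
        _, _, med_pairs = _synth_med_pairs(
            seed=2, noise_sd=0.0, lambda_true=m.LambdaWeights()
        )
        _, trace = m.random_walk_fit(med_pairs, m.LambdaWeights(), seed=3)
        assert trace[-1] <= trace[0]

    def test_fit_improves_over_zero_lambda_with_true_effect(self):
        _, _, med_pairs = _synth_med_pairs(seed=3)
        evaluator_lam, trace = m.random_walk_fit(
            med_pairs, m.LambdaWeights(), seed=4
        )
        assert trace[-1] < trace[0]

    def test_fewer_pairs_than_folds_rejected(self):
        _, _, med_pairs = _synth_med_pairs(seed=4, n_pairs=5, n_agents=4)
        with pytest.raises(ValueError):
            m.random_walk_fit(med_pairs, m.LambdaWeights(), folds=10)


class TestFitFusion:
    def test_learnable_identity_mapping(self):
        rng = np.random.default_rng(0)
        gold = rng.uniform(0, 5, 80)
        graph_scores = rng.uniform(0, 5, 80)
        fusion = m.fit_fusion(graph_scores, gold, gold)
        preds = fusion.predict(graph_scores, gold)
        assert np.mean((preds - gold) ** 2) < 0.25

    def test_constant_gold_within_epsilon_tube(self):
        rng = np.random.default_rng(1)
        gold = np.full(40, 2.0)
        fusion = m.fit_fusion(rng.uniform(0, 5, 40), rng.uniform(0, 5, 40), gold)
        preds = fusion.predict(rng.uniform(0, 5, 40), rng.uniform(0, 5, 40))
        assert np.all(np.abs(preds - 2.0) <= fusion.epsilon + 1e-6)

    def test_row_order_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.uniform(0, 5, 60)
        b = rng.uniform(0, 5, 60)
        y = np.clip(0.5 * g + 0.5 * b + rng.normal(0, 0.1, 60), 0, 5)
        f1 = m.fit_fusion(g, b, y, grid_C=[10.0], grid_eps=[0.1])
        perm = rng.permutation(60)
        f2 = m.fit_fusion(g[perm], b[perm], y[perm], grid_C=[10.0], grid_eps=[0.1])
        q = np.linspace(0, 5, 20)
        np.testing.assert_allclose(f1.predict(q, q), f2.predict(q, q), atol=1e-6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            m.fit_fusion([1.0] * 10, [1.0] * 9, [1.0] * 10)


@pytest.fixture(scope="module")
def fitted():
    cfg = m.SynthConfig(
        n_agents=12, n_pairs=150, med_fraction=0.7, noise_sd=0.2, seed=21
    )
    corpus, truth = m.generate_corpus(cfg)
    base = np.full(len(corpus), float(np.mean(corpus.scores())))
    model = m.alternate_fit(corpus, base, seed=17, steps=15)
    return corpus, truth, base, model


class TestAlternateFitAndReplacement:
    def test_reproducible_under_seed(self, fitted):
        corpus, _, base, model = fitted
        model2 = m.alternate_fit(corpus, base, seed=17, steps=15)
        assert model.lam == model2.lam
        assert model.mse_trace == model2.mse_trace

    def test_trace_never_increases_across_iterations(self, fitted):
        _, _, _, model = fitted
        assert model.mse_trace[-1] <= model.mse_trace[0]

    def test_replacement_only_touches_medication_subset(self, fitted):
        corpus, truth, base, model = fitted
        preds = m.predict_with_replacement(
            corpus, base, model.graph, model.lam, model.fusion, model.cfg
        )
        changed = preds != base
        assert np.all(truth.is_medication[changed])
        assert np.all((preds >= 0) & (preds <= 5))

    def test_no_medication_pairs_keeps_base_and_fit_errors(self):
        cfg = m.SynthConfig(
            n_agents=5, n_pairs=30, med_fraction=0.0, noise_sd=0.1, seed=5
        )
        corpus, _ = m.generate_corpus(cfg)
        base = np.linspace(0, 5, len(corpus))
        with pytest.raises(ValueError):
            m.alternate_fit(corpus, base, seed=1)


class TestGraphModelPersistence:
    def test_save_load_round_trip(self, tmp_path):
        cfg = m.SynthConfig(
            n_agents=8, n_pairs=60, med_fraction=1.0, noise_sd=0.2, seed=8
        )
        corpus, _ = m.generate_corpus(cfg)
        base = np.full(len(corpus), 2.5)
        model = m.alternate_fit(corpus, base, seed=2, steps=5, iterations=1)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = m.GraphModel.load(path)
        assert loaded.lam == model.lam
        assert loaded.graph.edges == model.graph.edges
        p1 = m.predict_with_replacement(
            corpus, base, model.graph, model.lam, model.fusion, model.cfg
        )
        p2 = m.predict_with_replacement(
            corpus, base, loaded.graph, loaded.lam, loaded.fusion, loaded.cfg
        )
        np.testing.assert_allclose(p1, p2, atol=1e-9)
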