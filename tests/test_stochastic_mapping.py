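import numpy as np
import pytest

import styleevo as se
from styleevo.mk_hmm import ALL_RATES_DIFFERENT, EQUAL_RATES
from styleevo.stochastic_mapping import (
    count_transitions,
    density_mode,
    event_ages,
    ltt_by_state,
    simulate_branch_conditional,
    summarize_maps,
)
from styleevo.synthetic_data import simulate_traits

from conftest import expected_conditional_events, random_tree


def _fit_result(model, rates):
    return se.FitResult(
        model=model, rates=np.asarray(rates, float), logL=0.0,
        converged=True, n_restarts=0,
    )


class TestBranchConditional:
    def test_zero_rate_empty_path(self):
        Q = np.zeros((2, 2))
        rng = np.random.default_rng(0)
        assert simulate_branch_conditional(Q, 1.0, 0, 0, rng) == []

    def test_impossible_endpoints_rejected(self):
        Q = np.zeros((2, 2))
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            simulate_branch_conditional(Q, 1.0, 0, 1, rng)

    def test_unequal_endpoints_have_odd_event_count(self):
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([0.5])
        rng = np.random.default_rng(1)
        for _ in range(200):
            path = simulate_branch_conditional(Q, 2.0, 0, 1, rng)
            assert len(path) % 2 == 1
            assert path[-1][1] == 1
            times = [t for t, _ in path]
            assert times == sorted(times)
            assert all(0 < t < 2.0 for t in times)

    def test_zero_event_probability_matches_closed_form(self):
        # P(no change | start=end=0) = exp(-qt) / P00(t) for binary ER
        q, t = 1.0, 1.0
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([q])
        p00 = 0.5 * (1 + np.exp(-2 * q * t))
        expected = np.exp(-q * t) / p00
        rng = np.random.default_rng(42)
        n = 20000
        zero = sum(
            not simulate_branch_conditional(Q, t, 0, 0, rng) for _ in range(n)
        )
        se_mc = np.sqrt(expected * (1 - expected) / n)
        assert abs(zero / n - expected) < 3 * se_mc

    def test_mean_event_count_matches_integral_oracle(self):
        q, t = 0.5, 2.0
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([q])
        want = expected_conditional_events(Q, t, 0, 1)
        rng = np.random.default_rng(7)
        n = 20000
        counts = np.array(
            [len(simulate_branch_conditional(Q, t, 0, 1, rng)) for _ in range(n)]
        )
        se_mc = counts.std(ddof=1) / np.sqrt(n)
        assert abs(counts.mean() - want) < 3 * se_mc


class TestSampleHistory:
    def test_zero_rate_constant_data_gives_eventless_maps(self, three_tip_tree):
        m = se.build_model(2, 1, EQUAL_RATES)
        fit = _fit_result(m, [1e-12])
        hs = se.sample_history(three_tip_tree, {"A": 0, "B": 0, "C": 0}, fit,
                               n_maps=20, seed=3)
        for h in hs:
            assert all(len(ev) == 0 for ev in h.events)
            assert np.all(h.node_states == 0)

    def test_histories_are_valid_and_reproducible(self):
        tree = random_tree(25, seed=6, root_age=20.0)
        m = se.build_model(2, 1, ALL_RATES_DIFFERENT)
        tips, _ = simulate_traits(tree, m, [0.05, 0.1], seed=2)
        fit = _fit_result(m, [0.05, 0.1])
        hs1 = se.sample_history(tree, tips, fit, n_maps=5, seed=11)
        hs2 = se.sample_history(tree, tips, fit, n_maps=5, seed=11)
        for h1, h2 in zip(hs1, hs2):
            h1.validate()
            assert np.array_equal(h1.node_states, h2.node_states)
            assert h1.events == h2.events
        # tip states in every map agree with the data
        for h in hs1:
            for i in tree.tip_indices:
                assert int(h.node_states[i]) % 2 == tips[tree.labels[i]]

    def test_mean_mapped_counts_match_unconditional_expectation(self):
        # maps drawn with fully ambiguous tips are unconditional forward
        # paths, so mean counts must match t * pi_i q_ij summed over edges
        tree = random_tree(40, seed=8, root_age=10.0)
        m = se.build_model(2, 1, EQUAL_RATES)
        q = 0.12
        fit = _fit_result(m, [q])
        tips = {lab: None for lab in tree.tip_labels}
        hs = se.sample_history(tree, tips, fit, n_maps=400, seed=5)
        counts = np.array([count_transitions(h, "observed")[0, 1] for h in hs])
        # stationary pi = 1/2; expected 0->1 events = T_total * pi * q
        want = tree.total_length * 0.5 * q
        se_mc = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - want) < 3.5 * se_mc


class TestCountTransitions:
    def test_projection_by_hand(self):
        # two events on one branch: R1M->R1P (gain), R1P->R2P (category switch)
        tree = se.read_newick("(A:10);")
        h = se.CharacterHistory(
            tree=tree, n_obs=2, n_hidden=2,
            node_states=np.array([0, 3]),  # root R1M, tip R2P
            events=[[], [(6.0, 1), (3.0, 3)]],
        )
        obs = count_transitions(h, "observed")
        hid = count_transitions(h, "hidden")
        assert obs[0, 1] == 1 and obs[1, 0] == 0
        assert hid[0, 1] == 1 and hid[1, 0] == 0
        comp = count_transitions(h, "composite")
        assert comp.sum() == 2

    def test_empty_history_all_zero(self, three_tip_tree):
        h = se.CharacterHistory(
            tree=three_tip_tree, n_obs=2, n_hidden=1,
            node_states=np.zeros(5, dtype=int),
            events=[[] for _ in range(5)],
        )
        assert count_transitions(h, "observed").sum() == 0

    def test_composite_counts_decompose_into_layers(self):
        tree = random_tree(30, seed=13, root_age=60.0)
        m = se.build_model(2, 2, ALL_RATES_DIFFERENT)
        rates = [0.01, 0.02, 0.1, 0.2, 0.02, 0.02, 0.05, 0.05]
        _, truth = simulate_traits(tree, m, rates, seed=9)
        comp = count_transitions(truth, "composite")
        obs = count_transitions(truth, "observed")
        hid = count_transitions(truth, "hidden")
        assert comp.sum() == obs.sum() + hid.sum()


class TestEventAges:
    def test_ages_bounded_by_branch(self):
        tree = random_tree(20, seed=4, root_age=30.0)
        m = se.build_model(2, 1, EQUAL_RATES)
        tips, truth = simulate_traits(tree, m, [0.08], seed=6)
        ages = se.node_ages(tree)
        for pair in [(0, 1), (1, 0)]:
            for a in event_ages([truth], pair):
                assert 0 < a < ages.max()

    def test_empty_sample_for_absent_type(self, three_tip_tree):
        h = se.CharacterHistory(
            tree=three_tip_tree, n_obs=2, n_hidden=1,
            node_states=np.zeros(5, dtype=int),
            events=[[] for _ in range(5)],
        )
        assert event_ages([h], (0, 1)).size == 0
        per_map = event_ages([h], (0, 1), per_map=True)
        assert len(per_map) == 1 and per_map[0].size == 0


class TestDensityMode:
    def test_degenerate_sample_returns_value(self):
        assert density_mode(np.array([3.3, 3.3, 3.3])) == pytest.approx(3.3)

    def test_known_mixture_mode(self):
        rng = np.random.default_rng(123)
        n = 10_000
        comp = rng.random(n) < 0.8
        x = np.where(comp, rng.normal(5, 1, n), rng.normal(50, 2, n))
        mode = density_mode(x, support=(0.0, 60.0))
        assert abs(mode - 5.0) < 0.5

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            density_mode(np.array([1.0]))


class TestLttByState:
    def test_constant_state_history_equals_plain_ltt(self, three_tip_tree):
        h = se.CharacterHistory(
            tree=three_tip_tree, n_obs=2, n_hidden=1,
            node_states=np.zeros(5, dtype=int),
            events=[[] for _ in range(5)],
        )
        df = ltt_by_state(h)
        s0 = df[df.state == 0].sort_values("time", ascending=False)
        # 2 lineages from the root split, 3 after the second split
        assert list(s0["count"]) == [2, 3, 3]
        assert (df[df.state == 1]["count"] == 0).all()

    def test_counts_sum_to_live_lineages_and_present_matches_tips(self):
        tree = random_tree(25, seed=19, root_age=50.0)
        m = se.build_model(2, 1, EQUAL_RATES)
        tips, truth = simulate_traits(tree, m, [0.05], seed=3)
        df = ltt_by_state(truth)
        wide = df.pivot(index="time", columns="state", values="count")
        totals = wide.sum(axis=1).sort_index(ascending=False)
        # total lineage count is the plain LTT: non-decreasing, ends at n_tips
        assert totals.iloc[-1] == tree.n_tips
        assert (np.diff(totals.values) >= 0).all()
        at_present = wide.loc[0.0]
        tallies = np.bincount(
            [tips[lab] for lab in tree.tip_labels], minlength=2
        )
        assert list(at_present) == list(tallies)


class TestSummarizeMaps:
    def test_hand_percentiles(self, three_tip_tree):
        # three maps with gain counts 1, 2, 3 -> mean 2, CI [1.05, 2.95]
        histories = []
        ev_templates = [
            [[], [(1.9, 1)], [], [], []],
            [[], [(1.9, 1), (1.7, 0), (1.5, 1)], [], [], []],
            [[], [(1.9, 1), (1.8, 0), (1.7, 1), (1.6, 0), (1.5, 1)], [], [], []],
        ]
        # node order from read_newick: root, (AB), A, B, C
        states = np.array([0, 1, 1, 1, 0])
        for i, ev in enumerate(ev_templates):
            histories.append(
                se.CharacterHistory(
                    tree=three_tip_tree, n_obs=2, n_hidden=1,
                    node_states=states, events=ev, map_index=i,
                )
            )
        s = summarize_maps(histories)
        g = s.count_stats("observed", 0, 1)
        assert g["mean"] == pytest.approx(2.0)
        assert g["q2.5"] == pytest.approx(1.05)
        assert g["q97.5"] == pytest.approx(2.95)

    def test_absent_type_zero_interval(self, three_tip_tree):
        histories = [
            se.CharacterHistory(
                tree=three_tip_tree, n_obs=2, n_hidden=1,
                node_states=np.zeros(5, dtype=int),
                events=[[] for _ in range(5)], map_index=i,
            )
            for i in range(3)
        ]
        s = summarize_maps(histories)
        g = s.count_stats("observed", 1, 0)
        assert g["mean"] == 0 and g["q2.5"] == 0 and g["q97.5"] == 0

    def test_needs_two_maps(self, three_tip_tree):
        h = se.CharacterHistory(
            tree=three_tip_tree, n_obs=2, n_hidden=1,
            node_states=np.zeros(5, dtype=int),
            events=[[] for _ in range(5)],
        )
        with pytest.raises(ValueError):
            summarize_maps([h])
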