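import numpy as np
import pytest

import styleevo as se
from styleevo.mk_hmm import (
    ALL_RATES_DIFFERENT,
    EQUAL_RATES,
    PruningEngine,
    branch_transition_matrices,
    tip_partials,
    transition_probability,
)
from styleevo.synthetic_data import SimulationScenario, simulate_tree, simulate_traits

from conftest import brute_force_loglik, brute_force_marginals, random_tree


class TestBuildModel:
    @pytest.mark.parametrize(
        "n_hidden,constraint,expected_k",
        [
            (1, EQUAL_RATES, 1),
            (1, ALL_RATES_DIFFERENT, 2),
            (2, EQUAL_RATES, 4),
            (2, ALL_RATES_DIFFERENT, 8),
        ],
    )
    def test_binary_parameter_counts(self, n_hidden, constraint, expected_k):
        m = se.build_model(2, n_hidden, constraint)
        assert m.n_params == expected_k

    def test_dual_transitions_forbidden(self):
        m = se.build_model(2, 2, ALL_RATES_DIFFERENT)
        im = m.index_matrix
        for i in range(4):
            for j in range(4):
                if i % 2 != j % 2 and i // 2 != j // 2:
                    assert im[i, j] == 0
        assert np.all(np.diag(im) == 0)
        # every allowed transition cell carries a distinct parameter
        allowed = im[im > 0]
        assert sorted(allowed) == list(range(1, 9))

    def test_unknown_constraint_rejected(self):
        with pytest.raises(ValueError):
            se.build_model(2, 1, "sym")

    def test_rate_matrix_rows_sum_to_zero(self):
        m = se.build_model(2, 2, ALL_RATES_DIFFERENT)
        Q = m.rate_matrix(np.arange(1.0, 9.0))
        assert np.allclose(Q.sum(axis=1), 0.0)
        off = Q[~np.eye(4, dtype=bool)]
        assert np.all(off >= 0)


class TestTransitionProbability:
    def test_zero_time_is_identity(self):
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([0.7])
        assert np.allclose(transition_probability(Q, 0.0), np.eye(2))

    def test_binary_er_closed_form(self):
        # P(t) diagonal = (1 + exp(-2qt))/2 for the symmetric binary chain
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([0.5])
        P = transition_probability(Q, 1.0)
        assert P[0, 0] == pytest.approx(0.5 * (1 + np.exp(-1.0)), abs=1e-12)
        assert P[0, 1] == pytest.approx(0.5 * (1 - np.exp(-1.0)), abs=1e-12)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)

    def test_long_time_reaches_stationary(self):
        m = se.build_model(2, 1, ALL_RATES_DIFFERENT)
        Q = m.rate_matrix([0.3, 0.9])
        P = transition_probability(Q, 500.0)
        # stationary distribution of the 2-state chain: (q10, q01)/(q01+q10)
        pi = np.array([0.9, 0.3]) / 1.2
        assert np.allclose(P, np.vstack([pi, pi]), atol=1e-9)

    def test_negative_time_rejected(self):
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([0.5])
        with pytest.raises(ValueError):
            transition_probability(Q, -1.0)

    def test_batched_matches_single(self):
        m = se.build_model(2, 2, ALL_RATES_DIFFERENT)
        Q = m.rate_matrix([0.1, 0.8, 0.4, 0.2, 0.05, 0.02, 0.3, 0.07])
        ts = np.array([0.0, 0.3, 1.7, 42.0])
        batch = branch_transition_matrices(Q, ts)
        for P, t in zip(batch, ts):
            assert np.allclose(P, transition_probability(Q, t), atol=1e-9)


class TestLogLikelihood:
    def test_two_tip_closed_form(self, cherry):
        # ln(0.5 p00^2 + 0.5 p01^2) with p00 = 0.6839397 at q=0.5, t=1
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([0.5])
        ll = se.log_likelihood(cherry, {"A": 0, "B": 0}, Q)
        assert ll == pytest.approx(-1.25936635, abs=1e-6)

    def test_zero_rate_constant_trait(self, cherry):
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([0.0])
        ll = se.log_likelihood(cherry, {"A": 0, "B": 0}, Q)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    @pytest.mark.parametrize("n_obs,n_hidden", [(2, 1), (4, 1), (2, 2)])
    def test_matches_brute_force_on_small_trees(self, n_obs, n_hidden):
        rng = np.random.default_rng(2024)
        m = se.build_model(n_obs, n_hidden, ALL_RATES_DIFFERENT)
        S = m.n_states
        for rep in range(12):
            tree = random_tree(int(rng.integers(2, 6)), seed=int(rng.integers(1e6)))
            Q = m.rate_matrix(rng.uniform(0.02, 2.0, m.n_params))
            tips = {lab: int(rng.integers(n_obs)) for lab in tree.tip_labels}
            tipL = tip_partials(tree, tips, n_obs, n_hidden)
            got = PruningEngine(tree, tipL).loglik(Q, "flat")
            want = brute_force_loglik(tree, tipL, Q, np.full(S, 1 / S))
            assert got == pytest.approx(want, abs=1e-10)

    def test_hmm_one_category_equals_plain_mk(self):
        tree = random_tree(15, seed=5)
        rng = np.random.default_rng(1)
        tips = {lab: int(rng.integers(2)) for lab in tree.tip_labels}
        q01, q10 = 0.4, 0.9
        mk = se.build_model(2, 1, ALL_RATES_DIFFERENT)
        ll_plain = se.log_likelihood(tree, tips, mk.rate_matrix([q01, q10]))
        # a 2-category model with identical categories and zero switch rates
        hmm = se.build_model(2, 2, ALL_RATES_DIFFERENT)
        Q = hmm.rate_matrix([q01, q10, q01, q10, 0, 0, 0, 0])
        ll_hmm = se.log_likelihood(tree, tips, Q, n_obs=2)
        assert ll_hmm == pytest.approx(ll_plain, abs=1e-9)

    def test_invariant_under_child_reorder_and_degree2_split(self):
        m = se.build_model(2, 1, ALL_RATES_DIFFERENT)
        Q = m.rate_matrix([0.3, 0.6])
        tips = {"A": 0, "B": 1, "C": 0}
        t1 = se.read_newick("((A:1,B:1):1,C:2);")
        t2 = se.read_newick("(C:2,(B:1,A:1):1);")
        # the same tree with the C edge split by a degree-2 node
        t3 = se.read_newick("((A:1,B:1):1,(C:1.2):0.8);")
        lls = [se.log_likelihood(t, tips, Q) for t in (t1, t2, t3)]
        assert lls[0] == pytest.approx(lls[1], abs=1e-12)
        assert lls[0] == pytest.approx(lls[2], abs=1e-10)

    def test_ambiguous_tip_is_marginalised(self, three_tip_tree):
        m = se.build_model(2, 1, EQUAL_RATES)
        Q = m.rate_matrix([0.5])
        ll_both = np.logaddexp(
            se.log_likelihood(three_tip_tree, {"A": 0, "B": 0, "C": 0}, Q),
            se.log_likelihood(three_tip_tree, {"A": 0, "B": 0, "C": 1}, Q),
        )
        ll_missing = se.log_likelihood(three_tip_tree, {"A": 0, "B": 0, "C": None}, Q)
        assert ll_missing == pytest.approx(ll_both, abs=1e-10)

    def test_missing_tip_raises_without_flag(self, three_tip_tree):
        Q = se.build_model(2, 1, EQUAL_RATES).rate_matrix([0.5])
        with pytest.raises(KeyError):
            se.log_likelihood(three_tip_tree, {"A": 0, "B": 0}, Q)
        ll = se.log_likelihood(
            three_tip_tree, {"A": 0, "B": 0}, Q, fill_missing=True
        )
        assert np.isfinite(ll)


class TestFitML:
    def test_aic_identity(self):
        tree = random_tree(40, seed=9, root_age=50.0)
        m = se.build_model(2, 1, EQUAL_RATES)
        tips, _ = simulate_traits(tree, m, [0.05], seed=3)
        fit = se.fit_ml(tree, tips, m, n_restarts=2, seed=0)
        assert fit.AIC == pytest.approx(2 * fit.k - 2 * fit.logL, abs=1e-12)

    def test_constant_trait_drives_rate_to_lower_bound(self):
        tree = random_tree(30, seed=10, root_age=50.0)
        tips = {lab: 0 for lab in tree.tip_labels}
        m = se.build_model(2, 1, EQUAL_RATES)
        with pytest.warns(UserWarning, match="one observed state"):
            fit = se.fit_ml(tree, tips, m, n_restarts=2, seed=0)
        assert fit.rates[0] <= 1e-6

    def test_reproducible_given_seed(self):
        tree = random_tree(40, seed=21, root_age=80.0)
        m = se.build_model(2, 1, ALL_RATES_DIFFERENT)
        tips, _ = simulate_traits(tree, m, [0.02, 0.05], seed=4)
        f1 = se.fit_ml(tree, tips, m, n_restarts=3, seed=7)
        f2 = se.fit_ml(tree, tips, m, n_restarts=3, seed=7)
        assert np.allclose(f1.rates, f2.rates)
        assert f1.logL == f2.logL

    def test_er_rate_recovery_single_dataset(self):
        # one large dataset; the acceptance suite runs the replicated version
        tree = random_tree(800, seed=2, root_age=100.0, birth=0.1, death=0.0)
        m = se.build_model(2, 1, EQUAL_RATES)
        tips, _ = simulate_traits(tree, m, [0.05], seed=8)
        fit = se.fit_ml(tree, tips, m, n_restarts=3, seed=1)
        assert 0.02 < fit.rates[0] < 0.12


class TestModelSelect:
    def test_aic_formula_row(self):
        tree = random_tree(20, seed=3, root_age=30.0)
        m = se.build_model(2, 1, ALL_RATES_DIFFERENT)
        tips, _ = simulate_traits(tree, m, [0.05, 0.1], seed=1)
        fits = [se.fit_ml(tree, tips, m, n_restarts=2, seed=0)]
        tab = se.model_select(fits)
        assert tab.loc[0, "AIC"] == pytest.approx(
            2 * fits[0].k - 2 * fits[0].logL
        )
        assert tab.loc[0, "dAIC"] == 0.0

    def test_nested_er_ard_consistency(self):
        tree = random_tree(60, seed=14, root_age=60.0)
        m_er = se.build_model(2, 1, EQUAL_RATES)
        m_ard = se.build_model(2, 1, ALL_RATES_DIFFERENT)
        tips, _ = simulate_traits(tree, m_ard, [0.02, 0.2], seed=5)
        f_er = se.fit_ml(tree, tips, m_er, n_restarts=3, seed=0)
        f_ard = se.fit_ml(
            tree, tips, m_ard, n_restarts=3, seed=0,
            start=[f_er.rates[0], f_er.rates[0]],
        )
        assert f_ard.logL >= f_er.logL - 1e-6
        assert f_ard.AIC >= f_er.AIC - 2 * (f_ard.k - f_er.k) - 1e-6

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            se.model_select([])


class TestMarginalAncestralStates:
    def test_zero_rate_constant_data_pins_root(self, three_tip_tree):
        m = se.build_model(2, 1, EQUAL_RATES)
        fit = se.FitResult(
            model=m, rates=np.array([1e-12]), logL=0.0, converged=True, n_restarts=0
        )
        marg = se.marginal_ancestral_states(
            three_tip_tree, {"A": 0, "B": 0, "C": 0}, fit
        )
        root = three_tip_tree.root
        assert marg["observed"][root] == pytest.approx([1.0, 0.0], abs=1e-6)

    @pytest.mark.parametrize("n_obs,n_hidden", [(2, 1), (2, 2)])
    def test_matches_brute_force_posteriors(self, n_obs, n_hidden):
        rng = np.random.default_rng(77)
        m = se.build_model(n_obs, n_hidden, ALL_RATES_DIFFERENT)
        for rep in range(6):
            tree = random_tree(3, seed=int(rng.integers(1e6)))
            rates = rng.uniform(0.05, 1.5, m.n_params)
            tips = {lab: int(rng.integers(n_obs)) for lab in tree.tip_labels}
            fit = se.FitResult(
                model=m, rates=rates, logL=0.0, converged=True, n_restarts=0
            )
            marg = se.marginal_ancestral_states(tree, tips, fit)
            tipL = tip_partials(tree, tips, n_obs, n_hidden)
            S = m.n_states
            want = brute_force_marginals(tree, tipL, fit.Q, np.full(S, 1 / S))
            internal = [v for v in range(tree.n_nodes) if tree.children[v]]
            assert np.allclose(marg["composite"][internal], want[internal], atol=1e-10)
            assert np.allclose(marg["composite"].sum(axis=1), 1.0, atol=1e-9)
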