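import itertools

import numpy as np
import pytest

import styleevo as se
from styleevo.mk_hmm import transition_probability, tip_partials
from styleevo.synthetic_data import SimulationScenario, simulate_tree


@pytest.fixture
def three_tip_tree():
    return se.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def cherry():
    return se.read_newick("(A:1,B:1);")


def random_tree(n_tips: int, seed: int, root_age: float = 3.0, birth=0.4, death=0.1):
    return simulate_tree(
        SimulationScenario(
            n_tips=n_tips, birth=birth, death=death, root_age=root_age, seed=seed
        )
    )


def brute_force_loglik(tree, tipL, Q, prior) -> float:
    """Independent oracle: enumerate every internal-node state assignment."""
    S = Q.shape[0]
    P = {
        v: transition_probability(Q, tree.edge_length[v])
        for v in range(tree.n_nodes)
        if tree.parent[v] >= 0
    }
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    total = 0.0
    for assign in itertools.product(range(S), repeat=len(internal)):
        st = dict(zip(internal, assign))
        pr = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if tree.children[v]:
                pr *= P[v][st[p], st[v]]
            else:
                pr *= float(P[v][st[p]] @ tipL[v])
        total += pr
    return float(np.log(total))


def brute_force_marginals(tree, tipL, Q, prior) -> np.ndarray:
    """Posterior state probabilities at every internal node by enumeration."""
    S = Q.shape[0]
    P = {
        v: transition_probability(Q, tree.edge_length[v])
        for v in range(tree.n_nodes)
        if tree.parent[v] >= 0
    }
    internal = [v for v in range(tree.n_nodes) if tree.children[v]]
    post = np.zeros((tree.n_nodes, S))
    for assign in itertools.product(range(S), repeat=len(internal)):
        st = dict(zip(internal, assign))
        pr = prior[st[tree.root]]
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if tree.children[v]:
                pr *= P[v][st[p], st[v]]
            else:
                pr *= float(P[v][st[p]] @ tipL[v])
        for v in internal:
            post[v, st[v]] += pr
    post[internal] /= post[internal].sum(axis=1, keepdims=True)
    return post


def expected_conditional_events(Q, t, a, b) -> float:
    """Expected number of state changes on an endpoint-conditioned branch,
    by numerical integration of E[N] = sum_{i != j} q_ij
    int_0^t P_ai(s) P_jb(t-s) ds / P_ab(t)."""
    from scipy.integrate import quad
    from scipy.linalg import expm

    S = Q.shape[0]
    Pab = expm(Q * t)[a, b]
    total = 0.0
    for i in range(S):
        for j in range(S):
            if i == j or Q[i, j] <= 0:
                continue
            val, _ = quad(
                lambda s: expm(Q * s)[a, i] * expm(Q * (t - s))[j, b],
                0.0,
                t,
                limit=200,
            )
            total += Q[i, j] * val
    return total / Pab
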