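"""Synthetic trees and trait data with the structure the analysis assumes.

Provides a forward-Gillespie birth-death tree simulator (pruned to extant
tips, rescaled to a target crown age), forward simulation of discrete
characters under any model in the package's CTMC family (recording the
true character history), a calibrated rare-polymorphism scenario, and
two-trait simulation under the 4-state dependent/independent chains.

The default rare-polymorphism scenario emulates the macroevolutionary
setting the package targets: a time-calibrated angiosperm-scale tree
(crown age 140 Myr), a binary style-length trait whose derived
(polymorphic) state sits at roughly 2% of tips, and a two-category
hidden-rate regime — a slow background category R1 whose loss rate is ~100
times the gain rate, and a fast category R2 whose loss rate is 2.7 times
the gain rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import yaml

from .mk_hmm import ALL_RATES_DIFFERENT, MkHmmModel, build_model
from .phylo_core import PhyloTree
from .stochastic_mapping import CharacterHistory
from . import phylo_core

__all__ = [
    "SimulationScenario",
    "simulate_tree",
    "simulate_traits",
    "heterostyly_scenario",
    "HETEROSTYLY_TRUE_RATES",
    "simulate_correlated_traits",
]

#: crown age used for angiosperm-scale scenarios, Myr
DEFAULT_ROOT_AGE = 140.0

#: true rates of the rare-polymorphism scenario, events/Myr, in the
#: parameter order of ``build_model(2, 2, all_rates_different)``:
#: R1 gain, R1 loss, R2 gain, R2 loss, then category switches
#: M:R1->R2, P:R1->R2, M:R2->R1, P:R2->R1.
HETEROSTYLY_TRUE_RATES = {
    "gain_R1": 1e-4,
    "loss_R1": 1e-2,   # loss 100x gain in the slow category
    "gain_R2": 0.02,
    "loss_R2": 0.054,  # loss 2.7x gain in the fast category
    "R1_to_R2": 0.002,
    "R2_to_R1": 0.04,  # R2 transient, concentrated near the present
}


@dataclass
class SimulationScenario:
    """Fully serialisable description of one synthetic dataset."""

    n_tips: int
    birth: float = 0.1
    death: float = 0.0
    root_age: float = DEFAULT_ROOT_AGE
    model_kind: str = "mk"  # mk | hmm | pagel
    n_obs: int = 2
    n_hidden: int = 1
    constraint: str = ALL_RATES_DIFFERENT
    rates: tuple = ()
    root_state: int = 0
    seed: int = 0

    def __post_init__(self):
        if not self.birth > self.death >= 0:
            raise ValueError("need birth > death >= 0")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be non-negative")

    def to_yaml(self) -> str:
        d = asdict(self)
        d["rates"] = [float(r) for r in self.rates]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimulationScenario":
        d = yaml.safe_load(text)
        d["rates"] = tuple(d.get("rates", ()))
        return cls(**d)


def simulate_tree(scenario: SimulationScenario, max_retries: int = 1000) -> PhyloTree:
    """Forward birth-death simulation conditioned on the number of extant
    tips, pruned to the extant crown group and rescaled to the target
    crown age.

    The process runs until the extant lineage count reaches ``n_tips``,
    then advances by one further waiting time so the youngest tips carry
    positive terminal branches.  Whole runs are resampled on clade
    extinction, up to ``max_retries``.
    """
    n = scenario.n_tips
    if n < 2:
        raise ValueError("need n_tips >= 2")
    rng = np.random.default_rng(scenario.seed)
    lam, mu = scenario.birth, scenario.death
    for _ in range(max_retries):
        # node bookkeeping: parents, birth times; alive = current tips
        parent = [-1]
        btime = [0.0]  # time the node came into existence
        alive = [0]
        t = 0.0
        ok = True
        while len(alive) < n:
            k = len(alive)
            if k == 0:
                ok = False
                break
            total = k * (lam + mu)
            t += rng.exponential(1.0 / total)
            idx = int(rng.integers(k))
            node = alive[idx]
            if rng.random() < lam / (lam + mu):
                for _ in range(2):
                    parent.append(node)
                    btime.append(t)
                    alive.extend([len(parent) - 1])
                alive.pop(idx)
            else:
                alive.pop(idx)
        if not ok:
            continue
        # sample past the n-th birth so the youngest tips get positive
        # terminal branches; no event occurs in the appended interval
        T = t + rng.exponential(1.0 / (n * (lam + mu)))
        parent_arr = np.asarray(parent)
        n_nodes = len(parent)
        is_tip_alive = np.zeros(n_nodes, dtype=bool)
        is_tip_alive[alive] = True
        # keep ancestors of living tips
        keep = is_tip_alive.copy()
        order = np.argsort(btime)[::-1]
        for v in order:
            p = parent_arr[v]
            if keep[v] and p >= 0:
                keep[p] = True
        # build pruned tree with unifurcations suppressed
        end_time = np.where(is_tip_alive, T, np.asarray(btime))
        # children map on kept nodes
        children: dict[int, list[int]] = {v: [] for v in range(n_nodes)}
        for v in range(n_nodes):
            p = parent_arr[v]
            if p >= 0 and keep[v]:
                children[p].append(v)
        # find crown root: first kept node with >= 2 kept children
        root = 0
        while True:
            kids = children[root]
            if len(kids) == 1 and not is_tip_alive[root]:
                root = kids[0]
            else:
                break
        new_parent: list[int] = []
        new_edge: list[float] = []
        new_labels: list = []
        tip_counter = [0]
        stack = [(root, -1, float(btime[root]))]
        while stack:
            v, pnew, start = stack.pop()
            kids = children[v]
            if len(kids) == 1 and not is_tip_alive[v]:
                stack.append((kids[0], pnew, start))
                continue
            my = len(new_parent)
            split_time = T if is_tip_alive[v] else _split_time(v, btime, children, is_tip_alive, T)
            new_parent.append(pnew)
            new_edge.append((split_time - start) if pnew >= 0 else 0.0)
            if is_tip_alive[v]:
                tip_counter[0] += 1
                new_labels.append(f"t{tip_counter[0]}")
            else:
                new_labels.append(None)
            for c in reversed(kids):
                stack.append((c, my, split_time))
        tree = PhyloTree(np.asarray(new_parent), np.asarray(new_edge), tuple(new_labels))
        if tree.n_tips != n:
            continue
        # rescale crown depth to the target root age
        depth = tree.depth
        if depth <= 0:
            continue
        scale = scenario.root_age / depth
        return PhyloTree(tree.parent, tree.edge_length * scale, tree.labels)
    raise RuntimeError(f"clade went extinct in all {max_retries} attempts")


def _split_time(v, btime, children, is_tip_alive, T):
    # an internal kept node's split time is its children's birth time
    kids = children[v]
    if kids:
        return float(btime[kids[0]])
    return T


def _model_from_scenario(scn: SimulationScenario) -> MkHmmModel:
    return build_model(scn.n_obs, scn.n_hidden, scn.constraint)


def simulate_traits(
    tree: PhyloTree,
    model: MkHmmModel,
    true_rates: Sequence[float],
    root_state: int = 0,
    seed: int = 0,
):
    """Forward Gillespie simulation of a character down the tree.

    Returns ``(tips, truth)``: the observed tip states (hidden categories
    stripped) and the complete true :class:`CharacterHistory`.
    """
    Q = model.rate_matrix(true_rates)
    S = model.n_states
    rng = np.random.default_rng(seed)
    ages = phylo_core.node_ages(tree)
    node_states = np.empty(tree.n_nodes, dtype=np.int64)
    node_states[tree.root] = int(root_state)
    events: list = [[] for _ in range(tree.n_nodes)]
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        s = int(node_states[p])
        t_remaining = float(tree.edge_length[v])
        age = float(ages[p])
        branch_events = []
        while True:
            out_rate = -Q[s, s]
            if out_rate <= 0:
                break
            wait = rng.exponential(1.0 / out_rate)
            if wait >= t_remaining:
                break
            t_remaining -= wait
            age -= wait
            w = Q[s].copy()
            w[s] = 0.0
            s = int(
                min(
                    np.searchsorted(np.cumsum(w), rng.random() * w.sum(), side="right"),
                    S - 1,
                )
            )
            branch_events.append((age, s))
        node_states[v] = s
        events[v] = branch_events
    tips = {
        tree.labels[i]: int(node_states[i]) % model.n_obs for i in tree.tip_indices
    }
    truth = CharacterHistory(
        tree=tree,
        n_obs=model.n_obs,
        n_hidden=model.n_hidden,
        node_states=node_states,
        events=events,
        map_index=-1,
        seed=seed,
    )
    return tips, truth


def heterostyly_scenario(n_tips: int = 2000, seed: int = 0):
    """Full calibrated bundle: tree, binary tip states, truth, model, rates.

    A pure-birth tree rescaled to crown age 140 Myr carries a binary trait
    under the two-category all-rates-different regime of
    :data:`HETEROSTYLY_TRUE_RATES`, rooted in the monomorphic slow state;
    the derived polymorphic state ends up at roughly 1-4% of tips.
    Returns a dict with keys ``tree``, ``tips``, ``truth``, ``model``,
    ``rates``, ``scenario``.
    """
    model = build_model(2, 2, ALL_RATES_DIFFERENT)
    rates = _rates_vector(model)
    scn = SimulationScenario(
        n_tips=n_tips,
        birth=0.1,
        death=0.0,
        root_age=DEFAULT_ROOT_AGE,
        model_kind="hmm",
        n_obs=2,
        n_hidden=2,
        constraint=ALL_RATES_DIFFERENT,
        rates=tuple(float(r) for r in rates),
        root_state=0,  # R1, monomorphic
        seed=seed,
    )
    tree = simulate_tree(scn)
    tips, truth = simulate_traits(tree, model, rates, root_state=0, seed=seed + 1)
    return {
        "tree": tree,
        "tips": tips,
        "truth": truth,
        "model": model,
        "rates": rates,
        "scenario": scn,
    }


def _rates_vector(model: MkHmmModel) -> np.ndarray:
    """HETEROSTYLY_TRUE_RATES in the parameter order of the 2x2 ARD model."""
    r = HETEROSTYLY_TRUE_RATES
    # build_model order: obs transitions per category (0->1, 1->0 for R1,
    # then R2), then switches (R1->R2 at M, at P; R2->R1 at M, at P)
    vec = np.array(
        [
            r["gain_R1"],
            r["loss_R1"],
            r["gain_R2"],
            r["loss_R2"],
            r["R1_to_R2"],
            r["R1_to_R2"],
            r["R2_to_R1"],
            r["R2_to_R1"],
        ]
    )
    assert model.n_params == vec.size
    return vec


def simulate_correlated_traits(
    tree: PhyloTree,
    pagel_model: MkHmmModel,
    true_rates: Sequence[float],
    seed: int = 0,
    root_state: int = 0,
):
    """Forward simulation under a 4-state two-trait chain.

    Returns ``(x, y, truth)`` where x and y are binary tip-state dicts
    decoded from the joint state ``s = 2x + y``.
    """
    if pagel_model.n_obs != 4 or pagel_model.n_hidden != 1:
        raise ValueError("expected a 4-state two-trait model")
    joint, truth = simulate_traits(
        tree, pagel_model, true_rates, root_state=root_state, seed=seed
    )
    x = {lab: s // 2 for lab, s in joint.items()}
    y = {lab: s % 2 for lab, s in joint.items()}
    return x, y, truth
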