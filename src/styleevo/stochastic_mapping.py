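"""Stochastic character mapping: sampling full character histories.

Given a fitted CTMC and tip data, draws complete state paths along every
branch conditional on the data (simmap-style), then counts and dates state
changes.  Node states are sampled jointly on a downward pass (each node
conditional on its sampled parent and its subtree partials); branch paths
are endpoint-conditioned CTMC bridges drawn exactly by uniformization.

Gains and losses of a binary trait are changes on the observed layer
(monomorphic -> polymorphic and back), pooling hidden rate categories;
switches between rate categories are counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .mk_hmm import FitResult, PruningEngine, tip_partials, _root_distribution
from .phylo_core import PhyloTree, node_ages

__all__ = [
    "CharacterHistory",
    "MappingSummary",
    "sample_history",
    "simulate_branch_conditional",
    "count_transitions",
    "event_ages",
    "density_mode",
    "ltt_by_state",
    "summarize_maps",
]

#: kernel-density grid used by :func:`density_mode`
DENSITY_GRID_SIZE = 512


@dataclass
class CharacterHistory:
    """One complete character history on a tree.

    ``events[v]`` lists the state changes on the branch above node ``v`` as
    ``(age, new_state)`` pairs ordered from the parent (oldest) toward the
    node; ``node_states[v]`` is the composite state at each node.
    """

    tree: PhyloTree
    n_obs: int
    n_hidden: int
    node_states: np.ndarray
    events: list  # per node: list[(age, new_composite_state)]
    map_index: int = 0
    seed: int | None = None

    @property
    def n_states(self) -> int:
        return self.n_obs * self.n_hidden

    def validate(self, ages: np.ndarray | None = None) -> None:
        """Check path consistency: segments connect parent to child states
        and event ages decrease within the branch bounds."""
        tree = self.tree
        if ages is None:
            ages = node_ages(tree)
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            state = self.node_states[p]
            prev_age = ages[p]
            for age, new in self.events[v]:
                if not (ages[v] < age < prev_age) and not np.isclose(age, prev_age):
                    raise ValueError(f"event age {age} outside branch above node {v}")
                if new == state:
                    raise ValueError("event does not change the state")
                state = new
                prev_age = age
            if state != self.node_states[v]:
                raise ValueError(f"path does not reach the child state at node {v}")

    def to_events_frame(self) -> pd.DataFrame:
        rows = []
        for v in range(self.tree.n_nodes):
            p = self.tree.parent[v]
            if p < 0:
                continue
            state = int(self.node_states[p])
            for age, new in self.events[v]:
                rows.append(
                    {
                        "branch": v,
                        "age": float(age),
                        "from_state": state,
                        "to_state": int(new),
                        "map_index": self.map_index,
                    }
                )
                state = int(new)
        return pd.DataFrame(
            rows, columns=["branch", "age", "from_state", "to_state", "map_index"]
        )


# ---------------------------------------------------------------------------
# Endpoint-conditioned path sampling (uniformization)


class _Uniformizer:
    """Exact endpoint-conditioned CTMC path sampler.

    Uniformizes with dominating rate ``omega = max_i |Q_ii|``; the number of
    (possibly virtual) jumps given the endpoints is drawn from its exact
    conditional distribution, states along the bridge from the discrete
    skeleton, and virtual self-jumps are discarded.

    A bridge from a to b almost surely stays inside the taboo set of states
    reachable from a and co-reachable to b, so the sampler restricts the
    generator to that set before uniformizing.  This keeps the dominating
    rate small when maximum-likelihood fits park a huge rate on a composite
    state the conditioned paths never visit (a common boundary solution of
    hidden-rate models), and it makes truly-zero endpoint probabilities
    exact rather than a numerical accident.
    """

    MAX_JUMPS = 1_000_000

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self.S = self.Q.shape[0]
        self.omega = float(np.max(-np.diag(self.Q)))
        if self.omega > 0:
            self.R = np.eye(self.S) + self.Q / self.omega
        else:
            self.R = np.eye(self.S)
        self._powers = [np.eye(self.S), self.R]
        # reachability in the jump graph: P(t)[a, b] > 0 for t > 0 iff
        # b is reachable from a
        adj = (self.Q > 0) | np.eye(self.S, dtype=bool)
        reach = adj.copy()
        for _ in range(self.S - 1):
            reach = reach @ adj
        self.reachable = reach
        self._subsamplers: dict = {}
        self._pair_sub: dict = {}
        self._cum_cache: dict = {}

    def power(self, n: int) -> np.ndarray:
        while len(self._powers) <= n:
            self._powers.append(self._powers[-1] @ self.R)
        return self._powers[n]

    def _taboo(self, a: int, b: int):
        """Sub-sampler on the states visitable by an a->b bridge, or None
        when the full chain is already the right space."""
        cached = self._pair_sub.get((a, b))
        if cached is not None:
            return cached
        mask = self.reachable[a] & self.reachable[:, b]
        if not mask[a] or not mask[b]:
            self._pair_sub[(a, b)] = (None, mask)
            return None, mask  # endpoints not connected
        if mask.all():
            self._pair_sub[(a, b)] = (self, mask)
            return self, mask
        key = mask.tobytes()
        sub = self._subsamplers.get(key)
        if sub is None:
            idx = np.flatnonzero(mask)
            # keep original diagonals: excursions to excluded states are
            # conditioned away, giving taboo (sub-stochastic) dynamics
            Qsub = self.Q[np.ix_(idx, idx)].copy()
            sub = _Uniformizer.__new__(_Uniformizer)
            sub.Q = Qsub
            sub.S = idx.size
            sub.omega = float(np.max(-np.diag(Qsub))) if idx.size else 0.0
            if sub.omega > 0:
                sub.R = np.eye(sub.S) + Qsub / sub.omega
            else:
                sub.R = np.eye(sub.S)
            sub._powers = [np.eye(sub.S), sub.R]
            sub.reachable = np.ones((sub.S, sub.S), dtype=bool)
            sub._subsamplers = {}
            sub._pair_sub = {}
            sub._cum_cache = {}
            sub._index = idx
            self._subsamplers[key] = sub
        self._pair_sub[(a, b)] = (sub, mask)
        return sub, mask

    def _cumulative_series(self, t: float, a: int, b: int) -> np.ndarray:
        """Cumulative sums over n of Poisson(omega t; n) * R^n[a, b].

        The last entry is P(X_t = b | X_0 = a); cached per (t, a, b) so
        repeated maps over the same branches reuse the series.
        """
        key = (t, a, b)
        c = self._cum_cache.get(key)
        if c is not None:
            return c
        lam = self.omega * t
        n_max = _series_cutoff(lam)
        terms = []
        total = 0.0
        pois_cum = 0.0
        for n, logw in _poisson_log_terms(lam):
            w = np.exp(logw)
            pois_cum += w
            total += w * self.power(n)[a, b]
            terms.append(total)
            # remaining Poisson mass bounds the truncation error (entries
            # of R powers are at most 1)
            if (1.0 - pois_cum) < 1e-14 * max(total, 1e-12) or n >= n_max:
                break
        c = np.asarray(terms)
        if len(self._cum_cache) > 200_000:
            self._cum_cache.clear()
        self._cum_cache[key] = c
        return c

    def endpoint_probability(self, t: float, a: int, b: int) -> float:
        """P(X_t = b | X_0 = a) by the uniformization series (log-stable)."""
        if not self.reachable[a, b]:
            return 0.0
        sub, mask = self._taboo(a, b)
        if sub is not self:
            idx = np.flatnonzero(mask)
            pos = {int(v): k for k, v in enumerate(idx)}
            return sub.endpoint_probability(t, pos[a], pos[b])
        if self.omega == 0:
            return 1.0 if a == b else 0.0
        return float(self._cumulative_series(t, a, b)[-1])

    def sample_path(self, t: float, a: int, b: int, rng) -> list:
        """Draw one bridge from a to b over duration t.

        Returns the real state changes as ``(time_from_start, new_state)``.
        """
        if t < 0:
            raise ValueError("negative duration")
        if t == 0 or self.omega == 0:
            if a != b:
                raise ValueError("impossible endpoint pair at zero rate/duration")
            return []
        if not self.reachable[a, b]:
            raise ValueError(f"endpoint pair ({a}->{b}) has zero probability")
        sub, mask = self._taboo(a, b)
        if sub is not self:
            idx = np.flatnonzero(mask)
            pos = {int(v): k for k, v in enumerate(idx)}
            path = sub.sample_path(t, pos[a], pos[b], rng)
            return [(tt, int(idx[s])) for tt, s in path]
        c = self._cumulative_series(t, a, b)
        p_ab = float(c[-1])
        if p_ab <= 0:
            raise ValueError(f"endpoint pair ({a}->{b}) has zero probability")
        # draw N | endpoints from its exact conditional distribution
        n = int(np.searchsorted(c, rng.random() * p_ab, side="left"))
        n = min(n, c.size - 1)
        if n == 0:
            return []
        # jump times: order statistics of uniforms
        times = np.sort(rng.random(n)) * t
        # skeleton states via backward products
        states = np.empty(n + 1, dtype=np.int64)
        states[0] = a
        for k in range(1, n + 1):
            back = self.power(n - k)[:, b]
            w = self.R[states[k - 1]] * back
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError("numerical failure in bridge sampling")
            states[k] = min(
                int(np.searchsorted(np.cumsum(w), rng.random() * tot, side="right")),
                self.S - 1,
            )
        if states[n] != b:  # numerically should not happen
            states[n] = b
        path = []
        cur = a
        for k in range(1, n + 1):
            if states[k] != cur:
                path.append((float(times[k - 1]), int(states[k])))
                cur = int(states[k])
        return path


def _series_cutoff(lam: float) -> int:
    # Poisson mass beyond lam + 20 sqrt(lam) is far below double precision
    return int(np.ceil(lam + 20.0 * np.sqrt(lam + 1.0) + 30.0))


def _poisson_log_terms(lam: float):
    """Yield (n, log Poisson(lam) pmf at n) for n = 0, 1, ... in order,
    numerically stable for large lam."""
    from math import lgamma, log

    loglam = log(lam) if lam > 0 else -np.inf
    n = 0
    while n <= _Uniformizer.MAX_JUMPS:
        yield n, (-lam + n * loglam - lgamma(n + 1))
        n += 1


_uniformizer_cache: dict = {}


def simulate_branch_conditional(
    Q: np.ndarray, t: float, start_state: int, end_state: int, rng
) -> list:
    """Exact endpoint-conditioned path on one branch.

    Returns the real state changes as ``(time_from_start, new_state)``
    pairs; empty when the bridge has no change.  Raises when the endpoint
    pair has zero probability.  Samplers are cached per rate matrix so
    repeated draws under one Q reuse the power series.
    """
    Q = np.asarray(Q, dtype=float)
    key = (Q.shape[0], Q.tobytes())
    uni = _uniformizer_cache.get(key)
    if uni is None:
        if len(_uniformizer_cache) > 32:
            _uniformizer_cache.clear()
        uni = _uniformizer_cache[key] = _Uniformizer(Q)
    return uni.sample_path(t, int(start_state), int(end_state), rng)


# ---------------------------------------------------------------------------
# History sampling


def sample_history(
    tree: PhyloTree,
    tips,
    fit: FitResult,
    n_maps: int = 100,
    seed: int = 0,
    fill_missing: bool = False,
) -> list:
    """Draw ``n_maps`` character histories conditional on the tip data.

    One master seed spawns independent per-map substreams; the map index
    and seed are recorded on each history.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    model = fit.model
    Q = fit.Q
    tipL = tip_partials(tree, tips, model.n_obs, model.n_hidden, fill_missing)
    engine = PruningEngine(tree, tipL)
    out = engine.partials(Q)
    if out is None:
        raise ValueError("tip data impossible under the fitted model")
    L, _, P = out
    ages = node_ages(tree)
    pi = _root_distribution(model.root_prior, L[tree.root])
    root_post = pi * L[tree.root]
    root_post = root_post / root_post.sum()
    uni = _Uniformizer(Q)
    S = model.n_states
    preorder = tree.preorder
    parent = tree.parent
    edge = tree.edge_length

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_maps)
    histories = []
    for m in range(n_maps):
        rng = np.random.default_rng(child_seeds[m])
        node_states = np.empty(tree.n_nodes, dtype=np.int64)
        node_states[tree.root] = min(
            int(np.searchsorted(np.cumsum(root_post), rng.random(), side="right")),
            S - 1,
        )
        events: list = [[] for _ in range(tree.n_nodes)]
        for v in preorder:
            p = parent[v]
            if p < 0:
                continue
            i = node_states[p]
            w = P[v][i] * L[v]
            w[~uni.reachable[i]] = 0.0
            tot = w.sum()
            if tot <= 0:
                raise RuntimeError("zero conditional distribution while sampling")
            j = min(
                int(np.searchsorted(np.cumsum(w), rng.random() * tot, side="right")),
                S - 1,
            )
            node_states[v] = j
            t = edge[v]
            if t > 0:
                path = uni.sample_path(t, int(i), int(j), rng)
            else:
                path = []
            start_age = ages[p]
            events[v] = [(start_age - dt, s) for dt, s in path]
        histories.append(
            CharacterHistory(
                tree=tree,
                n_obs=model.n_obs,
                n_hidden=model.n_hidden,
                node_states=node_states,
                events=events,
                map_index=m,
                seed=seed,
            )
        )
    return histories


# ---------------------------------------------------------------------------
# Counting, dating, summarising


def _project(state: int, n_obs: int, layer: str) -> int:
    if layer == "observed":
        return state % n_obs
    if layer == "hidden":
        return state // n_obs
    if layer == "composite":
        return state
    raise ValueError(f"unknown layer {layer!r}")


def count_transitions(history: CharacterHistory, layer: str = "observed") -> np.ndarray:
    """Counts of ordered state-pair changes in one history.

    ``layer`` projects composite states to the observed trait, the hidden
    rate category, or keeps the composite space.  An event that changes
    only the other layer contributes nothing.
    """
    if layer == "observed":
        K = history.n_obs
    elif layer == "hidden":
        K = history.n_hidden
    else:
        K = history.n_states
    counts = np.zeros((K, K), dtype=np.int64)
    tree = history.tree
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        state = int(history.node_states[p])
        for _, new in history.events[v]:
            a = _project(state, history.n_obs, layer)
            b = _project(int(new), history.n_obs, layer)
            if a != b:
                counts[a, b] += 1
            state = int(new)
    return counts


def event_ages(
    histories: Sequence[CharacterHistory],
    transition_type: tuple,
    layer: str = "observed",
    per_map: bool = False,
):
    """Ages (Myr before present) of events of one projected type.

    ``transition_type`` is an ordered ``(from, to)`` pair on the chosen
    layer; e.g. ``(0, 1)`` on the observed layer collects trait gains.
    With ``per_map`` a list of per-history arrays is returned instead of
    one pooled array (the study dates events within a single map).
    """
    a_want, b_want = transition_type
    out = []
    for h in histories:
        ages = []
        tree = h.tree
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            state = int(h.node_states[p])
            for age, new in h.events[v]:
                a = _project(state, h.n_obs, layer)
                b = _project(int(new), h.n_obs, layer)
                if (a, b) == (a_want, b_want):
                    ages.append(float(age))
                state = int(new)
        out.append(np.asarray(ages))
    if per_map:
        return out
    return np.concatenate(out) if out else np.asarray([])


def density_mode(
    ages: np.ndarray,
    bandwidth_rule: str | float = "silverman",
    support: tuple | None = None,
    grid_size: int = DENSITY_GRID_SIZE,
) -> float:
    """Mode of a Gaussian kernel density estimate of event ages.

    The density is evaluated on a fixed grid over ``support`` (default: the
    data range); degenerate samples (all equal) return that value.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 2:
        raise ValueError("need at least 2 ages for a density mode")
    if np.ptp(ages) == 0:
        return float(ages[0])
    kde = gaussian_kde(ages, bw_method=bandwidth_rule)
    lo, hi = support if support is not None else (ages.min(), ages.max())
    grid = np.linspace(lo, hi, grid_size)
    dens = kde(grid)
    return float(grid[np.argmax(dens)])


def ltt_by_state(history: CharacterHistory, layer: str = "observed") -> pd.DataFrame:
    """Lineages-through-time per projected state.

    Returns a long table ``(time, state, count)`` with ``time`` in Myr
    before present, descending; each ``count`` holds on ``[time_i,
    time_{i+1})``.  At every breakpoint the counts over states sum to the
    number of live lineages, and at time 0 they equal the tip-state
    tallies.
    """
    tree = history.tree
    ages = node_ages(tree)
    K = history.n_obs if layer == "observed" else (
        history.n_hidden if layer == "hidden" else history.n_states
    )
    # segments: (start_age, end_age, state); start > end (toward present)
    segments = []
    root = tree.root
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p < 0:
            continue
        state = _project(int(history.node_states[p]), history.n_obs, layer)
        start = ages[p]
        for age, new in history.events[v]:
            segments.append((start, age, state))
            state = _project(int(new), history.n_obs, layer)
            start = age
        segments.append((start, ages[v], state))

    breaks = sorted({round(float(b), 12) for seg in segments for b in seg[:2]}, reverse=True)
    # sweep: delta at each break per state
    delta = {b: np.zeros(K) for b in breaks}
    for start, end, state in segments:
        delta[round(float(start), 12)][state] += 1
        delta[round(float(end), 12)][state] -= 1
    rows = []
    running = np.zeros(K)
    for b in breaks:
        running = running + delta[b]
        for s in range(K):
            rows.append({"time": b, "state": s, "count": int(round(running[s]))})
    # at the present (time 0) the sweep has closed all segments; report tips
    df = pd.DataFrame(rows)
    if not df.empty and df["time"].min() == 0.0:
        tip_states = [
            _project(int(history.node_states[v]), history.n_obs, layer)
            for v in tree.tip_indices
        ]
        tallies = np.bincount(tip_states, minlength=K)
        df.loc[df["time"] == 0.0, "count"] = [tallies[s] for s in range(K)]
    return df


@dataclass
class MappingSummary:
    """Per-transition-type statistics across stochastic maps."""

    n_maps: int
    counts: dict  # (layer, from, to) -> np.ndarray of per-map counts
    table: pd.DataFrame  # layer, from, to, mean, median, q2.5, q97.5
    ages: dict  # (layer, from, to) -> list of per-map age arrays

    def count_stats(self, layer: str, a: int, b: int) -> dict:
        c = self.counts[(layer, a, b)]
        return {
            "mean": float(np.mean(c)),
            "median": float(np.median(c)),
            "q2.5": float(np.percentile(c, 2.5)),
            "q97.5": float(np.percentile(c, 97.5)),
        }

    def to_dict(self) -> dict:
        return {
            "n_maps": self.n_maps,
            "transitions": [
                {
                    "layer": layer,
                    "from": a,
                    "to": b,
                    "per_map_counts": [int(x) for x in c],
                    **self.count_stats(layer, a, b),
                }
                for (layer, a, b), c in self.counts.items()
            ],
        }


def summarize_maps(histories: Sequence[CharacterHistory]) -> MappingSummary:
    """Mean, median and central 95% percentile interval (linear
    interpolation) of each transition type's count across maps, plus the
    per-map event-age samples."""
    if len(histories) < 2:
        raise ValueError("need at least 2 maps to summarise")
    h0 = histories[0]
    layers = [("observed", h0.n_obs)]
    if h0.n_hidden > 1:
        layers.append(("hidden", h0.n_hidden))
    counts: dict = {}
    ages: dict = {}
    for layer, K in layers:
        per_map = np.stack([count_transitions(h, layer) for h in histories])
        for a in range(K):
            for b in range(K):
                if a == b:
                    continue
                counts[(layer, a, b)] = per_map[:, a, b]
                ages[(layer, a, b)] = event_ages(
                    histories, (a, b), layer=layer, per_map=True
                )
    rows = []
    for (layer, a, b), c in counts.items():
        rows.append(
            {
                "layer": layer,
                "from": a,
                "to": b,
                "mean": float(np.mean(c)),
                "median": float(np.median(c)),
                "q2.5": float(np.percentile(c, 2.5)),
                "q97.5": float(np.percentile(c, 97.5)),
            }
        )
    return MappingSummary(
        n_maps=len(histories), counts=counts, table=pd.DataFrame(rows), ages=ages
    )
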