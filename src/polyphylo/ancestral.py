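"""Ancestral-state reconstruction by stochastic character mapping.

A discrete trait (ploidy level, stem nodulation, ecology, ...) evolves
along a time-calibrated tree under an Mk model: a continuous-time Markov
chain with instantaneous rate matrix Q on k states. Tip states (with
unknowns allowed) condition the process; stochastic mapping samples full
character histories — the state at every point of every branch — from
the posterior distribution of histories given the tips:

1. conditional likelihoods at every node by the pruning algorithm,
2. node states sampled root-to-tips from those conditionals,
3. branch histories sampled conditional on their endpoint states by
   uniformization (robust where rejection sampling stalls, e.g. a short
   branch whose endpoints force a change).

Summaries over sampled histories (per-node state frequencies, change
counts) estimate marginal ancestral posteriors and expected numbers of
transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize, minimize_scalar

from .trees import PhyloTree, TreeError

#: Tip-state tokens treated as unknown/uninformative.
MISSING_TOKENS = {None, "", "-", "?", "NA"}


@dataclass
class MkModel:
    """A k-state Mk model: rate matrix plus root state prior."""

    states: list[str]
    Q: np.ndarray
    root_prior: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.root_prior = np.asarray(self.root_prior, dtype=float)
        k = len(self.states)
        if k < 1 or self.Q.shape != (k, k):
            raise ValueError("Q must be square with one row per state")
        off = self.Q[~np.eye(k, dtype=bool)]
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be non-negative")
        if not np.allclose(self.Q.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("rows of Q must sum to zero")
        if not np.isclose(self.root_prior.sum(), 1.0):
            raise ValueError("root prior must sum to one")

    @property
    def k(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(f"state {state!r} not in model states {self.states}") from None

    @classmethod
    def equal_rates(cls, states: Sequence[str], rate: float,
                    root_prior: Optional[Sequence[float]] = None) -> "MkModel":
        """ER model: a single rate q for every transition."""
        k = len(states)
        Q = np.full((k, k), rate, dtype=float)
        np.fill_diagonal(Q, -rate * (k - 1))
        prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
        return cls(list(states), Q, prior)

    @classmethod
    def all_rates_different(cls, states: Sequence[str], rates: np.ndarray,
                            root_prior: Optional[Sequence[float]] = None) -> "MkModel":
        """ARD model from a full matrix of off-diagonal rates."""
        k = len(states)
        Q = np.array(rates, dtype=float)
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        prior = np.full(k, 1.0 / k) if root_prior is None else np.asarray(root_prior, float)
        return cls(list(states), Q, prior)


CharacterData = Mapping[str, Optional[str]]


def _tip_partials(tree: PhyloTree, model: MkModel,
                  data: CharacterData) -> dict[int, np.ndarray]:
    """Leaf partial-likelihood vectors; unknown tips are all-ones."""
    partials: dict[int, np.ndarray] = {}
    for leaf in tree.leaves:
        state = data.get(leaf.label)
        if state in MISSING_TOKENS:
            partials[leaf.id] = np.ones(model.k)
        else:
            v = np.zeros(model.k)
            v[model.state_index(state)] = 1.0
            partials[leaf.id] = v
    return partials


class _TransitionCache:
    def __init__(self, Q: np.ndarray):
        self.Q = Q
        self._cache: dict[float, np.ndarray] = {}

    def __call__(self, t: float) -> np.ndarray:
        if t not in self._cache:
            self._cache[t] = expm(self.Q * t)
        return self._cache[t]


def _node_partials(tree: PhyloTree, model: MkModel,
                   data: CharacterData) -> tuple[dict[int, np.ndarray], float]:
    """Post-order conditional likelihoods; returns (partials, log scale)."""
    tips = _tip_partials(tree, model, data)
    pmat = _TransitionCache(model.Q)
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder():
        if node.is_leaf:
            partials[node.id] = tips[node.id]
            continue
        v = np.ones(model.k)
        for child in node.children:
            if child.length is None:
                raise TreeError(
                    f"branch length missing above {child.label!r}; ancestral "
                    "mapping requires a fully length-annotated tree"
                )
            v = v * (pmat(child.length) @ partials[child.id])
        mx = v.max()
        if mx > 0:
            v = v / mx
            log_scale += float(np.log(mx))
        partials[node.id] = v
    return partials, log_scale


def prune_likelihood(tree: PhyloTree, model: MkModel, data: CharacterData) -> float:
    """Log-likelihood of the tip data by the pruning algorithm."""
    if tree.root.is_leaf:
        tips = _tip_partials(tree, model, data)
        like = float(model.root_prior @ tips[tree.root.id])
        return float(np.log(like)) if like > 0 else -np.inf
    partials, log_scale = _node_partials(tree, model, data)
    like = float(model.root_prior @ partials[tree.root.id])
    if like <= 0:
        return -np.inf
    return float(np.log(like)) + log_scale


def marginal_ancestral_posteriors(
    tree: PhyloTree, model: MkModel, data: CharacterData
) -> dict[int, np.ndarray]:
    """Exact marginal state posterior at every node (up-down algorithm)."""
    partials, _ = _node_partials(tree, model, data)
    pmat = _TransitionCache(model.Q)
    up: dict[int, np.ndarray] = {tree.root.id: model.root_prior.copy()}
    for node in tree.preorder():
        for child in node.children:
            P = pmat(child.length)
            sib = up[node.id].copy()
            for other in node.children:
                if other is not child:
                    sib = sib * (pmat(other.length) @ partials[other.id])
            up[child.id] = sib @ P
    out = {}
    for node in tree.postorder():
        post = up[node.id] * partials[node.id]
        total = post.sum()
        if total <= 0:
            raise TreeError("tip data have zero likelihood under this model")
        out[node.id] = post / total
    return out


def fit_mk(
    tree: PhyloTree,
    data: CharacterData,
    model_class: str = "ER",
    states: Optional[Sequence[str]] = None,
    root_prior: Optional[Sequence[float]] = None,
) -> tuple[MkModel, float]:
    """Maximum-likelihood Mk rates; returns (model, log-likelihood).

    ``model_class`` is ``"ER"`` (one rate, bounded 1-D optimization) or
    ``"ARD"`` (k(k-1) rates, quasi-Newton on log rates). A single
    observed state yields the boundary fit at rate 0 with a warning.
    """
    observed = sorted(
        {s for s in data.values() if s not in MISSING_TOKENS}
    )
    if states is None:
        states = observed
    if not states:
        raise TreeError("no observed states to fit")
    k = len(states)
    total_len = tree.total_length()
    if total_len <= 0:
        raise TreeError("tree has no positive branch length to fit rates on")

    if len(observed) < 2:
        warnings.warn(
            "all observed tips share one state; rate fitted at the 0 boundary",
            stacklevel=2,
        )
        model = MkModel.equal_rates(states, 0.0, root_prior)
        return model, prune_likelihood(tree, model, data)

    if model_class.upper() == "ER":
        def neg(q: float) -> float:
            return -prune_likelihood(
                tree, MkModel.equal_rates(states, q, root_prior), data
            )

        hi = 100.0 * k / total_len
        res = minimize_scalar(neg, bounds=(1e-9, hi), method="bounded",
                              options={"xatol": 1e-8})
        q = float(res.x)
        model = MkModel.equal_rates(states, q, root_prior)
        return model, -float(res.fun)

    if model_class.upper() == "ARD":
        idx = [(i, j) for i in range(k) for j in range(k) if i != j]

        def build(logr: np.ndarray) -> MkModel:
            R = np.zeros((k, k))
            for (i, j), v in zip(idx, np.exp(logr)):
                R[i, j] = v
            return MkModel.all_rates_different(states, R, root_prior)

        def neg(logr: np.ndarray) -> float:
            return -prune_likelihood(tree, build(logr), data)

        er_model, _ = fit_mk(tree, data, "ER", states, root_prior)
        q0 = max(float(er_model.Q[0, 1]), 1e-6)
        x0 = np.full(len(idx), np.log(q0))
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(-20, 10)] * len(idx))
        return build(res.x), -float(res.fun)

    raise ValueError(f"unknown model class {model_class!r}; use 'ER' or 'ARD'")


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------

@dataclass
class SimmapHistory:
    """One sampled character history: states along every branch.

    ``branch_segments[node_id]`` lists ``(state_index, duration)`` pieces
    for the branch above the node, ordered from the parent end downward;
    ``node_states`` gives the state at every node.
    """

    tree: PhyloTree
    states: list[str]
    node_states: dict[int, int]
    branch_segments: dict[int, list[tuple[int, float]]] = field(default_factory=dict)

    def dwell_times(self) -> np.ndarray:
        out = np.zeros(len(self.states))
        for segs in self.branch_segments.values():
            for state, dur in segs:
                out[state] += dur
        return out

    def n_changes(self) -> int:
        return int(self.change_matrix().sum())

    def change_matrix(self) -> np.ndarray:
        k = len(self.states)
        out = np.zeros((k, k))
        for segs in self.branch_segments.values():
            for (a, _), (b, _) in zip(segs, segs[1:]):
                out[a, b] += 1
        return out


@dataclass
class AncestralSummary:
    """Per-node posterior state frequencies across sampled histories."""

    tree: PhyloTree
    states: list[str]
    node_frequencies: dict[int, np.ndarray]
    mean_changes: np.ndarray

    def to_dataframe(self) -> "pd.DataFrame":  # noqa: F821 - lazy import
        import pandas as pd

        rows = []
        for node in self.tree.postorder():
            freq = self.node_frequencies[node.id]
            row = {"node_id": node.id, "label": node.label,
                   "is_leaf": node.is_leaf}
            row.update({f"p_{s}": freq[i] for i, s in enumerate(self.states)})
            rows.append(row)
        return pd.DataFrame(rows)


def _sample_path(rng: np.random.Generator, Q: np.ndarray, i: int, j: int,
                 t: float, P_t: np.ndarray) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on [0, t] by uniformization."""
    k = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0 or t <= 0:
        if i != j:
            raise TreeError("impossible history: state change on a zero-rate branch")
        return [(i, t)]
    p_ij = float(P_t[i, j])
    if p_ij <= 0:
        raise TreeError("impossible history: endpoint pair has zero probability")
    R = np.eye(k) + Q / lam

    # draw the number of uniformized jumps n | endpoints
    powers = [np.eye(k)]
    target = rng.random() * p_ij
    term = float(np.exp(-lam * t))   # Poisson(lam*t) pmf at n=0
    n = 0
    acc = term * powers[0][i, j]
    while acc < target:
        n += 1
        if n > 100_000:
            raise TreeError("uniformization failed to converge")
        powers.append(powers[-1] @ R)
        term *= lam * t / n
        acc += term * powers[n][i, j]

    if n == 0:
        return [(i, t)]
    # jump-chain states conditional on endpoints
    states = [i]
    for m in range(1, n):
        prev = states[-1]
        w = R[prev, :] * powers[n - m][:, j]
        w_sum = w.sum()
        states.append(int(rng.choice(k, p=w / w_sum)))
    states.append(j)
    times = np.sort(rng.random(n)) * t

    # collapse virtual (self) jumps into dwell segments
    segments: list[tuple[int, float]] = []
    current, start = states[0], 0.0
    for s, tm in zip(states[1:], times):
        if s != current:
            segments.append((current, float(tm - start)))
            current, start = s, float(tm)
    segments.append((current, float(t - start)))
    return segments


def stochastic_map(
    tree: PhyloTree,
    model: MkModel,
    data: CharacterData,
    n_maps: int = 10,
    seed: Optional[int] = None,
) -> list[SimmapHistory]:
    """Sample ``n_maps`` character histories from their posterior given tips.

    Reproducible given ``seed``. The default of 10 histories per
    character mirrors common practice; statistical summaries want more.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    rng = np.random.default_rng(seed)
    partials, _ = _node_partials(tree, model, data)
    pmat = _TransitionCache(model.Q)
    root_post = model.root_prior * partials[tree.root.id]
    total = root_post.sum()
    if total <= 0:
        raise TreeError("impossible history: tip data have zero likelihood")
    root_post = root_post / total

    histories = []
    for _ in range(n_maps):
        node_states: dict[int, int] = {
            tree.root.id: int(rng.choice(model.k, p=root_post))
        }
        segments: dict[int, list[tuple[int, float]]] = {}
        for node in tree.preorder():
            for child in node.children:
                P = pmat(child.length)
                w = P[node_states[node.id], :] * partials[child.id]
                w_sum = w.sum()
                if w_sum <= 0:
                    raise TreeError("impossible history: no consistent child state")
                j = int(rng.choice(model.k, p=w / w_sum))
                node_states[child.id] = j
                segments[child.id] = _sample_path(
                    rng, model.Q, node_states[node.id], j, child.length, P
                )
        histories.append(SimmapHistory(tree, list(model.states), node_states, segments))
    return histories


def summarize_maps(histories: Sequence[SimmapHistory]) -> AncestralSummary:
    """Empirical per-node state frequencies and mean change counts."""
    if not histories:
        raise ValueError("at least one history is required")
    tree = histories[0].tree
    states = histories[0].states
    if any(h.tree is not tree or h.states != states for h in histories):
        raise ValueError("histories must share one tree and state space")
    k = len(states)
    freq = {n.id: np.zeros(k) for n in tree.postorder()}
    changes = np.zeros((k, k))
    for h in histories:
        for node_id, s in h.node_states.items():
            freq[node_id][s] += 1
        changes += h.change_matrix()
    n = len(histories)
    for node_id in freq:
        freq[node_id] /= n
    return AncestralSummary(tree, states, freq, changes / n)
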