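"""Enumeration and ranking of allopolyploidy hypotheses.

The competing evolutionary histories for a clade of polyploid taxa are:

* 0 events — a plain species tree (one backbone per alternative
  placement of the polyploid clade, e.g. following the A- or the
  B-subgenome topology: T1, T2);
* 1 event — the polyploid clade as a whole arose by one hybridization
  between two backbone edges;
* 2 events — the two subclades obtained by splitting the polyploid
  clade at its root each arose by their own hybridization.

Attachment edges are drawn from the backbone pruned of the polyploid
clade and identified by the taxon set below them; a pair qualifies when
at least one of its edges is the pendant edge of a candidate parent
species. Every hypothesis is scored by summed assignment-minimized
duplication-loss reconciliation cost over the gene families, and the
preferred hypothesis is the one with fewest events whose score is
within ``delta_threshold`` of the global minimum — encoding the
parsimony argument that a small score improvement does not justify an
extra hybridization event.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .reconcile import HypothesisScore, ReconciliationCosts, score_hypothesis
from .trees import (
    GeneFamily,
    MulTree,
    Node,
    PhyloTree,
    TreeError,
    _clone_subtree,
    _graft,
)

EdgeId = frozenset
EdgePair = tuple[EdgeId, EdgeId]


@dataclass
class Hypothesis:
    """One candidate evolutionary history with its MUL-tree expansion."""

    label: str
    n_events: int
    mul: MulTree
    attachments: tuple[EdgePair, ...] = ()


@dataclass
class ScanReport:
    """Ranked hypothesis comparison; ranking is non-decreasing in score."""

    ranked: list[tuple[Hypothesis, HypothesisScore]]
    preferred: Hypothesis
    delta_threshold: float

    @property
    def best_score(self) -> float:
        return self.ranked[0][1].total_score

    @property
    def best_per_events(self) -> dict[int, tuple[Hypothesis, HypothesisScore]]:
        out: dict[int, tuple[Hypothesis, HypothesisScore]] = {}
        for hyp, score in self.ranked:
            if hyp.n_events not in out:
                out[hyp.n_events] = (hyp, score)
        return out

    def score_of(self, label: str) -> float:
        for hyp, score in self.ranked:
            if hyp.label == label:
                return score.total_score
        raise KeyError(label)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        best = self.best_score
        for rank, (hyp, score) in enumerate(self.ranked, start=1):
            rows.append(
                {
                    "rank": rank,
                    "hypothesis": hyp.label,
                    "n_events": hyp.n_events,
                    "total_score": score.total_score,
                    "delta": score.total_score - best,
                    "preferred": hyp.label == self.preferred.label,
                    "family_costs": ";".join(f"{c:g}" for c in score.family_costs),
                }
            )
        return pd.DataFrame(rows)


def _edge_name(edge: EdgeId) -> str:
    return "+".join(sorted(edge))


def _pair_name(pair: EdgePair) -> str:
    return f"{_edge_name(pair[0])}x{_edge_name(pair[1])}"


def _edge_sort_key(edge: EdgeId):
    return (len(edge), tuple(sorted(edge)))


def prune_polyploid_clade(
    backbone: PhyloTree, polyploid_taxa: Sequence[str]
) -> tuple[PhyloTree, PhyloTree]:
    """Split a backbone into (pruned diploid backbone, polyploid clade).

    The polyploid taxa must be monophyletic in the backbone.
    """
    taxa = frozenset(polyploid_taxa)
    if not taxa:
        raise TreeError("polyploid taxon set is empty")
    work = backbone.copy()
    clade_node = work.find_clade(taxa)
    if clade_node.parent is None:
        raise TreeError("the polyploid clade cannot be the whole backbone")
    parent = clade_node.parent
    parent.children.remove(clade_node)
    clade_node.parent = None
    clade_node.length = None
    work.reindex()
    work.suppress_unary()
    clade = PhyloTree(clade_node)
    return work, clade


def backbone_edges(pruned: PhyloTree) -> list[EdgeId]:
    """All edges of the pruned backbone (one per non-root node), sorted."""
    edges = [pruned.clade(n) for n in pruned.postorder() if n.parent is not None]
    return sorted(edges, key=_edge_sort_key)


def qualifying_pairs(
    pruned: PhyloTree, candidate_parents: Sequence[str]
) -> list[EdgePair]:
    """Unordered edge pairs with >=1 pendant edge of a candidate parent."""
    candidates = set(candidate_parents)
    if not candidates:
        raise TreeError("candidate parent set is empty")
    pendant = {frozenset([c]) for c in candidates}
    edges = backbone_edges(pruned)
    return [
        (e1, e2)
        for e1, e2 in itertools.combinations(edges, 2)
        if e1 in pendant or e2 in pendant
    ]


def _graft_events(
    pruned: PhyloTree,
    events: Sequence[tuple[PhyloTree, EdgePair]],
) -> MulTree:
    """Expand a hypothesis: graft each event's clade into both its edges.

    Targets are resolved to node objects before any grafting so that an
    earlier graft cannot change a later edge's taxon set; two grafts onto
    the same edge nest deterministically (later graft closer to the
    original child).
    """
    work = pruned.copy()
    resolved: list[tuple[PhyloTree, Node, Node]] = []
    for clade_tree, (e1, e2) in events:
        if e1 == e2:
            raise TreeError("the two parent edges of a hybridization must be distinct")
        resolved.append((clade_tree, work.find_clade(e1), work.find_clade(e2)))
    tagged: list[tuple[Node, str]] = []
    for clade_tree, n1, n2 in resolved:
        for target, tag in ((n1, "A"), (n2, "B")):
            copy_root = _clone_subtree(clade_tree.root)
            _graft(work, target, copy_root)
            stack = [copy_root]
            while stack:
                n = stack.pop()
                if n.is_leaf:
                    tagged.append((n, tag))
                stack.extend(n.children)
    work.reindex()
    return MulTree(work, {leaf.id: tag for leaf, tag in tagged})


def enumerate_no_event(
    backbones: Sequence[PhyloTree], labels: Optional[Sequence[str]] = None
) -> list[Hypothesis]:
    """One 0-event hypothesis per backbone, labeled T1, T2, ... by default."""
    if labels is None:
        labels = [f"T{i + 1}" for i in range(len(backbones))]
    return [
        Hypothesis(label, 0, MulTree(backbone.copy()))
        for label, backbone in zip(labels, backbones)
    ]


def enumerate_one_event(
    backbone: PhyloTree,
    polyploid_taxa: Sequence[str],
    candidate_parents: Sequence[str],
) -> list[Hypothesis]:
    """All 1-hybridization hypotheses for the polyploid clade as a unit."""
    pruned, clade = prune_polyploid_clade(backbone, polyploid_taxa)
    hyps = []
    for pair in qualifying_pairs(pruned, candidate_parents):
        mul = _graft_events(pruned, [(clade, pair)])
        hyps.append(Hypothesis(f"N1:{_pair_name(pair)}", 1, mul, (pair,)))
    return hyps


def enumerate_two_event(
    backbone: PhyloTree,
    polyploid_taxa: Sequence[str],
    candidate_parents: Sequence[str],
) -> list[Hypothesis]:
    """All 2-hybridization hypotheses, splitting the clade at its root."""
    pruned, clade = prune_polyploid_clade(backbone, polyploid_taxa)
    if len(clade.root.children) != 2:
        raise TreeError(
            "a two-event hypothesis needs a polyploid clade with two root subclades"
        )
    sub1 = PhyloTree(_clone_subtree(clade.root.children[0]))
    sub2 = PhyloTree(_clone_subtree(clade.root.children[1]))
    sub1.root.length = sub2.root.length = None
    pairs = qualifying_pairs(pruned, candidate_parents)
    hyps = []
    seen: set = set()
    for pair1, pair2 in itertools.product(pairs, pairs):
        key = (pair1, pair2)
        if key in seen:
            continue
        seen.add(key)
        mul = _graft_events(pruned, [(sub1, pair1), (sub2, pair2)])
        label = f"N2:({_pair_name(pair1)})+({_pair_name(pair2)})"
        hyps.append(Hypothesis(label, 2, mul, (pair1, pair2)))
    return hyps


def run_scan(
    backbones: Sequence[PhyloTree],
    polyploid_taxa: Sequence[str],
    candidate_parents: Sequence[str],
    families: Sequence[GeneFamily],
    costs: ReconciliationCosts = ReconciliationCosts(),
    delta_threshold: float = 5.0,
    backbone_labels: Optional[Sequence[str]] = None,
    max_events: int = 2,
) -> ScanReport:
    """Score every hypothesis and pick the preferred one.

    The better-scoring backbone seeds the 1- and 2-event enumerations.
    ``preferred`` is the hypothesis with fewest hybridization events whose
    score is within ``delta_threshold`` of the global minimum.
    """
    if not backbones:
        raise TreeError("at least one backbone is required")
    zero = enumerate_no_event(backbones, backbone_labels)
    scored: list[tuple[Hypothesis, HypothesisScore]] = [
        (h, score_hypothesis(h.mul, families, costs, h.label)) for h in zero
    ]
    score_by_label = {h.label: s.total_score for h, s in scored}
    base = min(zero, key=lambda h: (score_by_label[h.label], h.label))
    base_tree = base.mul.tree

    more: list[Hypothesis] = []
    if max_events >= 1:
        more.extend(enumerate_one_event(base_tree, polyploid_taxa, candidate_parents))
    if max_events >= 2 and len(polyploid_taxa) >= 2:
        more.extend(enumerate_two_event(base_tree, polyploid_taxa, candidate_parents))
    scored.extend(
        (h, score_hypothesis(h.mul, families, costs, h.label)) for h in more
    )

    scored.sort(key=lambda hs: (hs[1].total_score, hs[0].n_events, hs[0].label))
    best = scored[0][1].total_score
    within = [
        hs for hs in scored if hs[1].total_score <= best + delta_threshold
    ]
    preferred = min(
        within, key=lambda hs: (hs[0].n_events, hs[1].total_score, hs[0].label)
    )[0]
    return ScanReport(scored, preferred, delta_threshold)
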