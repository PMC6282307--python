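"""Duplication-loss reconciliation against species trees and MUL-trees.

The score of an allopolyploidy hypothesis is the classical LCA
duplication-loss reconciliation cost of each gene tree against the
hypothesis's MUL-tree expansion, minimized over all assignments of each
homeolog copy to one of the repeated (subgenome-tagged) species leaves.
Duplications and losses each cost 1 by default; both are configurable.

Losses are charged on the host tree *restricted to the subtree spanning
the images of sampled leaves*: species absent from a gene family (and
unused leaf copies) contribute no losses. The study's gene sets do not
cover every species for every gene, and charging every absence as a loss
would swamp the hybridization signal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .trees import GeneFamily, MulTree, PhyloTree, TreeError


@dataclass(frozen=True)
class ReconciliationCosts:
    """Per-event costs; the duplication-loss parsimony weights."""

    dup_cost: float = 1.0
    loss_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.dup_cost < 0 or self.loss_cost < 0:
            raise ValueError("event costs must be non-negative")


#: Maps gene-leaf label -> host leaf node id, for leaves of repeated species.
LeafAssignment = dict[str, int]


@dataclass
class ReconciliationResult:
    """LCA mapping with event counts for one gene family vs one host."""

    node_map: dict[int, int]            # gene node id -> host node id
    n_duplications: int
    n_losses: int
    total_cost: float
    assignment: LeafAssignment
    duplication_nodes: list[int] = field(default_factory=list)


@dataclass
class HypothesisScore:
    """Sum over gene families of their minimum reconciliation cost."""

    hypothesis_id: str
    family_costs: list[float]
    total_score: float

    @classmethod
    def from_costs(cls, hypothesis_id: str, costs: Sequence[float]) -> "HypothesisScore":
        return cls(hypothesis_id, list(costs), float(sum(costs)))


class _HostIndex:
    """Flat-array view of a host tree for fast repeated reconciliations."""

    def __init__(self, host: Union[PhyloTree, MulTree]):
        if isinstance(host, MulTree):
            tree = host.tree
            self.leaf_copies = host.leaf_copies()
        else:
            tree = host
            self.leaf_copies = {}
            for leaf in tree.leaves:
                self.leaf_copies.setdefault(leaf.label, []).append((leaf.id, None))
        tree.validate(require_binary=True)
        self.tree = tree
        n = len(tree.nodes)
        self.n = n
        self.parent = [-1] * n
        self.depth = [0] * n
        self.children: list[list[int]] = [[] for _ in range(n)]
        for node in tree.preorder():
            if node.parent is not None:
                self.parent[node.id] = node.parent.id
                self.depth[node.id] = self.depth[node.parent.id] + 1
        for node in tree.postorder():
            if node.parent is not None:
                self.children[node.parent.id].append(node.id)

    def lca2(self, a: int, b: int) -> int:
        depth, parent = self.depth, self.parent
        while a != b:
            if depth[a] >= depth[b]:
                a = parent[a]
            else:
                b = parent[b]
        return a


class _GenePrep:
    """Gene tree flattened to arrays; reused across assignments."""

    def __init__(self, family: GeneFamily):
        family.tree.validate(require_binary=True)
        self.family = family
        tree = family.tree
        n = len(tree.nodes)
        self.n = n
        self.left = [-1] * n
        self.right = [-1] * n
        self.leaf_label: list[Optional[str]] = [None] * n
        for node in tree.postorder():
            if node.is_leaf:
                self.leaf_label[node.id] = node.label
            else:
                self.left[node.id] = node.children[0].id
                self.right[node.id] = node.children[1].id


def _reconcile_core(prep: _GenePrep, host: _HostIndex,
                    images: Sequence[int]) -> tuple[int, int, list[int], list[int]]:
    """LCA mapping + event counts given per-gene-leaf host images.

    Returns ``(duplications, losses, node_map, duplication_node_ids)``.
    Losses use the host tree induced by the used leaves: a gene edge g->c
    spanning k induced-host edges contributes k-1 losses when g is a
    speciation and k when g is a duplication.
    """
    n_host = host.n
    used = [False] * n_host
    for img in images:
        used[img] = True

    # used-leaf counts below each host node (ids are post-order)
    below = [1 if used[v] else 0 for v in range(n_host)]
    total_used = sum(below)
    parent = host.parent
    for v in range(n_host):
        p = parent[v]
        if p >= 0:
            below[p] += below[v]

    # induced root: the deepest node covering all used leaves
    r = next(v for v in range(n_host) if below[v] == total_used)

    induced = [False] * n_host
    for v in range(n_host):
        if used[v]:
            induced[v] = True
        else:
            induced[v] = sum(1 for c in host.children[v] if below[c] > 0) >= 2

    # number of induced ancestors-or-self below the induced root
    idepth = [0] * n_host
    stack = list(host.children[r])
    while stack:
        v = stack.pop()
        if below[v] == 0:
            continue
        idepth[v] = idepth[parent[v]] + (1 if induced[v] else 0)
        stack.extend(host.children[v])

    left, right = prep.left, prep.right
    node_map = [0] * prep.n
    dups = 0
    losses = 0
    dup_nodes: list[int] = []
    leaf_idx = 0
    lca2 = host.lca2
    for g in range(prep.n):  # gene ids are post-order
        if left[g] < 0:
            node_map[g] = images[leaf_idx]
            leaf_idx += 1
        else:
            ml, mr = node_map[left[g]], node_map[right[g]]
            m = lca2(ml, mr)
            node_map[g] = m
            if m == ml or m == mr:
                dups += 1
                dup_nodes.append(g)
                losses += (idepth[ml] - idepth[m]) + (idepth[mr] - idepth[m])
            else:
                losses += (idepth[ml] - idepth[m] - 1) + (idepth[mr] - idepth[m] - 1)
    return dups, losses, node_map, dup_nodes


def _leaf_images(prep: _GenePrep, host: _HostIndex,
                 assignment: LeafAssignment) -> list[int]:
    """Host image for each gene leaf, in gene post-order."""
    images = []
    for g in range(prep.n):
        label = prep.leaf_label[g]
        if label is None:
            continue
        if label in assignment:
            images.append(assignment[label])
            continue
        sp = prep.family.leaf_to_species[label]
        copies = host.leaf_copies.get(sp)
        if not copies:
            raise TreeError(f"species {sp!r} is missing from the host tree")
        if len(copies) > 1:
            raise TreeError(
                f"leaf {label!r} (species {sp!r}) is repeated in the host; "
                "an explicit assignment is required"
            )
        images.append(copies[0][0])
    return images


def _result(prep: _GenePrep, host: _HostIndex, images: Sequence[int],
            assignment: LeafAssignment,
            costs: ReconciliationCosts) -> ReconciliationResult:
    d, l, node_map, dup_nodes = _reconcile_core(prep, host, images)
    return ReconciliationResult(
        node_map=dict(enumerate(node_map)),
        n_duplications=d,
        n_losses=l,
        total_cost=costs.dup_cost * d + costs.loss_cost * l,
        assignment=dict(assignment),
        duplication_nodes=dup_nodes,
    )


def lca_reconcile(
    family: GeneFamily,
    host: Union[PhyloTree, MulTree],
    assignment: Optional[LeafAssignment] = None,
    costs: ReconciliationCosts = ReconciliationCosts(),
) -> ReconciliationResult:
    """Classical LCA duplication-loss reconciliation under a fixed assignment.

    ``assignment`` maps each gene leaf whose species is repeated in the
    host to a specific host leaf id; leaves of unrepeated species are
    mapped implicitly (their host leaf is unique).
    """
    hidx = _HostIndex(host)
    prep = _GenePrep(family)
    assignment = dict(assignment or {})
    images = _leaf_images(prep, hidx, assignment)
    return _result(prep, hidx, images, assignment, costs)


def _ambiguous_choices(prep: _GenePrep, host: _HostIndex):
    """Ambiguous leaves sorted by label; choices per leaf in tag order A < B."""
    amb: list[tuple[str, list[int]]] = []
    for g in range(prep.n):
        label = prep.leaf_label[g]
        if label is None:
            continue
        sp = prep.family.leaf_to_species[label]
        copies = host.leaf_copies.get(sp)
        if copies is None:
            raise TreeError(f"species {sp!r} is missing from the host tree")
        if len(copies) > 1:
            amb.append((label, [leaf_id for leaf_id, _tag in copies]))
    amb.sort(key=lambda t: t[0])
    return amb


def _minimize_over_assignments(
    family: GeneFamily,
    mul: Union[PhyloTree, MulTree],
    costs: ReconciliationCosts,
    max_ambiguous: Optional[int] = None,
    stop_at_zero: bool = True,
) -> ReconciliationResult:
    hidx = _HostIndex(mul)
    prep = _GenePrep(family)
    amb = _ambiguous_choices(prep, hidx)
    if max_ambiguous is not None and len(amb) > max_ambiguous:
        raise TreeError(
            f"{len(amb)} ambiguous leaves exceed the combinatorial guard "
            f"({max_ambiguous})"
        )
    labels = [label for label, _ in amb]
    base: LeafAssignment = {}
    if not amb:
        images = _leaf_images(prep, hidx, base)
        return _result(prep, hidx, images, base, costs)

    # Leaf slots in gene post-order; ambiguous slots patched per assignment.
    slot_of_label: dict[str, int] = {}
    images: list[int] = []
    slot = 0
    for g in range(prep.n):
        label = prep.leaf_label[g]
        if label is None:
            continue
        sp = prep.family.leaf_to_species[label]
        copies = hidx.leaf_copies[sp]
        slot_of_label[label] = slot
        images.append(copies[0][0])
        slot += 1

    best: Optional[tuple[float, tuple[int, ...]]] = None
    zero_floor = 0.0
    # lexicographic order over (ambiguous label, A-before-B) makes the first
    # minimum encountered the deterministic tie-break winner
    for combo in itertools.product(*(choices for _, choices in amb)):
        for label, leaf_id in zip(labels, combo):
            images[slot_of_label[label]] = leaf_id
        d, l, _, _ = _reconcile_core(prep, hidx, images)
        cost = costs.dup_cost * d + costs.loss_cost * l
        if best is None or cost < best[0]:
            best = (cost, combo)
            if stop_at_zero and cost <= zero_floor:
                break

    assert best is not None
    assignment = dict(zip(labels, best[1]))
    for label, leaf_id in zip(labels, best[1]):
        images[slot_of_label[label]] = leaf_id
    return _result(prep, hidx, images, assignment, costs)


def _lca_table(host: _HostIndex) -> "np.ndarray":
    import numpy as np

    n = host.n
    table = np.empty((n, n), dtype=np.int64)
    for a in range(n):
        for b in range(a, n):
            table[a, b] = table[b, a] = host.lca2(a, b)
    return table


def _induced_idepth(host: _HostIndex, used_leaves: frozenset) -> "np.ndarray":
    """Induced-tree depth per host node for one used-leaf set (array form)."""
    import numpy as np

    used = [False] * host.n
    for v in used_leaves:
        used[v] = True
    below = [1 if used[v] else 0 for v in range(host.n)]
    for v in range(host.n):
        p = host.parent[v]
        if p >= 0:
            below[p] += below[v]
    total = sum(1 for u in used if u)
    r = next(v for v in range(host.n) if below[v] == total)
    induced = [
        used[v] or sum(1 for c in host.children[v] if below[c] > 0) >= 2
        for v in range(host.n)
    ]
    idepth = np.zeros(host.n, dtype=np.int64)
    stack = list(host.children[r])
    while stack:
        v = stack.pop()
        if below[v] == 0:
            continue
        idepth[v] = idepth[host.parent[v]] + (1 if induced[v] else 0)
        stack.extend(host.children[v])
    return idepth


def _vectorized_min(
    family: GeneFamily,
    mul: Union[PhyloTree, MulTree],
    costs: ReconciliationCosts,
) -> ReconciliationResult:
    """Minimum over all assignments, evaluated for every assignment at once.

    The induced-subtree loss term depends on the assignment only through
    which copy leaves (A, B or both) each repeated species uses, so the
    per-node induced depths are cached per usage pattern while the LCA
    mapping itself is batched with numpy over the full assignment grid.
    Assignments are enumerated in lexicographic order (leaves by label,
    A before B), so the first minimum is the deterministic tie-break.
    """
    import numpy as np

    hidx = _HostIndex(mul)
    prep = _GenePrep(family)
    amb = _ambiguous_choices(prep, hidx)
    if not amb or any(len(choices) != 2 for _, choices in amb):
        return _minimize_over_assignments(family, mul, costs, stop_at_zero=True)

    labels = [label for label, _ in amb]
    m = len(amb)
    n_assign = 1 << m
    # bit i (most significant first) selects the B copy of ambiguous leaf i
    bits = (np.arange(n_assign)[:, None] >> np.arange(m - 1, -1, -1)) & 1

    # leaf slots in gene post-order
    slot_labels: list[str] = []
    fixed_images: list[int] = []
    for g in range(prep.n):
        label = prep.leaf_label[g]
        if label is None:
            continue
        slot_labels.append(label)
        sp = prep.family.leaf_to_species[label]
        fixed_images.append(hidx.leaf_copies[sp][0][0])
    n_slots = len(slot_labels)
    images = np.tile(np.array(fixed_images, dtype=np.int64), (n_assign, 1))
    choice_arrays = {
        label: np.array(choices, dtype=np.int64) for label, choices in amb
    }
    amb_slot = {label: i for i, label in enumerate(slot_labels) if label in choice_arrays}
    for i, label in enumerate(labels):
        images[:, amb_slot[label]] = choice_arrays[label][bits[:, i]]

    # usage-pattern index per assignment (per repeated species: A/B/both)
    repeated = sorted(
        sp for sp, copies in hidx.leaf_copies.items()
        if len(copies) > 1 and any(prep.family.leaf_to_species[l] == sp for l in slot_labels)
    )
    pattern = np.zeros(n_assign, dtype=np.int64)
    sp_copy_ids = {}
    for sp in repeated:
        a_id, b_id = (c[0] for c in hidx.leaf_copies[sp])
        sp_copy_ids[sp] = (a_id, b_id)
        cols = [amb_slot[l] for l in slot_labels
                if prep.family.leaf_to_species[l] == sp]
        use_a = (images[:, cols] == a_id).any(axis=1)
        use_b = (images[:, cols] == b_id).any(axis=1)
        code = np.where(use_a & use_b, 2, np.where(use_b, 1, 0))
        pattern = pattern * 3 + code

    fixed_used = {
        img for label, img in zip(slot_labels, fixed_images)
        if label not in choice_arrays
    }
    idepth_rows: dict[int, int] = {}
    idepth_list: list[np.ndarray] = []
    pattern_row = np.empty(n_assign, dtype=np.int64)
    for pat in np.unique(pattern):
        used = set(fixed_used)
        rem = int(pat)
        for sp in reversed(repeated):
            code = rem % 3
            rem //= 3
            a_id, b_id = sp_copy_ids[sp]
            if code == 0:
                used.add(a_id)
            elif code == 1:
                used.add(b_id)
            else:
                used.update((a_id, b_id))
        idepth_rows[int(pat)] = len(idepth_list)
        idepth_list.append(_induced_idepth(hidx, frozenset(used)))
    for pat, row in idepth_rows.items():
        pattern_row[pattern == pat] = row
    idepth_mat = np.vstack(idepth_list)           # patterns x host nodes

    lca_tab = _lca_table(hidx)
    chunk = 1 << 15
    best = -1
    best_cost = float("inf")
    for start in range(0, n_assign, chunk):
        stop = min(start + chunk, n_assign)
        blk = slice(start, stop)
        size = stop - start
        node_map = np.empty((size, prep.n), dtype=np.int64)
        dup_count = np.zeros(size, dtype=np.int64)
        loss_count = np.zeros(size, dtype=np.int64)
        prow = pattern_row[blk]
        leaf_idx = 0
        for g in range(prep.n):
            if prep.left[g] < 0:
                node_map[:, g] = images[blk, leaf_idx]
                leaf_idx += 1
                continue
            ml = node_map[:, prep.left[g]]
            mr = node_map[:, prep.right[g]]
            mg = lca_tab[ml, mr]
            node_map[:, g] = mg
            is_dup = (mg == ml) | (mg == mr)
            dup_count += is_dup
            k = (idepth_mat[prow, ml] - idepth_mat[prow, mg]) \
                + (idepth_mat[prow, mr] - idepth_mat[prow, mg])
            loss_count += k - 2 * (~is_dup)
        total = costs.dup_cost * dup_count + costs.loss_cost * loss_count
        i = int(np.argmin(total))
        if total[i] < best_cost:
            best_cost = float(total[i])
            best = start + i
        if best_cost <= 0:
            break
    assignment = {
        label: int(choice_arrays[label][bits[best, i]])
        for i, label in enumerate(labels)
    }
    best_images = [int(x) for x in images[best]]
    return _result(prep, hidx, best_images, assignment, costs)


def mul_reconcile(
    family: GeneFamily,
    mul: Union[PhyloTree, MulTree],
    costs: ReconciliationCosts = ReconciliationCosts(),
) -> ReconciliationResult:
    """Minimum-cost reconciliation over all homeolog-to-subgenome assignments.

    Ties are broken deterministically: ambiguous leaves ordered by label,
    and the A copy preferred to the B copy. With no repeated species this
    reduces to :func:`lca_reconcile` with the unique assignment.
    """
    return _vectorized_min(family, mul, costs)


def brute_force_mul_score(
    family: GeneFamily,
    mul: Union[PhyloTree, MulTree],
    costs: ReconciliationCosts = ReconciliationCosts(),
) -> ReconciliationResult:
    """Exhaustive minimum over every assignment; the testing oracle.

    Refuses instances with more than 20 ambiguous leaves.
    """
    return _minimize_over_assignments(
        family, mul, costs, max_ambiguous=20, stop_at_zero=False
    )


def score_hypothesis(
    mul: Union[PhyloTree, MulTree],
    families: Sequence[GeneFamily],
    costs: ReconciliationCosts = ReconciliationCosts(),
    hypothesis_id: str = "",
) -> HypothesisScore:
    """Total duplication-loss parsimony score of a hypothesis over families."""
    if not families:
        raise TreeError("at least one gene family is required")
    per_family = [mul_reconcile(f, mul, costs).total_cost for f in families]
    return HypothesisScore.from_costs(hypothesis_id, per_family)
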