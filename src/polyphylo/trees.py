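"""Rooted trees, hybridization networks and multi-labeled (MUL) trees.

This module provides the structures every downstream stage shares:

* :class:`PhyloTree` — a rooted tree with optional branch lengths and
  support values, stable integer node ids assigned in post-order.
* :class:`SpeciesNetwork` — a rooted DAG with at most two in-degree-2
  hybridization nodes, parsed from extended newick (``#H<k>`` tags).
* :class:`MulTree` — the multi-labeled tree expansion of a network, in
  which every species below a hybridization appears twice, tagged with
  the subgenome it descends from (``A`` for the first parent edge, ``B``
  for the second).

Newick parsing is done here rather than through an external library
because the extended-newick dialect with hybrid tags is not supported by
the installed tree libraries, and both dialects share one tokenizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence


class TreeError(ValueError):
    """Invalid tree/network structure or operation."""


class NewickParseError(TreeError):
    """Malformed newick/eNewick input; reports the offending position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class Node:
    """A node of a rooted tree. ``id`` is assigned by the owning tree."""

    __slots__ = ("id", "label", "length", "support", "parent", "children")

    def __init__(self, label: str = "", length: Optional[float] = None,
                 support: Optional[float] = None):
        self.id: int = -1
        self.label = label
        self.length = length
        self.support = support
        self.parent: Optional[Node] = None
        self.children: list[Node] = []

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.id} {self.label!r} {kind}>"


class PhyloTree:
    """A rooted phylogenetic tree.

    Node ids are stable integers assigned in post-order at indexing time;
    label strings are never used as keys internally.
    """

    def __init__(self, root: Node):
        self.root = root
        self._postorder: list[Node] = []
        self.reindex()

    # -- structure -------------------------------------------------------

    def reindex(self) -> None:
        """(Re)assign post-order ids after structural edits."""
        order: list[Node] = []
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                order.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        for i, node in enumerate(order):
            node.id = i
        self._postorder = order

    def postorder(self) -> Iterator[Node]:
        return iter(self._postorder)

    def preorder(self) -> Iterator[Node]:
        return reversed(self._postorder)

    @property
    def nodes(self) -> Sequence[Node]:
        return self._postorder

    def node(self, node_id: int) -> Node:
        return self._postorder[node_id]

    @property
    def leaves(self) -> list[Node]:
        return [n for n in self._postorder if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self._postorder)

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self._postorder if n.parent is not None)

    def validate(self, require_binary: bool = False) -> None:
        seen = set()
        for n in self._postorder:
            if id(n) in seen:
                raise TreeError("tree is not acyclic")
            seen.add(id(n))
            if n.length is not None and n.length < 0:
                raise TreeError(f"negative branch length on node {n.label!r}")
            if require_binary and len(n.children) not in (0, 2):
                raise TreeError(
                    f"node {n.label!r} has {len(n.children)} children; "
                    "a strictly bifurcating tree is required"
                )

    # -- queries ---------------------------------------------------------

    def depths(self) -> list[int]:
        """Edge-count depth per node id (root = 0)."""
        depth = [0] * len(self._postorder)
        for node in self.preorder():
            if node.parent is not None:
                depth[node.id] = depth[node.parent.id] + 1
        return depth

    def clade(self, node: Node) -> frozenset:
        """Leaf-label set below ``node`` (the edge identifier used by scans)."""
        if node.is_leaf:
            return frozenset([node.label])
        labels = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                labels.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(labels)

    def find_clade(self, taxa: Iterable[str]) -> Node:
        """The node whose leaf set equals ``taxa`` exactly.

        Raises :class:`TreeError` when the taxa are not monophyletic here.
        """
        want = frozenset(taxa)
        for node in self.postorder():
            if self.clade(node) == want:
                return node
        raise TreeError(f"taxa {sorted(want)} are not a clade of this tree")

    def copy(self) -> "PhyloTree":
        def clone(n: Node) -> Node:
            m = Node(n.label, n.length, n.support)
            for c in n.children:
                m.add_child(clone(c))
            return m

        return PhyloTree(clone(self.root))

    def suppress_unary(self) -> None:
        """Remove internal nodes with a single child, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self._postorder):
                if len(node.children) == 1 and node.parent is not None:
                    child = node.children[0]
                    if node.length is not None or child.length is not None:
                        child.length = (node.length or 0.0) + (child.length or 0.0)
                    parent = node.parent
                    parent.children[parent.children.index(node)] = child
                    child.parent = parent
                    changed = True
            if len(self.root.children) == 1:
                new_root = self.root.children[0]
                new_root.parent = None
                new_root.length = None
                self.root = new_root
                changed = True
            if changed:
                self.reindex()


def lca(tree: PhyloTree, nodes: Iterable[Node]) -> Node:
    """Lowest common ancestor of a non-empty set of nodes of ``tree``."""
    nodes = list(nodes)
    if not nodes:
        raise TreeError("lca of an empty node set is undefined")
    depth = tree.depths()
    current = nodes[0]
    for other in nodes[1:]:
        a, b = current, other
        while a is not b:
            if depth[a.id] >= depth[b.id]:
                a = a.parent
            else:
                b = b.parent
        current = a
    return current


@dataclass
class GeneFamily:
    """A rooted gene tree plus the leaf -> species map; the unit reconciled.

    Multiple gene copies per species are allowed (homeologs or paralogs);
    ``leaf_to_species`` must cover every leaf of ``tree``.
    """

    tree: PhyloTree
    leaf_to_species: dict[str, str]
    gene_name: str = ""

    def __post_init__(self) -> None:
        labels = self.tree.leaf_labels()
        if len(labels) < 2:
            raise TreeError(f"gene family {self.gene_name!r} needs >= 2 leaves")
        missing = [l for l in labels if l not in self.leaf_to_species]
        if missing:
            raise TreeError(
                f"gene family {self.gene_name!r}: leaves without a species mapping: "
                f"{missing}"
            )
        if any(not sp for sp in self.leaf_to_species.values()):
            raise TreeError("species names must be non-empty")

    @property
    def species(self) -> set[str]:
        return {self.leaf_to_species[l] for l in self.tree.leaf_labels()}


# ---------------------------------------------------------------------------
# Newick / extended newick I/O
# ---------------------------------------------------------------------------

_PUNCT = "(),;:"


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
        elif c in _PUNCT:
            tokens.append((c, i))
            i += 1
        elif c == "'":
            j = text.find("'", i + 1)
            if j < 0:
                raise NewickParseError("unterminated quoted label", i)
            tokens.append((text[i + 1:j], i))
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in _PUNCT and not text[j].isspace():
                j += 1
            tokens.append((text[i:j], i))
            i = j
    return tokens


class _Parser:
    def __init__(self, text: str):
        if not text or not text.strip():
            raise NewickParseError("empty newick input", 0)
        self.text = text
        self.tokens = _tokenize(text)
        self.pos = 0

    def peek(self) -> Optional[tuple[str, int]]:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> tuple[str, int]:
        tok = self.peek()
        if tok is None:
            raise NewickParseError("unexpected end of input", len(self.text))
        self.pos += 1
        return tok

    def parse(self) -> Node:
        root = self._subtree()
        tok = self.peek()
        if tok is None or tok[0] != ";":
            raise NewickParseError(
                "expected ';' terminating the newick statement",
                tok[1] if tok else len(self.text),
            )
        self.pos += 1
        if self.peek() is not None:
            raise NewickParseError("trailing content after ';'", self.peek()[1])
        return root

    def _subtree(self) -> Node:
        tok = self.peek()
        if tok is None:
            raise NewickParseError("unexpected end of input", len(self.text))
        node = Node()
        if tok[0] == "(":
            self.next()
            node.add_child(self._subtree())
            while True:
                sep = self.next()
                if sep[0] == ",":
                    node.add_child(self._subtree())
                elif sep[0] == ")":
                    break
                else:
                    raise NewickParseError(
                        f"expected ',' or ')', found {sep[0]!r}", sep[1]
                    )
        self._label_and_length(node)
        return node

    def _label_and_length(self, node: Node) -> None:
        tok = self.peek()
        if tok is not None and tok[0] not in _PUNCT:
            node.label = self.next()[0]
            if node.children and node.label:
                try:
                    node.support = float(node.label)
                except ValueError:
                    pass
        tok = self.peek()
        if tok is not None and tok[0] == ":":
            self.next()
            val, pos = self.next()
            try:
                node.length = float(val)
            except ValueError:
                raise NewickParseError(f"invalid branch length {val!r}", pos) from None


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted newick statement into a :class:`PhyloTree`."""
    tree = PhyloTree(_Parser(text).parse())
    tree.validate()
    return tree


def _node_to_newick(node: Node, parts: list[str]) -> None:
    if node.children:
        parts.append("(")
        for i, child in enumerate(node.children):
            if i:
                parts.append(",")
            _node_to_newick(child, parts)
        parts.append(")")
    label = node.label
    if any(ch in label for ch in "(),;: '"):
        label = "'" + label.replace("'", "''") + "'"
    parts.append(label)
    if node.length is not None:
        parts.append(f":{node.length:g}")


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree; the output reparses to an isomorphic tree."""
    parts: list[str] = []
    _node_to_newick(tree.root, parts)
    parts.append(";")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Species networks
# ---------------------------------------------------------------------------

class NetNode:
    """A node of a species network; hybridization nodes have two parents."""

    __slots__ = ("id", "label", "parents", "children")

    def __init__(self, label: str = ""):
        self.id: int = -1
        self.label = label
        self.parents: list[NetNode] = []
        self.children: list[NetNode] = []

    @property
    def is_hybrid(self) -> bool:
        return len(self.parents) == 2

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<NetNode {self.id} {self.label!r}>"


class SpeciesNetwork:
    """A rooted DAG with 0, 1 or 2 in-degree-2 hybridization nodes.

    Branch lengths live on edges (``lengths[(parent_id, child_id)]``)
    because the two incoming edges of a hybridization node may differ.
    """

    def __init__(self, root: NetNode, lengths: Optional[dict] = None):
        self.root = root
        self.lengths: dict[tuple[int, int], Optional[float]] = lengths or {}
        self._order: list[NetNode] = []
        self._index()
        self.validate()

    def _index(self) -> None:
        order: list[NetNode] = []
        seen: set[int] = set()

        def visit(node: NetNode) -> None:
            if id(node) in seen:
                return
            seen.add(id(node))
            for child in node.children:
                visit(child)
            order.append(node)

        visit(self.root)
        for i, node in enumerate(order):
            node.id = i
        self._order = order

    @property
    def nodes(self) -> Sequence[NetNode]:
        return self._order

    @property
    def hybrid_nodes(self) -> list[NetNode]:
        return [n for n in self._order if n.is_hybrid]

    @property
    def n_hybridizations(self) -> int:
        return len(self.hybrid_nodes)

    def edge_length(self, parent: NetNode, child: NetNode) -> Optional[float]:
        return self.lengths.get((parent.id, child.id))

    def validate(self) -> None:
        for node in self._order:
            if node is self.root:
                if node.parents:
                    raise TreeError("root must have in-degree 0")
            elif len(node.parents) not in (1, 2):
                raise TreeError(f"node {node.label!r} has in-degree {len(node.parents)}")
        if self.n_hybridizations > 2:
            raise TreeError(
                f"networks with {self.n_hybridizations} hybridizations are unsupported "
                "(at most 2)"
            )


def parse_enewick(text: str) -> SpeciesNetwork:
    """Parse extended newick with ``#H<k>`` hybrid tags into a network.

    Each tag must occur exactly twice; the occurrence carrying children
    (or, failing that, the first occurrence) contributes the hybrid
    node's subtree, the other contributes only its second parent edge.
    A tag-free input yields a 0-hybridization network.
    """
    raw = PhyloTree(_Parser(text).parse())

    # First pass: build NetNodes mirroring the parsed tree, collect tagged nodes.
    tagged: dict[str, list[tuple[Node, NetNode]]] = {}
    lengths: dict[int, Optional[float]] = {}  # id(netnode) -> incoming length

    def convert(n: Node) -> NetNode:
        label = n.label
        tag = None
        if "#" in label:
            name, _, tag_part = label.partition("#")
            label, tag = name, tag_part
        m = NetNode(label)
        lengths[id(m)] = n.length
        for c in n.children:
            child = convert(c)
            m.children.append(child)
            child.parents.append(m)
        if tag is not None:
            tagged.setdefault(tag, []).append((n, m))
        return m

    root = convert(raw.root)

    # Merge the two occurrences of each hybrid tag into one node.
    merged_lengths: dict[tuple[int, NetNode], Optional[float]] = {}
    for tag, occurrences in tagged.items():
        if len(occurrences) != 2:
            raise TreeError(
                f"hybrid tag #{tag} appears {len(occurrences)} time(s); expected exactly 2"
            )
        (_, a), (_, b) = occurrences
        keeper, stub = (a, b) if a.children or not b.children else (b, a)
        if keeper.children and stub.children:
            raise TreeError(f"hybrid tag #{tag} carries a subtree at both occurrences")
        if not keeper.label:
            keeper.label = stub.label
        for parent in keeper.parents:
            merged_lengths[(id(parent), keeper)] = lengths[id(keeper)]
        for parent in stub.parents:
            parent.children[parent.children.index(stub)] = keeper
            keeper.parents.append(parent)
            merged_lengths[(id(parent), keeper)] = lengths[id(stub)]

    # Suppress unary pass-through nodes introduced by "(#H1)"-style stubs.
    def suppress(node: NetNode) -> None:
        for child in list(node.children):
            suppress(child)
        for child in list(node.children):
            if len(child.children) == 1 and not child.is_hybrid and not child.label:
                grand = child.children[0]
                node.children[node.children.index(child)] = grand
                grand.parents[grand.parents.index(child)] = node
                lg = lengths[id(child)]
                inc = merged_lengths.pop((id(child), grand), None)
                if inc is None:
                    inc = lengths[id(grand)]
                if lg is not None or inc is not None:
                    merged_lengths[(id(node), grand)] = (lg or 0.0) + (inc or 0.0)

    suppress(root)
    while len(root.children) == 1 and not root.children[0].is_hybrid:
        old = root
        root = root.children[0]
        root.parents.remove(old)

    net = SpeciesNetwork(root)
    edge_lengths: dict[tuple[int, int], Optional[float]] = {}
    for node in net.nodes:
        for child in node.children:
            val = merged_lengths.get((id(node), child))
            if val is None and len(child.parents) == 1:
                val = lengths.get(id(child))
            edge_lengths[(node.id, child.id)] = val
    net.lengths = edge_lengths
    return net


# ---------------------------------------------------------------------------
# MUL-trees
# ---------------------------------------------------------------------------

@dataclass
class MulTree:
    """A species tree in which polyploid leaf labels may appear twice.

    ``copy_tag`` maps leaf node id -> "A"/"B" for repeated species (A
    descends from the first parent edge of the hybridization, B from the
    second, following the subgenome convention of the gene data), or
    ``None`` for species that appear once.
    """

    tree: PhyloTree
    copy_tag: dict[int, Optional[str]] = field(default_factory=dict)
    provenance: Optional[object] = None

    def __post_init__(self) -> None:
        for leaf in self.tree.leaves:
            self.copy_tag.setdefault(leaf.id, None)

    def leaf_copies(self) -> dict[str, list[tuple[int, Optional[str]]]]:
        """species -> [(leaf id, tag)], tags sorted A < B."""
        out: dict[str, list[tuple[int, Optional[str]]]] = {}
        for leaf in self.tree.leaves:
            out.setdefault(leaf.label, []).append((leaf.id, self.copy_tag.get(leaf.id)))
        for copies in out.values():
            copies.sort(key=lambda t: (t[1] is not None, t[1] or ""))
        return out

    def repeated_species(self) -> set[str]:
        return {sp for sp, copies in self.leaf_copies().items() if len(copies) > 1}


def _graft(tree: PhyloTree, attach_child: Node, clade_root: Node) -> Node:
    """Subdivide the edge above ``attach_child`` and hang ``clade_root`` there."""
    parent = attach_child.parent
    if parent is None:
        raise TreeError("cannot graft onto the root edge")
    mid = Node()
    if attach_child.length is not None:
        mid.length = attach_child.length / 2.0
        attach_child.length = attach_child.length / 2.0
    parent.children[parent.children.index(attach_child)] = mid
    mid.parent = parent
    mid.add_child(attach_child)
    mid.add_child(clade_root)
    return mid


def _clone_subtree(node: Node) -> Node:
    m = Node(node.label, node.length, node.support)
    for c in node.children:
        m.add_child(_clone_subtree(c))
    return m


def build_mul_tree(
    backbone: PhyloTree,
    polyploid_clade: PhyloTree,
    parent_edge_1: frozenset,
    parent_edge_2: frozenset,
    provenance: Optional[object] = None,
) -> MulTree:
    """Graft a polyploid clade into two backbone edges, tagging copies A/B.

    Edges are identified by the leaf-label set below them, which is stable
    across serializations. The copy under ``parent_edge_1`` is the A
    subgenome, the one under ``parent_edge_2`` the B subgenome.
    """
    e1, e2 = frozenset(parent_edge_1), frozenset(parent_edge_2)
    if e1 == e2:
        raise TreeError("the two parent edges of a hybridization must be distinct")
    backbone_taxa = set(backbone.leaf_labels())
    poly_taxa = set(polyploid_clade.leaf_labels())
    if backbone_taxa & poly_taxa:
        raise TreeError(
            f"polyploid taxa overlap the backbone: {sorted(backbone_taxa & poly_taxa)}"
        )

    work = backbone.copy()
    targets = [work.find_clade(e1), work.find_clade(e2)]
    tagged_leaves: list[tuple[Node, str]] = []
    for target, tag in zip(targets, ("A", "B")):
        copy_root = _clone_subtree(polyploid_clade.root)
        _graft(work, target, copy_root)
        stack = [copy_root]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                tagged_leaves.append((n, tag))
            stack.extend(n.children)
    work.reindex()
    tags = {leaf.id: tag for leaf, tag in tagged_leaves}
    return MulTree(work, tags, provenance)


def network_to_multree(network: SpeciesNetwork) -> MulTree:
    """Expand a network into its MUL-tree (each hybrid subtree duplicated).

    Stacked hybridizations (one hybrid ancestral to another) are rejected.
    """
    hybrids = network.hybrid_nodes
    for h in hybrids:
        below: set[int] = set()
        stack = list(h.children)
        while stack:
            n = stack.pop()
            below.add(n.id)
            stack.extend(n.children)
        if any(other.id in below for other in hybrids if other is not h):
            raise TreeError("stacked hybridizations are unsupported")

    tagged_leaves: list[tuple[Node, str]] = []

    def expand(net_node: NetNode, via_parent: Optional[NetNode], tag: Optional[str]) -> Node:
        t = Node(net_node.label)
        if via_parent is not None:
            t.length = network.edge_length(via_parent, net_node)
        for child in net_node.children:
            child_tag = tag
            if child.is_hybrid:
                slot = [i for i, p in enumerate(child.parents) if p is net_node]
                child_tag = "A" if slot[0] == 0 else "B"
            t.add_child(expand(child, net_node, child_tag))
        if not net_node.children and tag is not None:
            tagged_leaves.append((t, tag))
        return t

    root = expand(network.root, None, None)
    tree = PhyloTree(root)
    tree.suppress_unary()
    # suppress_unary reindexes; recover tags by object identity
    tags: dict[int, Optional[str]] = {}
    tagged_ids = {id(leaf): tag for leaf, tag in tagged_leaves}
    for leaf in tree.leaves:
        if id(leaf) in tagged_ids:
            tags[leaf.id] = tagged_ids[id(leaf)]
    return MulTree(tree, tags, network)
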