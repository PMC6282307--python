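import random

import numpy as np
import pytest

import polyphylo as pp
from polyphylo.trees import Node, PhyloTree


def random_binary_tree(labels, rng, with_lengths=False):
    """Random rooted binary tree over the given leaf labels."""
    nodes = [Node(l) for l in labels]
    if with_lengths:
        for n in nodes:
            n.length = round(rng.uniform(0.1, 2.0), 3)
    while len(nodes) > 1:
        a = nodes.pop(rng.randrange(len(nodes)))
        b = nodes.pop(rng.randrange(len(nodes)))
        p = Node()
        if with_lengths:
            p.length = round(rng.uniform(0.1, 2.0), 3)
        p.add_child(a)
        p.add_child(b)
        nodes.append(p)
    root = nodes[0]
    root.length = None
    return PhyloTree(root)


def random_mul_instance(rng, max_species=6, max_gene_leaves=10, max_repeated=3):
    """A random MUL-tree plus a random gene family over its species."""
    n_sp = rng.randint(3, max_species)
    species = [f"S{i}" for i in range(n_sp)]
    repeated = rng.sample(species, rng.randint(1, min(max_repeated, n_sp)))
    mul_tree = random_binary_tree(species + repeated, rng)
    tags, seen = {}, set()
    for leaf in mul_tree.leaves:
        if leaf.label in repeated:
            tags[leaf.id] = "B" if leaf.label in seen else "A"
            seen.add(leaf.label)
    mul = pp.MulTree(mul_tree, tags)
    leaf_map, counts = {}, {}
    for _ in range(rng.randint(2, max_gene_leaves)):
        sp = rng.choice(species)
        counts[sp] = counts.get(sp, 0) + 1
        leaf_map[f"{sp.lower()}c{counts[sp]}"] = sp
    gene_tree = random_binary_tree(list(leaf_map), rng)
    return pp.GeneFamily(gene_tree, leaf_map), mul


@pytest.fixture
def five_leaf_tree():
    return pp.parse_newick("((A:0.5,B:0.8):0.3,(C:0.4,(D:0.6,E:0.2):0.3):0.5);")


@pytest.fixture
def toy_host():
    return pp.parse_newick("((A,B),C);")


@pytest.fixture
def pso_mul():
    """MUL-tree (((P,H),(S,H)),O) with H tagged A on the P side."""
    return pp.build_mul_tree(
        pp.parse_newick("((P,S),O);"),
        pp.parse_newick("H;"),
        frozenset(["P"]),
        frozenset(["S"]),
    )


@pytest.fixture
def py_rng():
    return random.Random(20240917)


@pytest.fixture
def np_rng():
    return np.random.default_rng(20240917)
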