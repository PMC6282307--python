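"""Synthetic data generators for every pipeline stage.

Three generators provide desk-scale inputs with the statistical
structure the analyses assume:

* gene families evolving by a duplication-loss birth-death process
  along a species network, where an allopolyploid hybridization node
  merges the genomes of its two parent lineages — every extant copy on
  each parent edge is inherited by the hybrid, producing the A/B
  homeolog-pair structure of true allopolyploids;
* discrete traits evolving under a known Mk rate matrix (ground truth
  for ancestral-state recovery);
* genotype matrices with k diverged groups under a Balding-Nichols
  allele-frequency model plus independent missingness, written as VCF.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .ancestral import MkModel, SimmapHistory
from .diversity import GenotypeMatrix
from .trees import GeneFamily, Node, PhyloTree, SpeciesNetwork, TreeError


# ---------------------------------------------------------------------------
# Gene families along a species network
# ---------------------------------------------------------------------------

@dataclass
class GeneFamilySimConfig:
    """Birth-death gene-family simulation settings.

    Rates are events per gene copy per unit branch length; the cost-free
    default network is supplied by the caller and must carry branch
    lengths on every edge.
    """

    network: SpeciesNetwork
    dup_rate: float = 0.2
    loss_rate: float = 0.2
    n_families: int = 4
    seed: Optional[int] = None
    #: Redraw families in which any species retains more copies than this.
    #: Emulates the deliberate choice of *low-copy* nuclear markers: a family
    #: that ballooned to many paralogs would never be used as a ploidy marker.
    max_copies_per_species: Optional[int] = 4

    def __post_init__(self) -> None:
        if self.dup_rate < 0 or self.loss_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.n_families < 1:
            raise ValueError("n_families must be >= 1")
        if self.max_copies_per_species is not None and self.max_copies_per_species < 1:
            raise ValueError("max_copies_per_species must be >= 1 (or None)")


@dataclass
class BranchEventRecord:
    """Events on one species-network edge during one family's history."""

    edge: tuple[str, str]                # (parent label/id, child label/id)
    length: float
    n_entering: int
    n_duplications: int
    n_losses: int


@dataclass
class FamilyTruth:
    """Ground-truth event log returned alongside each simulated family."""

    branch_events: list[BranchEventRecord] = field(default_factory=list)
    n_duplications: int = 0
    n_losses: int = 0
    n_redraws: int = 0


def _evolve_edge(entry_tips: Sequence[Node], length: float, lam: float, mu: float,
                 rng: np.random.Generator) -> tuple[list[Node], int, int]:
    """Birth-death evolution of gene copies along one edge.

    Each entering tip extends its pending branch; duplications bifurcate,
    losses kill the lineage. Returns (surviving tips, dups, losses).
    """
    survivors: list[Node] = []
    n_dup = n_loss = 0
    total = lam + mu
    stack = [(tip, length) for tip in entry_tips]
    while stack:
        node, remaining = stack.pop()
        if total <= 0:
            node.length = (node.length or 0.0) + remaining
            survivors.append(node)
            continue
        wait = rng.exponential(1.0 / total)
        if wait >= remaining:
            node.length = (node.length or 0.0) + remaining
            survivors.append(node)
        elif rng.random() < lam / total:
            n_dup += 1
            node.length = (node.length or 0.0) + wait
            c1, c2 = Node(length=0.0), Node(length=0.0)
            node.add_child(c1)
            node.add_child(c2)
            stack.append((c2, remaining - wait))
            stack.append((c1, remaining - wait))
        else:
            n_loss += 1
            node.length = (node.length or 0.0) + wait
            node.label = ""
            # Node has __slots__; extinction is marked via the support field
            node.support = float("-inf")
    return survivors, n_dup, n_loss


def _is_dead(node: Node) -> bool:
    return node.support == float("-inf")


def _prune_extinct(root: Node) -> Optional[Node]:
    """Drop extinct lineages; returns None when nothing survives."""
    if not root.children:
        return None if _is_dead(root) or not root.label else root
    kept = []
    for child in root.children:
        sub = _prune_extinct(child)
        if sub is not None:
            kept.append(sub)
    root.children = []
    for c in kept:
        root.add_child(c)
    if not kept:
        return None
    return root


def simulate_gene_family(
    config: GeneFamilySimConfig,
    rng: Optional[np.random.Generator] = None,
    gene_name: str = "",
    max_redraws: int = 10_000,
) -> tuple[GeneFamily, FamilyTruth]:
    """Simulate one gene family along the species network.

    A single ancestral copy enters at the root; copies duplicate and die
    along edges, bifurcate at speciations, and at a hybridization node
    the hybrid inherits every extant copy from *both* parent edges
    (genome merger: with no losses every hybrid-descendant species
    carries one homeolog per subgenome). Families with fewer than two
    surviving copies are redrawn, so the output is always a valid
    family; the redraw count is reported in the truth record.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    net = config.network
    lam, mu = config.dup_rate, config.loss_rate

    for redraw in range(max_redraws + 1):
        truth = FamilyTruth(n_redraws=redraw)
        gene_root = Node()
        copies_at: dict[int, list[Node]] = {net.root.id: [gene_root]}
        leaf_map: dict[str, str] = {}
        species_counter: dict[str, int] = {}

        # nodes are indexed children-first; reversed order is parents-first
        for u in reversed(net.nodes):
            copies = copies_at.get(u.id, [])
            if u.is_leaf:
                for tip in copies:
                    idx = species_counter.get(u.label, 0) + 1
                    species_counter[u.label] = idx
                    tip.label = f"{u.label}_{idx}"
                    leaf_map[tip.label] = u.label
                continue
            for tip in copies:
                for v in u.children:
                    t = net.edge_length(u, v)
                    if t is None:
                        raise TreeError(
                            "gene-family simulation needs branch lengths on "
                            f"every network edge (missing on {u.label!r}->{v.label!r})"
                        )
                    cont = Node(length=0.0)
                    tip.add_child(cont)
                    entering = [cont]
                    surv, nd, nl = _evolve_edge(entering, t, lam, mu, rng)
                    truth.branch_events.append(
                        BranchEventRecord(
                            (u.label or str(u.id), v.label or str(v.id)),
                            t, len(entering), nd, nl,
                        )
                    )
                    truth.n_duplications += nd
                    truth.n_losses += nl
                    copies_at.setdefault(v.id, []).extend(surv)

        pruned = _prune_extinct(gene_root)
        if pruned is None:
            continue
        tree = PhyloTree(pruned)
        tree.suppress_unary()
        if len(tree.leaves) < 2:
            continue
        cap = config.max_copies_per_species
        if cap is not None and any(c > cap for c in species_counter.values()):
            continue
        tree.root.length = None
        family = GeneFamily(tree, leaf_map, gene_name)
        return family, truth
    raise TreeError("failed to simulate a non-empty family; rates too extreme")


def simulate_gene_families(
    config: GeneFamilySimConfig, gene_names: Optional[Sequence[str]] = None
) -> list[tuple[GeneFamily, FamilyTruth]]:
    """Simulate ``config.n_families`` families from one seeded stream."""
    rng = np.random.default_rng(config.seed)
    names = list(gene_names or (f"gene{i + 1}" for i in range(config.n_families)))
    return [
        simulate_gene_family(config, rng, gene_name=names[i])
        for i in range(config.n_families)
    ]


# ---------------------------------------------------------------------------
# Discrete traits
# ---------------------------------------------------------------------------

def simulate_trait(
    tree: PhyloTree, model: MkModel, seed: Optional[int] = None
) -> tuple[dict[str, str], SimmapHistory]:
    """Evolve a discrete trait along the tree; returns (tips, true history)."""
    rng = np.random.default_rng(seed)
    Q = model.Q
    root_state = int(rng.choice(model.k, p=model.root_prior))
    node_states = {tree.root.id: root_state}
    segments: dict[int, list[tuple[int, float]]] = {}
    for node in tree.preorder():
        for child in node.children:
            if child.length is None:
                raise TreeError("trait simulation requires branch lengths")
            state = node_states[node.id]
            t_left = child.length
            segs: list[tuple[int, float]] = []
            start = 0.0
            elapsed = 0.0
            while True:
                rate = -Q[state, state]
                if rate <= 0:
                    break
                wait = rng.exponential(1.0 / rate)
                if elapsed + wait >= t_left:
                    break
                elapsed += wait
                segs.append((state, elapsed - start))
                start = elapsed
                probs = Q[state, :].clip(min=0.0)
                probs[state] = 0.0
                state = int(rng.choice(model.k, p=probs / probs.sum()))
            segs.append((state, t_left - start))
            segments[child.id] = segs
            node_states[child.id] = state
    tips = {leaf.label: model.states[node_states[leaf.id]] for leaf in tree.leaves}
    history = SimmapHistory(tree, list(model.states), node_states, segments)
    return tips, history


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeSimConfig:
    """Structured-population genotype simulation settings.

    ``divergence_f`` is the Balding-Nichols F: group allele frequencies
    are Beta-distributed around the ancestral frequency with variance
    F p(1-p); F = 0 collapses to one panmictic population.
    """

    n_groups: int = 3
    samples_per_group: int = 20
    n_snps: int = 500
    divergence_f: float = 0.3
    missing_rate: float = 0.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.divergence_f < 1:
            raise ValueError("divergence_f must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.maf_range
        if not 0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if min(self.n_groups, self.samples_per_group, self.n_snps) < 1:
            raise ValueError("counts must be positive")


def simulate_genotypes(
    config: GenotypeSimConfig,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Simulate genotypes for k diverged groups; returns (matrix, labels)."""
    rng = np.random.default_rng(config.seed)
    k, m = config.n_groups, config.samples_per_group
    n = k * m
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=config.n_snps)
    F = config.divergence_f
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_group = rng.beta(a, b, size=(k, config.n_snps))
    else:
        p_group = np.broadcast_to(p_anc, (k, config.n_snps)).copy()
    labels = np.repeat(np.arange(k), m)
    calls = rng.binomial(2, p_group[labels, :]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = np.nan
    samples = [f"g{g + 1}_s{i + 1}" for g in range(k) for i in range(m)]
    variant_ids = [f"snp{j + 1}" for j in range(config.n_snps)]
    matrix = GenotypeMatrix(samples, variant_ids, calls,
                            chrom=["1"] * config.n_snps,
                            pos=list(range(1, config.n_snps + 1)))
    return matrix, labels


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write dosages as a minimal VCF v4.2 with GT fields."""
    gt_of = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = genotypes.chrom or ["1"] * genotypes.n_variants
        for c in dict.fromkeys(chroms):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(genotypes.samples) + "\n")
        pos = genotypes.pos or list(range(1, genotypes.n_variants + 1))
        for j, vid in enumerate(genotypes.variant_ids):
            gts = [
                "./." if np.isnan(genotypes.calls[i, j])
                else gt_of[genotypes.calls[i, j]]
                for i in range(genotypes.n_samples)
            ]
            fh.write(f"{chroms[j]}\t{pos[j]}\t{vid}\tA\tT\t.\t.\t.\tGT\t"
                     + "\t".join(gts) + "\n")
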