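# Methods

This note documents the models and numerical choices behind each stage,
what the synthetic generators do and do not emulate, and the design
decisions taken where more than one defensible convention exists.

## Reconciliation score

A hypothesis about the origin of a polyploid clade is represented as a
rooted species network with 0, 1 or 2 hybridization (in-degree-2) nodes
and expanded into its MUL-tree: the sub-DAG below each hybridization is
duplicated under both parent edges, the copy under the first parent
tagged subgenome A, under the second subgenome B. Stacked
hybridizations (one ancestral to another) are not supported.

Given a gene family *G* (rooted binary gene tree + leaf→species map)
and a host MUL-tree *M*, a **leaf assignment** sends each gene copy of a
repeated species to one of its host copies. For a fixed assignment the
cost is the classical LCA duplication–loss reconciliation: each internal
gene node maps to the LCA of its children's images; a node is a
duplication when its image equals a child's image; a gene edge g→c
spanning *k* edges of the host tree contributes *k−1* losses at a
speciation and *k* at a duplication. The score of the family against
*M* is the minimum cost over all assignments (dup and loss each cost 1
by default, both configurable), and a hypothesis's score is the sum
over families.

**Losses on the induced host tree.** Gene families rarely sample every
species. Losses are therefore counted on the host tree restricted to
the subtree spanning the images of the sampled leaves (unused leaf
copies and unsampled species contribute nothing). Charging unsampled
taxa as losses would add a constant penalty per missing species that
swamps the topological signal the score exists to measure.

**Minimization.** With two host copies per repeated species and *m*
ambiguous gene leaves there are 2^m assignments. The production path
evaluates all of them in a single numpy batch: an LCA lookup table over
host-node pairs drives the vectorized bottom-up mapping, and the
induced-subtree loss depths — which depend on the assignment only
through *which* copies each species uses (A, B or both, ≤ 3^(species)
patterns) — are cached per usage pattern. Assignments are enumerated in
lexicographic order (ambiguous leaves by label, A before B), so ties
break deterministically toward the lexicographically smallest
assignment. A plain per-assignment Python implementation
(`brute_force_mul_score`, guarded at 20 ambiguous leaves) is exported
as an independent oracle and the two are compared on hundreds of random
instances in the test suite.

## Hypothesis scan

The search space is deliberately the smallest one consistent with the
questions asked of it:

* 0 events: each supplied backbone (the polyploid clade placed per one
  subgenome's topology) is a hypothesis (T1, T2, ...).
* 1 event: the polyploid clade, pruned from the better-scoring
  backbone, is re-attached as a hybrid of every unordered pair of
  distinct edges of the pruned backbone such that at least one edge is
  the pendant edge of a candidate parent species.
* 2 events: the clade is split at its root; each subclade independently
  receives a qualifying edge pair (cross-product, exact duplicates
  removed). Non-root splits are not searched.

Edges are identified by the taxon set below them, making hypothesis
labels stable across serializations; the root edge is not an attachment
point. Grafts are resolved to node objects before any grafting so two
events can target the same backbone edge (the later graft nests below
the earlier one, deterministically).

The **preferred** hypothesis is the one with fewest events whose score
lies within `delta_threshold` (default 5) of the global minimum. This
encodes the standard parsimony argument: an extra hybridization event
must buy a non-trivial score improvement. With `delta_threshold = 0`
the rule degenerates to the arg-min with ties broken toward fewer
events.

## Stochastic character mapping

Discrete traits evolve under an Mk model: rate matrix Q (equal-rates by
default; all-rates-different available), branch lengths in the tree's
time units, and a root prior (uniform by default; the paper trail for
any given dataset rarely records these choices, so both are explicit
parameters). Unknown tip states ("-", "?", empty) enter the pruning
algorithm as all-ones partial likelihoods.

Histories are sampled in three steps: (1) post-order conditional
likelihoods with per-branch matrix exponentials (cached by branch
length, scaled to avoid underflow); (2) node states sampled root-to-tip
from the conditionals; (3) branch paths conditional on endpoint states
by **uniformization** — the jump count is drawn from its exact
endpoint-conditioned distribution via accumulated powers of
R = I + Q/Λ (Λ = max leaving rate), interior jump-chain states by
backward smoothing, jump times as uniform order statistics, and virtual
self-jumps collapsed. Uniformization is used because rejection sampling
stalls on short branches whose endpoints force a change. Zero-likelihood
inputs (e.g. conflicting tips across zero-length branches) raise an
impossible-history error rather than returning degenerate output.

ER rates are fitted by bounded 1-D maximum likelihood (scipy's bounded
Brent, upper bound 100·k/tree-length); ARD by L-BFGS-B on log rates
initialized at the ER fit. Monomorphic tip data yield the boundary fit
at rate 0 with a warning. The default of 10 maps per character mirrors
common practice; calibration checks in the tests use 2000 maps, at
which the sampled root-state frequency matches the exact marginal
posterior (computed by an up-down pass) to within ±0.03.

## Ploidy metrics

The 2n→ploidy call is a pure lookup over the counts documented for this
group — {20: 2x, 28: 4x, 38: 4x, 40: 4x, 56: 8x, 60: 6x, 76: 8x} — with
every other count reported as `unknown`: dysploid counts (28, 38) belong
to known tetraploid lineages, so rounding 2n/20 would misclassify them,
and guessing for unobserved counts is worse than admitting ignorance.
Genome sizes convert at 1 pg DNA = 978 Mb, so Mb/1C = (2C pg)/2 × 978;
computed values are reported at full precision, never prose roundings.
Copy-count consensus calls a taxon diploid-like when every low-copy gene
yielded one sequence and polyploid-like when the fraction of two-copy
genes reaches the threshold (default 0.5, encoding "a homeolog pair for
most genes"); disagreement with the karyotype raises a conflict flag and
the karyotype call wins (chromosome counts are the more direct
evidence).

## Diversity (IBS + MDS)

Variants are filtered on per-variant missingness (> 10% removed) and
minor allele frequency computed on non-missing calls (< 1% removed;
the MAF threshold is inclusive — keep ≥ 0.01 — matching common
filtering practice where the comparator is usually left implicit).
The pairwise distance is 1 − mean IBS allele sharing,
s = 1 − |d_i − d_j|/2 per variant, averaged over pairwise-complete
variants with no imputation; a pair sharing no genotyped variant is an
error. Classical (Torgerson) MDS double-centers −D²/2 and takes the
top-k positive eigenpairs, coordinates scaled by √eigenvalue, axis
signs fixed so the largest-magnitude loading is positive. Negative
eigenvalues (non-Euclidean residue of the IBS metric) are reported but
never selected as axes. Group assignment is a seeded k-medoids (PAM)
partition of the leading coordinates with 10 restarts, written in-house
because no installed library provides k-medoids; the group count k is
always user-supplied, never auto-selected.

## Synthetic generators

**Gene families.** A single ancestral copy enters the network root and
evolves tipward: per copy, duplications (rate λ) and losses (rate μ)
occur as a birth–death process along each edge; copies bifurcate at
speciations; at a hybridization node the hybrid inherits **every**
extant copy from both parent edges — a genome merger, so with no losses
each hybrid-descendant species carries exactly one homeolog per
subgenome. Two conditioning rules apply, both by redraw and both
recorded in the truth log: families with fewer than two surviving
copies (a gene family must have ≥ 2 leaves), and families in which any
species retains more than `max_copies_per_species` copies (default 4).
The cap emulates the deliberate selection of *low-copy* nuclear markers
— a family that ballooned into a large paralog fan would never be used
to diagnose ploidy — and keeps the assignment space of the
reconciliation bounded. Both conditions bias the per-branch event
distribution slightly at high rates; the Poisson moment checks in the
tests therefore run at low rates with the cap disabled.

**Traits.** Forward CTMC simulation from a root state drawn from the
prior; returns tips plus the full true history for recovery tests.

**Genotypes.** Ancestral allele frequencies uniform in a configurable
range (default 0.05–0.5); group frequencies Beta-distributed around
them with Balding–Nichols divergence F (variance F·p(1−p)); genotypes
binomial(2, group frequency); missingness independent per call. What
this emulates is the *group structure* of a reduced-representation SNP
panel — it does not model linkage, allele-frequency spectra under
drift, batch effects of library preparation, or reference-alignment
bias, so passing clustering tests demonstrates the correctness of the
distance/MDS/grouping machinery, not robustness to those artifacts.

## Example system and problem sizes

The bundled example (`polyphylo.datasets`) is an 8-taxon system: five
diploids (including candidate parents PAT and SEM and an outgroup) and
a three-taxon polyploid clade created by one hybridization between the
pendant edges of PAT and SEM. Branch lengths (0.3–1.8 time units,
total MUL-tree length ≈ 8) are chosen so that the default rates of 0.2
duplications and 0.2 losses per copy per unit length yield a handful of
events per family — enough noise to make the scan non-trivial while
keeping families low-copy. Validation runs use 4 families per replicate
and 50 replicates for recovery rates, 200 random instances for oracle
equivalence, and 2000 sampled histories for mapping calibration.

## Known limitations

* Networks are limited to two non-stacked hybridizations; gene trees
  and hosts must be binary (polytomies are rejected, not resolved —
  arbitrary resolution would silently change scores).
* The reconciliation model covers duplication and loss only: no
  transfers, no incomplete lineage sorting, no probabilistic
  reconciliation.
* The assignment minimization is exponential in the number of homeolog
  copies per family; it is exact and fast for low-copy families (the
  intended regime) but not suitable for large multi-copy gene families.
* Rooting of input gene trees is the caller's responsibility; scores
  are sensitive to it.
* Ancestral mapping requires a strictly bifurcating, fully
  length-annotated tree; resolving polytomies (e.g. of a consensus
  tree) is an upstream choice that should be recorded by the caller.
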