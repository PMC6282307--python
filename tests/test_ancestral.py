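"""Mk likelihoods, rate fitting and stochastic character mapping."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import polyphylo as pp
from polyphylo.ancestral import (
    MkModel,
    fit_mk,
    marginal_ancestral_posteriors,
    prune_likelihood,
    stochastic_map,
    summarize_maps,
)
from polyphylo.simulate import simulate_trait
from polyphylo.trees import TreeError

from conftest import random_binary_tree


def exhaustive_likelihood(tree, model, data):
    """Oracle: sum the joint likelihood over all interior state combinations."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    P = {n.id: expm(model.Q * n.length) for n in nodes if n.parent is not None}
    sidx = {s: i for i, s in enumerate(model.states)}
    total = 0.0
    for combo in itertools.product(range(model.k), repeat=len(internals)):
        st = {n.id: c for n, c in zip(internals, combo)}
        for leaf in tree.leaves:
            obs = data.get(leaf.label)
            if obs is None or obs == "-":
                continue
            st[leaf.id] = sidx[obs]
        missing = [l for l in tree.leaves if l.id not in st]
        for miss_combo in itertools.product(range(model.k), repeat=len(missing)):
            for n, c in zip(missing, miss_combo):
                st[n.id] = c
            p = model.root_prior[st[tree.root.id]]
            for n in nodes:
                if n.parent is not None:
                    p *= P[n.id][st[n.parent.id], st[n.id]]
            total += p
    return float(np.log(total))


class TestPruneLikelihood:
    def test_matches_exhaustive_summation(self, py_rng):
        """Pruning equals brute-force state summation (<=6 leaves, <=3 states)."""
        for trial in range(12):
            n_leaves = py_rng.randint(2, 6)
            k = py_rng.choice([2, 3])
            tree = random_binary_tree(
                [f"t{i}" for i in range(n_leaves)], py_rng, with_lengths=True
            )
            model = MkModel.equal_rates(
                [str(s) for s in range(k)], py_rng.uniform(0.1, 1.5)
            )
            data = {
                f"t{i}": ("-" if py_rng.random() < 0.2 else str(py_rng.randrange(k)))
                for i in range(n_leaves)
            }
            assert prune_likelihood(tree, model, data) == pytest.approx(
                exhaustive_likelihood(tree, model, data), abs=1e-10
            )

    def test_zero_rate_limit_is_root_prior_mass(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 1e-13)
        data = {l: "0" for l in five_leaf_tree.leaf_labels()}
        assert np.exp(prune_likelihood(five_leaf_tree, model, data)) == pytest.approx(
            0.5, abs=1e-9
        )

    def test_single_leaf_tree_returns_root_prior(self):
        tree = pp.parse_newick("A;")
        model = MkModel.equal_rates(["0", "1"], 0.3, root_prior=[0.7, 0.3])
        assert np.exp(prune_likelihood(tree, model, {"A": "1"})) == pytest.approx(0.3)

    def test_all_missing_likelihood_is_one(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 0.4)
        data = {l: "-" for l in five_leaf_tree.leaf_labels()}
        assert prune_likelihood(five_leaf_tree, model, data) == pytest.approx(0.0)

    def test_missing_branch_length_raises(self):
        tree = pp.parse_newick("((A:1,B),C:1);")
        model = MkModel.equal_rates(["0", "1"], 0.4)
        with pytest.raises(TreeError, match="branch length"):
            prune_likelihood(tree, model, {"A": "0", "B": "0", "C": "1"})

    def test_unknown_state_raises(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 0.4)
        with pytest.raises(ValueError, match="state"):
            prune_likelihood(five_leaf_tree, model,
                             {l: "9" for l in five_leaf_tree.leaf_labels()})


class TestFitMk:
    def test_monomorphic_tips_hit_zero_boundary(self, five_leaf_tree):
        data = {l: "0" for l in five_leaf_tree.leaf_labels()}
        with pytest.warns(UserWarning, match="boundary"):
            model, logl = fit_mk(five_leaf_tree, data, states=["0", "1"])
        assert model.Q[0, 1] == 0.0
        assert logl == pytest.approx(np.log(0.5))

    def test_fitted_rate_beats_grid(self, five_leaf_tree):
        data = {"A": "0", "B": "1", "C": "1", "D": "0", "E": "1"}
        model, logl = fit_mk(five_leaf_tree, data, "ER")
        for q in np.linspace(0.01, 5.0, 20):
            other = MkModel.equal_rates(model.states, q)
            assert logl >= prune_likelihood(five_leaf_tree, other, data) - 1e-6

    def test_rate_recovery_on_simulated_data(self, py_rng):
        """ER rate recovered within a factor of 2 in >=80% of replicates.

        Branch lengths are kept in [0.1, 1.0] so that a rate of 0.5 does
        not saturate the branches (a saturated tip pattern carries little
        rate information for any estimator).
        """
        true_rate = 0.5
        tree = random_binary_tree([f"t{i}" for i in range(50)], py_rng,
                                  with_lengths=True)
        for node in tree.postorder():
            if node.length is not None:
                node.length = round(0.1 + (node.length - 0.1) / 1.9 * 0.9, 3)
        model = MkModel.equal_rates(["0", "1"], true_rate)
        ok, rel_err = 0, []
        n_rep = 50
        for rep in range(n_rep):
            tips, _ = simulate_trait(tree, model, seed=1000 + rep)
            if len(set(tips.values())) < 2:
                continue
            fitted, _ = fit_mk(tree, tips, "ER")
            q = fitted.Q[0, 1]
            ok += (true_rate / 2) <= q <= (true_rate * 2)
            rel_err.append(abs(q - true_rate) / true_rate)
        assert ok >= 0.8 * n_rep
        assert np.median(rel_err) < 0.5

    def test_ard_fit_runs_and_matches_er_shape(self, five_leaf_tree):
        data = {"A": "0", "B": "1", "C": "1", "D": "0", "E": "1"}
        model, logl = fit_mk(five_leaf_tree, data, "ARD")
        assert model.Q.shape == (2, 2)
        er_model, er_logl = fit_mk(five_leaf_tree, data, "ER")
        assert logl >= er_logl - 1e-4  # ARD nests ER


class TestStochasticMap:
    def test_zero_rates_give_constant_histories(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 0.0)
        data = {l: "0" for l in five_leaf_tree.leaf_labels()}
        for h in stochastic_map(five_leaf_tree, model, data, n_maps=5, seed=1):
            assert h.n_changes() == 0
            assert set(h.node_states.values()) == {0}

    def test_root_frequency_matches_pruning_marginal(self, five_leaf_tree):
        """Sampled root states converge to the exact marginal posterior."""
        model = MkModel.equal_rates(["0", "1"], 0.7)
        data = {"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"}
        histories = stochastic_map(five_leaf_tree, model, data, n_maps=2000, seed=7)
        marginal = marginal_ancestral_posteriors(five_leaf_tree, model, data)
        rid = five_leaf_tree.root.id
        empirical = np.mean([h.node_states[rid] == 0 for h in histories])
        assert empirical == pytest.approx(marginal[rid][0], abs=0.03)

    def test_dwell_times_sum_to_tree_length(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 1.2)
        data = {"A": "0", "B": "1", "C": "1", "D": "0", "E": "1"}
        total = five_leaf_tree.total_length()
        for h in stochastic_map(five_leaf_tree, model, data, n_maps=50, seed=3):
            assert h.dwell_times().sum() == pytest.approx(total, abs=1e-9)

    def test_seed_reproducibility(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 0.7)
        data = {"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"}
        h1 = stochastic_map(five_leaf_tree, model, data, n_maps=3, seed=11)
        h2 = stochastic_map(five_leaf_tree, model, data, n_maps=3, seed=11)
        h3 = stochastic_map(five_leaf_tree, model, data, n_maps=3, seed=12)
        assert [h.branch_segments for h in h1] == [h.branch_segments for h in h2]
        assert any(a.branch_segments != b.branch_segments for a, b in zip(h1, h3))

    def test_conflicting_tips_on_zero_length_tree_impossible(self):
        tree = pp.parse_newick("(A:0,B:0);")
        model = MkModel.equal_rates(["0", "1"], 0.0)
        with pytest.raises(TreeError, match="impossible"):
            stochastic_map(tree, model, {"A": "0", "B": "1"}, n_maps=1, seed=0)


class TestSummaries:
    def test_single_history_gives_indicator_frequencies(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 0.7)
        data = {"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"}
        hist = stochastic_map(five_leaf_tree, model, data, n_maps=1, seed=2)
        summary = summarize_maps(hist)
        for freq in summary.node_frequencies.values():
            assert sorted(freq) == [0.0, 1.0]

    def test_frequencies_sum_to_one(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 0.7)
        data = {"A": "0", "B": "0", "C": "1", "D": "1", "E": "0"}
        summary = summarize_maps(
            stochastic_map(five_leaf_tree, model, data, n_maps=40, seed=2)
        )
        for freq in summary.node_frequencies.values():
            assert freq.sum() == pytest.approx(1.0)

    def test_zero_rate_mass_on_single_state(self, five_leaf_tree):
        model = MkModel.equal_rates(["0", "1"], 0.0)
        data = {l: "1" for l in five_leaf_tree.leaf_labels()}
        summary = summarize_maps(
            stochastic_map(five_leaf_tree, model, data, n_maps=10, seed=2)
        )
        for freq in summary.node_frequencies.values():
            assert freq[1] == 1.0
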