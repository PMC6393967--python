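"""Marginal posterior reconstruction against brute-force enumeration."""

import numpy as np
import pytest
from scipy.linalg import expm

import stokeshift as ss
from stokeshift.io import AA_INDEX, AMINO_ACIDS


def brute_force_posteriors(aln, tree, matrix, rates):
    """Independent oracle: enumerate every assignment of states to inner
    nodes, with transition probabilities from scipy's expm applied to the
    generator directly."""
    inner = [i for i in range(tree.n_nodes) if not tree.is_leaf[i]]
    codes = {
        sid: [AA_INDEX.get(ch, 20) for ch in row]
        for sid, row in zip(aln.ids, aln.rows)
    }
    post = {i: np.zeros((aln.length, 20)) for i in inner}
    for c in range(rates.ncat):
        pm = {
            i: expm(matrix.q * tree.branch_lengths[i] * rates.rates[c])
            for i in range(tree.n_nodes)
        }
        for site in range(aln.length):
            leaf_state = {
                i: codes[tree.names[i]][site]
                for i in range(tree.n_nodes)
                if tree.is_leaf[i]
            }
            from itertools import product

            for assign in product(range(20), repeat=len(inner)):
                state = dict(zip(inner, assign))
                lik = matrix.frequencies[state[tree.root]]
                for i in range(tree.n_nodes):
                    if i == tree.root:
                        continue
                    parent_state = state[tree.parent[i]]
                    if tree.is_leaf[i]:
                        x = leaf_state[i]
                        if x == 20:
                            continue  # missing: sums to 1 over child states
                        lik *= pm[i][parent_state, x]
                    else:
                        lik *= pm[i][parent_state, state[i]]
                w = rates.weights[c] * lik
                for i in inner:
                    post[i][site, state[i]] += w
    return {
        tree.names[i]: post[i] / post[i].sum(axis=1, keepdims=True) for i in inner
    }


class TestMarginalPosteriors:
    def test_zero_length_star_forces_identity(self, jtt):
        tree = ss.PhyloTree.from_newick("(A:0.0,B:0.0,C:0.0);")
        aln = ss.MultipleAlignment(["A", "B", "C"], ["A", "A", "A"])
        prof = ss.marginal_posteriors(aln, tree, jtt, ss.GammaRates.constant())
        root = tree.names[tree.root]
        assert prof[root][0, AA_INDEX["A"]] == pytest.approx(1.0, abs=1e-12)

    def test_three_leaf_matches_enumeration(self, jtt):
        rates = ss.discrete_gamma(0.8, 3)
        tree = ss.PhyloTree.from_newick("(A:0.1,B:0.2,C:0.3);")
        aln = ss.MultipleAlignment(["A", "B", "C"], ["AR", "RR", "AW"])
        prof = ss.marginal_posteriors(aln, tree, jtt, rates)
        oracle = brute_force_posteriors(aln, tree, jtt, rates)
        for node, arr in oracle.items():
            assert np.abs(prof[node] - arr).max() < 1e-10

    def test_all_gap_site_returns_equilibrium(self, jtt, gamma6):
        tree = ss.PhyloTree.from_newick("((A:0.1,B:0.2):0.3,C:0.2);")
        aln = ss.MultipleAlignment(["A", "B", "C"], ["-A", "-A", "-A"])
        prof = ss.marginal_posteriors(aln, tree, jtt, gamma6)
        for node in prof.nodes:
            assert np.abs(prof[node][0] - jtt.frequencies).max() < 1e-10

    def test_posteriors_sum_to_one(self, jtt, gamma6):
        tree = ss.simulate_yule_tree(10, seed=9)
        aln, _ = ss.simulate_evolution(tree, jtt, gamma6, 80, seed=9)
        prof = ss.marginal_posteriors(aln, tree, jtt, gamma6)
        for node in prof.nodes:
            assert np.abs(prof[node].sum(axis=1) - 1).max() < 1e-9

    def test_leaf_order_invariance(self, jtt, gamma6):
        aln1 = ss.MultipleAlignment(["A", "B", "C"], ["AR", "RR", "AW"])
        aln2 = ss.MultipleAlignment(["C", "A", "B"], ["AW", "AR", "RR"])
        tree = ss.PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.25);")
        p1 = ss.marginal_posteriors(aln1, tree, jtt, gamma6)
        p2 = ss.marginal_posteriors(aln2, tree, jtt, gamma6)
        for node in p1.nodes:
            assert np.abs(p1[node] - p2[node]).max() < 1e-12

    def test_reroot_invariance_along_branch(self, jtt, gamma6):
        # same unrooted tree, root slid along the inner-node--C branch:
        # posteriors at the AB ancestor are unchanged under reversibility
        aln = ss.MultipleAlignment(["A", "B", "C"], ["ARNDC", "RRNDW", "AWNDC"])
        t1 = ss.PhyloTree.from_newick("((A:0.1,B:0.2):0.15,C:0.25);")
        t2 = ss.PhyloTree.from_newick("((A:0.1,B:0.2):0.05,C:0.35);")
        p1 = ss.marginal_posteriors(aln, t1, jtt, gamma6)
        p2 = ss.marginal_posteriors(aln, t2, jtt, gamma6)
        u1 = next(n for n in p1.nodes if n != t1.names[t1.root])
        u2 = next(n for n in p2.nodes if n != t2.names[t2.root])
        assert np.abs(p1[u1] - p2[u2]).max() < 1e-8

    def test_map_recovers_true_ancestors(self, jtt, gamma6):
        # moderate-height trees: MAP sequence >= 90% identical to truth
        for seed in (1, 2, 3):
            tree = ss.simulate_yule_tree(16, seed=seed, height=0.5)
            aln, truth = ss.simulate_evolution(tree, jtt, gamma6, 300, seed=seed)
            prof = ss.marginal_posteriors(aln, tree, jtt, gamma6)
            accs = [
                np.mean([a == b for a, b in zip(prof.map_sequence(n), s)])
                for n, s in truth.true_ancestors.items()
            ]
            assert np.mean(accs) >= 0.90


class TestSampleLibrary:
    def test_point_mass_gives_map_copies(self):
        arr = np.zeros((4, 20))
        arr[:, AA_INDEX["W"]] = 1.0
        prof = ss.AncestralProfile({"n": arr})
        lib = ss.sample_library(prof, "n", 5, seed=0)
        assert lib.sequences == ["WWWW"] * 5
        assert lib.provenance == "sampled"

    def test_sampling_frequency_concentrates(self):
        arr = np.zeros((1, 20))
        arr[0, AA_INDEX["A"]] = 0.7
        arr[0, AA_INDEX["S"]] = 0.3
        prof = ss.AncestralProfile({"n": arr})
        lib = ss.sample_library(prof, "n", 10_000, seed=42)
        freq_a = np.mean([s[0] == "A" for s in lib.sequences])
        assert abs(freq_a - 0.7) < 0.02

    def test_single_sample(self):
        arr = np.full((3, 20), 0.05)
        prof = ss.AncestralProfile({"n": arr})
        lib = ss.sample_library(prof, "n", 1, seed=1)
        assert len(lib) == 1 and len(lib.sequences[0]) == 3

    def test_seeded_reproducibility(self):
        arr = np.full((10, 20), 0.05)
        prof = ss.AncestralProfile({"n": arr})
        a = ss.sample_library(prof, "n", 20, seed=7)
        b = ss.sample_library(prof, "n", 20, seed=7)
        assert a.sequences == b.sequences

    def test_unknown_node_rejected(self):
        prof = ss.AncestralProfile({"n": np.full((2, 20), 0.05)})
        with pytest.raises(KeyError):
            ss.sample_library(prof, "zzz", 1, seed=0)
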