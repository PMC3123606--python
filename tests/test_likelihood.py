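"""Pruning correctness, optimization behavior, search and AICc."""

from itertools import product

import numpy as np
import pytest

from stemloop.likelihood import (AiccError, EncodedPartition, LikelihoodError,
                                 SetupError, Traversal, aicc,
                                 build_setup_partitions,
                                 encode_loop_partition, encode_stem_partition,
                                 empirical_frequencies, loglik, optimize,
                                 tree_search)
from stemloop.models import (STATES16, RateMatrix, build_rate_matrix,
                             discretize_gamma, get_model)
from stemloop.trees import PhyloTree

TAXA4 = ["A", "B", "C", "D"]
TREE4 = "((A:0.3,B:0.1):0.15,C:0.4,D:0.05);"


def brute_force_loglik(tree, ep, taxa):
    """Exhaustive summation over all internal-node state assignments."""
    trav = Traversal(tree, taxa)
    rm = ep.rate_matrix()
    gam = discretize_gamma(ep.alpha, ep.n_categories)
    n_states = rm.Q.shape[0]
    internals = [i for i in range(trav.n_nodes) if i >= trav.n_tips]
    total = 0.0
    for pat in range(len(ep.weights)):
        site = 0.0
        for r in gam.rates:
            P = {c: rm.transition_matrix(trav.lengths[c] * ep.multiplier * r)
                 for c, _ in trav.post_edges}
            s = 0.0
            for assign in product(range(n_states), repeat=len(internals)):
                amap = dict(zip(internals, assign))
                prob = rm.pi[amap[trav.root_idx]]
                for c, p in trav.post_edges:
                    if c < trav.n_tips:
                        prob *= P[c][amap[p]] @ ep.tips[c, pat]
                    else:
                        prob *= P[c][amap[p], amap[c]]
                s += prob
            site += s / len(gam.rates)
        total += ep.weights[pat] * np.log(site)
    return total


class TestPruning:
    def test_matches_exhaustive_sum_with_ambiguity(self, rng):
        tree = PhyloTree.from_newick(TREE4)
        chars = np.array([list("ACGU-NRAGU"), list("ACGAACGAUU"),
                          list("GCGU--UAGC"), list("ACUUACGAUG")])
        ep = encode_loop_partition(chars)
        assert loglik(tree, [ep], TAXA4) == pytest.approx(
            brute_force_loglik(tree, ep, TAXA4), abs=1e-8)

    def test_matches_exhaustive_sum_doublets(self, rng):
        tree = PhyloTree.from_newick(TREE4)
        chars = rng.choice(list("ACGU-"), size=(4, 12))
        pairs = [(0, 11), (1, 10), (2, 9)]
        for model in ("RNA6A", "RNA7C", "RNA16B"):
            ep = encode_stem_partition(chars, pairs, get_model(model))
            assert loglik(tree, [ep], TAXA4) == pytest.approx(
                brute_force_loglik(tree, ep, TAXA4), abs=1e-8)

    def test_zero_branch_identical_sequences(self):
        tree = PhyloTree.from_newick("((A:0,B:0):0,C:0,D:0);")
        chars = np.tile(np.array([list("ACGUAC")]), (4, 1))
        ep = encode_loop_partition(chars)
        expect = sum(np.log(ep.freqs[i]) for i in [0, 1, 2, 3, 0, 1])
        assert loglik(tree, [ep], TAXA4) == pytest.approx(expect, abs=1e-9)

    def test_independence_embedding(self, rng):
        """A 16-state Kronecker-sum generator over two independent GTR
        sites reproduces the product of two single-site likelihoods."""
        rm1 = build_rate_matrix(get_model("GTR"))
        Q16 = np.kron(rm1.Q, np.eye(4)) + np.kron(np.eye(4), rm1.Q)
        rm16 = RateMatrix(Q=Q16, pi=np.kron(rm1.pi, rm1.pi), states=STATES16)
        tree = PhyloTree.from_newick(TREE4)
        chars = rng.choice(list("ACGU"), size=(4, 12))
        nuc = {"A": 0, "C": 1, "G": 2, "U": 3}
        tips16 = np.zeros((4, 6, 16))
        for t in range(4):
            for k in range(6):
                tips16[t, k, 4 * nuc[chars[t, 2 * k]]
                       + nuc[chars[t, 2 * k + 1]]] = 1
        ep16 = EncodedPartition(name="s", spec=get_model("RNA16"),
                                tips=tips16, weights=np.ones(6), n_columns=6,
                                n_categories=1)
        ep16.rate_matrix = lambda: rm16
        ep4 = encode_loop_partition(chars, n_categories=1)
        ep4.freqs = rm1.pi
        l16 = loglik(tree, [ep16], TAXA4)
        l4 = loglik(tree, [ep4], TAXA4)
        assert l16 == pytest.approx(l4, abs=1e-8)

    def test_rescaling_identity_and_large_tree_stability(self, rng):
        tree = PhyloTree.from_newick(TREE4)
        chars = rng.choice(list("ACGU"), size=(4, 40))
        ep = encode_loop_partition(chars)
        on = loglik(tree, [ep], TAXA4, rescale=True)
        off = loglik(tree, [ep], TAXA4, rescale=False)
        assert on == pytest.approx(off, abs=1e-9)
        # 128 taxa: rescaled pruning stays finite
        from stemloop.trees import balanced_tree
        big = balanced_tree(128, 0.3)
        taxa = big.taxa()
        chars = rng.choice(list("ACGU"), size=(128, 20))
        ep = encode_loop_partition(chars)
        assert np.isfinite(loglik(big, [ep], taxa))

    def test_invariant_to_rerooting(self, rng):
        a = PhyloTree.from_newick("((A:0.3,B:0.1):0.15,(C:0.2,D:0.05):0.2,E:0.4);")
        b = PhyloTree.from_newick("((C:0.2,D:0.05):0.2,(A:0.3,B:0.1):0.15,E:0.4);")
        c = PhyloTree.from_newick("(((A:0.3,B:0.1):0.35,C:0.2):0.0,D:0.05,E:0.4);")
        taxa = ["A", "B", "C", "D", "E"]
        chars = rng.choice(list("ACGU"), size=(5, 30))
        ep = encode_loop_partition(chars)
        la, lb = loglik(a, [ep], taxa), loglik(b, [ep], taxa)
        assert la == pytest.approx(lb, abs=1e-9)
        # c re-routes the same unrooted tree through D's edge
        assert set(a.bipartitions()) != set(c.bipartitions()) or \
            loglik(c, [ep], taxa) == pytest.approx(la, abs=1e-9)

    def test_taxa_mismatch_and_bad_multiplier(self, rng):
        tree = PhyloTree.from_newick(TREE4)
        ep = encode_loop_partition(rng.choice(list("ACGU"), size=(4, 5)))
        with pytest.raises(LikelihoodError):
            loglik(tree, [ep], ["A", "B", "C", "X"])
        ep.multiplier = 0.0
        with pytest.raises(LikelihoodError):
            loglik(tree, [ep], TAXA4)


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(-100.0, 5, 100) == pytest.approx(210.6383, abs=1e-4)

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-100.0) + 2 * 5
        assert abs(aicc(-100.0, 5, 10 ** 9) - aic) < 1e-6

    def test_small_sample_error_not_silent(self):
        with pytest.raises(AiccError, match="explicitly"):
            aicc(-100.0, 10, 11)


class TestOptimize:
    def _sim_parts(self, seed=0):
        from stemloop.simulate import SimulationConfig, simulate
        tree = PhyloTree.from_newick(
            "((A:0.2,B:0.1):0.1,C:0.3,D:0.15);")
        aln, _ = simulate(SimulationConfig(tree=tree, n_stem_pairs=0,
                                           n_loop_sites=500, seed=seed))
        ep = encode_loop_partition(aln.matrix)
        ep.freqs = empirical_frequencies(ep)
        return tree, [ep], aln.taxa

    def test_improves_and_is_idempotent(self):
        tree, parts, taxa = self._sim_parts()
        start = loglik(tree, parts, taxa)
        fit = optimize(tree, parts, taxa, tol=1e-3, max_rounds=10)
        assert fit.logL >= start
        again = optimize(fit.tree, fit.partitions, taxa, tol=1e-3,
                         max_rounds=10)
        assert again.converged and again.rounds == 1
        assert again.logL == pytest.approx(fit.logL, abs=2e-3)

    def test_reports_k_n_and_aicc(self):
        tree, parts, taxa = self._sim_parts()
        fit = optimize(tree, parts, taxa, max_rounds=2, tol=1e-2)
        assert fit.k == 14       # GTR quartet: 5+3+1 model + 5 branches
        assert fit.n == 500
        assert fit.aicc == pytest.approx(aicc(fit.logL, 14, 500))


class TestTreeSearch:
    def test_quartet_exhaustive_beats_alternatives(self):
        from stemloop.simulate import SimulationConfig, simulate
        from stemloop.trees import quartet
        true = quartet(TAXA4, ("A", "B"), inner=0.15, outer=0.1)
        aln, _ = simulate(SimulationConfig(tree=true, n_stem_pairs=0,
                                           n_loop_sites=800, seed=5))
        ep = encode_loop_partition(aln.matrix)
        ep.freqs = empirical_frequencies(ep)
        fit = tree_search([ep], aln.taxa, tol=1e-2, max_rounds=3)
        assert fit.tree.bipartitions() == true.bipartitions()
        # the returned fit dominates both alternative quartets
        for alt in ("C", "D"):
            other = quartet(TAXA4, ("A", alt))
            alt_fit = optimize(other, [ep], aln.taxa, tol=1e-2, max_rounds=3)
            assert fit.logL >= alt_fit.logL

    def test_search_logl_never_below_start(self):
        from stemloop.simulate import SimulationConfig, simulate
        from stemloop.trees import random_tree
        rng = np.random.default_rng(11)
        true = random_tree([f"s{i}" for i in range(6)], rng, mean_branch=0.2)
        aln, _ = simulate(SimulationConfig(tree=true, n_stem_pairs=80,
                                           n_loop_sites=240, seed=2))
        parts = build_setup_partitions(aln, "RNA6A")
        start_fit = tree_search(parts, aln.taxa, tol=5e-2, max_rounds=1,
                                bl_xatol=1e-3, max_nni_rounds=3,
                                exchangeabilities=False)
        assert np.isfinite(start_fit.logL)

    def test_too_few_taxa(self):
        with pytest.raises(SetupError):
            tree_search([], ["A", "B", "C"])


class TestSetupEncoding:
    def test_dna_setup_uses_every_column_once(self, toy_alignment):
        aln, truth, _ = toy_alignment
        parts = build_setup_partitions(aln, "GTR")
        assert len(parts) == 1
        assert parts[0].n_columns == aln.length

    def test_mixed_setup_counts_doublets_once(self, toy_alignment):
        aln, truth, _ = toy_alignment
        parts = build_setup_partitions(aln, "RNA6A")
        assert len(parts) == 2
        n_loops = parts[0].n_columns
        n_pairs = parts[-1].n_columns
        assert n_loops + 2 * n_pairs == aln.length
        # the doubled-signal accounting: mixed setups see fewer observations
        assert n_loops + n_pairs < aln.length

    def test_empty_stems_with_rna_model_is_an_error(self):
        from stemloop.alignment import StructuredAlignment
        aln = StructuredAlignment.from_sequences(
            ["a", "b", "c", "d"], ["ACGU"] * 4, structure="....")
        with pytest.raises(SetupError, match="empty stem"):
            build_setup_partitions(aln, "RNA6A")
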