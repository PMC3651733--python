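import math
from itertools import product

import numpy as np
import pytest
from scipy.special import logsumexp

import modelswitch.likelihood as lk
from modelswitch.likelihood import (
    Alignment,
    AugmentedState,
    PhyloTree,
    PowerPosteriorKernel,
    ancestral_gap_mask,
    compute_U,
    context_branch_log_table,
    context_loglik,
    gtr_complete_loglik,
    gtr_tree_loglik,
    power_log_kernel,
)
from modelswitch.models import (
    GAP,
    ContextModelParams,
    GTRParams,
    RootMarkovChain,
    gtr_transition_probs,
    psi_lookup,
    root_log_prob,
)


def brute_force_gtr_loglik(alignment, tree, params):
    """Exhaustive enumeration over all internal-node state assignments,
    built directly from transition matrices and the gap-as-missing rule."""
    perm = tree.tip_permutation(alignment.labels)
    data = alignment.matrix[perm]
    internals = list(tree.internal_nodes)
    mats = {
        int(v): gtr_transition_probs(params, float(tree.branch_lengths[v]))
        for v in tree.branch_nodes
    }
    pi = params.base_frequencies
    total = 0.0
    for site in range(alignment.length):
        site_lik = 0.0
        for assign in product(range(4), repeat=len(internals)):
            states = {int(v): s for v, s in zip(internals, assign)}
            for t in range(tree.n_tips):
                states[t] = int(data[t, site])
            lik = pi[states[tree.root]]
            for v in tree.branch_nodes:
                child = states[int(v)]
                if child == GAP:
                    continue
                lik *= mats[int(v)][states[int(tree.parent[v])], child]
            site_lik += lik
        total += math.log(site_lik)
    return total


class TestGTRTreeLoglik:
    def test_matches_enumeration_three_taxa(self, tiny_alignment, three_taxon_tree,
                                            gtr_params):
        assert gtr_tree_loglik(tiny_alignment, three_taxon_tree, gtr_params) == (
            pytest.approx(
                brute_force_gtr_loglik(tiny_alignment, three_taxon_tree, gtr_params)
            )
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_four_taxa_random(self, seed):
        rng = np.random.default_rng(seed)
        tree = PhyloTree.from_newick("((A:0.2,B:0.7):0.3,(C:0.1,D:0.4):0.2);")
        params = GTRParams(rng.exponential(1, 5), rng.dirichlet(np.ones(4)))
        mat = rng.integers(0, 5, size=(4, 3)).astype(np.int8)
        aln = Alignment(["A", "B", "C", "D"], mat)
        assert gtr_tree_loglik(aln, tree, params) == pytest.approx(
            brute_force_gtr_loglik(aln, tree, params)
        )

    def test_zero_branch_lengths_identical_tips(self, gtr_params):
        tree = PhyloTree.from_newick("((A:0.0,B:0.0):0.0,C:0.0);")
        aln = Alignment.from_sequences({"A": "ACG", "B": "ACG", "C": "ACG"})
        expected = sum(
            math.log(gtr_params.base_frequencies[b]) for b in [0, 1, 2]
        )
        assert gtr_tree_loglik(aln, tree, gtr_params) == pytest.approx(expected)

    def test_all_gap_alignment(self, three_taxon_tree, gtr_params):
        aln = Alignment.from_sequences({"A": "--", "B": "--", "C": "--"})
        assert gtr_tree_loglik(aln, three_taxon_tree, gtr_params) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_label_mismatch_rejected(self, gtr_params, three_taxon_tree):
        aln = Alignment.from_sequences({"A": "AC", "B": "AG", "X": "GT"})
        with pytest.raises(ValueError, match="mismatch"):
            gtr_tree_loglik(aln, three_taxon_tree, gtr_params)


class TestGTRCompleteData:
    def test_marginalization_recovers_pruning(self, tiny_alignment,
                                              three_taxon_tree, gtr_params):
        vals = []
        for a1 in product(range(4), repeat=2):
            for a2 in product(range(4), repeat=2):
                aug = AugmentedState(np.array([a1, a2], dtype=np.int8))
                vals.append(
                    gtr_complete_loglik(tiny_alignment, three_taxon_tree,
                                        gtr_params, aug)
                )
        assert logsumexp(vals) == pytest.approx(
            gtr_tree_loglik(tiny_alignment, three_taxon_tree, gtr_params)
        )


class TestContextLoglik:
    def _unnormalized_params(self, rng, scale=0.3):
        # small psi keeps every per-branch row strictly substochastic at t=1,
        # so branch factors at t=1 coincide with psi_lookup semantics
        psi = np.zeros((4, 4, 4, 4))
        for w, y, x in product(range(4), repeat=3):
            block = scale * rng.dirichlet(np.ones(3))
            psi[w, y, x, [z for z in range(4) if z != x]] = block
        return ContextModelParams(psi, np.full((4, 4, 4), 0.25))

    def test_all_gap_data(self, uniform_chain):
        tree = PhyloTree.from_newick("(A:1.0);")
        aln = Alignment.from_sequences({"A": "---"})
        params = ContextModelParams.uniform()
        aug = AugmentedState(np.full((1, 3), GAP, dtype=np.int8))
        assert context_loglik(aln, tree, params, uniform_chain, aug) == 0.0

    def test_single_branch_hand_product(self, rng, uniform_chain):
        tree = PhyloTree.from_newick("(A:1.0);")
        params = self._unnormalized_params(rng)
        aln = Alignment.from_sequences({"A": "ACG"})
        root_seq = np.array([2, 1, 3], dtype=np.int8)  # GCT
        aug = AugmentedState(root_seq[None, :])
        # root chain term + the middle site's factor (edge sites have a
        # missing neighbor and contribute factor 1)
        expected = root_log_prob(uniform_chain, "GCT") + math.log(
            psi_lookup(params, 1, 1, 2, 3)  # x=C -> z=C | w=G, y=T
        )
        got = context_loglik(aln, tree, params, uniform_chain, aug)
        assert got == pytest.approx(expected)

    def test_psi_lookup_site_loop_oracle(self, rng):
        # independent accumulation: explicit per-site psi_lookup products
        tree = PhyloTree.from_newick("((A:1.0,B:1.0):1.0,C:1.0);")
        params = self._unnormalized_params(rng)
        chain = RootMarkovChain.random_from_prior(rng, 1)
        aln = Alignment.from_sequences({"A": "ACGT-", "B": "A-GTC", "C": "TCG-A"})
        gaps = ancestral_gap_mask(tree, aln)
        anc = rng.integers(0, 4, size=gaps.shape).astype(np.int8)
        anc[gaps] = GAP
        aug = AugmentedState(anc)
        perm = tree.tip_permutation(aln.labels)
        seqs = {v: aln.matrix[perm][v] for v in range(tree.n_tips)}
        for v in tree.internal_nodes:
            seqs[int(v)] = anc[v - tree.n_tips]
        expected = root_log_prob(chain, seqs[tree.root])
        for v in tree.branch_nodes:
            p, c = seqs[int(tree.parent[v])], seqs[int(v)]
            for i in range(aln.length):
                w = p[i - 1] if i > 0 else GAP
                y = p[i + 1] if i < aln.length - 1 else GAP
                expected += math.log(psi_lookup(params, p[i], c[i], w, y))
        got = context_loglik(aln, tree, params, chain, aug)
        assert got == pytest.approx(expected)

    def test_reverse_complement_invariance_under_strand_symmetry(self, rng):
        from modelswitch.models import normalize_context_model

        tree = PhyloTree.from_newick("((A:0.6,B:0.4):0.5,C:0.7);")
        params = ContextModelParams.random_from_prior(rng, strand_symmetric=True)
        chain = RootMarkovChain.uniform(0)
        mat = rng.integers(0, 4, size=(3, 8)).astype(np.int8)
        aln = Alignment(["A", "B", "C"], mat)
        anc = rng.integers(0, 4, size=(2, 8)).astype(np.int8)
        ll = context_loglik(aln, tree, params, chain, AugmentedState(anc))
        # reverse-complement every sequence: complements swap and the
        # neighbor roles reverse, exactly the strand-symmetry map
        rc = lambda m: (3 - m)[:, ::-1].astype(np.int8)
        ll_rc = context_loglik(
            Alignment(["A", "B", "C"], rc(mat)), tree, params, chain,
            AugmentedState(rc(anc)),
        )
        assert ll == pytest.approx(ll_rc)

    def test_missing_augmented_node_rejected(self, uniform_chain):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:1);")
        aln = Alignment.from_sequences({"A": "AC", "B": "AG", "C": "GT"})
        with pytest.raises(ValueError, match="internal nodes"):
            context_loglik(aln, tree, ContextModelParams.uniform(), uniform_chain,
                           AugmentedState(np.zeros((1, 2), dtype=np.int8)))


class TestBranchTable:
    def test_zero_time_is_identity(self, context_params):
        table = np.exp(context_branch_log_table(context_params, 0.0))
        for w, y in product(range(4), repeat=2):
            assert np.allclose(table[w, y], np.eye(4))

    def test_rows_are_distributions(self, context_params):
        for t in (0.05, 0.5, 5.0, 500.0):
            table = np.exp(context_branch_log_table(context_params, t))
            assert np.allclose(table.sum(axis=-1), 1.0)
            assert table.min() >= 0.0


class _StubModel:
    def __init__(self, ll, lp):
        self._ll, self._lp = ll, lp

    def log_likelihood(self, state):
        return self._ll(state)

    def log_prior(self, state):
        return self._lp(state)


class TestPowerKernel:
    def test_identical_models_give_zero_U(self):
        m = _StubModel(lambda s: -3.0 * s, lambda s: -0.5 * s * s)
        for s in (0.0, 1.3, -2.0):
            assert compute_U(s, m, m) == 0.0

    def test_prior_cancellation(self):
        prior = lambda s: -0.5 * s * s
        m0 = _StubModel(lambda s: -1.0, prior)
        m1 = _StubModel(lambda s: -1.0 + 4.2, prior)
        assert compute_U(0.7, m0, m1) == pytest.approx(4.2)

    def test_beta_binomial_closed_form(self):
        from modelswitch.toybench import default_beta_binomial_pair

        s0, s1 = default_beta_binomial_pair()
        theta = 0.62
        expected = (
            s1.log_likelihood(theta) + s1.log_prior(theta)
            - s0.log_likelihood(theta) - s0.log_prior(theta)
        )
        assert compute_U(theta, s0, s1) == pytest.approx(expected)

    def test_kernel_endpoints(self):
        m0 = _StubModel(lambda s: -1.0, lambda s: -0.1)
        m1 = _StubModel(lambda s: -5.0, lambda s: -0.2)
        k0 = PowerPosteriorKernel(m0, m1, 0.0)
        k1 = PowerPosteriorKernel(m0, m1, 1.0)
        assert power_log_kernel(k0, None) == pytest.approx(-1.1)
        assert power_log_kernel(k1, None) == pytest.approx(-5.2)

    def test_midpoint_is_mean_of_kernels(self):
        m0 = _StubModel(lambda s: -1.0, lambda s: -0.1)
        m1 = _StubModel(lambda s: -5.0, lambda s: -0.2)
        k = PowerPosteriorKernel(m0, m1, 0.5)
        assert power_log_kernel(k, None) == pytest.approx(0.5 * (-1.1 - 5.2))

    @pytest.mark.parametrize("beta", [0.0, 0.123, 0.5, 0.87, 1.0])
    def test_power_identity_in_beta(self, beta):
        m0 = _StubModel(lambda s: -2.0 * s, lambda s: -0.3)
        m1 = _StubModel(lambda s: 1.5 * s, lambda s: -0.9)
        s = 0.77
        k = PowerPosteriorKernel(m0, m1, beta)
        k0 = PowerPosteriorKernel(m0, m1, 0.0)
        lhs = power_log_kernel(k, s) - power_log_kernel(k0, s)
        assert lhs == pytest.approx(beta * compute_U(s, m0, m1), abs=1e-10)

    def test_beta_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            PowerPosteriorKernel(None, None, 1.5)


class TestTreeContainer:
    def test_gap_mask_column_convention(self, three_taxon_tree):
        aln = Alignment.from_sequences({"A": "A--", "B": "A--", "C": "A-C"})
        gaps = ancestral_gap_mask(three_taxon_tree, aln)
        # site 1 gapped everywhere; site 2 gapped in the AB clade only
        assert gaps.tolist() == [[False, True, True], [False, True, False]]

    def test_newick_roundtrip(self, laurasiatheria_tree):
        t2 = PhyloTree.from_newick(laurasiatheria_tree.to_newick())
        assert t2.topology_id() == laurasiatheria_tree.topology_id()
        assert np.allclose(
            np.sort(t2.branch_lengths[t2.branch_nodes]),
            np.sort(laurasiatheria_tree.branch_lengths[laurasiatheria_tree.branch_nodes]),
        )
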