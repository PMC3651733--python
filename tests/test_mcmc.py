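import math

import numpy as np
import pytest
from scipy.stats import beta as beta_dist
from scipy.stats import chi2

from modelswitch import estimators as est
from modelswitch.likelihood import PhyloTree, context_loglik, gtr_complete_loglik
from modelswitch.mcmc import (
    PhyloSwitchProblem,
    effective_samples,
    run_path,
    update_cycle,
)
from modelswitch.models import GTRParams
from modelswitch.schedules import constant_schedule
from modelswitch.toybench import (
    SimulationSpec,
    ToySwitchProblem,
    default_beta_binomial_pair,
    simulate_alignment,
)


class TestEffectiveSamples:
    def test_iid_series_has_tau_near_one(self, rng):
        _, tau = effective_samples(rng.normal(size=5000))
        assert tau < 1.3

    def test_duplicated_series_halves_effective_size(self, rng):
        x = rng.normal(size=400)
        doubled = np.repeat(x, 2)  # consecutive duplicates: strong lag-1 corr
        k_eff, tau = effective_samples(doubled)
        assert k_eff <= doubled.size / 2 + 1
        assert tau >= 1.9

    def test_constant_series_warns_tau_one(self):
        with pytest.warns(UserWarning, match="constant"):
            k_eff, tau = effective_samples(np.full(10, 3.0))
        assert tau == 1.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            effective_samples([1.0] * 9)

    def test_agrees_with_arviz_on_ar1(self, rng):
        arviz = pytest.importorskip("arviz")
        x = np.empty(4000)
        x[0] = 0.0
        for i in range(1, x.size):
            x[i] = 0.7 * x[i - 1] + rng.normal()
        k_eff, _ = effective_samples(x)
        k_az = float(arviz.ess(x[None, :]))
        assert 0.5 < k_eff / k_az < 2.0


class TestRunPath:
    def test_minimal_schedule_has_two_betas(self, rng):
        s0, s1 = default_beta_binomial_pair()
        tr = run_path(ToySwitchProblem(s0, s1), constant_schedule(1, 5), rng=rng)
        assert tr.betas.size == 2

    def test_identical_models_give_zero_potential(self, rng):
        s0, _ = default_beta_binomial_pair()
        tr = run_path(ToySwitchProblem(s0, s0), constant_schedule(3, 5), rng=rng)
        assert all(np.all(s == 0.0) for s in tr.U_samples)

    def test_fixed_seed_reproducibility(self):
        s0, s1 = default_beta_binomial_pair()
        prob = ToySwitchProblem(s0, s1)
        sched = constant_schedule(5, 10)
        tr1 = run_path(prob, sched, rng=np.random.default_rng(42), save_interval=2)
        tr2 = run_path(prob, sched, rng=np.random.default_rng(42), save_interval=2)
        for a, b in zip(tr1.U_samples, tr2.U_samples):
            assert np.array_equal(a, b)

    def test_melting_traverses_reversed_grid(self, rng):
        s0, s1 = default_beta_binomial_pair()
        sched = constant_schedule(4, 2).reversed()
        tr = run_path(ToySwitchProblem(s0, s1), sched, rng=rng)
        assert np.all(np.diff(tr.betas) < 0)

    def test_classic_mode_saves_one_per_beta(self, rng):
        s0, s1 = default_beta_binomial_pair()
        tr = run_path(ToySwitchProblem(s0, s1), constant_schedule(3, 7),
                      mode="classic", rng=rng)
        assert all(s.size == 1 for s in tr.U_samples)

    def test_mean_mode_discards_early_cycles_when_affordable(self, rng):
        s0, s1 = default_beta_binomial_pair()
        # Q=50 > 2*10: first 10 cycles dropped -> saves at 20,30,40,50
        tr = run_path(ToySwitchProblem(s0, s1), constant_schedule(2, 50),
                      mode="mean", rng=rng, save_interval=10)
        assert all(s.size == 4 for s in tr.U_samples)


class TestChainCorrectness:
    def test_posterior_mean_at_beta_zero(self, rng):
        s0, s1 = default_beta_binomial_pair()
        prob = ToySwitchProblem(s0, s1)
        theta = prob.initial_state(rng, 0.0)
        samples = []
        for _ in range(10_000):
            theta = update_cycle(prob, theta, 0.0, rng)
            samples.append(theta)
        samples = np.array(samples)
        a_post, b_post = s0.posterior_params()
        analytic_mean = a_post / (a_post + b_post)
        k_eff, _ = effective_samples(samples)
        mcse = samples.std(ddof=1) / math.sqrt(k_eff)
        assert abs(samples.mean() - analytic_mean) < 3 * mcse

    def test_power_posterior_chi2_gof(self, rng):
        # at beta the power posterior of the Beta(1,1)/Beta(2,2) pair is
        # Beta(k + 1 + beta, n - k + 1 + beta) exactly
        s0, s1 = default_beta_binomial_pair()
        n, k = s0.data
        b = 0.5
        prob = ToySwitchProblem(s0, s1)
        theta = prob.initial_state(rng, 0.0)
        for _ in range(500):
            theta = update_cycle(prob, theta, b, rng)
        samples = []
        for i in range(200_000):
            theta = update_cycle(prob, theta, b, rng)
            if i % 10 == 0:
                samples.append(theta)
        samples = np.array(samples)
        dist = beta_dist(k + 1 + b, n - k + 1 + b)
        edges = dist.ppf(np.linspace(0, 1, 21))
        counts, _ = np.histogram(samples, bins=edges)
        expected = samples.size / 20.0
        stat = float(np.sum((counts - expected) ** 2 / expected))
        assert stat < chi2(19).ppf(0.99)


@pytest.fixture(scope="module")
def phylo_setup():
    tree = PhyloTree.from_newick(
        "((((cow:0.1,sheep:0.1):0.1,muntjak:0.1):0.1,pig:0.1):0.1,horse:0.1);"
    )
    gtr = GTRParams(np.array([1.0, 4.0, 1.0, 1.0, 4.0]),
                    np.array([0.3, 0.2, 0.2, 0.3]))
    aln = simulate_alignment(SimulationSpec(tree, 120, gtr, seed=5))
    return tree, aln


class TestPhyloSampler:
    @pytest.mark.parametrize("root_order", [0, 1, 2])
    @pytest.mark.parametrize("strand_symmetric", [True, False])
    def test_cached_potential_matches_fresh_evaluation(self, phylo_setup,
                                                       root_order, strand_symmetric):
        tree, aln = phylo_setup
        prob = PhyloSwitchProblem(aln, tree, root_order=root_order,
                                  strand_symmetric=strand_symmetric)
        rng = np.random.default_rng(8)
        st = prob.initial_state(rng, 0.3)
        for _ in range(3):
            st = prob.update_cycle(st, 0.3, rng)
        ms = prob.to_model_state(st)
        from modelswitch.likelihood import _with_lengths

        t = _with_lengths(tree, ms.branch_lengths)
        ll1 = context_loglik(aln, t, ms.context, ms.root_chain, ms.aug)
        ll0 = gtr_complete_loglik(aln, t, ms.gtr, ms.aug)
        assert prob.potential(st) == pytest.approx(ll1 - ll0, abs=1e-6)

    def test_state_invariants_preserved(self, phylo_setup):
        tree, aln = phylo_setup
        prob = PhyloSwitchProblem(aln, tree)
        rng = np.random.default_rng(9)
        st = prob.initial_state(rng, 0.7)
        for _ in range(5):
            st = prob.update_cycle(st, 0.7, rng)
        assert np.all(st.branch_lengths > 0)
        assert st.mu > 0
        assert np.allclose(st.gtr.base_frequencies.sum(), 1.0)
        # every raw psi context block remains a simplex over its 12 entries
        assert np.allclose(st.raw_psi.sum(axis=(2, 3)), 1.0)
        assert np.allclose(st.f.sum(axis=-1), 1.0)
        # gap pattern untouched
        assert np.array_equal(st.anc == 4, prob.anc_gaps)

    def test_strand_symmetry_maintained_by_updates(self, phylo_setup):
        tree, aln = phylo_setup
        prob = PhyloSwitchProblem(aln, tree, strand_symmetric=True)
        rng = np.random.default_rng(10)
        st = prob.initial_state(rng, 0.5)
        for _ in range(3):
            st = prob.update_cycle(st, 0.5, rng)
        mirrored = st.raw_psi[::-1, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3)
        assert np.allclose(st.raw_psi, mirrored, atol=1e-12)

    def test_seed_determinism(self, phylo_setup):
        tree, aln = phylo_setup
        prob = PhyloSwitchProblem(aln, tree)
        sched = constant_schedule(2, 3)
        tr1 = run_path(prob, sched, rng=np.random.default_rng(3), equilibration=2)
        tr2 = run_path(prob, sched, rng=np.random.default_rng(3), equilibration=2)
        for a, b in zip(tr1.U_samples, tr2.U_samples):
            assert np.array_equal(a, b)
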