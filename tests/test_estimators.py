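import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from modelswitch import estimators as est
from modelswitch.mcmc import PathTrace
from modelswitch.schedules import constant_schedule


def make_trace(betas, samples, direction="annealing", mode="mean", comps=None):
    return PathTrace(
        betas=np.asarray(betas, dtype=float),
        U_samples=[np.atleast_1d(np.asarray(s, dtype=float)) for s in samples],
        direction=direction,
        mode=mode,
        component_samples=comps,
    )


class TestHME:
    def test_constant_input(self):
        assert est.hme([3.7] * 10) == pytest.approx(3.7)

    def test_two_point_harmonic_mean(self):
        # harmonic mean of likelihoods {1, 3} is 1.5
        assert est.hme([math.log(1.0), math.log(3.0)]) == pytest.approx(math.log(1.5))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            est.hme([])


class TestSHME:
    def test_constant_fixed_point(self):
        assert est.shme([2.5] * 20, delta=0.3) == pytest.approx(2.5)

    def test_delta_to_zero_limit_is_hme(self):
        ll = np.log([1.0, 3.0, 0.5, 2.0])
        assert est.shme(ll, delta=1e-8) == pytest.approx(est.hme(ll), abs=1e-6)

    def test_matches_natural_scale_fixed_point_oracle(self):
        ll = np.array([math.log(1.0), math.log(3.0)])
        delta = 0.01
        # independent fixed-point iteration on the natural scale
        L = np.exp(ll)
        m = L.size
        A = delta * m / (1 - delta)
        z = 1.0
        for _ in range(10_000):
            denom = delta * z + (1 - delta) * L
            z_new = (A + np.sum(L / denom)) / (A / z + np.sum(1.0 / denom))
            if abs(z_new - z) < 1e-14:
                break
            z = z_new
        assert est.shme(ll, delta=delta) == pytest.approx(math.log(z), abs=1e-9)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            est.shme([1.0, 2.0], delta=1.5)


class TestPathSampling:
    def test_constant_U(self):
        tr = make_trace([0, 0.5, 1], [[2.0], [2.0], [2.0]], mode="classic")
        assert est.ps_estimate(tr).log_bf == pytest.approx(2.0)

    def test_single_step_is_endpoint_average(self):
        tr = make_trace([0, 1], [[1.0], [3.0]], mode="classic")
        assert est.ps_estimate(tr).log_bf == pytest.approx(2.0)

    def test_linear_U_exact_on_constant_grid(self):
        # U(beta) = beta on K=2: trapezoid equals the exact integral 0.5
        tr = make_trace([0, 0.5, 1], [[0.0], [0.5], [1.0]], mode="classic")
        assert est.ps_estimate(tr).log_bf == pytest.approx(0.5)

    @given(
        st.lists(st.floats(0.01, 1.0), min_size=2, max_size=20),
        st.floats(-5, 5),
        st.floats(-5, 5),
    )
    @settings(derandomize=True, max_examples=50)
    def test_trapezoid_exact_for_linear_potential(self, incs, a, b):
        betas = np.concatenate([[0.0], np.cumsum(incs)])
        betas /= betas[-1]
        betas[-1] = 1.0
        tr = make_trace(betas, [[a + b * x] for x in betas], mode="classic")
        exact = a + b / 2.0
        assert est.ps_estimate(tr).log_bf == pytest.approx(exact, abs=1e-10)

    def test_mean_estimate_with_one_sample_equals_classic(self, rng):
        samples = [[v] for v in rng.normal(size=6)]
        tr = make_trace(np.linspace(0, 1, 6), samples)
        assert est.ps_mean_estimate(tr).log_bf == pytest.approx(
            est.ps_estimate(tr).log_bf
        )

    def test_mean_estimate_invariant_to_duplication(self, rng):
        samples = [rng.normal(size=4) for _ in range(6)]
        tr1 = make_trace(np.linspace(0, 1, 6), samples)
        tr2 = make_trace(np.linspace(0, 1, 6), [np.tile(s, 2) for s in samples])
        assert est.ps_mean_estimate(tr1).log_bf == pytest.approx(
            est.ps_mean_estimate(tr2).log_bf
        )


class TestDiscretizationError:
    def test_constant_expectation_gives_zero(self):
        tr = make_trace([0, 0.5, 1], [[1.0], [1.0], [1.0]])
        assert est.discretization_error(tr) == 0.0

    @pytest.mark.parametrize("K", [2, 5, 50])
    def test_linear_expectation_telescopes(self, K):
        betas = np.arange(K + 1) / K
        tr = make_trace(betas, [[b] for b in betas])
        assert est.discretization_error(tr) == pytest.approx(1.0 / (2 * K))

    def test_nonnegative_for_monotone_input(self, rng):
        e = np.sort(rng.normal(size=8))
        tr = make_trace(np.linspace(0, 1, 8), [[v] for v in e])
        assert est.discretization_error(tr) >= 0.0


class TestPSSamplingVariance:
    def test_zero_variances(self):
        assert est.ps_sampling_variance([0, 0.5, 1], [0, 0, 0]) == 0.0

    def test_worked_value_k2_unit_variances(self):
        # V[(U0 + 2 U1 + U2)/4] with unit variances = 6/16 = 0.375
        v = est.ps_sampling_variance([0, 0.5, 1], [1.0, 1.0, 1.0], tau=1.0)
        assert v == pytest.approx(0.375)

    def test_linear_in_variances(self, rng):
        betas = np.sort(np.concatenate([[0, 1], rng.random(5)]))
        V = rng.random(7)
        assert est.ps_sampling_variance(betas, 2 * V) == pytest.approx(
            2 * est.ps_sampling_variance(betas, V)
        )

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            est.ps_sampling_variance([0, 1], [-1.0, 0.0])


class TestSteppingStone:
    def test_zero_width_step(self):
        assert est.ss_step_log_ratio([1.0, 2.0], 0.3, 0.3) == 0.0

    def test_single_sample(self):
        assert est.ss_step_log_ratio([2.5], 0.2, 0.6) == pytest.approx(0.4 * 2.5)

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=40), st.floats(0.001, 1.0))
    @settings(derandomize=True, max_examples=50)
    def test_factored_equals_unfactored(self, ells, d):
        ells = np.asarray(ells)
        factored = est.ss_step_log_ratio(ells, 0.0, d)
        plain = logsumexp(d * ells) - math.log(ells.size)
        assert factored == pytest.approx(plain, abs=1e-10)

    def test_identical_models_give_zero(self):
        tr = make_trace(np.linspace(0, 1, 5), [[0.0, 0.0]] * 5, mode="ss")
        assert est.ss_log_bf(tr).log_bf == 0.0

    def test_single_step_composition(self):
        tr = make_trace([0.0, 1.0], [[1.7], [0.0]], mode="ss")
        assert est.ss_log_bf(tr).log_bf == pytest.approx(1.7)

    def test_melting_direction_uses_upper_endpoint_samples(self, rng):
        # constant-U traces must give the same answer in both directions
        samples = [[0.8, 0.8]] * 6
        tr_a = make_trace(np.linspace(0, 1, 6), samples, mode="ss")
        tr_m = make_trace(np.linspace(1, 0, 6), samples, "melting", mode="ss")
        assert est.ss_log_bf(tr_a).log_bf == pytest.approx(0.8)
        assert est.ss_log_bf(tr_m).log_bf == pytest.approx(0.8)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            est.ss_step_log_ratio([], 0.0, 0.5)


class TestSSVariance:
    def test_identical_samples_contribute_zero(self):
        tr = make_trace([0, 0.5, 1], [[1.0, 1.0], [2.0, 2.0], [0.0, 0.0]], mode="ss")
        assert est.ss_variance(tr) == pytest.approx(0.0, abs=1e-12)

    def test_two_point_hand_calculation(self):
        a, b, d = 0.3, 1.1, 0.5
        tr = make_trace([0, d / d * 0.5, 1], [[a, b], [a, b], [0.0]], mode="ss")
        total = 0.0
        for ell in ([a, b], [a, b]):
            w = np.exp(0.5 * np.asarray(ell))
            r = w.mean()
            var = np.sum((w - r) ** 2) / w.size**2
            total += var / r**2
        assert est.ss_variance(tr) == pytest.approx(total, rel=1e-10)

    def test_single_sample_step_rejected(self):
        tr = make_trace([0, 1], [[1.0], [0.0]], mode="ss")
        with pytest.raises(ValueError):
            est.ss_variance(tr)

    def test_variance_calibrated_against_replicates(self, rng):
        # delta-method variance should match the replicate spread within 2x
        d = 0.5
        reported, estimates = [], []
        for _ in range(200):
            ells = rng.normal(0.0, 1.0, size=50)
            tr = make_trace([0, d, 1], [ells, ells, [0.0, 0.0]], mode="ss")
            tr = make_trace([0, 1], [ells, [0.0, 0.0]], mode="ss")
            estimates.append(est.ss_log_bf(tr).log_bf)
            reported.append(est.ss_variance(tr))
        ratio = np.var(estimates, ddof=1) / np.mean(reported)
        assert 0.5 < ratio < 2.0


class TestVarianceComparison:
    def test_constant_denominator_forces_zero_covariance(self, rng):
        # with one kernel constant the covariance term vanishes and the two
        # variance structures coincide
        n, K = 30, 4
        comps = [
            np.column_stack([rng.normal(size=n), np.zeros(n)]) for _ in range(K + 1)
        ]
        tr = make_trace(np.linspace(0, 1, K + 1),
                        [c[:, 0] - c[:, 1] for c in comps], mode="ss", comps=comps)
        rep = est.variance_comparison(tr)
        assert rep["covariance_term"] == pytest.approx(0.0, abs=1e-12)
        assert rep["direct_variance"] == pytest.approx(
            rep["ratio_structure_variance"], rel=1e-10
        )

    def test_positively_coupled_kernels_favor_direct(self, rng):
        n, K = 40, 5
        comps = []
        for _ in range(K + 1):
            shared = rng.normal(size=n)
            comps.append(np.column_stack([shared + 0.1 * rng.normal(size=n), shared]))
        tr = make_trace(np.linspace(0, 1, K + 1),
                        [c[:, 0] - c[:, 1] for c in comps], mode="ss", comps=comps)
        rep = est.variance_comparison(tr)
        assert rep["covariance_term"] > 0
        assert rep["direct_le_ratio"]

    def test_single_sample_warns(self, rng):
        comps = [np.array([[1.0, 0.5]]) for _ in range(3)]
        tr = make_trace([0, 0.5, 1], [[0.5], [0.5], [0.5]], mode="ss", comps=comps)
        with pytest.warns(UserWarning, match="n=1"):
            est.variance_comparison(tr)

    def test_missing_components_rejected(self):
        tr = make_trace([0, 1], [[1.0], [1.0]], mode="ss")
        with pytest.raises(ValueError):
            est.variance_comparison(tr)

    def test_different_priors_warn(self, rng):
        comps = [np.column_stack([rng.normal(size=5), rng.normal(size=5)])
                 for _ in range(3)]
        tr = make_trace([0, 0.5, 1], [c[:, 0] - c[:, 1] for c in comps],
                        mode="ss", comps=comps)
        with pytest.warns(UserWarning, match="priors"):
            est.variance_comparison(tr, same_priors=False)


class TestBidirectional:
    def _est(self, log_bf, splits, variance=0.01):
        e = est.BFEstimate(log_bf, "ss", "annealing", variance=variance)
        e.split_contributions = np.asarray(splits, dtype=float)
        return e

    def test_identical_contributions(self):
        a = self._est(1.0, [0.5, 0.5])
        m = self._est(1.0, [0.5, 0.5])
        out = est.bidirectional_summary(a, m)
        assert out.bidirectional_error == 0.0
        assert out.log_bf == 1.0

    def test_twenty_splits_differing_by_tenth(self):
        a = self._est(2.0, [0.1] * 20)
        m = self._est(4.0, [0.2] * 20)
        out = est.bidirectional_summary(a, m)
        assert out.bidirectional_error == pytest.approx(2.0)
        assert out.log_bf == pytest.approx(3.0)
        assert out.thermic_lag_expected is True

    def test_mismatched_splits_rejected(self):
        with pytest.raises(ValueError):
            est.bidirectional_summary(self._est(1, [1.0]), self._est(1, [0.5, 0.5]))


@pytest.mark.parametrize(
    "value,expected",
    [
        (0.5, "not worth more than a bare mention"),
        (2.0, "positive evidence against M0"),
        (4.0, "strong evidence against M0"),
        (6.0, "very strong evidence against M0"),
        (-2.0, "positive evidence for M0"),
        (-7.0, "very strong evidence for M0"),
    ],
)
def test_interpret_log_bf(value, expected):
    assert est.interpret_log_bf(value) == expected


def test_interpret_log_bf_rejects_nonfinite():
    with pytest.raises(ValueError):
        est.interpret_log_bf(math.inf)
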