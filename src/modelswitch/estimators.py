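"""Log marginal-likelihood and log Bayes-factor estimators with error theory.

Implements the harmonic mean estimator (HME) and its stabilized variant
(sHME), classic model-switch path sampling (trapezoid rule over the potential
U along the beta path), its mean-of-samples extension, model-switch
stepping-stone sampling (product of per-step importance ratios), and the
accompanying diagnostics: discretization error, sampling variance for path
sampling, delta-method simulation variance for stepping stones, the
direct-path versus ratio-of-marginals variance comparison, and the
bidirectional (annealing/melting) error summary.

All products of ratios are accumulated in log space; per-step importance
ratios always factor out the largest sampled term for numerical stability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "BFEstimate",
    "hme",
    "shme",
    "ps_estimate",
    "ps_mean_estimate",
    "ss_step_log_ratio",
    "ss_log_bf",
    "discretization_error",
    "ps_sampling_variance",
    "ss_variance",
    "variance_comparison",
    "bidirectional_summary",
    "interpret_log_bf",
    "per_step_contributions",
]


@dataclass
class BFEstimate:
    """A log Bayes factor (log Z_1 - log Z_0) with method and diagnostics."""

    log_bf: float
    method: str
    direction: str
    variance: float = math.nan
    discretization_error: float = math.nan
    bidirectional_error: float = math.nan
    split_contributions: np.ndarray | None = None
    thermic_lag_expected: bool | None = None

    @property
    def se(self) -> float:
        """Monte Carlo standard error implied by the estimated variance."""
        return math.sqrt(self.variance) if self.variance == self.variance else math.nan

    def __post_init__(self):
        if self.variance == self.variance and self.variance < 0:
            raise ValueError("variance must be >= 0")


# ---------------------------------------------------------------------------
# Harmonic mean estimators
# ---------------------------------------------------------------------------


def hme(log_likelihoods) -> float:
    """Harmonic mean estimator of the log marginal likelihood.

    log N - logsumexp(-l_i) over posterior-sample log likelihoods.  The HME
    systematically overestimates the marginal likelihood because posterior
    samples almost never visit the low-likelihood region that carries the
    dimensional penalty.
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.size == 0:
        raise ValueError("hme requires at least one log likelihood")
    return float(math.log(ll.size) - logsumexp(-ll))


def shme(log_likelihoods, delta: float = 0.01, max_iter: int = 1000, tol: float = 1e-10) -> float:
    """Stabilized harmonic mean estimator (delta-mixture fixed point).

    Mixes the posterior sample with an imagined fraction ``delta`` of prior
    draws whose likelihood equals the current marginal-likelihood estimate,
    and iterates the resulting self-consistency equation to a fixed point.
    Reduces to :func:`hme` as ``delta -> 0``.
    """
    ll = np.asarray(log_likelihoods, dtype=float)
    if ll.size == 0:
        raise ValueError("shme requires at least one log likelihood")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must lie in (0, 1)")
    m = ll.size
    log_delta, log_1md = math.log(delta), math.log1p(-delta)
    log_A = log_delta + math.log(m) - log_1md  # delta*m/(1-delta)
    log_z = hme(ll)
    for _ in range(max_iter):
        # s_i = log(delta*Z + (1-delta)*L_i)
        s = np.logaddexp(log_delta + log_z, log_1md + ll)
        log_num = logsumexp(np.append(ll - s, log_A))
        log_den = logsumexp(np.append(-s, log_A - log_z))
        new = float(log_num - log_den)
        if abs(new - log_z) < tol:
            return new
        log_z = new
    raise RuntimeError(f"shme did not converge within {max_iter} iterations")


# ---------------------------------------------------------------------------
# Trace access helpers
# ---------------------------------------------------------------------------


def _ascending(trace):
    """(betas, per-beta sample arrays) in ascending beta order, regardless of
    the traversal direction recorded in the trace."""
    betas = np.asarray(trace.betas, dtype=float)
    samples = [np.atleast_1d(np.asarray(s, dtype=float)) for s in trace.U_samples]
    if betas.size != len(samples):
        raise ValueError("trace length mismatch between betas and U samples")
    if betas.size < 2:
        raise ValueError("trace must cover at least two beta values")
    if betas[0] > betas[-1]:
        betas, samples = betas[::-1], samples[::-1]
    if np.any(np.diff(betas) <= 0):
        raise ValueError("trace betas must be strictly monotone")
    for s in samples:
        if s.size == 0:
            raise ValueError("a beta value has zero saved samples")
    return betas, samples


def _direction(trace) -> str:
    return getattr(trace, "direction", "annealing")


# ---------------------------------------------------------------------------
# Path sampling
# ---------------------------------------------------------------------------


def per_step_contributions(trace, method: str = "ps") -> np.ndarray:
    """Per-step contributions (ascending in beta) to the log Bayes factor;
    their sum is the corresponding whole-path estimate."""
    betas, samples = _ascending(trace)
    d = np.diff(betas)
    if method in ("ps", "ps_mean"):
        if method == "ps":
            u = np.array([s[-1] for s in samples])  # the classic save point
        else:
            u = np.array([s.mean() for s in samples])
        return d * 0.5 * (u[:-1] + u[1:])
    if method == "ss":
        melting = _direction(trace) == "melting"
        out = np.empty(d.size)
        for k in range(d.size):
            if melting:
                # samples at the step's upper endpoint estimate c_{k}/c_{k+1}
                out[k] = -ss_step_log_ratio(-samples[k + 1], betas[k], betas[k + 1])
            else:
                out[k] = ss_step_log_ratio(samples[k], betas[k], betas[k + 1])
        return out
    raise ValueError(f"unknown method {method!r}")


def ps_estimate(trace, schedule=None) -> BFEstimate:
    """Classic model-switch path sampling: trapezoid rule over the single
    U value saved before each beta update."""
    contributions = per_step_contributions(trace, "ps")
    est = BFEstimate(
        log_bf=float(contributions.sum()),
        method="ps",
        direction=_direction(trace),
        discretization_error=discretization_error(trace, classic=True),
    )
    _attach_splits(est, contributions, schedule)
    return est


def ps_mean_estimate(trace, schedule=None) -> BFEstimate:
    """Path sampling using the per-beta mean of all saved samples."""
    from .mcmc import effective_samples

    betas, samples = _ascending(trace)
    contributions = per_step_contributions(trace, "ps_mean")
    variances = np.array([s.var(ddof=1) if s.size > 1 else 0.0 for s in samples])
    ns = np.array([s.size for s in samples])
    taus = np.array(
        [effective_samples(s)[1] if s.size >= 10 else 1.0 for s in samples]
    )
    var = ps_sampling_variance(betas, variances * taus / ns)
    est = BFEstimate(
        log_bf=float(contributions.sum()),
        method="ps_mean",
        direction=_direction(trace),
        variance=var,
        discretization_error=discretization_error(trace),
    )
    _attach_splits(est, contributions, schedule)
    return est


def discretization_error(trace, classic: bool = False) -> float:
    """Worst-case discretization error sigma_d of the trapezoid estimator.

    Equals the area between the piecewise-linear interpolant of the per-beta
    expectations E_beta[U] and the step functions built from them:
    |sum_k 0.5 (beta_{k+1}-beta_k)(E_{k+1} - E_k)|.
    """
    betas, samples = _ascending(trace)
    if betas.size < 2:
        raise ValueError("need at least two beta values")
    if classic:
        e = np.array([s[-1] for s in samples])
    else:
        e = np.array([s.mean() for s in samples])
    return abs(float(0.5 * np.sum(np.diff(betas) * np.diff(e))))


def ps_sampling_variance(betas_or_trace, per_beta_variances, tau: float = 1.0) -> float:
    """Sampling variance of the trapezoid path-sampling estimator.

    With increments d_k = beta_{k+1} - beta_k and per-beta variances V_k of
    the U value entering the trapezoid sum:

        V = 1/4 [ sum_k d_k^2 (V_k + V_{k+1})
                  + 2 sum_{k=1}^{K-1} d_k d_{k-1} V_k ]

    (the quarter multiplies both sums).  ``tau`` is the decorrelation time
    K/K_eff; it scales the result when the saved points are autocorrelated.
    """
    betas = np.asarray(getattr(betas_or_trace, "betas", betas_or_trace), dtype=float)
    if betas[0] > betas[-1]:
        betas = betas[::-1]
    V = np.asarray(per_beta_variances, dtype=float)
    if np.any(V < 0):
        raise ValueError("variances must be nonnegative")
    if tau < 1.0:
        raise ValueError("tau must be >= 1")
    if V.size != betas.size:
        raise ValueError("need one variance per beta")
    d = np.diff(betas)
    main = np.sum(d**2 * (V[:-1] + V[1:]))
    cross = 2.0 * np.sum(d[1:] * d[:-1] * V[1:-1])
    return float(tau * 0.25 * (main + cross))


# ---------------------------------------------------------------------------
# Stepping-stone sampling
# ---------------------------------------------------------------------------


def ss_step_log_ratio(samples_at_prev_beta, beta_prev: float, beta_k: float) -> float:
    """Log of one stepping-stone ratio c_{beta_k} / c_{beta_prev}.

    ``samples_at_prev_beta`` are log importance ratios
    l_i = log k_1(theta_i) - log k_0(theta_i) drawn from the power posterior
    at ``beta_prev``.  The largest term is factored out:

        log r_k = d log eta + log[(1/n) sum_i exp(d (l_i - log eta))]

    with d = beta_k - beta_prev and log eta = max_i l_i, algebraically
    identical to the plain mean of exp(d l_i).
    """
    ell = np.atleast_1d(np.asarray(samples_at_prev_beta, dtype=float))
    if ell.size == 0:
        raise ValueError("empty sample set")
    d = beta_k - beta_prev
    if d == 0.0:
        return 0.0
    log_eta = float(ell.max())
    return float(d * log_eta + logsumexp(d * (ell - log_eta)) - math.log(ell.size))


def ss_log_bf(trace, schedule=None) -> BFEstimate:
    """Model-switch stepping-stone estimate of the log Bayes factor.

    Sums the per-step log importance ratios; on the natural scale the
    product of per-step ratios is unbiased, while the log transform
    introduces a bias that shrinks as K grows.
    """
    contributions = per_step_contributions(trace, "ss")
    try:
        var = ss_variance(trace)
    except ValueError:
        var = math.nan
    est = BFEstimate(
        log_bf=float(contributions.sum()),
        method="ss",
        direction=_direction(trace),
        variance=var,
        discretization_error=discretization_error(trace),
    )
    _attach_splits(est, contributions, schedule)
    return est


def _relative_moments(log_terms: np.ndarray):
    """log mean(exp(t)) and the relative variance Var/mean^2 (1/n^2-style
    denominator as in the per-step simulation variance)."""
    n = log_terms.size
    log_m1 = logsumexp(log_terms) - math.log(n)
    log_m2 = logsumexp(2.0 * log_terms) - math.log(n)
    rel_var = max(math.expm1(log_m2 - 2.0 * log_m1), 0.0) / n
    return log_m1, rel_var


def ss_variance(trace, tau: float = 1.0) -> float:
    """Delta-method simulation variance of the stepping-stone log estimate:
    sum_k Var(r_k) / r_k^2 with Var(r_k) = (1/n^2) sum_i (w_i - mean w)^2,
    w_i = exp(d l_i), evaluated stably in log space.

    The formula assumes independent draws at each step; ``tau`` (the
    decorrelation time K/K_eff) scales the result when the per-step
    samples are autocorrelated.
    """
    if tau < 1.0:
        raise ValueError("tau must be >= 1")
    betas, samples = _ascending(trace)
    d = np.diff(betas)
    melting = _direction(trace) == "melting"
    total = 0.0
    for k in range(d.size):
        ell = samples[k + 1] if melting else samples[k]
        if ell.size < 2:
            raise ValueError("ss_variance needs >= 2 samples per step")
        sign = -1.0 if melting else 1.0
        _, rel_var = _relative_moments(sign * d[k] * ell)
        total += rel_var
    return float(tau * total)


def variance_comparison(
    direct_trace, ml_trace_0=None, ml_trace_1=None, same_priors: bool = True
) -> dict:
    """Compare the variance of direct-path stepping-stone Bayes factor
    estimation against the ratio-of-marginals alternative.

    The direct-path variance and the no-covariance (ratio-structure)
    variance differ exactly by the covariance term arising because both
    models' powered kernels are evaluated in the same parameter draws;
    that covariance is typically positive, making the direct path the
    lower-variance estimator.  Requires a direct trace that recorded
    per-sample component log kernels.  When the two per-model
    marginal-likelihood traces (independent prior<->posterior runs) are
    supplied, their delta-method variances are summed into
    ``ratio_of_marginals_variance``.
    """
    if not same_priors:
        warnings.warn(
            "the direct-vs-ratio variance identity assumes both models share "
            "their priors; the comparison is only indicative here"
        )
    comps = getattr(direct_trace, "component_samples", None)
    if comps is None:
        raise ValueError("direct trace must record component log kernels")
    betas = np.asarray(direct_trace.betas, dtype=float)
    if betas[0] > betas[-1]:
        betas = betas[::-1]
        comps = comps[::-1]
    d = np.diff(betas)
    melting = _direction(direct_trace) == "melting"
    direct_var = ratio_var = cov_term = 0.0
    for k in range(d.size):
        c = np.asarray(comps[k + 1] if melting else comps[k], dtype=float)
        n = c.shape[0]
        sign = -1.0 if melting else 1.0
        l1, l0 = sign * d[k] * c[:, 0], sign * d[k] * c[:, 1]
        if n < 2:
            warnings.warn("single-sample step: point estimates only (n=1)")
            continue
        _, rv1 = _relative_moments(l1)
        _, rv0 = _relative_moments(l0)
        _, rvr = _relative_moments(l1 - l0)
        m1 = logsumexp(l1) - math.log(n)
        m0 = logsumexp(l0) - math.log(n)
        m10 = logsumexp(l1 + l0) - math.log(n)
        rel_cov = math.expm1(m10 - m1 - m0) / n
        direct_var += rvr
        ratio_var += rv1 + rv0
        cov_term += 2.0 * rel_cov
    report = {
        "direct_variance": float(direct_var),
        "ratio_structure_variance": float(ratio_var),
        "covariance_term": float(cov_term),
        "direct_le_ratio": bool(direct_var <= ratio_var),
    }
    if ml_trace_0 is not None and ml_trace_1 is not None:
        report["ratio_of_marginals_variance"] = float(
            ss_variance(ml_trace_0) + ss_variance(ml_trace_1)
        )
    return report


# ---------------------------------------------------------------------------
# Bidirectional summary and interpretation
# ---------------------------------------------------------------------------


def _attach_splits(est: BFEstimate, contributions: np.ndarray, schedule) -> None:
    if schedule is not None:
        est.split_contributions = np.array(
            [contributions[sl].sum() for sl in schedule.split_step_slices()]
        )


def bidirectional_summary(annealing: BFEstimate, melting: BFEstimate) -> BFEstimate:
    """Combine annealing and melting runs: the mean is the final estimate,
    and the summed absolute per-split contribution differences form the
    bidirectional error (a repeatability diagnostic).

    The thermic-lag flag records whether the runs show the expected
    direction (annealing below melting): a chain lagging behind a rising
    beta samples from a slightly cooler power posterior, underestimating
    the log Bayes factor on the way up and overestimating it on the way
    down.
    """
    a, m = annealing, melting
    if a.split_contributions is None or m.split_contributions is None:
        raise ValueError("both estimates need per-split contributions")
    if a.split_contributions.size != m.split_contributions.size:
        raise ValueError("mismatched split boundaries")
    bde = float(np.abs(a.split_contributions - m.split_contributions).sum())
    var = math.nan
    if a.variance == a.variance and m.variance == m.variance:
        var = 0.25 * (a.variance + m.variance)
    return BFEstimate(
        log_bf=0.5 * (a.log_bf + m.log_bf),
        method=a.method,
        direction="bidirectional",
        variance=var,
        bidirectional_error=bde,
        split_contributions=0.5 * (a.split_contributions + m.split_contributions),
        thermic_lag_expected=bool(a.log_bf < m.log_bf),
    )


def interpret_log_bf(value: float) -> str:
    """Kass-Raftery gradation of a log Bayes factor as evidence against M0
    (symmetric reading for negative values, as evidence for M0)."""
    if not math.isfinite(value):
        raise ValueError("log Bayes factor must be finite")
    against = "against M0" if value > 0 else "for M0"
    v = abs(value)
    if v <= 1.0:
        return "not worth more than a bare mention"
    if v <= 3.0:
        return f"positive evidence {against}"
    if v <= 5.0:
        return f"strong evidence {against}"
    return f"very strong evidence {against}"
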