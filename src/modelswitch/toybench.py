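"""Analytic toy models and synthetic sequence data.

The toy families (beta-binomial and conjugate normal) have closed-form
marginal likelihoods and exact posterior samplers, making them independent
oracles for every path-based estimator.  The sequence simulators invert the
two substitution models on a fixed rooted tree and provide synthetic
alignments for the model-comparison experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import betaln, gammaln

from . import likelihood as lk
from .mcmc import PhyloSwitchProblem, SwitchProblem, UpdateCycle, run_path
from .models import (
    GAP,
    ContextModelParams,
    GTRParams,
    RootMarkovChain,
    gtr_transition_probs,
)
from .schedules import Schedule, sigmoid_schedule

__all__ = [
    "ToyModelSpec",
    "SimulationSpec",
    "analytic_log_marginal",
    "analytic_log_bf",
    "ToySwitchProblem",
    "ToyMarginalProblem",
    "simulate_alignment",
    "recovery_experiment",
    "default_beta_binomial_pair",
    "separated_beta_binomial_pair",
    "normal_scale_pair",
    "thermic_lag_experiment",
    "variance_comparison_experiment",
    "ss_unbiasedness_experiment",
    "hme_overestimation_experiment",
    "gtr_vs_context_sign_experiment",
    "demo_tree",
    "demo_gtr_params",
]


# ---------------------------------------------------------------------------
# Toy model specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ToyModelSpec:
    """A 1-D model with a conjugate prior and closed-form marginal.

    ``family`` is ``"beta-binomial"`` (parameter: success probability p;
    hyperparameters a, b; data (n, k)) or ``"conjugate-normal"``
    (parameter: mean theta; hyperparameters prior_mean, prior_sd, lik_sd;
    data: an observation vector).
    """

    family: str
    hyperparameters: dict
    data: tuple

    def __post_init__(self):
        if self.family not in ("beta-binomial", "conjugate-normal"):
            raise ValueError(f"unsupported family {self.family!r}")
        if self.family == "conjugate-normal":
            object.__setattr__(self, "data", tuple(float(v) for v in np.atleast_1d(self.data)))

    # -- densities --------------------------------------------------------

    def log_prior(self, theta: float) -> float:
        h = self.hyperparameters
        if self.family == "beta-binomial":
            a, b = h["a"], h["b"]
            if not 0.0 < theta < 1.0:
                return -math.inf
            return (
                (a - 1.0) * math.log(theta)
                + (b - 1.0) * math.log1p(-theta)
                - betaln(a, b)
            )
        m, s = h["prior_mean"], h["prior_sd"]
        return -0.5 * ((theta - m) / s) ** 2 - math.log(s) - 0.5 * math.log(2 * math.pi)

    def log_likelihood(self, theta: float) -> float:
        h = self.hyperparameters
        if self.family == "beta-binomial":
            n, k = self.data
            if not 0.0 < theta < 1.0:
                return -math.inf
            logC = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
            return float(logC + k * math.log(theta) + (n - k) * math.log1p(-theta))
        y = np.asarray(self.data)
        s = h["lik_sd"]
        return float(
            -0.5 * np.sum(((y - theta) / s) ** 2)
            - y.size * (math.log(s) + 0.5 * math.log(2 * math.pi))
        )

    # -- exact samplers ---------------------------------------------------

    def sample_prior(self, rng: np.random.Generator) -> float:
        h = self.hyperparameters
        if self.family == "beta-binomial":
            return float(rng.beta(h["a"], h["b"]))
        return float(rng.normal(h["prior_mean"], h["prior_sd"]))

    def posterior_params(self):
        h = self.hyperparameters
        if self.family == "beta-binomial":
            n, k = self.data
            return h["a"] + k, h["b"] + n - k
        y = np.asarray(self.data)
        prec = 1.0 / h["prior_sd"] ** 2 + y.size / h["lik_sd"] ** 2
        mean = (h["prior_mean"] / h["prior_sd"] ** 2 + y.sum() / h["lik_sd"] ** 2) / prec
        return mean, math.sqrt(1.0 / prec)

    def sample_posterior(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        p1, p2 = self.posterior_params()
        if self.family == "beta-binomial":
            return rng.beta(p1, p2, size=size)
        return rng.normal(p1, p2, size=size)


def analytic_log_marginal(spec: ToyModelSpec) -> float:
    """Exact log marginal likelihood of a toy model.

    beta-binomial: log C(n,k) + log B(k+a, n-k+b) - log B(a,b);
    conjugate normal: the data are jointly Gaussian with mean m 1 and
    covariance lik_sd^2 I + prior_sd^2 J.
    """
    h = spec.hyperparameters
    if spec.family == "beta-binomial":
        n, k = spec.data
        logC = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return float(logC + betaln(k + h["a"], n - k + h["b"]) - betaln(h["a"], h["b"]))
    y = np.asarray(spec.data)
    n = y.size
    m, s2, v2 = h["prior_mean"], h["lik_sd"] ** 2, h["prior_sd"] ** 2
    # Woodbury/determinant identities for sigma^2 I + v^2 11^T
    total_var = s2 + n * v2
    resid = np.sum((y - y.mean()) ** 2)
    logdet = (n - 1) * math.log(s2) + math.log(total_var)
    quad = resid / s2 + n * (y.mean() - m) ** 2 / total_var
    return float(-0.5 * (n * math.log(2 * math.pi) + logdet + quad))


def analytic_log_bf(spec0: ToyModelSpec, spec1: ToyModelSpec) -> float:
    """Exact log Bayes factor log Z1 - log Z0 for two toys sharing data."""
    if spec0.data != spec1.data:
        raise ValueError("the two specs must share their data")
    return analytic_log_marginal(spec1) - analytic_log_marginal(spec0)


# ---------------------------------------------------------------------------
# Toy sampling problems
# ---------------------------------------------------------------------------


class _ToyProblemBase(SwitchProblem):
    def __init__(self, proposals: UpdateCycle = UpdateCycle()):
        self.prop = proposals

    def _log_kernel(self, which: int, theta: float) -> float:
        raise NotImplementedError

    def potential(self, theta: float) -> float:
        return self._log_kernel(1, theta) - self._log_kernel(0, theta)

    def kernel_components(self, theta: float):
        return self._log_kernel(1, theta), self._log_kernel(0, theta)

    def _power_target(self, beta: float, theta: float) -> float:
        if beta == 0.0:
            return self._log_kernel(0, theta)
        if beta == 1.0:
            return self._log_kernel(1, theta)
        return (1.0 - beta) * self._log_kernel(0, theta) + beta * self._log_kernel(1, theta)


class ToySwitchProblem(_ToyProblemBase):
    """Direct model-switch path between two toy models sharing their data.

    The scalar parameter is updated by one random-walk Metropolis step per
    cycle (on the logit scale for probabilities, identity scale for
    means)."""

    def __init__(self, spec0: ToyModelSpec, spec1: ToyModelSpec, proposals=UpdateCycle()):
        super().__init__(proposals)
        if spec0.family != spec1.family:
            raise ValueError("both models must share a likelihood family")
        if spec0.data != spec1.data:
            raise ValueError("both models must share their data")
        self.spec0, self.spec1 = spec0, spec1
        self._bounded = spec0.family == "beta-binomial"

    def _log_kernel(self, which: int, theta: float) -> float:
        spec = self.spec1 if which else self.spec0
        return spec.log_likelihood(theta) + spec.log_prior(theta)

    def initial_state(self, rng: np.random.Generator, beta: float) -> float:
        spec = self.spec1 if beta >= 0.5 else self.spec0
        return spec.sample_prior(rng)

    def update_cycle(self, theta: float, beta: float, rng: np.random.Generator) -> float:
        step = self.prop.toy_step
        if self._bounded:
            logit = math.log(theta) - math.log1p(-theta)
            prop = 1.0 / (1.0 + math.exp(-(logit + step * rng.normal())))
            prop = min(max(prop, 1e-12), 1.0 - 1e-12)
            # Jacobian of the logit reparameterization
            log_h = (
                math.log(prop) + math.log1p(-prop) - math.log(theta) - math.log1p(-theta)
            )
        else:
            prop = theta + step * rng.normal()
            log_h = 0.0
        delta = self._power_target(beta, prop) - self._power_target(beta, theta) + log_h
        if delta >= 0 or math.log(rng.random()) < delta:
            return prop
        return theta


class ToyMarginalProblem(ToySwitchProblem):
    """Prior-to-posterior path for a single toy model: kernel 0 is the bare
    prior (normalizing constant 1), kernel 1 the posterior kernel, so the
    path estimate is the model's log marginal likelihood."""

    def __init__(self, spec: ToyModelSpec, proposals=UpdateCycle()):
        _ToyProblemBase.__init__(self, proposals)
        self.spec0 = self.spec1 = spec
        self._bounded = spec.family == "beta-binomial"

    def _log_kernel(self, which: int, theta: float) -> float:
        base = self.spec0.log_prior(theta)
        return base + self.spec0.log_likelihood(theta) if which else base


# -- standard study configurations ------------------------------------------


def default_beta_binomial_pair():
    """Beta(1,1) vs Beta(2,2) priors on 14 successes out of 20 trials: the
    standard accuracy benchmark (analytic log BF available)."""
    data = (20, 14)
    return (
        ToyModelSpec("beta-binomial", {"a": 1.0, "b": 1.0}, data),
        ToyModelSpec("beta-binomial", {"a": 2.0, "b": 2.0}, data),
    )


def separated_beta_binomial_pair():
    """Beta(1,1) vs Beta(150,50) on the same data: strongly separated
    priors give the potential U a large spread along the path (the
    annealing/melting lag scales with the integrated variance of U), which
    makes the thermic lag of short per-step chains visible above Monte
    Carlo noise."""
    data = (20, 14)
    return (
        ToyModelSpec("beta-binomial", {"a": 1.0, "b": 1.0}, data),
        ToyModelSpec("beta-binomial", {"a": 150.0, "b": 50.0}, data),
    )


def normal_scale_pair(rng: np.random.Generator, n: int = 10):
    """Two conjugate-normal models with a shared N(0,1) prior on the mean
    but different known observation scales (1.0 vs 1.5) — the shared-prior
    setting of the direct-vs-ratio variance comparison."""
    y = tuple(rng.normal(0.5, 1.0, size=n))
    h = {"prior_mean": 0.0, "prior_sd": 1.0}
    return (
        ToyModelSpec("conjugate-normal", {**h, "lik_sd": 1.0}, y),
        ToyModelSpec("conjugate-normal", {**h, "lik_sd": 1.5}, y),
    )


# -- focused experiments ------------------------------------------------------


def thermic_lag_experiment(
    n_pairs: int = 20, rng=None, K: int = 5, Q: int = 5
) -> dict:
    """Annealing/melting pairs under deliberately short per-step chains.

    With only Q = 5 cycles per beta the chain lags behind the moving
    target: on the way up it samples from a slightly cooler power
    posterior than the current beta, underestimating the log Bayes
    factor, and symmetrically overestimates it on the way down.  Uses the
    strongly separated beta-binomial pair, a short constant grid and a
    deliberately sticky random-walk proposal, all of which amplify the
    lag relative to Monte Carlo noise.
    """
    from . import estimators as est
    from .schedules import constant_schedule

    rng = np.random.default_rng() if rng is None else rng
    s0, s1 = separated_beta_binomial_pair()
    problem = ToySwitchProblem(s0, s1, UpdateCycle(toy_step=0.3))
    anneal, melt = [], []
    for _ in range(n_pairs):
        sched = constant_schedule(K, Q)
        tr_a = run_path(problem, sched, mode="mean", rng=rng, save_interval=1)
        tr_m = run_path(problem, sched.reversed(), mode="mean", rng=rng, save_interval=1)
        anneal.append(est.ps_mean_estimate(tr_a).log_bf)
        melt.append(est.ps_mean_estimate(tr_m).log_bf)
    return {
        "annealing_mean": float(np.mean(anneal)),
        "melting_mean": float(np.mean(melt)),
        "lag": float(np.mean(melt) - np.mean(anneal)),
        "analytic_log_bf": analytic_log_bf(s0, s1),
        "n_pairs": n_pairs,
    }


def variance_comparison_experiment(
    n_replicates: int = 100, rng=None, K: int = 10, Q: int = 20, save_interval: int = 5
) -> dict:
    """Direct-path versus ratio-of-marginals stepping-stone variance.

    Two conjugate-normal models share their prior but differ in known
    observation scale.  Per replicate, one direct model-switch SS run and
    two independent prior-to-posterior SS runs (one per model) are
    performed over the same grid; across replicates the empirical
    variance of the direct log Bayes factor is compared with the variance
    of the difference of the two marginal-likelihood estimates, and the
    positive covariance term (both kernels evaluated in the same draws)
    is estimated from the direct runs' component samples.
    """
    from . import estimators as est
    from .schedules import sigmoid_schedule

    rng = np.random.default_rng() if rng is None else rng
    s0, s1 = normal_scale_pair(rng)
    direct = ToySwitchProblem(s0, s1)
    marg0, marg1 = ToyMarginalProblem(s0), ToyMarginalProblem(s1)
    sched = sigmoid_schedule(K, Q, 4.0)
    direct_bfs, ratio_bfs, cov_terms = [], [], []
    for _ in range(n_replicates):
        tr_d = run_path(direct, sched, mode="ss", rng=rng,
                        save_interval=save_interval, record_components=True)
        tr_0 = run_path(marg0, sched, mode="ss", rng=rng, save_interval=save_interval)
        tr_1 = run_path(marg1, sched, mode="ss", rng=rng, save_interval=save_interval)
        direct_bfs.append(est.ss_log_bf(tr_d).log_bf)
        ratio_bfs.append(est.ss_log_bf(tr_1).log_bf - est.ss_log_bf(tr_0).log_bf)
        cov_terms.append(est.variance_comparison(tr_d)["covariance_term"])
    return {
        "direct_variance": float(np.var(direct_bfs, ddof=1)),
        "ratio_variance": float(np.var(ratio_bfs, ddof=1)),
        "mean_covariance_term": float(np.mean(cov_terms)),
        "analytic_log_bf": analytic_log_bf(s0, s1),
        "direct_mean": float(np.mean(direct_bfs)),
        "ratio_mean": float(np.mean(ratio_bfs)),
        "n_replicates": n_replicates,
    }


def ss_unbiasedness_experiment(
    n_replicates: int = 500, rng=None, Q: int = 100, save_interval: int = 10
) -> dict:
    """Natural-scale unbiasedness of the single-step stepping-stone ratio.

    With K = 1 the estimator is the plain importance-sampling mean of the
    kernel ratio under the M0 posterior; averaging exp(log r) across many
    independent replicates must recover the analytic Bayes factor."""
    from . import estimators as est
    from .schedules import constant_schedule

    rng = np.random.default_rng() if rng is None else rng
    s0, s1 = default_beta_binomial_pair()
    problem = ToySwitchProblem(s0, s1)
    sched = constant_schedule(1, Q)
    ratios = []
    for _ in range(n_replicates):
        tr = run_path(problem, sched, mode="ss", rng=rng, save_interval=save_interval)
        ratios.append(math.exp(est.ss_log_bf(tr).log_bf))
    ratios = np.array(ratios)
    return {
        "mean_ratio": float(ratios.mean()),
        "se_ratio": float(ratios.std(ddof=1) / math.sqrt(n_replicates)),
        "analytic_bf": math.exp(analytic_log_bf(s0, s1)),
        "n_replicates": n_replicates,
    }


def hme_overestimation_experiment(
    n_replicates: int = 20, n_samples: int = 50_000, rng=None
) -> dict:
    """HME bias demonstration on the conjugate-normal toy: exact posterior
    samples are available, so the experiment isolates the estimator's own
    bias (the mode-width blindness) from any MCMC error."""
    from . import estimators as est

    rng = np.random.default_rng() if rng is None else rng
    spec = ToyModelSpec(
        "conjugate-normal",
        {"prior_mean": 0.0, "prior_sd": 1.0, "lik_sd": 1.0},
        tuple(rng.normal(0.5, 1.0, size=10)),
    )
    analytic = analytic_log_marginal(spec)
    hmes, shmes = [], []
    for _ in range(n_replicates):
        thetas = spec.sample_posterior(rng, size=n_samples)
        ll = np.array([spec.log_likelihood(t) for t in thetas])
        hmes.append(est.hme(ll))
        shmes.append(est.shme(ll))
    return {
        "mean_hme": float(np.mean(hmes)),
        "mean_shme": float(np.mean(shmes)),
        "analytic_log_marginal": float(analytic),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Settings for simulating an alignment on a fixed rooted tree.

    ``model`` is a :class:`GTRParams` (root drawn from the stationary
    frequencies) or a normalized :class:`ContextModelParams` (root drawn
    from ``root_chain``).  ``gap_mask`` marks columns that are gaps in
    every sequence (gaps are copied through, never evolved).
    """

    tree: lk.PhyloTree
    length: int
    model: object
    root_chain: Optional[RootMarkovChain] = None
    seed: int = 0
    gap_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if isinstance(self.model, ContextModelParams) and self.root_chain is None:
            raise ValueError("context-model simulation needs a root chain")


def _sample_root_chain(chain: RootMarkovChain, L: int, rng) -> np.ndarray:
    seq = np.empty(L, dtype=np.int8)
    for i in range(L):
        if chain.order == 0:
            p = chain.transitions
        elif chain.order == 1:
            p = chain.initial[0] if i == 0 else chain.transitions[seq[i - 1]]
        else:
            if i == 0:
                p = chain.initial[0]
            elif i == 1:
                p = chain.initial[1][seq[0]]
            else:
                p = chain.transitions[seq[i - 2], seq[i - 1]]
        seq[i] = rng.choice(4, p=p)
    return seq


def _evolve_gtr(parent: np.ndarray, P: np.ndarray, rng) -> np.ndarray:
    child = parent.copy()
    for b in range(4):
        idx = np.flatnonzero(parent == b)
        if idx.size:
            child[idx] = rng.choice(4, size=idx.size, p=P[b])
    return child


def _evolve_context(parent: np.ndarray, table: np.ndarray, rng) -> np.ndarray:
    """One branch of context-dependent evolution with neighbors fixed at the
    parent sequence.  Sites whose factor involves a gap (including the two
    sequence ends) carry no substitution process and copy the parent."""
    L = parent.size
    child = parent.copy()
    w = np.empty(L, dtype=np.int8)
    y = np.empty(L, dtype=np.int8)
    w[0], w[1:] = GAP, parent[:-1]
    y[-1], y[:-1] = GAP, parent[1:]
    ok = np.flatnonzero((w != GAP) & (y != GAP) & (parent != GAP))
    if ok.size == 0:
        return child
    probs = table[w[ok], y[ok], parent[ok]]  # (n_ok, 4) rows sum to 1
    u = rng.random(ok.size)
    child[ok] = (np.cumsum(probs, axis=1) < u[:, None]).sum(axis=1).astype(np.int8)
    return child


def simulate_alignment(spec: SimulationSpec) -> lk.Alignment:
    """Simulate tip sequences under the spec's model; seeded and
    reproducible."""
    rng = np.random.default_rng(spec.seed)
    tree, L = spec.tree, spec.length
    is_context = isinstance(spec.model, ContextModelParams)
    if is_context:
        root = _sample_root_chain(spec.root_chain, L, rng)
        tables = {}
    else:
        root = rng.choice(4, size=L, p=spec.model.base_frequencies).astype(np.int8)
    if spec.gap_mask is not None:
        mask = np.asarray(spec.gap_mask, dtype=bool)
        if mask.shape != (L,):
            raise ValueError("gap mask must have one flag per column")
        root[mask] = GAP
    seqs = {tree.root: root}
    order = [v for v in tree.postorder[::-1]]  # preorder: parents first
    for v in order:
        if v == tree.root:
            continue
        t = float(tree.branch_lengths[v])
        parent_seq = seqs[tree.parent[v]]
        if is_context:
            if t not in tables:
                tables[t] = np.exp(lk.context_branch_log_table(spec.model, t))
            seqs[v] = _evolve_context(parent_seq, tables[t], rng)
        else:
            seqs[v] = _evolve_gtr(parent_seq, gtr_transition_probs(spec.model, t), rng)
    labels = tree.tip_labels
    return lk.Alignment(labels, np.array([seqs[i] for i in range(tree.n_tips)]))


def demo_tree() -> lk.PhyloTree:
    """The five-taxon mammal topology used throughout the examples, with
    all branch lengths 0.1."""
    return lk.PhyloTree.from_newick(
        "((((cow:0.1,sheep:0.1):0.1,muntjak:0.1):0.1,pig:0.1):0.1,horse:0.1);"
    )


def demo_gtr_params() -> GTRParams:
    """A transition/transversion-biased GTR parameterization for the
    synthetic alignments (kappa-like rates 4 on transitions)."""
    return GTRParams(np.array([1.0, 4.0, 1.0, 1.0, 4.0]),
                     np.array([0.3, 0.2, 0.2, 0.3]))


def gtr_vs_context_sign_experiment(
    n_replicates: int = 10,
    length: int = 2000,
    rng=None,
    K: int = 30,
    Q: int = 10,
    alpha: float = 10.0,
    save_interval: int = 5,
    equilibration: int = 100,
) -> dict:
    """Model comparison on data without context signal.

    Alignments are simulated under GTR on the five-taxon demo tree; the
    GTR-versus-context-model log Bayes factor is then estimated by
    annealing stepping-stone sampling.  Absent genuine neighbor
    dependence, the 96 extra parameters of the strand-symmetric context
    model are pure prior penalty, so the log Bayes factor must come out
    negative on average.
    """
    from . import estimators as est

    rng = np.random.default_rng() if rng is None else rng
    tree = demo_tree()
    gtr = demo_gtr_params()
    sched = sigmoid_schedule(K, Q, alpha)
    log_bfs = []
    for _ in range(n_replicates):
        aln = simulate_alignment(
            SimulationSpec(tree, length, gtr, seed=int(rng.integers(2**31 - 1)))
        )
        problem = PhyloSwitchProblem(aln, tree, root_order=0, strand_symmetric=True)
        trace = run_path(problem, sched, mode="ss", rng=rng,
                         save_interval=save_interval, equilibration=equilibration)
        log_bfs.append(est.ss_log_bf(trace).log_bf)
    return {
        "log_bfs": [float(v) for v in log_bfs],
        "mean_log_bf": float(np.mean(log_bfs)),
        "n_replicates": n_replicates,
        "length": length,
    }


# ---------------------------------------------------------------------------
# Recovery experiments
# ---------------------------------------------------------------------------

DEFAULT_SETTINGS = {
    "K": 50,
    "Q": 200,
    "alpha": 10.0,
    "n_splits": 5,
    "save_interval": 10,
    "mode": "ss",
    "equilibration": None,
}


def _make_schedule(settings: dict, direction: str) -> Schedule:
    return sigmoid_schedule(
        settings["K"],
        settings["Q"],
        settings["alpha"],
        direction=direction,
        n_splits=settings.get("n_splits", 1),
    )


def recovery_experiment(spec, settings: Optional[dict] = None, rng=None) -> dict:
    """Simulate-and-estimate harness.

    ``spec`` is either a (spec0, spec1) pair of toys — annealing and
    melting runs of PS, mean-sample PS and SS are compared against the
    analytic log Bayes factor — or a :class:`SimulationSpec`, in which
    case an alignment is simulated and the GTR-versus-context-model log
    Bayes factor is estimated by stepping-stone sampling.  ``settings``
    may include ``n_replicates`` (0 gives an empty report).
    """
    from . import estimators as est

    cfg = {**DEFAULT_SETTINGS, **(settings or {})}
    rng = np.random.default_rng() if rng is None else rng
    n_rep = cfg.get("n_replicates", 1)
    report = {"replicates": [], "settings": {k: v for k, v in cfg.items()}}
    if n_rep == 0:
        return report
    for _ in range(n_rep):
        if isinstance(spec, SimulationSpec):
            report["replicates"].append(_phylo_replicate(spec, cfg, rng))
        else:
            report["replicates"].append(_toy_replicate(spec, cfg, rng, est))
    keys = [k for k, v in report["replicates"][0].items() if isinstance(v, float)]
    report["means"] = {
        k: float(np.mean([r[k] for r in report["replicates"]])) for k in keys
    }
    return report


def _toy_replicate(spec, cfg, rng, est) -> dict:
    spec0, spec1 = spec
    problem = ToySwitchProblem(spec0, spec1)
    sched_a = _make_schedule(cfg, "annealing")
    sched_m = sched_a.reversed()
    out = {"analytic_log_bf": analytic_log_bf(spec0, spec1)}
    kw = dict(
        mode=cfg["mode"],
        save_interval=cfg["save_interval"],
        equilibration=cfg["equilibration"],
    )
    tr_a = run_path(problem, sched_a, rng=rng, **kw)
    tr_m = run_path(problem, sched_m, rng=rng, **kw)
    ss = est.bidirectional_summary(
        est.ss_log_bf(tr_a, sched_a), est.ss_log_bf(tr_m, sched_m)
    )
    ps = est.bidirectional_summary(
        est.ps_mean_estimate(tr_a, sched_a), est.ps_mean_estimate(tr_m, sched_m)
    )
    out.update(
        ss_log_bf=ss.log_bf,
        ss_se=ss.se,
        ss_bde=ss.bidirectional_error,
        ps_mean_log_bf=ps.log_bf,
        ps_mean_se=ps.se,
        ps_mean_bde=ps.bidirectional_error,
    )
    return out


def _phylo_replicate(spec: SimulationSpec, cfg, rng) -> dict:
    from . import estimators as est

    sim = SimulationSpec(
        tree=spec.tree,
        length=spec.length,
        model=spec.model,
        root_chain=spec.root_chain,
        seed=int(rng.integers(2**31 - 1)),
        gap_mask=spec.gap_mask,
    )
    aln = simulate_alignment(sim)
    problem = PhyloSwitchProblem(
        aln,
        spec.tree,
        root_order=cfg.get("root_order", 0),
        strand_symmetric=cfg.get("strand_symmetric", True),
    )
    sched = _make_schedule(cfg, "annealing")
    trace = run_path(
        problem,
        sched,
        mode=cfg["mode"],
        rng=rng,
        save_interval=cfg["save_interval"],
        equilibration=cfg["equilibration"],
    )
    ss = est.ss_log_bf(trace, sched)
    return {"ss_log_bf": ss.log_bf, "ss_variance": ss.variance}
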