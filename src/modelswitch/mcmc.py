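"""Metropolis-within-Gibbs sampling over power posteriors.

`run_path` drives a problem object along a beta schedule: equilibrate at
the starting endpoint, then for each beta run Q update cycles, saving the
potential U (the log kernel ratio between the two models) before each beta
update, and — in mean/ss modes — additional samples at fixed cycle
intervals.  An update cycle touches every model parameter, every branch
length and every ancestral site exactly once.

Problem objects implement ``initial_state``, ``update_cycle``,
``potential`` and (optionally, for variance-comparison traces)
``kernel_components``.  Toy problems live in :mod:`modelswitch.toybench`;
the phylogenetic GTR-versus-context-model problem is implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import gammaln
from scipy.stats import invgamma

from . import likelihood as lk
from .models import (
    GAP,
    ContextModelParams,
    GTRParams,
    PriorConfig,
    RootMarkovChain,
    canonical_contexts,
    _self_complementary_pairs,
)
from .schedules import Schedule

__all__ = [
    "UpdateCycle",
    "PathTrace",
    "SwitchProblem",
    "update_cycle",
    "run_path",
    "run_beta_sequence",
    "effective_samples",
    "PhyloSwitchProblem",
    "propose_simplex",
    "propose_multiplier",
]


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------


@dataclass
class PathTrace:
    """Per-beta samples of the potential U along one traversal.

    ``betas`` is the visited beta sequence (nondecreasing for annealing,
    nonincreasing for melting); ``U_samples[k]`` holds the samples saved at
    ``betas[k]`` with the classic save point (the state just before the
    beta update) last.  ``component_samples``, when recorded, holds per
    save event the pair (log kernel 1, log kernel 0).
    """

    betas: np.ndarray
    U_samples: list
    direction: str = "annealing"
    mode: str = "ss"
    cycles_per_step: int = 1
    save_interval: int = 10
    seed: Optional[int] = None
    component_samples: Optional[list] = None

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        diffs = np.diff(self.betas)
        if self.direction == "annealing" and np.any(diffs < 0):
            raise ValueError("annealing trace must have nondecreasing betas")
        if self.direction == "melting" and np.any(diffs > 0):
            raise ValueError("melting trace must have nonincreasing betas")
        for s in self.U_samples:
            if not np.all(np.isfinite(s)):
                raise ValueError("non-finite potential in trace")

    @property
    def K(self) -> int:
        return self.betas.size - 1


@dataclass
class UpdateCycle:
    """Proposal settings for one full sweep of Metropolis-Hastings updates."""

    simplex_concentration: float = 200.0
    simplex_pseudocount: float = 0.05
    multiplier_step: float = 0.6  # branch lengths, mu, GTR rates
    toy_step: float = 0.6  # random-walk step for 1-D toy parameters


class SwitchProblem:
    """Contract for problems sampled by :func:`run_path`."""

    def initial_state(self, rng: np.random.Generator, beta: float):
        raise NotImplementedError

    def update_cycle(self, state, beta: float, rng: np.random.Generator):
        """One full MH sweep targeting the power posterior at ``beta``;
        mutates and returns the state."""
        raise NotImplementedError

    def potential(self, state) -> float:
        """U = log k1 - log k0 at the current state."""
        raise NotImplementedError

    def kernel_components(self, state):
        """(log kernel 1, log kernel 0); only needed for variance traces."""
        raise NotImplementedError


def update_cycle(problem: SwitchProblem, state, beta: float, rng: np.random.Generator):
    """One full update cycle of ``problem`` targeting the power posterior
    p_beta; rejected proposals keep their current values."""
    return problem.update_cycle(state, beta, rng)


def _save_cycles(Q: int, save_interval: int, mode: str):
    """Cycle indices (1-based) at which samples are saved within a step."""
    if mode == "classic":
        return [Q]
    burnin = save_interval if Q > 2 * save_interval else 0
    saves = [c for c in range(1, Q + 1) if c % save_interval == 0 and c > burnin]
    if not saves or saves[-1] != Q:
        saves.append(Q)
    return saves


def run_path(
    problem: SwitchProblem,
    schedule: Schedule,
    mode: str = "ss",
    rng: Optional[np.random.Generator] = None,
    equilibration: Optional[int] = None,
    save_interval: int = 10,
    record_components: bool = False,
    initial_state=None,
) -> PathTrace:
    """Traverse the schedule and collect a :class:`PathTrace`.

    The chain is equilibrated at the starting endpoint (default 10 Q
    cycles), then run for Q cycles at every grid value of beta, in
    annealing (0 -> 1) or melting (1 -> 0) order according to the
    schedule's direction.  ``mode`` is ``"classic"`` (one U per beta),
    ``"mean"`` or ``"ss"`` (a sample every ``save_interval`` cycles; the
    first ``save_interval`` cycles at each new beta are discarded when Q
    is large enough to afford it).
    """
    return run_beta_sequence(
        problem,
        schedule.traversal,
        schedule.Q,
        mode=mode,
        rng=rng,
        direction=schedule.direction,
        equilibration=equilibration,
        save_interval=save_interval,
        record_components=record_components,
        initial_state=initial_state,
    )


def run_beta_sequence(
    problem: SwitchProblem,
    betas_visit: np.ndarray,
    Q: int,
    mode: str = "ss",
    rng: Optional[np.random.Generator] = None,
    direction: str = "annealing",
    equilibration: Optional[int] = None,
    save_interval: int = 10,
    record_components: bool = False,
    initial_state=None,
) -> PathTrace:
    """Run the traversal protocol over an arbitrary beta sequence (used
    both for full schedules and for independent split-interval runs)."""
    if mode not in ("classic", "mean", "ss"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng() if rng is None else rng
    betas = np.asarray(betas_visit, dtype=float)
    state = problem.initial_state(rng, float(betas[0])) if initial_state is None else initial_state
    if not math.isfinite(problem.potential(state)):
        raise ValueError("non-finite kernel at initialization")
    n_equil = 10 * Q if equilibration is None else equilibration
    for _ in range(n_equil):
        state = problem.update_cycle(state, float(betas[0]), rng)
    save_set = set(_save_cycles(Q, save_interval, mode))
    U_samples = []
    comp_samples = [] if record_components else None
    for beta in betas:
        b = float(beta)
        us, comps = [], []
        for c in range(1, Q + 1):
            state = problem.update_cycle(state, b, rng)
            if c in save_set:
                us.append(problem.potential(state))
                if record_components:
                    comps.append(problem.kernel_components(state))
        U_samples.append(np.asarray(us))
        if record_components:
            comp_samples.append(np.asarray(comps))
    return PathTrace(
        betas=betas.copy(),
        U_samples=U_samples,
        direction=direction,
        mode=mode,
        cycles_per_step=Q,
        save_interval=save_interval,
        component_samples=comp_samples,
    )


# ---------------------------------------------------------------------------
# Effective sample size
# ---------------------------------------------------------------------------


def effective_samples(values):
    """Autocorrelation-based effective sample size and decorrelation time.

    Uses Geyer's initial monotone positive sequence on the paired
    autocorrelation sums.  Returns ``(K_eff, tau)`` with
    ``tau = K / K_eff >= 1``; a constant series yields tau = 1 with a
    warning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 values")
    xc = x - x.mean()
    if np.all(xc == 0.0):
        warnings.warn("constant series: reporting tau = 1")
        return float(n), 1.0
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acov = np.fft.irfft(f * np.conj(f), m)[:n].real / n
    rho = acov / acov[0]
    # paired sums Gamma_j = rho(2j) + rho(2j+1), truncated at the first
    # non-positive pair and forced monotone nonincreasing
    tau = -1.0
    prev = math.inf
    for j in range(n // 2):
        g = rho[2 * j] + (rho[2 * j + 1] if 2 * j + 1 < n else 0.0)
        if g <= 0.0:
            break
        g = min(g, prev)
        prev = g
        tau += 2.0 * g
    tau = min(max(tau, 1.0), float(n))
    return n / tau, tau


# ---------------------------------------------------------------------------
# Proposal kernels
# ---------------------------------------------------------------------------


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1.0) * np.log(x)).sum()
    )


def propose_simplex(
    x: np.ndarray, rng: np.random.Generator, conc: float = 200.0, pseudocount: float = 0.05
):
    """Dirichlet-perturbation proposal centered on the current simplex point;
    returns (proposal, log Hastings ratio)."""
    a_fwd = conc * x + pseudocount
    xp = rng.dirichlet(a_fwd)
    xp = np.maximum(xp, 1e-12)
    xp = xp / xp.sum()
    a_rev = conc * xp + pseudocount
    log_h = _dirichlet_logpdf(x, a_rev) - _dirichlet_logpdf(xp, a_fwd)
    return xp, log_h


def propose_multiplier(value: float, rng: np.random.Generator, step: float = 0.6):
    """Log-scale multiplier proposal for a positive scalar; the Hastings
    ratio is the log multiplier."""
    log_m = step * (rng.random() - 0.5)
    return value * math.exp(log_m), log_m


def _accept(delta: float, rng: np.random.Generator) -> bool:
    return delta >= 0.0 or math.log(rng.random()) < delta


# ---------------------------------------------------------------------------
# Phylogenetic model-switch problem: GTR (M0) vs context-dependent (M1)
# ---------------------------------------------------------------------------


@dataclass
class _PhyloState:
    """Sampler state with cached likelihood pieces.

    The context block is stored raw (each context's 12 off-diagonal psi
    entries form a simplex); the likelihood always sees the normalized
    table.  ``branch_ll[j]``/``g_branch_ll[j]`` are the summed per-branch
    log factors of the context and GTR complete-data likelihoods,
    ``root_ll``/``g_root_ll`` the corresponding root terms.
    """

    gtr: GTRParams
    raw_psi: np.ndarray
    f: np.ndarray
    root_chain: RootMarkovChain
    branch_lengths: np.ndarray
    mu: float
    anc: np.ndarray
    root_ll: float = math.nan
    branch_ll: np.ndarray = field(default_factory=lambda: np.empty(0))
    tables: list = field(default_factory=list)
    g_root_ll: float = math.nan
    g_branch_ll: np.ndarray = field(default_factory=lambda: np.empty(0))
    g_tables: list = field(default_factory=list)
    g_log_pi: np.ndarray = field(default_factory=lambda: np.empty(0))

    def context_params(self, strand_symmetric: bool) -> ContextModelParams:
        from .models import normalize_context_model

        return normalize_context_model(
            ContextModelParams(self.raw_psi, self.f, strand_symmetric)
        )


class PhyloSwitchProblem(SwitchProblem):
    """Direct path between the GTR model and the first-order
    context-dependent model on a fixed rooted tree.

    The joint state concatenates both models' parameter blocks plus shared
    branch lengths and mu; the augmented ancestral sequences belong to the
    context side and carry a uniform pseudo-prior over non-gap sites under
    the GTR side, so both endpoint normalizing constants are the models'
    marginal likelihoods and the path integral is the log Bayes factor.
    """

    def __init__(
        self,
        alignment: lk.Alignment,
        tree: lk.PhyloTree,
        prior: PriorConfig = PriorConfig(),
        root_order: int = 0,
        strand_symmetric: bool = True,
        proposals: UpdateCycle = UpdateCycle(),
    ):
        self.alignment = alignment
        self.tree = tree
        self.prior = prior
        self.root_order = root_order
        self.strand_symmetric = strand_symmetric
        self.prop = proposals
        self.L = alignment.length
        perm = tree.tip_permutation(alignment.labels)
        self.tip_data = alignment.matrix[perm]
        self.branch_nodes = tree.branch_nodes
        self.branch_index = {int(v): j for j, v in enumerate(self.branch_nodes)}
        self.anc_gaps = lk.ancestral_gap_mask(tree, alignment)
        self.n_free_anc = int(np.sum(~self.anc_gaps))
        self.contexts = canonical_contexts(strand_symmetric)
        self._offdiag = [(x, z) for x in range(4) for z in range(4) if x != z]
        self._sc_pairs = _self_complementary_pairs()
        # per internal node and stride phase: updatable (non-gap) sites
        self._anc_sites = [
            [
                np.flatnonzero(~self.anc_gaps[r] & (np.arange(self.L) % 3 == ph))
                for ph in range(3)
            ]
            for r in range(self.anc_gaps.shape[0])
        ]
        self.model_0 = lk.GTRSideModel(alignment, tree, prior)
        self.model_1 = lk.ContextSideModel(alignment, tree, prior)

    # -- state construction and caches ------------------------------------

    def initial_state(self, rng: np.random.Generator, beta: float) -> _PhyloState:
        mu = float(invgamma.rvs(self.prior.invgamma_shape, scale=self.prior.invgamma_scale,
                                random_state=rng))
        st = _PhyloState(
            gtr=GTRParams.random_from_prior(rng),
            raw_psi=self._raw_from_prior(rng),
            f=self._f_from_prior(rng),
            root_chain=RootMarkovChain.random_from_prior(rng, self.root_order),
            branch_lengths=rng.exponential(mu, size=self.branch_nodes.size),
            mu=mu,
            anc=lk.AugmentedState.random(self.tree, self.alignment, rng).sequences,
        )
        self._refresh_all(st)
        return st

    def _raw_from_prior(self, rng) -> np.ndarray:
        psi = np.zeros((4, 4, 4, 4))
        for (w, y, mirror) in self.contexts:
            if self.strand_symmetric and mirror is None:
                u = rng.dirichlet(np.ones(6))
                self._set_self_comp_block(psi, w, y, u)
            else:
                self._set_block(psi, w, y, rng.dirichlet(np.ones(12)), mirror)
        return psi

    def _f_from_prior(self, rng) -> np.ndarray:
        f = np.zeros((4, 4, 4))
        for (w, y, mirror) in self.contexts:
            f[w, y] = rng.dirichlet(np.ones(4))
            if mirror is not None:
                f[mirror[0], mirror[1]] = f[w, y][::-1]
        return f

    def _set_block(self, psi, w, y, block12, mirror):
        for v, (x, z) in zip(block12, self._offdiag):
            psi[w, y, x, z] = v
            if mirror is not None:
                psi[mirror[0], mirror[1], 3 - x, 3 - z] = v
    def _set_self_comp_block(self, psi, w, y, u6):
        for uj, (a, b) in zip(u6, self._sc_pairs):
            psi[w, y, a[0], a[1]] = uj / 2.0
            psi[w, y, b[0], b[1]] = uj / 2.0

    def _get_block(self, psi, w, y, mirror):
        if self.strand_symmetric and mirror is None:
            return np.array([psi[w, y, a[0], a[1]] + psi[w, y, b[0], b[1]]
                             for a, b in self._sc_pairs])
        return np.array([psi[w, y, x, z] for x, z in self._offdiag])

    def _norm_psi(self, raw_psi, f) -> np.ndarray:
        mass = np.einsum("wyx,wyxz->wy", f, raw_psi)
        return raw_psi / mass[:, :, None, None]

    def _branch_table(self, norm_psi, t: float) -> np.ndarray:
        return lk.context_branch_log_table(norm_psi, t)

    def _node_seq(self, st: _PhyloState, v: int) -> np.ndarray:
        return self.tip_data[v] if v < self.tree.n_tips else st.anc[v - self.tree.n_tips]

    def _branch_ll_one(self, st: _PhyloState, table, v: int) -> float:
        return float(
            lk.branch_site_log_factors(
                table, self._node_seq(st, int(self.tree.parent[v])), self._node_seq(st, v)
            ).sum()
        )

    def _refresh_context(self, st: _PhyloState) -> None:
        norm = self._norm_psi(st.raw_psi, st.f)
        st.tables = [
            self._branch_table(norm, float(st.branch_lengths[j]))
            for j in range(self.branch_nodes.size)
        ]
        st.branch_ll = np.array(
            [
                self._branch_ll_one(st, st.tables[j], int(v))
                for j, v in enumerate(self.branch_nodes)
            ]
        )

    def _gtr_tables(self, gtr: GTRParams, branch_lengths: np.ndarray):
        """Per-branch log transition matrices via one spectral
        decomposition of the reversible rate matrix."""
        pi = gtr.base_frequencies
        d = np.sqrt(np.maximum(pi, 1e-300))
        B = gtr.rate_matrix() * (d[:, None] / d[None, :])
        lam, V = np.linalg.eigh(0.5 * (B + B.T))
        lam = np.minimum(lam, 0.0)
        A, Bm = V / d[:, None], V.T * d[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            tables = [
                np.log(np.maximum(A @ (np.exp(lam * float(t))[:, None] * Bm), 0.0))
                for t in branch_lengths
            ]
            log_pi = np.log(pi)
        return tables, log_pi

    def _gtr_branch_ll_one(self, st: _PhyloState, logP: np.ndarray, v: int) -> float:
        p = self._node_seq(st, int(self.tree.parent[v]))
        c = self._node_seq(st, v)
        ok = (p != GAP) & (c != GAP)
        return float(logP[p[ok], c[ok]].sum())

    def _gtr_root_ll(self, st: _PhyloState, log_pi: np.ndarray) -> float:
        s = self._node_seq(st, self.tree.root)
        return float(log_pi[s[s != GAP]].sum())

    def _refresh_gtr(self, st: _PhyloState) -> None:
        st.g_tables, st.g_log_pi = self._gtr_tables(st.gtr, st.branch_lengths)
        st.g_branch_ll = np.array(
            [
                self._gtr_branch_ll_one(st, st.g_tables[j], int(v))
                for j, v in enumerate(self.branch_nodes)
            ]
        )
        st.g_root_ll = self._gtr_root_ll(st, st.g_log_pi)

    def _refresh_all(self, st: _PhyloState) -> None:
        self._refresh_gtr(st)
        st.root_ll = lk._root_chain_log_prob_vec(
            st.root_chain, self._node_seq(st, self.tree.root)
        )
        self._refresh_context(st)

    # -- potential ---------------------------------------------------------

    def potential(self, st: _PhyloState) -> float:
        """U = log f1(y,A|theta1) - log f0(y,A|theta0): both models are
        evaluated on the same augmented complete data, and the shared
        parameter-block priors cancel."""
        ll1 = st.root_ll + float(st.branch_ll.sum())
        ll0 = st.g_root_ll + float(st.g_branch_ll.sum())
        return ll1 - ll0

    def kernel_components(self, st: _PhyloState):
        ll1 = st.root_ll + float(st.branch_ll.sum())
        ll0 = st.g_root_ll + float(st.g_branch_ll.sum())
        return ll1, ll0

    def to_model_state(self, st: _PhyloState) -> lk.ModelState:
        return lk.ModelState(
            gtr=st.gtr,
            context=st.context_params(self.strand_symmetric),
            root_chain=st.root_chain,
            branch_lengths=st.branch_lengths.copy(),
            mu=st.mu,
            aug=lk.AugmentedState(st.anc.copy()),
        )

    # -- update cycle ------------------------------------------------------

    def update_cycle(self, st: _PhyloState, beta: float, rng: np.random.Generator):
        self._update_gtr_rates(st, beta, rng)
        self._update_gtr_freqs(st, beta, rng)
        self._update_context_blocks(st, beta, rng)
        self._update_root_chain(st, beta, rng)
        self._update_branch_lengths(st, beta, rng)
        self._update_mu(st, rng)
        for v in self.tree.internal_nodes:
            self._update_ancestral(st, int(v), beta, rng)
        return st

    def _gtr_candidate_ll(self, st, cand: GTRParams):
        tables, log_pi = self._gtr_tables(cand, st.branch_lengths)
        bll = np.array(
            [
                self._gtr_branch_ll_one(st, tables[j], int(v))
                for j, v in enumerate(self.branch_nodes)
            ]
        )
        return tables, log_pi, bll, self._gtr_root_ll(st, log_pi)

    def _gtr_ll_total(self, st) -> float:
        return st.g_root_ll + float(st.g_branch_ll.sum())

    def _try_gtr(self, st, cand: GTRParams, beta, extra_delta, rng) -> None:
        tables, log_pi, bll, root_ll = self._gtr_candidate_ll(st, cand)
        new_total = root_ll + float(bll.sum())
        delta = (1.0 - beta) * (new_total - self._gtr_ll_total(st)) + extra_delta
        if _accept(delta, rng):
            st.gtr = cand
            st.g_tables, st.g_log_pi = tables, log_pi
            st.g_branch_ll, st.g_root_ll = bll, root_ll

    def _update_gtr_rates(self, st, beta, rng):
        for j in range(5):
            ex = st.gtr.exchangeabilities.copy()
            new, log_h = propose_multiplier(ex[j], rng, self.prop.multiplier_step)
            d_prior = -(new - ex[j]) / self.prior.gtr_rate_mean
            ex[j] = new
            self._try_gtr(st, GTRParams(ex, st.gtr.base_frequencies), beta, d_prior + log_h, rng)

    def _update_gtr_freqs(self, st, beta, rng):
        xp, log_h = propose_simplex(
            st.gtr.base_frequencies, rng, self.prop.simplex_concentration,
            self.prop.simplex_pseudocount,
        )
        self._try_gtr(st, GTRParams(st.gtr.exchangeabilities, xp), beta, log_h, rng)

    def _context_delta_refresh(self, st, raw_psi, f):
        """Candidate tables and branch log likelihood for a context change."""
        norm = self._norm_psi(raw_psi, f)
        tables = [
            self._branch_table(norm, float(st.branch_lengths[j]))
            for j in range(self.branch_nodes.size)
        ]
        bll = np.array(
            [self._branch_ll_one(st, tables[j], int(v)) for j, v in enumerate(self.branch_nodes)]
        )
        return tables, bll

    def _update_context_blocks(self, st, beta, rng):
        for (w, y, mirror) in self.contexts:
            # psi block
            cur = self._get_block(st.raw_psi, w, y, mirror)
            xp, log_h = propose_simplex(
                cur, rng, self.prop.simplex_concentration, self.prop.simplex_pseudocount
            )
            raw = st.raw_psi.copy()
            if self.strand_symmetric and mirror is None:
                self._set_self_comp_block(raw, w, y, xp)
            else:
                self._set_block(raw, w, y, xp, mirror)
            tables, bll = self._context_delta_refresh(st, raw, st.f)
            if _accept(beta * (bll.sum() - st.branch_ll.sum()) + log_h, rng):
                st.raw_psi, st.tables, st.branch_ll = raw, tables, bll
            # f block
            xp, log_h = propose_simplex(
                st.f[w, y], rng, self.prop.simplex_concentration, self.prop.simplex_pseudocount
            )
            f = st.f.copy()
            f[w, y] = xp
            if mirror is not None:
                f[mirror[0], mirror[1]] = xp[::-1]
            tables, bll = self._context_delta_refresh(st, st.raw_psi, f)
            if _accept(beta * (bll.sum() - st.branch_ll.sum()) + log_h, rng):
                st.f, st.tables, st.branch_ll = f, tables, bll

    def _update_root_chain(self, st, beta, rng):
        chain = st.root_chain
        root_seq = self._node_seq(st, self.tree.root)
        arrays = [a.copy() for a in chain.initial] + [chain.transitions.copy()]

        def make():
            return RootMarkovChain(chain.order, arrays[-1], tuple(arrays[:-1]))

        cur_ll = st.root_ll
        for arr in arrays:
            rows = list(np.ndindex(arr.shape[:-1])) if arr.ndim > 1 else [()]
            for idx in rows:
                old_row = np.array(arr[idx], dtype=float, copy=True)
                xp, log_h = propose_simplex(
                    old_row, rng,
                    self.prop.simplex_concentration, self.prop.simplex_pseudocount,
                )
                arr[idx] = xp
                new_ll = lk._root_chain_log_prob_vec(make(), root_seq)
                if _accept(beta * (new_ll - cur_ll) + log_h, rng):
                    cur_ll = new_ll
                else:
                    arr[idx] = old_row
        st.root_chain = make()
        st.root_ll = cur_ll

    def _update_branch_lengths(self, st, beta, rng):
        norm = self._norm_psi(st.raw_psi, st.f)
        for j, v in enumerate(self.branch_nodes):
            t = float(st.branch_lengths[j])
            new_t, log_h = propose_multiplier(t, rng, self.prop.multiplier_step)
            g_tab, _ = self._gtr_tables(st.gtr, [new_t])
            g_ll_j = self._gtr_branch_ll_one(st, g_tab[0], int(v))
            table = self._branch_table(norm, new_t)
            bll_j = self._branch_ll_one(st, table, int(v))
            d_prior = -(new_t - t) / st.mu
            delta = (
                (1.0 - beta) * (g_ll_j - st.g_branch_ll[j])
                + beta * (bll_j - st.branch_ll[j])
                + d_prior
                + log_h
            )
            if _accept(delta, rng):
                st.branch_lengths[j] = new_t
                st.g_tables[j], st.g_branch_ll[j] = g_tab[0], g_ll_j
                st.tables[j], st.branch_ll[j] = table, bll_j

    def _update_mu(self, st, rng):
        new_mu, log_h = propose_multiplier(st.mu, rng, self.prop.multiplier_step)
        t = st.branch_lengths
        d = (
            self.prior.mu_log_prior(new_mu)
            - self.prior.mu_log_prior(st.mu)
            + self.prior.branch_lengths_log_prior(t, new_mu)
            - self.prior.branch_lengths_log_prior(t, st.mu)
        )
        if _accept(d + log_h, rng):
            st.mu = new_mu

    # -- ancestral sequence updates (vectorized, stride-3) ------------------

    def _anc_local_ll(self, st: _PhyloState, v: int, I: np.ndarray, bases: np.ndarray):
        """Summed log factors that involve node v's base at each site in I,
        evaluating with candidate ``bases`` substituted at those sites.
        Sequences are padded with two gap sentinels per side so edge and
        out-of-range neighbors fall under the gap rule automatically."""
        s = self._node_seq(st, v)
        sp = np.full(self.L + 4, GAP, dtype=np.int8)
        sp[2:-2] = s
        total = np.zeros(I.size)
        if v != self.tree.root:
            p = self._node_seq(st, int(self.tree.parent[v]))
            pp = np.full(self.L + 4, GAP, dtype=np.int8)
            pp[2:-2] = p
            T = st.tables[self.branch_index[v]]
            w, yy, x = pp[I + 1], pp[I + 3], pp[I + 2]
            ok = (w != GAP) & (yy != GAP) & (x != GAP)
            total[ok] += T[w[ok], yy[ok], x[ok], bases[ok]]
        else:
            total += self._root_local_ll(st, I, bases, sp)
        for c in self.tree.children[v]:
            u = self._node_seq(st, int(c))
            up = np.full(self.L + 4, GAP, dtype=np.int8)
            up[2:-2] = u
            T = st.tables[self.branch_index[int(c)]]
            # site i-1: bases act as right neighbor y
            w, x, z = sp[I], sp[I + 1], up[I + 1]
            ok = (w != GAP) & (x != GAP) & (z != GAP)
            total[ok] += T[w[ok], bases[ok], x[ok], z[ok]]
            # site i: bases act as focal parent base x
            w, yy, z = sp[I + 1], sp[I + 3], up[I + 2]
            ok = (w != GAP) & (yy != GAP) & (z != GAP)
            total[ok] += T[w[ok], yy[ok], bases[ok], z[ok]]
            # site i+1: bases act as left neighbor w
            yy, x, z = sp[I + 4], sp[I + 3], up[I + 3]
            ok = (yy != GAP) & (x != GAP) & (z != GAP)
            total[ok] += T[bases[ok], yy[ok], x[ok], z[ok]]
        return total

    def _root_local_ll(self, st, I, bases, sp):
        chain = st.root_chain
        if chain.order == 0:
            return np.log(chain.transitions[bases])
        # orders 1 and 2: few internal nodes, loop per site
        out = np.empty(I.size)
        s = self._node_seq(st, self.tree.root)
        for j, i in enumerate(I):
            tmp = s.copy()
            tmp[i] = bases[j]
            out[j] = sum(
                chain.log_prob_at(tmp, pos)
                for pos in range(i, min(i + chain.order + 1, self.L))
            )
        return out

    def _anc_local_gtr(self, st: _PhyloState, v: int, I: np.ndarray, bases: np.ndarray):
        """GTR complete-data log factors touching node v's base at sites I."""
        total = np.zeros(I.size)
        if v != self.tree.root:
            p = self._node_seq(st, int(self.tree.parent[v]))[I]
            logP = st.g_tables[self.branch_index[v]]
            ok = p != GAP
            total[ok] += logP[p[ok], bases[ok]]
        else:
            total += st.g_log_pi[bases]
        for c in self.tree.children[v]:
            u = self._node_seq(st, int(c))[I]
            logP = st.g_tables[self.branch_index[int(c)]]
            ok = u != GAP
            total[ok] += logP[bases[ok], u[ok]]
        return total

    def _update_ancestral(self, st: _PhyloState, v: int, beta: float, rng):
        r = v - self.tree.n_tips
        s = st.anc[r]
        child_branches = [self.branch_index[int(c)] for c in self.tree.children[v]]
        parent_branch = None if v == self.tree.root else self.branch_index[v]
        touched = ([] if parent_branch is None else [parent_branch]) + child_branches
        changed = False
        for phase in range(3):
            I = self._anc_sites[r][phase]
            if I.size == 0:
                continue
            prop = rng.integers(0, 4, size=I.size).astype(np.int8)
            delta = beta * (
                self._anc_local_ll(st, v, I, prop) - self._anc_local_ll(st, v, I, s[I])
            ) + (1.0 - beta) * (
                self._anc_local_gtr(st, v, I, prop) - self._anc_local_gtr(st, v, I, s[I])
            )
            acc = np.log(rng.random(I.size)) < delta
            if np.any(acc):
                s[I[acc]] = prop[acc]
                changed = True
        if not changed:
            return
        # refresh cached branch sums and root terms
        for j in touched:
            node = int(self.branch_nodes[j])
            st.branch_ll[j] = self._branch_ll_one(st, st.tables[j], node)
            st.g_branch_ll[j] = self._gtr_branch_ll_one(st, st.g_tables[j], node)
        if v == self.tree.root:
            st.root_ll = lk._root_chain_log_prob_vec(st.root_chain, s)
            st.g_root_ll = self._gtr_root_ll(st, st.g_log_pi)
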