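"""Substitution-model parameterizations, constraints, and prior densities.

Two model families are covered: the site-independent general time-reversible
(GTR) model and a first-order context-dependent model in which the
probability that base ``x`` mutates to ``z`` in one unit of time depends on
the immediate neighbors ``w`` (left) and ``y`` (right).  The context model is
parameterized by a table ``psi(x -> z | w y)`` over the 16 neighbor contexts
together with per-context frequencies ``f_wxy`` that fix the time scale so
one substitution per base is expected per unit time in every context.

Bases are encoded as integers ``A=0, C=1, G=2, T=3``; the gap symbol is
``GAP=4``.  Complementation is ``b -> 3-b``, so strand (complementary)
symmetry — psi(x->z|wy) = psi(x^c->z^c|y^c w^c) — is the index map
``(w,y,x,z) -> (3-y, 3-w, 3-x, 3-z)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm
from scipy.stats import invgamma

__all__ = [
    "BASES",
    "GAP",
    "ALPHABET",
    "complement",
    "GTRParams",
    "ContextModelParams",
    "RootMarkovChain",
    "PriorConfig",
    "gtr_transition_probs",
    "psi_lookup",
    "normalize_context_model",
    "count_free_parameters",
    "root_log_prob",
    "prior_log_density",
    "flat_dirichlet_log_density",
    "canonical_contexts",
    "SIMPLEX_TOL",
]

BASES = "ACGT"
GAP = 4
ALPHABET = "ACGT-"
SIMPLEX_TOL = 1e-9

#: order of the six GTR exchangeability pairs; the last (G<->T) is the
#: fixed scale reference.
GTR_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def complement(b: int) -> int:
    """Watson-Crick complement of an encoded base (gap maps to gap)."""
    return b if b == GAP else 3 - b


def encode_base(c) -> int:
    if isinstance(c, (int, np.integer)):
        if not 0 <= int(c) <= GAP:
            raise ValueError(f"base code out of range: {c}")
        return int(c)
    i = ALPHABET.find(str(c).upper())
    if i < 0:
        raise ValueError(f"unknown base symbol: {c!r}")
    return i


def _check_simplex(v, name: str) -> None:
    v = np.asarray(v, dtype=float)
    if np.any(v < -SIMPLEX_TOL):
        raise ValueError(f"{name} has negative entries")
    if abs(v.sum() - 1.0) > 1e-6:
        raise ValueError(f"{name} does not sum to 1 (sum={v.sum()!r})")


# ---------------------------------------------------------------------------
# GTR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GTRParams:
    """GTR substitution model: 5 free exchangeabilities + 3 free frequencies.

    ``exchangeabilities`` holds the five free relative rates for the pairs
    AC, AG, AT, CG, CT; the sixth pair (GT) is the scale reference, fixed
    at 1.  ``base_frequencies`` is a point on the 4-simplex.
    """

    exchangeabilities: np.ndarray
    base_frequencies: np.ndarray

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        pi = np.asarray(self.base_frequencies, dtype=float)
        if ex.shape != (5,):
            raise ValueError("expected 5 free exchangeabilities")
        if np.any(ex < 0):
            raise ValueError("exchangeabilities must be nonnegative")
        _check_simplex(pi, "base_frequencies")
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "base_frequencies", pi / pi.sum())

    @property
    def rates6(self) -> np.ndarray:
        """All six pairwise exchangeabilities (GT fixed at 1)."""
        return np.concatenate([self.exchangeabilities, [1.0]])

    def rate_matrix(self) -> np.ndarray:
        """Reversible rate matrix scaled to one expected substitution per
        unit time at stationarity."""
        pi = self.base_frequencies
        r = self.rates6
        Q = np.zeros((4, 4))
        for rate, (i, j) in zip(r, GTR_PAIRS):
            Q[i, j] = rate * pi[j]
            Q[j, i] = rate * pi[i]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        scale = -float(pi @ np.diag(Q))
        if scale <= 0:
            raise ValueError("degenerate rate matrix (zero total rate)")
        return Q / scale

    @classmethod
    def jukes_cantor(cls) -> "GTRParams":
        return cls(np.ones(5), np.full(4, 0.25))

    @classmethod
    def random_from_prior(cls, rng: np.random.Generator) -> "GTRParams":
        """Draw exchangeabilities iid Exponential(1), frequencies flat
        Dirichlet."""
        return cls(rng.exponential(1.0, size=5), rng.dirichlet(np.ones(4)))


def gtr_transition_probs(params: GTRParams, t: float) -> np.ndarray:
    """Transition probability matrix exp(Q t) for a branch of length ``t``."""
    if t < 0:
        raise ValueError(f"negative branch length: {t}")
    if t == 0.0:
        return np.eye(4)
    return expm(params.rate_matrix() * t)


# ---------------------------------------------------------------------------
# Context-dependent model
# ---------------------------------------------------------------------------


def canonical_contexts(strand_symmetric: bool):
    """Enumerate the free (w, y) neighbor contexts.

    Returns a list of ``(w, y, mirror_or_None)`` triples.  Without strand
    symmetry all 16 contexts are free.  With symmetry, each context (w, y)
    is tied to its mirror (y^c, w^c); the list contains one representative
    per orbit, with ``mirror`` set to the partner context (``None`` for
    self-complementary contexts, where the tie acts within the context).
    """
    out = []
    seen = set()
    for w in range(4):
        for y in range(4):
            if not strand_symmetric:
                out.append((w, y, None))
                continue
            m = (3 - y, 3 - w)
            if (w, y) in seen or m in seen:
                continue
            seen.add((w, y))
            out.append((w, y, None if m == (w, y) else m))
    return out


@dataclass(frozen=True)
class ContextModelParams:
    """First-order context-dependent substitution probabilities.

    ``psi[w, y, x, z]`` is the probability that base ``x`` with neighbors
    ``(w, y)`` mutates to ``z != x`` in one unit of time; diagonal entries
    (z == x) are ignored in storage and derived as the no-substitution
    completion by :func:`psi_lookup`.  ``context_frequencies[w, y, x]`` are
    the per-context base frequencies f_wxy used for time-scale
    normalization.
    """

    psi: np.ndarray
    context_frequencies: np.ndarray
    strand_symmetric: bool = False

    def __post_init__(self):
        psi = np.asarray(self.psi, dtype=float)
        f = np.asarray(self.context_frequencies, dtype=float)
        if psi.shape != (4, 4, 4, 4):
            raise ValueError("psi must have shape (4,4,4,4)")
        if f.shape != (4, 4, 4):
            raise ValueError("context_frequencies must have shape (4,4,4)")
        if np.any(psi < 0):
            raise ValueError("psi entries must be nonnegative")
        for w in range(4):
            for y in range(4):
                _check_simplex(f[w, y], f"context_frequencies[{w},{y}]")
        psi = psi.copy()
        for x in range(4):
            psi[:, :, x, x] = 0.0
        object.__setattr__(self, "psi", psi)
        object.__setattr__(self, "context_frequencies", f / f.sum(axis=-1, keepdims=True))
        if self.strand_symmetric:
            object.__setattr__(self, "psi", symmetrize_psi(psi))
            object.__setattr__(
                self, "context_frequencies", symmetrize_frequencies(self.context_frequencies)
            )

    @classmethod
    def uniform(cls, strand_symmetric: bool = False) -> "ContextModelParams":
        """All off-diagonal psi equal (1/12 before normalization), uniform f."""
        psi = np.full((4, 4, 4, 4), 1.0 / 12.0)
        f = np.full((4, 4, 4), 0.25)
        return cls(psi, f, strand_symmetric)

    @classmethod
    def random_from_prior(
        cls, rng: np.random.Generator, strand_symmetric: bool = False
    ) -> "ContextModelParams":
        """Flat-Dirichlet draws on each free psi block and frequency simplex."""
        psi = np.zeros((4, 4, 4, 4))
        f = np.zeros((4, 4, 4))
        offdiag = [(x, z) for x in range(4) for z in range(4) if x != z]
        for (w, y, mirror) in canonical_contexts(strand_symmetric):
            if strand_symmetric and mirror is None:
                # self-complementary context: 6 free tied pairs of entries
                u = rng.dirichlet(np.ones(6))
                for uj, (a, b) in zip(u, _self_complementary_pairs()):
                    psi[w, y, a[0], a[1]] = uj / 2.0
                    psi[w, y, b[0], b[1]] = uj / 2.0
            else:
                block = rng.dirichlet(np.ones(12))
                for v, (x, z) in zip(block, offdiag):
                    psi[w, y, x, z] = v
            f[w, y] = rng.dirichlet(np.ones(4))
            if mirror is not None:  # copy onto the tied partner context
                mw, my = mirror
                for x in range(4):
                    f[mw, my, 3 - x] = f[w, y, x]
                    for z in range(4):
                        psi[mw, my, 3 - x, 3 - z] = psi[w, y, x, z]
        params = cls(psi, f, strand_symmetric)
        return normalize_context_model(params)


def _self_complementary_pairs():
    """The 6 orbits of off-diagonal (x, z) pairs under x,z -> x^c,z^c."""
    offdiag = [(x, z) for x in range(4) for z in range(4) if x != z]
    seen, pairs = set(), []
    for x, z in offdiag:
        m = (3 - x, 3 - z)
        if (x, z) in seen or m in seen:
            continue
        seen.add((x, z))
        pairs.append(((x, z), m))
    return pairs


def symmetrize_psi(psi: np.ndarray) -> np.ndarray:
    """Average psi with its strand-complement image, enforcing the symmetry."""
    mirrored = psi[::-1, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3)
    # index map: psi_sym[w,y,x,z] = psi[3-y, 3-w, 3-x, 3-z]
    return 0.5 * (psi + mirrored)


def symmetrize_frequencies(f: np.ndarray) -> np.ndarray:
    mirrored = f[::-1, ::-1, ::-1].transpose(1, 0, 2)
    return 0.5 * (f + mirrored)


def psi_lookup(params: ContextModelParams, x, z, w, y) -> float:
    """Substitution probability psi(x -> z | w y) over one unit of time.

    Total over the alphabet plus gap: returns 1 if any argument is a gap;
    for ``z == x`` returns the no-substitution completion
    ``1 - sum_{z' != x} psi(x -> z' | w y)``.
    """
    x, z, w, y = (encode_base(b) for b in (x, z, w, y))
    if GAP in (x, z, w, y):
        return 1.0
    if z == x:
        return 1.0 - float(params.psi[w, y, x].sum())
    return float(params.psi[w, y, x, z])


def normalize_context_model(params: ContextModelParams) -> ContextModelParams:
    """Scale each context so one substitution per base is expected per unit
    of time: sum_x sum_{z != x} f_wxy psi(x->z|wy) = 1 for every (w, y).

    Idempotent; preserves within-context psi ratios.  Raises if a context
    carries zero total substitution mass.
    """
    psi = params.psi.copy()
    f = params.context_frequencies
    mass = np.einsum("wyx,wyxz->wy", f, psi)
    if np.any(mass <= 0):
        bad = np.argwhere(mass <= 0)[0]
        raise ValueError(f"context {tuple(bad)} has zero substitution mass; cannot scale")
    psi /= mass[:, :, None, None]
    return replace(params, psi=psi)


def count_free_parameters(model: str, *, order: int = 1, strand_symmetric: bool = False) -> int:
    """Exact count of free continuous substitution parameters (branch
    lengths and root chain excluded).

    ``model`` is one of ``"gtr"`` (5 exchangeabilities + 3 frequencies),
    ``"context"`` (first-order: 192 psi entries, 96 under strand symmetry),
    or ``"single-context"`` (one unrestricted 12-entry substitution block).
    """
    if model == "gtr":
        return 5 + 3
    if model == "single-context":
        return 12
    if model == "context":
        if order != 1:
            raise ValueError("only the first-order context model is supported")
        return 96 if strand_symmetric else 192
    raise ValueError(f"unknown model class: {model!r}")


# ---------------------------------------------------------------------------
# Root Markov chains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RootMarkovChain:
    """Markov chain of order 0, 1 or 2 along the ancestral root sequence.

    ``transitions`` is the highest-order conditional table:
    shape (4,) for order 0, (4, 4) (``[v, x]``) for order 1,
    (4, 4, 4) (``[v, w, x]``, ``v`` two back, ``w`` one back) for order 2.
    Leading positions with insufficient history use the explicit
    lower-order ``initial`` distributions.
    """

    order: int
    transitions: np.ndarray
    initial: tuple = ()

    def __post_init__(self):
        tr = np.asarray(self.transitions, dtype=float)
        expected = {0: (4,), 1: (4, 4), 2: (4, 4, 4)}
        if self.order not in expected:
            raise ValueError("order must be 0, 1 or 2")
        if tr.shape != expected[self.order]:
            raise ValueError(f"transitions shape {tr.shape} wrong for order {self.order}")
        for idx in np.ndindex(tr.shape[:-1]):
            _check_simplex(tr[idx], f"transitions[{idx}]")
        object.__setattr__(self, "transitions", tr / tr.sum(axis=-1, keepdims=True))
        init = tuple(np.asarray(a, dtype=float) for a in self.initial)
        if len(init) != self.order:
            raise ValueError(f"order {self.order} chain needs {self.order} initial distributions")
        shapes = [(4,), (4, 4)]
        for k, a in enumerate(init):
            if a.shape != shapes[k]:
                raise ValueError(f"initial[{k}] must have shape {shapes[k]}")
            for idx in np.ndindex(a.shape[:-1]):
                _check_simplex(a[idx], f"initial[{k}][{idx}]")
        object.__setattr__(self, "initial", tuple(a / a.sum(axis=-1, keepdims=True) for a in init))

    @classmethod
    def uniform(cls, order: int) -> "RootMarkovChain":
        shapes = {0: (4,), 1: (4, 4), 2: (4, 4, 4)}
        init = [np.full((4,), 0.25), np.full((4, 4), 0.25)][: order]
        return cls(order, np.full(shapes[order], 0.25), tuple(init))

    @classmethod
    def random_from_prior(cls, rng: np.random.Generator, order: int) -> "RootMarkovChain":
        shapes = {0: (4,), 1: (4, 4), 2: (4, 4, 4)}
        tr = rng.dirichlet(np.ones(4), size=shapes[order][:-1]).reshape(shapes[order])
        init = []
        if order >= 1:
            init.append(rng.dirichlet(np.ones(4)))
        if order >= 2:
            init.append(rng.dirichlet(np.ones(4), size=4))
        return cls(order, tr, tuple(init))

    def n_simplex_blocks(self) -> int:
        """Number of independent conditional distributions (for priors and
        update-cycle bookkeeping)."""
        return {0: 1, 1: 1 + 4, 2: 1 + 4 + 16}[self.order]

    def log_prob_at(self, seq: np.ndarray, i: int) -> float:
        """Log contribution of position ``i``; gaps in the focal base or any
        conditioning base contribute 0."""
        x = seq[i]
        if x == GAP:
            return 0.0
        if self.order == 0:
            return math.log(self.transitions[x])
        if self.order == 1:
            if i == 0:
                return math.log(self.initial[0][x])
            v = seq[i - 1]
            return 0.0 if v == GAP else math.log(self.transitions[v, x])
        # order 2
        if i == 0:
            return math.log(self.initial[0][x])
        if i == 1:
            v = seq[0]
            return 0.0 if v == GAP else math.log(self.initial[1][v, x])
        v, w = seq[i - 2], seq[i - 1]
        if v == GAP or w == GAP:
            return 0.0
        return math.log(self.transitions[v, w, x])


def root_log_prob(chain: RootMarkovChain, sequence) -> float:
    """Log probability of a gapped root sequence under the chain.

    Gap positions (focal or conditioning) contribute log 1 = 0; leading
    positions use the chain's initial distributions.
    """
    seq = np.asarray([encode_base(b) for b in sequence], dtype=np.int8)
    if seq.size == 0:
        raise ValueError("empty sequence")
    return float(sum(chain.log_prob_at(seq, i) for i in range(seq.size)))


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------


def flat_dirichlet_log_density(dim: int) -> float:
    """Log density of the flat Dirichlet on a dim-simplex: log Gamma(dim)."""
    return math.lgamma(dim)


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the joint prior.

    Branch lengths are iid Exponential with mean ``mu`` given the
    hyperparameter ``mu``, which carries an inverse-gamma(shape, scale)
    hyperprior (defaults 2.1, 1.1).  Every frequency/probability simplex
    block carries a flat Dirichlet of matching dimension.
    """

    invgamma_shape: float = 2.1
    invgamma_scale: float = 1.1
    gtr_rate_mean: float = 1.0  # Exponential mean for the 5 free GTR rates

    def mu_log_prior(self, mu: float) -> float:
        if mu <= 0:
            return -math.inf
        return float(invgamma.logpdf(mu, a=self.invgamma_shape, scale=self.invgamma_scale))

    def branch_lengths_log_prior(self, branch_lengths, mu: float) -> float:
        t = np.asarray(branch_lengths, dtype=float)
        if mu <= 0 or np.any(t < 0):
            return -math.inf
        return float(-t.size * math.log(mu) - t.sum() / mu)

    def gtr_rates_log_prior(self, rates) -> float:
        r = np.asarray(rates, dtype=float)
        if np.any(r < 0):
            return -math.inf
        m = self.gtr_rate_mean
        return float(-r.size * math.log(m) - r.sum() / m)


def _context_prior_log_density(params: ContextModelParams) -> float:
    total = 0.0
    for (w, y, mirror) in canonical_contexts(params.strand_symmetric):
        self_comp = params.strand_symmetric and mirror is None
        total += flat_dirichlet_log_density(6 if self_comp else 12)
        total += flat_dirichlet_log_density(4)  # the context's f simplex
    return total


def prior_log_density(state, config: PriorConfig) -> float:
    """Joint log prior density of a model state.

    Sums exponential terms for each branch length given mu, the
    inverse-gamma hyperprior on mu, flat-Dirichlet constants for every
    simplex block present, and exponential terms for free GTR rates.
    Out-of-support parameters yield ``-inf`` (never an exception).
    """
    total = 0.0
    mu = getattr(state, "mu", None)
    if mu is not None:
        total += config.mu_log_prior(mu)
        t = getattr(state, "branch_lengths", None)
        if t is not None:
            total += config.branch_lengths_log_prior(t, mu)
    gtr = getattr(state, "gtr", None)
    if gtr is not None:
        total += config.gtr_rates_log_prior(gtr.exchangeabilities)
        total += flat_dirichlet_log_density(4)
    context = getattr(state, "context", None)
    if context is not None:
        total += _context_prior_log_density(context)
    chain = getattr(state, "root_chain", None)
    if chain is not None:
        total += chain.n_simplex_blocks() * flat_dirichlet_log_density(4)
    return total
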