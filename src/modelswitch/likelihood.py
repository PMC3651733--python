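"""Likelihood evaluation and the power-posterior kernel.

The GTR reference model is evaluated by Felsenstein pruning (gaps are
missing data).  The context-dependent model is evaluated on an augmented
state carrying explicit ancestral sequences at every internal node: the
likelihood then factorizes into the root-chain probability of the root
sequence and, per branch and site, the probability that the parent base
mutates to the child base given the parent's immediate neighbors (which are
assumed to stay constant across a branch).  A site is skipped (factor 1)
whenever any base entering its factor is a gap, including the missing
neighbors at the two sequence ends.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import dendropy
import numpy as np

from .models import (
    GAP,
    ALPHABET,
    ContextModelParams,
    GTRParams,
    PriorConfig,
    RootMarkovChain,
    gtr_transition_probs,
    prior_log_density,
)

__all__ = [
    "Alignment",
    "PhyloTree",
    "AugmentedState",
    "ModelState",
    "PowerPosteriorKernel",
    "gtr_tree_loglik",
    "gtr_complete_loglik",
    "gtr_branch_log_matrix",
    "context_loglik",
    "context_branch_log_table",
    "compute_U",
    "power_log_kernel",
    "ancestral_gap_mask",
]

LOG4 = math.log(4.0)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


class Alignment:
    """A gapped nucleotide alignment: labels plus an int8 matrix (A=0..T=3,
    gap=4)."""

    def __init__(self, labels, matrix):
        self.labels = list(labels)
        self.matrix = np.asarray(matrix, dtype=np.int8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.labels):
            raise ValueError("matrix must have one row per label")
        if self.matrix.shape[1] == 0:
            raise ValueError("zero-length alignment")
        if self.matrix.min() < 0 or self.matrix.max() > GAP:
            raise ValueError("alignment codes must lie in 0..4")

    @classmethod
    def from_sequences(cls, records: dict) -> "Alignment":
        labels = list(records)
        lengths = {len(s) for s in records.values()}
        if len(lengths) != 1:
            raise ValueError("ragged alignment: sequences differ in length")
        matrix = np.array(
            [[ALPHABET.index(c.upper()) for c in records[l]] for l in labels], dtype=np.int8
        )
        return cls(labels, matrix)

    @property
    def n_sequences(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def sequence_str(self, label: str) -> str:
        row = self.matrix[self.labels.index(label)]
        return "".join(ALPHABET[b] for b in row)


class PhyloTree:
    """A fixed rooted topology as flat arrays (tips first, root last).

    ``parent[i]`` is the parent node index (-1 for the root);
    ``branch_lengths[i]`` is the length of the branch above node ``i``
    (nan for the root); ``postorder`` visits children before parents.
    """

    def __init__(self, parent, branch_lengths, tip_labels):
        self.parent = np.asarray(parent, dtype=int)
        self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        self.tip_labels = list(tip_labels)
        n = self.parent.size
        self.n_nodes = n
        self.n_tips = len(self.tip_labels)
        self.children = [[] for _ in range(n)]
        root = None
        for i, p in enumerate(self.parent):
            if p < 0:
                if root is not None:
                    raise ValueError("multiple roots")
                root = i
            else:
                self.children[p].append(i)
        if root is None:
            raise ValueError("no root")
        self.root = root
        order, stack = [], [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        self.postorder = np.array(order[::-1], dtype=int)
        if sorted(order) != list(range(n)):
            raise ValueError("tree is not connected")

    @property
    def internal_nodes(self) -> np.ndarray:
        return np.arange(self.n_tips, self.n_nodes)

    @property
    def branch_nodes(self) -> np.ndarray:
        """Every node below a branch (all nodes except the root)."""
        return np.array([i for i in range(self.n_nodes) if i != self.root])

    @classmethod
    def from_newick(cls, newick: str, default_branch_length: float = 1.0) -> "PhyloTree":
        """Parse a rooted Newick string; missing branch lengths default to
        the prior mean of the branch-length distribution (1.0)."""
        try:
            dt = dendropy.Tree.get(
                data=newick, schema="newick", suppress_internal_node_taxa=True
            )
        except Exception as e:  # dendropy raises its own error hierarchy
            raise ValueError(f"unparseable Newick: {e}") from e
        leaves = [lf for lf in dt.leaf_node_iter()]
        labels = [lf.taxon.label for lf in leaves]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels in tree")
        internals = [nd for nd in dt.postorder_node_iter() if not nd.is_leaf()]
        index = {id(nd): k for k, nd in enumerate(leaves)}
        for k, nd in enumerate(internals):
            index[id(nd)] = len(leaves) + k
        n = len(leaves) + len(internals)
        parent = np.full(n, -1, dtype=int)
        bl = np.full(n, np.nan)
        for nd in dt.preorder_node_iter():
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                bl[i] = (
                    nd.edge.length if nd.edge.length is not None else default_branch_length
                )
        return cls(parent, bl, labels)

    def to_newick(self, branch_lengths: Optional[np.ndarray] = None) -> str:
        bl = self.branch_lengths if branch_lengths is None else branch_lengths

        def rec(v):
            if v < self.n_tips:
                core = self.tip_labels[v]
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if v == self.root:
                return core
            return f"{core}:{bl[v]:.10g}"

        return rec(self.root) + ";"

    def topology_id(self) -> str:
        """Tip-order-independent canonical form of the topology (no branch
        lengths), usable as a stable hash."""

        def rec(v):
            if v < self.n_tips:
                return self.tip_labels[v]
            return "(" + ",".join(sorted(rec(c) for c in self.children[v])) + ")"

        return rec(self.root)

    def tip_permutation(self, labels) -> np.ndarray:
        """Row order mapping alignment labels onto tip indices."""
        try:
            return np.array([list(labels).index(l) for l in self.tip_labels])
        except ValueError as e:
            raise ValueError(f"tree/alignment label mismatch: {e}") from e


def ancestral_gap_mask(tree: PhyloTree, alignment: Alignment) -> np.ndarray:
    """Gap pattern for internal nodes: a site is a gap at an internal node
    iff every descendant tip is gapped at that site."""
    perm = tree.tip_permutation(alignment.labels)
    gap = np.zeros((tree.n_nodes, alignment.length), dtype=bool)
    gap[: tree.n_tips] = alignment.matrix[perm] == GAP
    for v in tree.postorder:
        if v >= tree.n_tips:
            gap[v] = np.all([gap[c] for c in tree.children[v]], axis=0)
    return gap[tree.n_tips :]


@dataclass
class AugmentedState:
    """Explicit ancestral sequences, one per internal node (root included),
    stored as an int8 matrix of shape (n_internal, alignment length)."""

    sequences: np.ndarray

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise ValueError("ancestral sequences must form a 2-D matrix")
        if self.sequences.min() < 0 or self.sequences.max() > GAP:
            raise ValueError("ancestral codes must lie in 0..4")

    def sequence_for(self, tree: PhyloTree, node: int) -> np.ndarray:
        if node < tree.n_tips:
            raise ValueError("tips are data, not augmented state")
        return self.sequences[node - tree.n_tips]

    @classmethod
    def random(
        cls, tree: PhyloTree, alignment: Alignment, rng: np.random.Generator
    ) -> "AugmentedState":
        """Uniform random non-gap bases, gap pattern inherited column-wise."""
        gaps = ancestral_gap_mask(tree, alignment)
        seqs = rng.integers(0, 4, size=gaps.shape).astype(np.int8)
        seqs[gaps] = GAP
        return cls(seqs)


@dataclass
class ModelState:
    """All parameters of a model pair on the shared path: both substitution
    blocks, the root chain, shared branch lengths and hyperparameter mu,
    and the augmented ancestral sequences of the context model."""

    gtr: GTRParams
    context: ContextModelParams
    root_chain: RootMarkovChain
    branch_lengths: np.ndarray
    mu: float
    aug: AugmentedState

    def copy(self) -> "ModelState":
        return replace(
            self,
            branch_lengths=self.branch_lengths.copy(),
            aug=AugmentedState(self.aug.sequences.copy()),
        )


# ---------------------------------------------------------------------------
# GTR pruning likelihood
# ---------------------------------------------------------------------------


def gtr_tree_loglik(alignment: Alignment, tree: PhyloTree, params: GTRParams) -> float:
    """Pruned log likelihood of the alignment under GTR; a gap at a tip is
    missing data (partial vector of ones); the root uses the stationary
    base frequencies."""
    perm = tree.tip_permutation(alignment.labels)
    data = alignment.matrix[perm]
    L = alignment.length
    partials = {}
    log_scale = np.zeros(L)
    # spectral decomposition of the reversible rate matrix (real by
    # similarity to a symmetric matrix) gives all branch matrices cheaply;
    # eigenvalues are clamped at 0, their exact upper bound
    pi = params.base_frequencies
    d = np.sqrt(np.maximum(pi, 1e-300))
    B = params.rate_matrix() * (d[:, None] / d[None, :])
    lam, V = np.linalg.eigh(0.5 * (B + B.T))
    lam = np.minimum(lam, 0.0)
    A, Bm = V / d[:, None], V.T * d[None, :]
    mats = {
        v: np.maximum(A @ (np.exp(lam * float(tree.branch_lengths[v]))[:, None] * Bm), 0.0)
        for v in tree.branch_nodes
    }
    for v in tree.postorder:
        if v < tree.n_tips:
            part = np.zeros((4, L))
            row = data[v]
            nz = row != GAP
            part[:, ~nz] = 1.0
            part[row[nz], np.flatnonzero(nz)] = 1.0
            partials[v] = part
        else:
            part = np.ones((4, L))
            for c in tree.children[v]:
                part *= mats[c] @ partials.pop(c)
            peak = part.max(axis=0)
            peak[peak == 0] = 1.0
            log_scale += np.log(peak)
            partials[v] = part / peak
    root_part = partials[tree.root]
    site_lik = params.base_frequencies @ root_part
    with np.errstate(divide="ignore"):
        out = float(np.sum(np.log(site_lik)) + log_scale.sum())
    return out if not math.isnan(out) else -math.inf


def gtr_branch_log_matrix(params: GTRParams, t: float) -> np.ndarray:
    """Log transition matrix over one branch under GTR."""
    with np.errstate(divide="ignore"):
        return np.log(gtr_transition_probs(params, t))


def gtr_complete_loglik(
    alignment: Alignment, tree: PhyloTree, params: GTRParams, aug: AugmentedState
) -> float:
    """Complete-data GTR log likelihood of tips plus augmented ancestral
    sequences: stationary-frequency root term plus per-branch, per-site
    transition factors (gaps contribute factor 1).

    Summing its exponential over all ancestral assignments recovers the
    pruned marginal :func:`gtr_tree_loglik` exactly, which is what makes
    the augmented model-switch path terminate at the GTR marginal
    likelihood.
    """
    perm = tree.tip_permutation(alignment.labels)
    data = alignment.matrix[perm]

    def seq_of(v):
        return data[v] if v < tree.n_tips else aug.sequences[v - tree.n_tips]

    with np.errstate(divide="ignore"):
        log_pi = np.log(params.base_frequencies)
    root_seq = seq_of(tree.root)
    total = float(log_pi[root_seq[root_seq != GAP]].sum())
    for v in tree.branch_nodes:
        logP = gtr_branch_log_matrix(params, float(tree.branch_lengths[v]))
        p, c = seq_of(tree.parent[v]), seq_of(v)
        ok = (p != GAP) & (c != GAP)
        total += float(logP[p[ok], c[ok]].sum())
    return total


# ---------------------------------------------------------------------------
# Context-dependent augmented likelihood
# ---------------------------------------------------------------------------


def context_branch_log_table(params, t: float, floor: float = 1e-12) -> np.ndarray:
    """Log substitution probabilities over a branch of length ``t``.

    psi is a per-unit-time substitution probability; across a branch the
    off-diagonal probability is ``t * psi`` with the row truncated
    (rescaled to ``1 - floor``) whenever the summed substitution
    probability would exceed 1, keeping each row a valid distribution.
    ``params`` is a :class:`ContextModelParams` (normalized) or a bare
    (4,4,4,4) psi array.  Index order ``[w, y, x, z]``; the diagonal holds
    the no-substitution completion.
    """
    if t < 0:
        raise ValueError("negative branch length")
    psi = params.psi if isinstance(params, ContextModelParams) else np.asarray(params)
    p = psi * t
    total = p.sum(axis=-1)  # (4,4,4): per (w,y,x) substitution mass
    over = total > 1.0 - floor
    if np.any(over):
        scale = np.where(over, (1.0 - floor) / np.where(total > 0, total, 1.0), 1.0)
        p = p * scale[..., None]
    table = p.copy()
    diag = 1.0 - p.sum(axis=-1)
    for x in range(4):
        table[:, :, x, x] = diag[:, :, x]
    with np.errstate(divide="ignore"):
        return np.log(np.maximum(table, 0.0))


def branch_site_log_factors(
    log_table: np.ndarray, parent_seq: np.ndarray, child_seq: np.ndarray
) -> np.ndarray:
    """Per-site log factors for one branch: log psi_t(x -> z | w y) with
    (w, x, y) read from the parent at sites (i-1, i, i+1) and z from the
    child at site i.  Any gap involved (including the missing neighbors at
    the sequence ends) gives log 1 = 0."""
    L = parent_seq.size
    w = np.empty(L, dtype=np.int8)
    y = np.empty(L, dtype=np.int8)
    w[0], w[1:] = GAP, parent_seq[:-1]
    y[-1], y[:-1] = GAP, parent_seq[1:]
    x, z = parent_seq, child_seq
    ok = (w != GAP) & (y != GAP) & (x != GAP) & (z != GAP)
    out = np.zeros(L)
    out[ok] = log_table[w[ok], y[ok], x[ok], z[ok]]
    return out


def _root_chain_log_prob_vec(chain: RootMarkovChain, seq: np.ndarray) -> float:
    """Vectorized root-chain log probability of an encoded sequence."""
    L = seq.size
    total = 0.0
    if chain.order == 0:
        ok = seq != GAP
        total = float(np.log(chain.transitions[seq[ok]]).sum())
        return total
    if chain.order == 1:
        if seq[0] != GAP:
            total += math.log(chain.initial[0][seq[0]])
        v, x = seq[:-1], seq[1:]
        ok = (v != GAP) & (x != GAP)
        total += float(np.log(chain.transitions[v[ok], x[ok]]).sum())
        return total
    # order 2
    if seq[0] != GAP:
        total += math.log(chain.initial[0][seq[0]])
    if L > 1 and seq[1] != GAP and seq[0] != GAP:
        total += math.log(chain.initial[1][seq[0], seq[1]])
    if L > 2:
        v, w, x = seq[:-2], seq[1:-1], seq[2:]
        ok = (v != GAP) & (w != GAP) & (x != GAP)
        total += float(np.log(chain.transitions[v[ok], w[ok], x[ok]]).sum())
    return total


def context_loglik(
    alignment: Alignment,
    tree: PhyloTree,
    params: ContextModelParams,
    chain: RootMarkovChain,
    aug: AugmentedState,
) -> float:
    """Complete-data log likelihood of the context model: root-chain
    probability of the augmented root sequence plus, over all branches and
    sites, the log branch substitution factors."""
    if aug.sequences.shape != (tree.n_nodes - tree.n_tips, alignment.length):
        raise ValueError("augmented state does not cover the internal nodes")
    perm = tree.tip_permutation(alignment.labels)
    data = alignment.matrix[perm]

    def seq_of(v):
        return data[v] if v < tree.n_tips else aug.sequences[v - tree.n_tips]

    total = _root_chain_log_prob_vec(chain, seq_of(tree.root))
    tables = {}
    for v in tree.branch_nodes:
        t = float(tree.branch_lengths[v])
        key = t
        if key not in tables:
            tables[key] = context_branch_log_table(params, t)
        total += float(
            branch_site_log_factors(tables[key], seq_of(tree.parent[v]), seq_of(v)).sum()
        )
    return total


# ---------------------------------------------------------------------------
# Power-posterior kernel
# ---------------------------------------------------------------------------


@dataclass
class PowerPosteriorKernel:
    """Geometric interpolation between two posterior kernels sharing data:
    q_beta = [f0 Pi0]^(1-beta) [f1 Pi1]^beta.

    ``model_0`` and ``model_1`` are objects exposing
    ``log_likelihood(state)`` and ``log_prior(state)``.
    """

    model_0: object
    model_1: object
    beta: float

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")

    def log_kernel_0(self, state) -> float:
        return self.model_0.log_likelihood(state) + self.model_0.log_prior(state)

    def log_kernel_1(self, state) -> float:
        return self.model_1.log_likelihood(state) + self.model_1.log_prior(state)


def compute_U(state, model_0, model_1) -> float:
    """Potential U = log f1 + log Pi1 - log f0 - log Pi0 at a state.

    A state outside either support yields a signed infinity (or nan when
    outside both), never an exception.
    """
    k1 = model_1.log_likelihood(state) + model_1.log_prior(state)
    k0 = model_0.log_likelihood(state) + model_0.log_prior(state)
    return k1 - k0


def power_log_kernel(kernel: PowerPosteriorKernel, state) -> float:
    """Log unnormalized power-posterior density:
    (1-beta)(loglik0 + logprior0) + beta(loglik1 + logprior1)."""
    b = kernel.beta
    if b == 0.0:
        return kernel.log_kernel_0(state)
    if b == 1.0:
        return kernel.log_kernel_1(state)
    return (1.0 - b) * kernel.log_kernel_0(state) + b * kernel.log_kernel_1(state)


# ---------------------------------------------------------------------------
# The two sides of the phylogenetic model-switch path
# ---------------------------------------------------------------------------


class GTRSideModel:
    """M0 on the joint path: GTR evaluated on the augmented complete data
    (tips plus ancestral sequences), so both models see the same set of
    likelihood contributions.  Marginalizing the ancestral block recovers
    the pruned GTR likelihood exactly, hence the beta = 0 normalizing
    constant of the path is the GTR marginal likelihood."""

    def __init__(self, alignment: Alignment, tree: PhyloTree, prior: PriorConfig):
        self.alignment = alignment
        self.tree = tree
        self.prior = prior

    def log_likelihood(self, state: ModelState) -> float:
        tree = _with_lengths(self.tree, state.branch_lengths)
        return gtr_complete_loglik(self.alignment, tree, state.gtr, state.aug)

    def log_prior(self, state: ModelState) -> float:
        return prior_log_density(state, self.prior)


class ContextSideModel:
    """M1 on the joint path: augmented complete-data likelihood of the
    context-dependent model (the ancestral block's distribution lives in
    the likelihood, so the endpoint normalizing constant is the context
    model's marginal likelihood)."""

    def __init__(self, alignment: Alignment, tree: PhyloTree, prior: PriorConfig):
        self.alignment = alignment
        self.tree = tree
        self.prior = prior

    def log_likelihood(self, state: ModelState) -> float:
        tree = _with_lengths(self.tree, state.branch_lengths)
        return context_loglik(self.alignment, tree, state.context, state.root_chain, state.aug)

    def log_prior(self, state: ModelState) -> float:
        return prior_log_density(state, self.prior)


def _with_lengths(tree: PhyloTree, branch_lengths: np.ndarray) -> PhyloTree:
    """A shallow view of the tree with branch lengths taken from the state
    (indexed by branch node)."""
    out = object.__new__(PhyloTree)
    out.__dict__.update(tree.__dict__)
    bl = np.full(tree.n_nodes, np.nan)
    bl[tree.branch_nodes] = branch_lengths
    out.branch_lengths = bl
    return out
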