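"""Power-posterior beta grids: constant, flexible-increment and sigmoid.

A schedule is an ordered grid 0 = beta_0 < ... < beta_K = 1 together with
the chain length Q per step, a traversal direction (annealing: 0 -> 1,
melting: 1 -> 0), and optional interior split boundaries that decompose
the integration interval for parallel runs and for the bidirectional
(repeatability) error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Schedule",
    "constant_schedule",
    "sigmoid_schedule",
    "flexible_schedule",
    "split_contributions",
]

ANNEALING = "annealing"
MELTING = "melting"


@dataclass(frozen=True)
class Schedule:
    """An ordered beta grid with direction, per-step chain length and splits.

    ``betas`` is always stored ascending; ``direction`` determines the
    traversal order used by the sampler.  ``splits`` holds the interior
    split boundaries (values of beta, each lying exactly on the grid).
    """

    betas: np.ndarray
    Q: int
    direction: str = ANNEALING
    kind: str = "constant"
    alpha: float | None = None
    splits: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        b = np.asarray(self.betas, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValueError("schedule needs at least 2 grid points")
        if b[0] != 0.0 or b[-1] != 1.0:
            raise ValueError("beta grid must start at exactly 0 and end at exactly 1")
        if np.any(np.diff(b) <= 0):
            raise ValueError("beta grid must be strictly increasing")
        if self.Q < 1:
            raise ValueError("Q must be >= 1")
        if self.direction not in (ANNEALING, MELTING):
            raise ValueError(f"unknown direction {self.direction!r}")
        s = np.asarray(self.splits, dtype=float)
        if np.any((s <= 0.0) | (s >= 1.0)):
            raise ValueError("split boundaries must lie strictly inside (0,1)")
        if np.any(np.diff(s) <= 0):
            raise ValueError("split boundaries must be strictly increasing")
        for v in s:
            if not np.any(b == v):
                raise ValueError(f"split boundary {v} is not on the beta grid")
        object.__setattr__(self, "betas", b)
        object.__setattr__(self, "splits", s)

    @property
    def K(self) -> int:
        """Number of steps (grid has K+1 points)."""
        return self.betas.size - 1

    @property
    def traversal(self) -> np.ndarray:
        """The beta sequence in visiting order for this direction."""
        return self.betas if self.direction == ANNEALING else self.betas[::-1]

    def reversed(self) -> "Schedule":
        """Same grid, opposite traversal direction."""
        other = MELTING if self.direction == ANNEALING else ANNEALING
        return replace(self, direction=other)

    def split_step_slices(self):
        """Slices of step indices (0..K-1) covered by each split interval."""
        bounds = np.concatenate([[0.0], self.splits, [1.0]])
        idx = [int(np.flatnonzero(self.betas == v)[0]) for v in bounds]
        return [slice(idx[j], idx[j + 1]) for j in range(len(idx) - 1)]


def _index_splits(betas: np.ndarray, n_splits: int) -> np.ndarray:
    """Interior boundaries dividing the grid into n_splits groups of steps,
    equal in step index (equal work per node)."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    K = betas.size - 1
    if n_splits > K:
        raise ValueError("more splits than steps")
    idx = np.unique(np.round(np.arange(1, n_splits) * K / n_splits).astype(int))
    idx = idx[(idx > 0) & (idx < K)]
    return betas[idx]


def constant_schedule(
    K: int, Q: int, *, direction: str = ANNEALING, n_splits: int = 1
) -> Schedule:
    """Constant-increment grid beta_k = k / K."""
    if K < 1:
        raise ValueError("K must be >= 1")
    betas = np.arange(K + 1) / K
    betas[0], betas[-1] = 0.0, 1.0
    return Schedule(betas, Q, direction, "constant", splits=_index_splits(betas, n_splits))


def sigmoid_schedule(
    K: int, Q: int, alpha: float, *, direction: str = ANNEALING, n_splits: int = 1
) -> Schedule:
    """Sigmoid grid: beta_k = (g(k/K) - g(0)) / (g(1) - g(0)) with
    g(u) = 1 / (1 + exp(-alpha (2u - 1))).

    Larger ``alpha`` concentrates grid points near both endpoints, where the
    power posterior approaches one model's prior-dominated kernel and changes
    fastest.  The grid is symmetric: beta_{K-k} = 1 - beta_k exactly.
    """
    if K < 2:
        raise ValueError("K must be >= 2 for a sigmoid grid")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")

    def g(u):
        return 1.0 / (1.0 + np.exp(-alpha * (2.0 * u - 1.0)))

    k = np.arange(K + 1)
    lower = k[k <= K // 2]
    b = np.empty(K + 1)
    b[lower] = (g(lower / K) - g(0.0)) / (g(1.0) - g(0.0))
    b[K - lower] = 1.0 - b[lower]  # enforce exact symmetry
    if K % 2 == 0:
        b[K // 2] = 0.5
    b[0], b[-1] = 0.0, 1.0
    if np.any(np.diff(b) <= 0):
        raise ValueError("sigmoid grid degenerated (alpha too large for this K)")
    return Schedule(b, Q, direction, "sigmoid", alpha, splits=_index_splits(b, n_splits))


def flexible_schedule(
    interval_boundaries,
    per_interval_K,
    Q: int,
    *,
    direction: str = ANNEALING,
    record_splits: bool = True,
) -> Schedule:
    """Piecewise-uniform grid: each interval [a_i, a_{i+1}] of the supplied
    partition of [0,1] uses its own constant increment (a_{i+1}-a_i)/K_i.

    Interval boundaries are recorded as split boundaries, matching their use
    for distributing the integration across nodes.
    """
    bounds = np.asarray(interval_boundaries, dtype=float)
    Ks = np.asarray(per_interval_K, dtype=int)
    if bounds.ndim != 1 or bounds.size < 2:
        raise ValueError("need at least one interval")
    if bounds[0] != 0.0 or bounds[-1] != 1.0 or np.any(np.diff(bounds) <= 0):
        raise ValueError("interval boundaries must partition [0,1] in increasing order")
    if Ks.size != bounds.size - 1 or np.any(Ks < 1):
        raise ValueError("need one K >= 1 per interval")
    pieces = [np.array([0.0])]
    for a, b, Ki in zip(bounds[:-1], bounds[1:], Ks):
        piece = a + (b - a) * (np.arange(1, Ki + 1) / Ki)
        piece[-1] = b  # interval boundaries sit on the grid exactly
        pieces.append(piece)
    betas = np.concatenate(pieces)
    betas[-1] = 1.0
    splits = bounds[1:-1] if record_splits else np.empty(0)
    return Schedule(betas, Q, direction, "flexible", splits=splits)


def split_contributions(trace, schedule: Schedule, method: str | None = None) -> np.ndarray:
    """Per-split-interval contributions of a path trace to the log Bayes
    factor; their sum equals the whole-path estimate exactly.

    ``method`` is one of ``"ps"``, ``"ps_mean"``, ``"ss"`` (default: the
    estimator matching ``trace.mode``).
    """
    from . import estimators  # local import: estimators builds on traces

    if method is None:
        method = {"classic": "ps", "mean": "ps_mean", "ss": "ss"}[trace.mode]
    per_step = estimators.per_step_contributions(trace, method=method)
    if per_step.size != schedule.K:
        raise ValueError("trace does not cover this schedule's grid")
    return np.array([per_step[sl].sum() for sl in schedule.split_step_slices()])
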