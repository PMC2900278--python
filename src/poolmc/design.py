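"""Expander-graph pooling designs.

A pooling design is an m x n binary matrix Phi: rows are pools (chips),
columns are samples, and a 1 in row i, column j means sample j is mixed
into pool i.  Phi is the adjacency matrix of a left-d-regular bipartite
graph with samples on the left and pools on the right.  The design is a
(k, eps)-unbalanced expander when every left subset X with |X| <= k has
at least (1 - eps) * d * |X| distinct pool neighbours; this expansion
property is what makes sparse profiles decodable from the pooled
measurements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoolingDesign",
    "ExpansionReport",
    "build_design",
    "verify_expansion",
    "design_for_guarantee",
    "chips_needed",
    "DEFAULT_SUBSET_BUDGET",
]

#: Maximum number of left subsets verify_expansion will enumerate before
#: refusing (no silent sampling).
DEFAULT_SUBSET_BUDGET = 10**6


@dataclass
class PoolingDesign:
    """An m x n binary pooling matrix with its construction parameters.

    Attributes
    ----------
    matrix : ndarray of shape (n_pools, n_samples)
        Binary; entry 1 means the sample (column) is present in the
        pool (row).
    left_degree : int
        Number of pools each sample appears in (ones per column).
    guarantee_k : int
        Number of spikes per gene the design certifies recoverable
        (0 if never certified).
    epsilon : float
        Expansion slack used for certification, in [0, 1).
    seed : int or None
        RNG seed used in construction, for provenance.
    sample_labels, pool_labels : list of str
        Ordered identifiers for columns and rows.
    """

    matrix: np.ndarray
    left_degree: int
    guarantee_k: int = 0
    epsilon: float = 0.25
    seed: int | None = None
    sample_labels: list[str] = field(default_factory=list)
    pool_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2-dimensional")
        vals = np.unique(self.matrix)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("design matrix entries must be 0 or 1")
        self.matrix = self.matrix.astype(np.int8)
        m, n = self.matrix.shape
        colsums = self.matrix.sum(axis=0)
        if not (colsums == self.left_degree).all():
            raise ValueError(
                f"every column must have exactly d={self.left_degree} ones; "
                f"column sums range {colsums.min()}..{colsums.max()}"
            )
        if m < self.left_degree:
            raise ValueError("need n_pools >= left_degree")
        if self.guarantee_k >= 1 and self._has_duplicate_columns():
            raise ValueError("duplicate column supports invalidate any spike guarantee")
        if not self.sample_labels:
            self.sample_labels = [f"S{j + 1}" for j in range(n)]
        if not self.pool_labels:
            self.pool_labels = [f"P{i + 1}" for i in range(m)]
        if len(self.sample_labels) != n or len(self.pool_labels) != m:
            raise ValueError("label counts must match matrix shape")

    def _has_duplicate_columns(self) -> bool:
        supports = {tuple(np.flatnonzero(self.matrix[:, j])) for j in range(self.n_samples)}
        return len(supports) < self.n_samples

    @property
    def n_pools(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[1]

    def column_support(self, j: int) -> tuple[int, ...]:
        """Pool indices (0-based) that sample ``j`` is mixed into."""
        return tuple(np.flatnonzero(self.matrix[:, j]))


@dataclass
class ExpansionReport:
    """Result of exhaustively checking the expansion property.

    ``epsilon_achieved`` is the smallest slack for which expansion holds
    over all left subsets of size <= ``k_checked``:
    ``1 - min_X |N(X)| / (d |X|)``.  ``worst_set`` attains that minimum.
    """

    k_checked: int
    epsilon_achieved: float
    worst_set: tuple[int, ...]
    is_expander: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon_achieved < 1.0):
            raise ValueError("epsilon_achieved must lie in [0, 1)")
        if len(self.worst_set) > self.k_checked:
            raise ValueError("worst_set cannot exceed k_checked")


def build_design(
    n_samples: int,
    n_pools: int,
    left_degree: int,
    seed: int,
) -> PoolingDesign:
    """Draw a random left-d-regular pooling design with distinct columns.

    Each column's pool support is a uniformly random ``left_degree``-subset
    of the ``n_pools`` pools, redrawn whenever it collides with an
    already-placed column, so all column supports are pairwise distinct.
    Deterministic given ``seed``.

    Raises
    ------
    ValueError
        If fewer distinct d-subsets exist than samples requested, i.e.
        C(n_pools, left_degree) < n_samples.
    """
    if n_samples < 1:
        raise ValueError("need at least one sample")
    if not (1 <= left_degree <= n_pools):
        raise ValueError("need 1 <= left_degree <= n_pools")
    n_supports = math.comb(n_pools, left_degree)
    if n_supports < n_samples:
        raise ValueError(
            f"infeasible: only C({n_pools}, {left_degree}) = {n_supports} distinct "
            f"pool subsets exist but {n_samples} distinct columns are required"
        )
    rng = np.random.default_rng(seed)
    matrix = np.zeros((n_pools, n_samples), dtype=np.int8)
    used: set[tuple[int, ...]] = set()
    for j in range(n_samples):
        while True:
            support = tuple(sorted(rng.choice(n_pools, size=left_degree, replace=False)))
            if support not in used:
                break
        used.add(support)
        matrix[list(support), j] = 1
    return PoolingDesign(matrix=matrix, left_degree=left_degree, seed=seed)


def _neighbor_count(matrix: np.ndarray, subset: tuple[int, ...]) -> int:
    # |N(X)|: pools touched by any sample in X
    return int(np.count_nonzero(matrix[:, list(subset)].any(axis=1)))


def verify_expansion(
    design: PoolingDesign,
    k: int,
    epsilon: float = 0.25,
    subset_budget: int = DEFAULT_SUBSET_BUDGET,
) -> ExpansionReport:
    """Exhaustively certify the (k, epsilon)-expansion property.

    Enumerates every left subset X with 1 <= |X| <= k and checks
    ``|N(X)| >= (1 - epsilon) * d * |X|``.  Reports the smallest slack
    for which the design expands and the worst subset found.

    Raises
    ------
    ValueError
        If the enumeration would exceed ``subset_budget`` subsets
        (exhaustiveness is required; no sampling fallback).
    """
    if not (0 <= k <= design.n_samples):
        raise ValueError("need 0 <= k <= n_samples")
    n, d = design.n_samples, design.left_degree
    total = sum(math.comb(n, s) for s in range(1, k + 1))
    if total > subset_budget:
        raise ValueError(
            f"budget exceeded: checking k={k} on n={n} samples requires "
            f"{total} subsets > budget {subset_budget}; lower k or raise the budget"
        )
    min_ratio = 1.0
    worst: tuple[int, ...] = ()
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(n), size):
            ratio = _neighbor_count(design.matrix, subset) / (d * size)
            if ratio < min_ratio:
                min_ratio = ratio
                worst = subset
    eps_achieved = 1.0 - min_ratio
    return ExpansionReport(
        k_checked=k,
        epsilon_achieved=eps_achieved,
        worst_set=worst,
        is_expander=bool(min_ratio >= 1.0 - epsilon - 1e-12),
    )


def design_for_guarantee(
    n_samples: int,
    k: int,
    epsilon: float = 0.25,
    left_degree: int = 2,
    seed: int = 0,
    max_attempts: int = 50,
    max_pools: int | None = None,
) -> PoolingDesign:
    """Search for the smallest certified (2k, epsilon)-expander design.

    Tries m = left_degree, left_degree + 1, ... pools; at each m draws up
    to ``max_attempts`` seeded random designs and returns the first one
    that :func:`verify_expansion` certifies as a (2k, epsilon)-expander.
    The returned design carries ``guarantee_k = k``.
    """
    if max_pools is None:
        max_pools = max(2 * n_samples, left_degree)
    last_m = left_degree
    for m in range(left_degree, max_pools + 1):
        last_m = m
        if math.comb(m, left_degree) < n_samples:
            continue
        for attempt in range(max_attempts):
            candidate = build_design(n_samples, m, left_degree, seed=seed + 104729 * attempt)
            report = verify_expansion(candidate, k=min(2 * k, n_samples), epsilon=epsilon)
            if report.is_expander:
                candidate.guarantee_k = k
                candidate.epsilon = epsilon
                return candidate
    raise ValueError(
        f"no certified ({2 * k}, {epsilon})-expander found with up to "
        f"{last_m} pools and {max_attempts} attempts per size"
    )


def chips_needed(n_samples: int, k_spikes: int) -> int:
    """Approximate number of chips to recover k spikes among n samples.

    Returns the nearest integer to ``k * ln(n / k)``.  This asymptotic
    sizing rule ignores measurement noise and is a lower bound on the
    experiment size, not the exact pool count of any constructed design.
    """
    if k_spikes < 1:
        raise ValueError("k_spikes must be >= 1 (zero spikes carry no information target)")
    if k_spikes > n_samples:
        raise ValueError("k_spikes cannot exceed n_samples")
    x = k_spikes * math.log(n_samples / k_spikes)
    return int(math.floor(x + 0.5))
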