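"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive re-implementations used to
cross-check the package: set-based neighbour counting for expansion,
and exhaustive support enumeration for the basis-pursuit optimum.  They
must stay independent of the code paths they verify.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from poolmc import PoolingDesign, build_design


@pytest.fixture(scope="session")
def paper_scale_design() -> PoolingDesign:
    """A 12-pool x 15-sample, degree-2 design with distinct columns.

    Seed 0 yields a design with every pool occupied and full row rank,
    certified as a (2, 1/4)-expander in the design tests.
    """
    return build_design(n_samples=15, n_pools=12, left_degree=2, seed=0)


@pytest.fixture(scope="session")
def square_design() -> PoolingDesign:
    """4x4 degree-2 design with columns {1,2},{3,4},{1,3},{2,4} (1-based)."""
    matrix = np.array(
        [
            [1, 0, 1, 0],
            [1, 0, 0, 1],
            [0, 1, 1, 0],
            [0, 1, 0, 1],
        ]
    )
    return PoolingDesign(matrix=matrix, left_degree=2)


def brute_force_expansion(matrix: np.ndarray, k: int) -> tuple[float, tuple[int, ...]]:
    """Set-based oracle: min over |X| <= k of |N(X)| / (d |X|) and its argmin."""
    m, n = matrix.shape
    supports = [frozenset(np.flatnonzero(matrix[:, j])) for j in range(n)]
    d = len(supports[0])
    best, argmin = 1.0, ()
    for size in range(1, k + 1):
        for subset in itertools.combinations(range(n), size):
            neighbors = frozenset().union(*(supports[j] for j in subset))
            ratio = len(neighbors) / (d * size)
            if ratio < best:
                best, argmin = ratio, subset
    return best, argmin


def basis_pursuit_oracle(phi: np.ndarray, y: np.ndarray, tol: float = 1e-9) -> float:
    """Exhaustive oracle for the basis-pursuit optimum value.

    The minimum of ||z||_1 subject to Phi z = y is attained at a vertex
    of the feasible polyhedron, i.e. on a support of at most m linearly
    independent columns.  Enumerate every support up to size m, solve
    the restricted system by least squares, keep consistent solutions,
    and return the smallest l1 norm found.  Exponential — tiny inputs
    only.
    """
    m, n = phi.shape
    if np.abs(y).max(initial=0.0) <= tol:
        return 0.0
    best = np.inf
    scale = max(np.abs(y).max(), 1.0)
    for size in range(1, min(m, n) + 1):
        for support in itertools.combinations(range(n), size):
            sub = phi[:, list(support)]
            z, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.abs(sub @ z - y).max() <= tol * scale:
                best = min(best, float(np.abs(z).sum()))
    return best
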