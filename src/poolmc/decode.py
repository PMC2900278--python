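"""Forward pooling operator and the l1-minimization linear-program decoder.

For each gene the pooled experiment measures ``y = Phi x`` where ``x`` is
the gene's (unknown) expression across the n samples and ``Phi`` is the
m x n pooling design with m < n.  The decoder returns the minimum-l1-norm
profile consistent with the measurements (basis pursuit),

    minimize  sum_j |z_j|   subject to   Phi z = y,

solved as a standard linear program by splitting z into nonnegative
positive and negative parts.  When the design is a (2k, eps)-expander
and x has at most k spikes, the decoded profile equals x up to the l1
mass of x outside its k largest entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import csr_matrix, eye_array, hstack

from .design import PoolingDesign

__all__ = [
    "DecodeOptions",
    "DecodeResult",
    "DecodedMatrix",
    "pool_profile",
    "decode_profile",
    "decode_matrix",
    "estimate_baseline",
]

# decoded linear intensities can be exactly zero; floor before log2 view
_LOG2_FLOOR = 2.0**-20


@dataclass
class DecodeOptions:
    """Decoder settings.

    Attributes
    ----------
    nonnegative : bool
        Constrain the decoded profile to x >= 0.  Off by default: the
        basis-pursuit program imposes only l1-minimality and consistency,
        but expression intensities are physically nonnegative so the
        constraint is available.
    noise_tolerance : float
        delta >= 0.  With delta = 0 the measurements are matched exactly
        (equality constraints); with delta > 0 the constraint relaxes to
        sum_i |(Phi z - y)_i| <= delta for noisy measurements.
    solver_tolerance : float
        Feasibility/optimality tolerance handed to the LP solver.
    scale : "linear" or "log2"
        Scale of the input measurements.  Pooling is additive in linear
        intensity, so log2 inputs are exponentiated before decoding.
    baseline_centering : bool
        Off by default.  When on, a shared per-gene baseline b is
        estimated from the measurements (median of y_i / pool size,
        robust to a few spiked pools), the *deviation* from b is decoded
        by basis pursuit, and b is added back.  A near-constant gene is
        sparse about its median, not about zero, so this is what makes
        baseline-plus-spike profiles exactly recoverable; profiles that
        are sparse about zero need no centering.
    """

    nonnegative: bool = False
    noise_tolerance: float = 0.0
    solver_tolerance: float = 1e-8
    scale: Literal["linear", "log2"] = "linear"
    baseline_centering: bool = False

    def __post_init__(self) -> None:
        if self.noise_tolerance < 0:
            raise ValueError("noise_tolerance must be >= 0")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be > 0")
        if self.scale not in ("linear", "log2"):
            raise ValueError("scale must be 'linear' or 'log2'")


@dataclass
class DecodeResult:
    """Decoded profile for one gene with l1 diagnostics."""

    x_hat: np.ndarray
    l1_norm: float
    residual_l1: float
    status: str

    @property
    def success(self) -> bool:
        return self.status == "optimal"


@dataclass
class DecodedMatrix:
    """Gene x sample decoded expression with per-gene diagnostics.

    ``linear`` always holds linear-scale intensities; ``log2`` is the
    same matrix on log2 scale (linear values floored at 2^-20 so exact
    zeros stay finite) and is populated when the input was log2-scaled.
    """

    linear: pd.DataFrame
    log2: pd.DataFrame | None
    results: list[DecodeResult] = field(default_factory=list)


def pool_profile(
    profile: np.ndarray,
    design: PoolingDesign,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Apply the forward pooling operator: y = Phi x.

    With the default binary design each pooled measurement is the plain
    sum of its member samples, ``y_i = sum_{j in pool i} x_j``.  An
    optional ``weights`` matrix (same shape and sparsity pattern as the
    design) replaces the unit entries, e.g. to model per-sample dilution
    when each chip receives equal total mRNA mass.
    """
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (design.n_samples,):
        raise ValueError(
            f"profile length {profile.shape} does not match n_samples={design.n_samples}"
        )
    if (profile < 0).any():
        raise ValueError("expression intensities must be nonnegative")
    if weights is None:
        operator = design.matrix.astype(float)
    else:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != design.matrix.shape:
            raise ValueError("weights must match the design matrix shape")
        if ((weights != 0) != (design.matrix != 0)).any():
            raise ValueError("weights must be zero exactly where the design is zero")
        operator = weights
    return operator @ profile


def pool_weights_equal_mass(design: PoolingDesign) -> np.ndarray:
    """Row-normalized mixing weights: equal total mass per pool/chip."""
    rowsums = design.matrix.sum(axis=1).astype(float)
    if (rowsums == 0).any():
        raise ValueError("design has an empty pool")
    return design.matrix / rowsums[:, None]


def _solve_basis_pursuit(
    phi: np.ndarray, y: np.ndarray, options: DecodeOptions
) -> tuple[np.ndarray, str]:
    """Solve min ||z||_1 s.t. Phi z = y (or sum|Phi z - y| <= delta)."""
    m, n = phi.shape
    phi_s = csr_matrix(phi)
    delta = options.noise_tolerance

    if delta == 0.0:
        # variables: z+ (n) [, z- (n)]; min 1'(z+ + z-), Phi(z+ - z-) = y
        if options.nonnegative:
            a_eq, cost = phi_s, np.ones(n)
        else:
            a_eq = hstack([phi_s, -phi_s], format="csr")
            cost = np.ones(2 * n)
        res = linprog(
            cost,
            A_eq=a_eq,
            b_eq=y,
            bounds=(0, None),
            method="highs",
            options={"primal_feasibility_tolerance": options.solver_tolerance},
        )
    else:
        # extra residual split r+ (m), r- (m): Phi(z+ - z-) - (r+ - r-) = y,
        # 1'(r+ + r-) <= delta; only z contributes to the objective.
        ident = eye_array(m, format="csr")
        if options.nonnegative:
            a_eq = hstack([phi_s, -ident, ident], format="csr")
            cost = np.concatenate([np.ones(n), np.zeros(2 * m)])
            a_ub = hstack([csr_matrix((1, n)), np.ones((1, 2 * m))], format="csr")
        else:
            a_eq = hstack([phi_s, -phi_s, -ident, ident], format="csr")
            cost = np.concatenate([np.ones(2 * n), np.zeros(2 * m)])
            a_ub = hstack([csr_matrix((1, 2 * n)), np.ones((1, 2 * m))], format="csr")
        res = linprog(
            cost,
            A_eq=a_eq,
            b_eq=y,
            A_ub=a_ub,
            b_ub=np.array([delta]),
            bounds=(0, None),
            method="highs",
            options={"primal_feasibility_tolerance": options.solver_tolerance},
        )

    if not res.success:
        return np.full(n, np.nan), res.message or "infeasible"
    sol = res.x
    if options.nonnegative:
        x_hat = sol[:n]
    else:
        x_hat = sol[:n] - sol[n : 2 * n]
    return x_hat, "optimal"


def decode_profile(
    design: PoolingDesign,
    y: np.ndarray,
    options: DecodeOptions | None = None,
) -> DecodeResult:
    """Decode one gene's profile from its pooled measurements.

    Returns the minimum-l1-norm profile x_hat with ``Phi x_hat = y``
    (relaxed to an l1 residual budget when ``options.noise_tolerance``
    is positive).  When the optimum is not unique the solver's choice is
    returned; the optimum *value* (the l1 norm) is unique regardless.
    An infeasible program is reported through ``status`` rather than
    silently zero-filled.
    """
    options = options or DecodeOptions()
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_pools,):
        raise ValueError(f"measurement length {y.shape} does not match n_pools={design.n_pools}")
    if not np.isfinite(y).all():
        raise ValueError("measurements must be finite")
    phi = design.matrix.astype(float)
    if options.baseline_centering:
        # like estimate_baseline but tolerant of empty pools (a random
        # design may leave a chip unused; it carries no information)
        rowsums = design.matrix.sum(axis=1).astype(float)
        occupied = rowsums > 0
        baseline = float(np.median(y[occupied] / rowsums[occupied]))
        y_centered = y - baseline * rowsums
        # the deviation from baseline is signed, so the LP runs without
        # the nonnegativity constraint; physical nonnegativity is
        # restored on the recombined profile below
        inner = DecodeOptions(
            nonnegative=False,
            noise_tolerance=options.noise_tolerance,
            solver_tolerance=options.solver_tolerance,
            scale=options.scale,
        )
        delta_hat, status = _solve_basis_pursuit(phi, y_centered, inner)
        if status == "optimal":
            delta_hat[np.abs(delta_hat) < options.solver_tolerance] = 0.0
            x_hat = delta_hat + baseline
            if options.nonnegative:
                x_hat = np.maximum(x_hat, 0.0)
    else:
        x_hat, status = _solve_basis_pursuit(phi, y, options)
        if status == "optimal":
            # snap solver noise below tolerance to exact zero
            x_hat[np.abs(x_hat) < options.solver_tolerance] = 0.0
    if status != "optimal":
        return DecodeResult(x_hat=x_hat, l1_norm=np.nan, residual_l1=np.nan, status=status)
    return DecodeResult(
        x_hat=x_hat,
        l1_norm=float(np.abs(x_hat).sum()),
        residual_l1=float(np.abs(phi @ x_hat - y).sum()),
        status=status,
    )


def decode_matrix(
    design: PoolingDesign,
    measurements: pd.DataFrame,
    options: DecodeOptions | None = None,
) -> DecodedMatrix:
    """Decode a gene x pool measurement matrix gene-by-gene.

    Each row is decoded independently with :func:`decode_profile`; gene
    order and identifiers are preserved.  If ``options.scale`` is
    ``"log2"`` the measurements are exponentiated (base 2) before
    decoding and the result carries both linear and log2 views.  Rows
    with missing values are rejected by gene name — no imputation.
    """
    options = options or DecodeOptions()
    if measurements.shape[1] != design.n_pools:
        raise ValueError(
            f"measurements have {measurements.shape[1]} columns but the design "
            f"has {design.n_pools} pools"
        )
    na_rows = measurements.index[measurements.isna().any(axis=1)]
    if len(na_rows):
        raise ValueError(f"missing values in gene(s): {list(na_rows[:5])}")

    values = measurements.to_numpy(dtype=float)
    if options.scale == "log2":
        values = np.exp2(values)

    results: list[DecodeResult] = []
    decoded = np.empty((values.shape[0], design.n_samples))
    for i in range(values.shape[0]):
        res = decode_profile(design, values[i], options)
        results.append(res)
        decoded[i] = res.x_hat

    sample_labels = design.sample_labels
    linear = pd.DataFrame(decoded, index=measurements.index, columns=sample_labels)
    log2_view = None
    if options.scale == "log2":
        log2_view = pd.DataFrame(
            np.log2(np.maximum(decoded, _LOG2_FLOOR)),
            index=measurements.index,
            columns=sample_labels,
        )
    return DecodedMatrix(linear=linear, log2=log2_view, results=results)


def estimate_baseline(y: np.ndarray, design: PoolingDesign) -> float:
    """Median-of-ratios baseline estimate for a near-constant gene.

    For a gene expressed at a constant level c across samples, every
    pooled measurement is c times its pool size, so the median over
    pools of ``y_i / pool_size_i`` recovers c; spikes perturb only the
    few pools containing the spiked sample and the median ignores them.
    Optional diagnostic — not part of the decoding path.
    """
    y = np.asarray(y, dtype=float)
    if y.shape != (design.n_pools,):
        raise ValueError("measurement length does not match the design")
    rowsums = design.matrix.sum(axis=1).astype(float)
    if (rowsums == 0).any():
        raise ValueError("design has a pool containing no samples")
    return float(np.median(y / rowsums))
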