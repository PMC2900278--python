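"""Error metrics, sparse-recovery bound checks, and matrix concordance.

The decoding guarantee for an expander pooling design bounds the l1
distance between the true and decoded profiles by a design-dependent
constant times the l1 mass of the true profile outside its k largest
entries (the "tail").  This module computes that tail, the l1 error,
and the bound check, plus spike calling and monoplex/decoded matrix
comparisons used to score simulations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "SparsityProfile",
    "l1_error",
    "sparsity_tail",
    "check_error_bound",
    "spike_calls",
    "compare_matrices",
]


@dataclass
class SparsityProfile:
    """The k largest-magnitude entries of a profile and the l1 tail outside them."""

    k: int
    S: tuple[int, ...]
    tail_l1: float

    def __post_init__(self) -> None:
        if len(self.S) != self.k:
            raise ValueError("|S| must equal k")
        if self.tail_l1 < -1e-12:
            raise ValueError("tail_l1 must be nonnegative")
        self.tail_l1 = max(self.tail_l1, 0.0)


def l1_error(x_true: np.ndarray, x_hat: np.ndarray) -> float:
    """Sum of absolute entry-wise differences between two profiles."""
    x_true = np.asarray(x_true, dtype=float)
    x_hat = np.asarray(x_hat, dtype=float)
    if x_true.shape != x_hat.shape:
        raise ValueError(f"shape mismatch: {x_true.shape} vs {x_hat.shape}")
    return float(np.abs(x_true - x_hat).sum())


def _lower_median(x: np.ndarray) -> float:
    # deterministic tie rule: for even length take the lower of the two
    # middle order statistics
    s = np.sort(x)
    return float(s[(len(s) - 1) // 2])


def sparsity_tail(
    x: np.ndarray,
    k: int,
    center: Literal["none", "median"] = "none",
) -> SparsityProfile:
    """Identify the k dominant entries and the l1 mass left outside them.

    With ``center="median"`` deviations are measured from the profile's
    (lower) median, matching the spike picture where a near-constant
    gene is sparse about its median; with ``"none"`` magnitudes are
    taken about zero.  S holds the indices of the k largest
    |x_j - center|, ties broken toward the lowest index.
    """
    x = np.asarray(x, dtype=float)
    if not (0 <= k <= x.size):
        raise ValueError("need 0 <= k <= len(x)")
    c = _lower_median(x) if center == "median" else 0.0
    dev = np.abs(x - c)
    # stable sort on (-magnitude, index) → ties go to the lowest index
    order = np.argsort(-dev, kind="stable")
    S = tuple(int(j) for j in sorted(order[:k]))
    tail = float(dev[order[k:]].sum())
    return SparsityProfile(k=k, S=S, tail_l1=tail)


def check_error_bound(
    x_true: np.ndarray,
    x_hat: np.ndarray,
    k: int,
    C: float,
    center: Literal["none", "median"] = "none",
    abs_tolerance: float = 1e-6,
) -> tuple[bool, float]:
    """Check the expander decoding-error bound  ||x - x_hat||_1 <= C * tail_k(x).

    ``C`` is the design-dependent constant; for an exactly k-sparse
    profile the tail vanishes and the bound demands (near-)exact
    recovery, allowed up to ``abs_tolerance`` times the profile's l1
    mass for solver round-off.  Returns (holds, margin) with
    margin = bound - error.
    """
    if C <= 0:
        raise ValueError("C must be > 0")
    err = l1_error(x_true, x_hat)
    tail = sparsity_tail(x_true, k, center=center).tail_l1
    slack = abs_tolerance * max(np.abs(np.asarray(x_true, dtype=float)).sum(), 1.0)
    bound = C * tail + slack
    return bool(err <= bound), float(bound - err)


def spike_calls(x_hat: np.ndarray, threshold_log2: float = 1.0) -> list[tuple[int, int]]:
    """Call spikes in a decoded profile by log2 deviation from the median.

    An entry is called a spike when |log2(x_j + 1) - log2(median + 1)|
    meets ``threshold_log2``; the +1 keeps zero intensities finite.
    Returns (index, sign) pairs, sign +1 for up-spikes, -1 for down.
    """
    if threshold_log2 <= 0:
        raise ValueError("threshold_log2 must be > 0")
    x = np.asarray(x_hat, dtype=float)
    med = _lower_median(x)
    dev = np.log2(np.maximum(x, 0.0) + 1.0) - np.log2(max(med, 0.0) + 1.0)
    calls = []
    for j in np.flatnonzero(np.abs(dev) >= threshold_log2):
        calls.append((int(j), 1 if dev[j] > 0 else -1))
    return calls


def compare_matrices(
    reference: pd.DataFrame,
    decoded: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """Concordance between a reference (monoplex) and decoded expression matrix.

    Both matrices must share shape and labels.  Returns:

    - ``per_sample``: Pearson correlation of log2 values per sample column;
    - ``per_gene``: l1 error per gene row (linear scale);
    - ``pairs``: long-format paired table (gene, sample, reference,
      decoded) ready for scatter plots.
    """
    if reference.shape != decoded.shape:
        raise ValueError("matrices must have identical shape")
    if list(reference.index) != list(decoded.index) or list(reference.columns) != list(
        decoded.columns
    ):
        raise ValueError("matrices must share gene and sample labels")

    ref_log = np.log2(reference.to_numpy(dtype=float) + 1.0)
    dec_log = np.log2(np.maximum(decoded.to_numpy(dtype=float), 0.0) + 1.0)

    corrs = []
    for j, label in enumerate(reference.columns):
        a, b = ref_log[:, j], dec_log[:, j]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            r = 1.0 if np.allclose(a, b) else float("nan")
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        corrs.append({"sample": label, "pearson_log2": r})
    per_sample = pd.DataFrame(corrs).set_index("sample")

    errs = np.abs(reference.to_numpy(dtype=float) - decoded.to_numpy(dtype=float)).sum(axis=1)
    per_gene = pd.DataFrame({"l1_error": errs}, index=reference.index)

    pairs = (
        reference.stack().rename("reference").to_frame()
        .join(decoded.stack().rename("decoded"))
        .reset_index()
    )
    pairs.columns = ["gene", "sample", "reference", "decoded"]
    return {"per_sample": per_sample, "per_gene": per_gene, "pairs": pairs}
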