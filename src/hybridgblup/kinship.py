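"""Genomic relationship matrices (additive and dominance) and PD repair.

The additive matrix is A = W_A W_A' / (2 Σ_k p_k(1-p_k)) and the dominance
matrix is D = W_D W_D' / (4 Σ_k (p_k(1-p_k))²), both referenced to the
allele frequencies used for the Cockerham coding.  Marker-built matrices
can be singular or indefinite; ``make_positive_definite`` repairs them by
replacing non-positive eigenvalues with a strictly decreasing sequence of
small positive constants bounded by a floor (default 1e-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "RelationshipMatrix",
    "additive_grm",
    "dominance_grm",
    "make_positive_definite",
    "is_positive_definite",
    "sample_variance_scale",
    "read_matrix_csv",
    "write_matrix_csv",
]

SYMMETRY_RTOL = 1e-8  # relative Frobenius tolerance


@dataclass
class RelationshipMatrix:
    """Symmetric n x n genomic relationship matrix."""

    values: np.ndarray
    flavor: str  # "additive" | "dominance"
    ids: Optional[np.ndarray] = None
    repaired: bool = False
    eigen_floor: Optional[float] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("relationship matrix must be square")
        _check_symmetric(self.values)
        if self.flavor not in ("additive", "dominance"):
            raise ValueError("flavor must be 'additive' or 'dominance'")
        if self.ids is not None:
            self.ids = np.asarray(self.ids)
            if self.ids.shape != (self.values.shape[0],):
                raise ValueError("ids length mismatch")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _check_symmetric(values: np.ndarray, rtol: float = SYMMETRY_RTOL) -> None:
    scale = np.linalg.norm(values)
    asym = np.linalg.norm(values - values.T)
    if scale > 0 and asym > rtol * scale:
        raise ValueError("matrix is not symmetric within tolerance")


def additive_grm(
    W_A: np.ndarray, p: np.ndarray, ids: Optional[np.ndarray] = None
) -> RelationshipMatrix:
    """A = W_A W_A' / (2 Σ_k p_k(1-p_k)).

    Monomorphic loci contribute zero to both the cross-product (their W_A
    column is constant 0 under the fixed homozygote) and the denominator.
    """
    W_A = np.asarray(W_A, dtype=float)
    p = np.asarray(p, dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom <= 0.0:
        raise ValueError("all loci monomorphic: additive GRM denominator is zero")
    values = W_A @ W_A.T / denom
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(values=values, flavor="additive", ids=ids)


def dominance_grm(
    W_D: np.ndarray, p: np.ndarray, ids: Optional[np.ndarray] = None
) -> RelationshipMatrix:
    """D = W_D W_D' / (4 Σ_k (p_k(1-p_k))²)."""
    W_D = np.asarray(W_D, dtype=float)
    p = np.asarray(p, dtype=float)
    denom = 4.0 * float(np.sum((p * (1.0 - p)) ** 2))
    if denom <= 0.0:
        raise ValueError("all loci monomorphic: dominance GRM denominator is zero")
    values = W_D @ W_D.T / denom
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(values=values, flavor="dominance", ids=ids)


def sample_variance_scale(k: Union["RelationshipMatrix", np.ndarray]) -> float:
    """tr(P K P)/(n-1) with P the centering projector.

    For u ~ N(0, sigma^2 K) the expected sample variance of u over the n
    individuals is sigma^2 * tr(PKP)/(n-1), so this factor converts a REML
    variance component into the variance realized in the sample that K
    describes.  It is 1 for an idealized K with unit diagonal and zero
    mean off-diagonal, but noticeably below 1 for a diallel whose hybrids
    share parents.
    """
    values = k.values if isinstance(k, RelationshipMatrix) else np.asarray(k)
    n = values.shape[0]
    P = np.eye(n) - np.ones((n, n)) / n
    return float(np.trace(P @ values @ P) / (n - 1))


def is_positive_definite(values: np.ndarray, tol: float = 0.0) -> bool:
    return bool(np.linalg.eigvalsh(np.asarray(values, dtype=float)).min() > tol)


def make_positive_definite(
    k: RelationshipMatrix, floor: float = 1e-4, threshold: float = 0.0
) -> RelationshipMatrix:
    """Repair a non-PD relationship matrix by eigenvalue replacement.

    Eigenvalues at or below ``threshold`` (default: non-positive) are
    replaced with strictly positive values of decreasing magnitude, all
    bounded by ``floor``: if r eigenvalues are replaced, the one closest
    to zero receives ``floor`` and the most negative receives ``floor/r``.
    Eigenvalues above the threshold are untouched; a matrix needing no
    replacement is returned unchanged.  A small relative ``threshold``
    (e.g. 1e-8 x the largest eigenvalue) also repairs numerically singular
    matrices, such as those of a diallel whose rank is bounded by the
    number of parent lines.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    _check_symmetric(k.values)
    eigval, eigvec = np.linalg.eigh(k.values)  # ascending
    nonpos = eigval <= threshold
    r = int(nonpos.sum())
    if r == 0:
        return k
    # ascending order: most negative first -> floor/r ... floor
    eigval = eigval.copy()
    eigval[:r] = floor * np.arange(1, r + 1) / r
    values = (eigvec * eigval) @ eigvec.T
    values = 0.5 * (values + values.T)
    return RelationshipMatrix(
        values=values, flavor=k.flavor, ids=k.ids, repaired=True, eigen_floor=floor
    )


def read_matrix_csv(path, flavor: str = "additive") -> RelationshipMatrix:
    df = pd.read_csv(path, index_col=0)
    return RelationshipMatrix(
        values=df.to_numpy(dtype=float), flavor=flavor, ids=df.index.to_numpy()
    )


def write_matrix_csv(k: RelationshipMatrix, path) -> None:
    ids = k.ids if k.ids is not None else np.arange(k.n)
    pd.DataFrame(k.values, index=ids, columns=ids).to_csv(path, index_label="id")
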