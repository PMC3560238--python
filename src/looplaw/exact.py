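"""Exact null-space and row-space computations.

Everything here runs in rational arithmetic (sympy under the hood); results
are exact, deterministic, and normalized to smallest-integer form.  A float
input is converted via its exact binary expansion, so callers who want the
float path must opt in explicitly via :func:`nullspace_basis_float`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import sympy

from ._rational import RatMat, RatVec, as_matrix, as_vector, dot, normalize_integer


@dataclass(frozen=True)
class NullspaceBasis:
    """Exact basis of null(A) together with rank(A).

    ``len(basis_vectors) == n − rank`` (rank–nullity) and ``A·b = 0`` holds
    exactly for every basis vector.
    """

    basis_vectors: tuple[RatVec, ...]
    rank: int

    def __len__(self) -> int:
        return len(self.basis_vectors)

    def as_array(self) -> np.ndarray:
        """Basis vectors as rows of a float array ((n − rank) × n); 0×0 when full rank."""
        if not self.basis_vectors:
            return np.zeros((0, 0))
        return np.array([[float(x) for x in b] for b in self.basis_vectors], dtype=float)


def _to_sympy(A: RatMat) -> sympy.Matrix:
    return sympy.Matrix([[sympy.Rational(x.numerator, x.denominator) for x in row] for row in A])


def nullspace_basis(A) -> NullspaceBasis:
    """Exact basis of {x : A·x = 0}, deterministic for a given A.

    Uses reduced-echelon pivoting in fixed column order; each basis vector is
    scaled to smallest integer form with its first nonzero entry positive.
    A full-rank matrix yields an empty basis.
    """
    A = as_matrix(A)
    if not A or not A[0]:
        ncols = len(A[0]) if A else 0
        return NullspaceBasis((), 0) if ncols == 0 else NullspaceBasis(
            tuple(normalize_integer(e) for e in _identity(ncols)), 0
        )
    M = _to_sympy(A)
    vectors = tuple(
        normalize_integer(tuple(Fraction(int(x.p), int(x.q)) for x in vec))
        for vec in M.nullspace()
    )
    return NullspaceBasis(vectors, M.rank())


def _identity(n: int) -> list[RatVec]:
    return [tuple(Fraction(int(i == j)) for j in range(n)) for i in range(n)]


def rank(A) -> int:
    A = as_matrix(A)
    if not A or not A[0]:
        return 0
    return _to_sympy(A).rank()


def in_row_space(A, g) -> bool:
    """Exact membership test g ∈ image(Aᵀ), by rank comparison.

    Appending g as an extra row leaves the rank unchanged iff g already lies
    in the span of the rows of A.
    """
    A = as_matrix(A)
    g = as_vector(g)
    ncols = len(A[0]) if A else 0
    if len(g) != ncols:
        raise ValueError(f"vector length {len(g)} != column count {ncols}")
    if all(x == 0 for x in g):
        return True
    if not A:
        return False
    augmented = A + (g,)
    return _to_sympy(A).rank() == _to_sympy(augmented).rank()


def nullspace_orthogonality_check(A, g) -> bool:
    """True iff b·g = 0 for every null-space basis vector b of A.

    By the fundamental theorem of linear algebra this must agree with
    :func:`in_row_space` on every input; the test suite enforces that.
    """
    A = as_matrix(A)
    g = as_vector(g)
    ncols = len(A[0]) if A else 0
    if len(g) != ncols:
        raise ValueError(f"vector length {len(g)} != column count {ncols}")
    basis = nullspace_basis(A)
    return all(dot(b, g) == 0 for b in basis.basis_vectors)


def nullspace_basis_float(A: np.ndarray, rcond: float = 1e-10) -> np.ndarray:
    """SVD null-space for non-rational float input (rows = basis vectors).

    Only for user-supplied float data; the exact path above is authoritative
    everywhere in the test and property suites.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    if A.size == 0:
        return np.eye(A.shape[1])
    u, s, vh = np.linalg.svd(A)
    cutoff = rcond * (s.max() if s.size else 0.0)
    num = int((s > cutoff).sum())
    return vh[num:]
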