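"""Certificates of looplessness via the theorem of the alternative.

For a matrix A and a sign pattern d, exactly one of two things exists: a
sign-consistent nonzero kernel vector (a loop), or a potential vector y whose
reaction energies Aᵀy oppose every active direction (a certificate).
:func:`check_dichotomy` machine-checks that exclusivity; any violation is an
implementation bug and raises, never returns.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy.optimize import linprog

from ._exactlp import solve_inequalities
from ._rational import (
    RatMat,
    RatVec,
    as_matrix,
    as_vector,
    columns,
    mat_vec,
    sign as _rsign,
    transpose,
)
from .loops import LoopVector, SolverError, loop_exists_bruteforce
from .model import SignPattern, StoichiometricNetwork, internal_submatrix

#: exact LP path is used when the potential dimension stays below this
EXACT_PATH_MAX_VARS = 16


@dataclass(frozen=True)
class ReducedMatrix:
    """Â: columns of A with dᵢ = 0 dropped and dᵢ = −1 negated, order kept."""

    matrix: RatMat
    column_map: tuple[int, ...]


@dataclass(frozen=True)
class GordanCertificate:
    """Metabolite potentials y with reaction energies G = Aᵀy opposing ``pattern``.

    Wherever the pattern is nonzero, sign(Gᵢ) = −patternᵢ holds exactly;
    components at patternᵢ = 0 are unconstrained.
    """

    y: RatVec
    G: RatVec
    pattern: SignPattern

    def __post_init__(self) -> None:
        object.__setattr__(self, "y", as_vector(self.y))
        object.__setattr__(self, "G", as_vector(self.G))

    def to_json(self) -> dict:
        return {
            "pattern": list(self.pattern.signs),
            "y": [str(x) for x in self.y],
            "G": [str(x) for x in self.G],
            "verified": True,
        }


class DichotomyError(AssertionError):
    """Both or neither Gordan statement held — an implementation bug by theorem."""


class DichotomyResult(enum.Enum):
    loop_exists = "loop_exists"
    certificate_exists = "certificate_exists"


def reduce_matrix(A, d: SignPattern) -> ReducedMatrix:
    """Drop dᵢ = 0 columns, negate dᵢ = −1 columns, preserve order."""
    A = as_matrix(A)
    ncols = len(A[0]) if A else 0
    if len(d) != ncols:
        raise ValueError(f"sign pattern length {len(d)} != column count {ncols}")
    kept = d.active
    mat = tuple(tuple(row[j] * d.signs[j] for j in kept) for row in A)
    return ReducedMatrix(mat, kept)


def _certificate_from_y(A: RatMat, d: SignPattern, y: RatVec) -> GordanCertificate:
    G = mat_vec(transpose(A), y) if A else ()
    return GordanCertificate(y, G, d)


def verify_certificate(A, d: SignPattern, y) -> bool:
    """Exact check: sign((Aᵀy)ᵢ) = −dᵢ at every active component."""
    A = as_matrix(A)
    y = as_vector(y)
    nrows = len(A)
    if len(y) != nrows:
        raise ValueError(f"potential length {len(y)} != row count {nrows}")
    ncols = len(A[0]) if A else 0
    if len(d) != ncols:
        raise ValueError(f"sign pattern length {len(d)} != column count {ncols}")
    G = mat_vec(transpose(A), y) if A else ()
    return all(_rsign(G[i]) == -d.signs[i] for i in d.active)


def find_certificate(A, d: SignPattern, exact: bool | None = None) -> GordanCertificate | None:
    """Find y with sign((Aᵀy)ᵢ) = −dᵢ on every active component, or None.

    On the reduced matrix this is the open cone Âᵀ(−y) > 0, encoded as
    Âᵀ(−y) ≥ 1 — lossless, since any strictly feasible y scales into it.
    Small systems are decided by the exact rational engine; larger ones by
    HiGHS with continued-fraction rounding and exact re-verification.
    """
    A = as_matrix(A)
    nrows = len(A)
    if len(d) != (len(A[0]) if A else 0):
        raise ValueError("sign pattern length != column count")
    if not d.active:
        y0 = tuple(Fraction(0) for _ in range(nrows))
        return _certificate_from_y(A, d, y0)  # vacuous certificate

    reduced = reduce_matrix(A, d)
    # inequality rows: ĉᵀ·y ≤ −1 for every retained (sign-adjusted) column ĉ
    rows_ub = [list(col) for col in columns(reduced.matrix)]
    b_ub = [Fraction(-1)] * len(rows_ub)

    if exact is None:
        exact = nrows <= EXACT_PATH_MAX_VARS
    if exact:
        y = solve_inequalities(rows_ub, b_ub)
        if y is None:
            return None
        cert = _certificate_from_y(A, d, y)
        assert verify_certificate(A, d, cert.y)
        return cert

    A_ub = np.array([[float(x) for x in r] for r in rows_ub], dtype=float)
    res = linprog(
        np.zeros(nrows),
        A_ub=A_ub,
        b_ub=-np.ones(len(rows_ub)),
        bounds=[(None, None)] * nrows,
        method="highs",
    )
    if res.status == 2:  # infeasible
        return None
    if not res.success:
        raise SolverError(f"certificate LP failed: {res.message}")
    y = tuple(Fraction(float(t)).limit_denominator(10**6) for t in res.x)
    if verify_certificate(A, d, y):
        return _certificate_from_y(A, d, y)
    if nrows <= EXACT_PATH_MAX_VARS:
        return find_certificate(A, d, exact=True)
    raise SolverError("LP certificate failed exact verification; exact fallback unavailable")


def check_dichotomy(A, d: SignPattern) -> DichotomyResult:
    """Decide which Gordan statement holds, verifying exclusivity.

    Both sides are decided by the exact rational engine: the loop side by the
    brute-force existence oracle, the certificate side by exact feasibility of
    the reduced cone.  Exactly one must hold; anything else raises
    :class:`DichotomyError` with a diagnostic dump.
    """
    A = as_matrix(A)
    ncols = len(A[0]) if A else 0
    if ncols > 12:
        raise ValueError(f"exact dichotomy path is guarded at 12 columns (got {ncols})")
    loop: LoopVector | None = loop_exists_bruteforce(A, d)
    cert = find_certificate(A, d, exact=True)
    if (loop is None) == (cert is None):
        raise DichotomyError(
            "Gordan dichotomy violated — implementation bug.\n"
            f"A = {[[str(x) for x in row] for row in A]}\n"
            f"d = {list(d.signs)}\n"
            f"loop witness = {None if loop is None else [str(x) for x in loop.values]}\n"
            f"certificate y = {None if cert is None else [str(x) for x in cert.y]}"
        )
    return DichotomyResult.loop_exists if loop is not None else DichotomyResult.certificate_exists


def potentials_to_reaction_energies(network: StoichiometricNetwork, y) -> RatVec:
    """G = S_intᵀ·y — reaction energies induced by metabolite potentials."""
    y = as_vector(y)
    if len(y) != network.m:
        raise ValueError(f"potential length {len(y)} != metabolite count {network.m}")
    s_int = internal_submatrix(network)
    return mat_vec(transpose(s_int), y) if s_int and s_int[0] else ()
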