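"""Deciding whether a flux distribution contains a thermodynamically
infeasible internal cycle.

Two independent routes exist on purpose: :func:`find_loop` is the production
path (float LP via HiGHS, witness re-verified exactly), while
:func:`enumerate_loops_bruteforce` / :func:`loop_exists_bruteforce` decide the
same question by exact rational feasibility and act as the oracle the property
suites arbitrate against.
"""

from __future__ import annotations

import itertools
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
    mat_vec,
    scale_to_integers,
    sign as _rsign,
)
from .model import (
    FluxDistribution,
    SignPattern,
    StoichiometricNetwork,
    internal_submatrix,
    sign_pattern,
)

#: LP objective values above this count as "strictly positive" in the float path.
LP_POSITIVE_THRESHOLD = 1e-7

#: column-count guard for the exhaustive oracle
BRUTEFORCE_MAX_COLUMNS = 12


class SolverError(RuntimeError):
    """An LP/MILP backend failed in a way that is not a feasibility verdict."""


@dataclass(frozen=True)
class LoopVector:
    """A nonzero internal cycle, sign-consistent with the pattern it witnesses."""

    values: RatVec
    witness_for: SignPattern

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", as_vector(self.values))

    def support(self) -> tuple[int, ...]:
        return tuple(i for i, x in enumerate(self.values) if x != 0)


def _sign_consistent(x: RatVec, d: SignPattern) -> bool:
    return all(_rsign(xi) in (di, 0) for xi, di in zip(x, d.signs))


def is_loop(network: StoichiometricNetwork, x) -> bool:
    """True iff x ≠ 0, x vanishes on exchange reactions, and S_int·x_int = 0.

    Decided in exact arithmetic (float entries are taken at their exact
    binary value).
    """
    x = as_vector(x)
    if len(x) != network.n:
        raise ValueError(f"vector length {len(x)} != reaction count {network.n}")
    if all(xi == 0 for xi in x):
        return False
    for j, internal in enumerate(network.internal_mask):
        if not internal and x[j] != 0:
            return False
    s_int = internal_submatrix(network)
    x_int = tuple(x[j] for j in network.internal_indices)
    return all(b == 0 for b in mat_vec(s_int, x_int))


def _embed_internal(network: StoichiometricNetwork, x_int: RatVec) -> RatVec:
    full = [Fraction(0)] * network.n
    for pos, j in enumerate(network.internal_indices):
        full[j] = x_int[pos]
    return tuple(full)


def find_loop(
    network: StoichiometricNetwork, v: FluxDistribution
) -> LoopVector | None:
    """Search for a loop consistent with the flux directions of ``v``.

    LP encoding: maximize Σtᵢ subject to S_int·x = 0 with, per active internal
    reaction, 0 ≤ tᵢ ≤ 1 and tᵢ ≤ dᵢ·xᵢ, and xᵢ = 0 where dᵢ = 0.  A loop
    exists iff the optimum is strictly positive (the auxiliary t variables
    make that scale-invariant — no magnitude cutoff on x itself).  Any witness
    is re-verified in exact arithmetic before being returned.
    """
    v.check_against(network)
    d_full = sign_pattern(v)
    idx = network.internal_indices
    d_int = SignPattern(tuple(d_full.signs[j] for j in idx))
    active = d_int.active
    if not active:
        return None  # includes the trivial case v = 0

    s_int = internal_submatrix(network)
    A = np.array([[float(x) for x in row] for row in s_int], dtype=float)
    n_int, n_act = len(idx), len(active)
    nvar = n_int + n_act  # x variables then t variables

    c = np.zeros(nvar)
    c[n_int:] = -1.0  # maximize Σt
    A_eq = np.hstack([A, np.zeros((A.shape[0], n_act))])
    b_eq = np.zeros(A.shape[0])
    # t_k − d_i·x_i ≤ 0
    A_ub = np.zeros((n_act, nvar))
    for k, i in enumerate(active):
        A_ub[k, i] = -d_int.signs[i]
        A_ub[k, n_int + k] = 1.0
    b_ub = np.zeros(n_act)
    bounds = []
    for i in range(n_int):
        s = d_int.signs[i]
        bounds.append((0.0, 1000.0) if s > 0 else (-1000.0, 0.0) if s < 0 else (0.0, 0.0))
    bounds += [(0.0, 1.0)] * n_act

    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    if not res.success:
        raise SolverError(f"loop-detection LP failed: {res.message}")
    if -res.fun <= LP_POSITIVE_THRESHOLD:
        return None

    x_int = _rationalize(res.x[:n_int])
    full = _embed_internal(network, x_int)
    candidate = LoopVector(scale_to_integers(full), d_full)
    if is_loop(network, candidate.values) and _sign_consistent(candidate.values, d_full):
        return candidate
    # float witness failed exact verification → exact fallback
    if n_int <= 16:
        exact = loop_exists_bruteforce(s_int, d_int)
        if exact is not None:
            return LoopVector(scale_to_integers(_embed_internal(network, exact.values)), d_full)
        return None
    raise SolverError("LP witness failed exact verification and network too large for exact fallback")


def _rationalize(x: np.ndarray, max_den: int = 10**6) -> RatVec:
    scale = max(abs(float(t)) for t in x) if len(x) else 0.0
    cutoff = 1e-7 * max(scale, 1.0)
    return tuple(
        Fraction(0) if abs(float(t)) < cutoff else Fraction(float(t)).limit_denominator(max_den)
        for t in x
    )


def _signed_columns(A: RatMat, d: SignPattern, cols: tuple[int, ...]) -> RatMat:
    """Rows of A restricted to ``cols`` with dᵢ = −1 columns negated."""
    return tuple(tuple(row[j] * d.signs[j] for j in cols) for row in A)


def _row_sign_prune(A_signed: RatMat) -> bool:
    """True if some row forbids any strictly positive solution of A·y = 0."""
    for row in A_signed:
        if any(x > 0 for x in row) and not any(x < 0 for x in row):
            return True
        if any(x < 0 for x in row) and not any(x > 0 for x in row):
            return True
    return False


def loop_exists_bruteforce(A, d: SignPattern) -> LoopVector | None:
    """Exact existence decision for a sign-consistent nonzero kernel vector.

    Feasibility of {ŷ ≥ 0, Â·ŷ = 0, Σŷ = 1} over the sign-adjusted active
    columns Â — nonempty exactly when a loop consistent with ``d`` exists.
    Decided by rational Fourier–Motzkin; no tolerances anywhere.
    """
    A = as_matrix(A)
    ncols = len(A[0]) if A else 0
    if len(d) != ncols:
        raise ValueError(f"sign pattern length {len(d)} != column count {ncols}")
    active = d.active
    if not active:
        return None
    A_signed = _signed_columns(A, d, active)
    k = len(active)
    A_ub = [[-(i == j) for j in range(k)] for i in range(k)]  # −ŷ ≤ 0
    b_ub = [0] * k
    A_eq = [list(row) for row in A_signed] + [[1] * k]
    b_eq = [0] * len(A_signed) + [1]
    w = solve_inequalities(A_ub, b_ub, A_eq, b_eq)
    if w is None:
        return None
    x = [Fraction(0)] * ncols
    for pos, j in enumerate(active):
        x[j] = d.signs[j] * w[pos]
    return LoopVector(scale_to_integers(x), d)


def enumerate_loops_bruteforce(A, d: SignPattern) -> list[LoopVector]:
    """All minimal-support sign-consistent loops, by exhaustive support search.

    For every support T within the active set (in order of increasing size,
    skipping supersets of supports already witnessed), decides exactly whether
    a vector with that exact support, matching ``d`` strictly on T, lies in
    null(A).  Witnesses come back in smallest-integer form.  The returned list
    is empty iff no sign-consistent loop exists at all.
    """
    A = as_matrix(A)
    ncols = len(A[0]) if A else 0
    if len(d) != ncols:
        raise ValueError(f"sign pattern length {len(d)} != column count {ncols}")
    if ncols > BRUTEFORCE_MAX_COLUMNS:
        raise ValueError(
            f"refusing brute-force enumeration beyond {BRUTEFORCE_MAX_COLUMNS} columns (got {ncols})"
        )
    active = d.active
    witnesses: list[LoopVector] = []
    found_supports: list[frozenset[int]] = []
    for size in range(1, len(active) + 1):
        for T in itertools.combinations(active, size):
            Tset = frozenset(T)
            if any(s <= Tset for s in found_supports):
                continue  # not minimal
            A_signed = _signed_columns(A, d, T)
            if _row_sign_prune(A_signed):
                continue
            k = len(T)
            A_ub = [[-(i == j) for j in range(k)] for i in range(k)]  # ŷ ≥ 1
            b_ub = [-1] * k
            A_eq = [list(row) for row in A_signed]
            b_eq = [0] * len(A_signed)
            w = solve_inequalities(A_ub, b_ub, A_eq, b_eq)
            if w is None:
                continue
            x = [Fraction(0)] * ncols
            for pos, j in enumerate(T):
                x[j] = d.signs[j] * w[pos]
            witnesses.append(LoopVector(scale_to_integers(x), d))
            found_supports.append(Tset)
    return witnesses
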