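"""Loopless flux balance analysis as a mixed-integer linear program.

Two interchangeable couplings of the reaction-energy variables G are built:
``nullspace`` (one orthogonality row per null-space basis vector of S_int) and
``image`` (G = S_intᵀ·y with free metabolite potentials y).  Their equivalence
is itself a checked operation, not an assumption.  Solutions are re-verified
loop-free after every solve; a solution that fails re-verification raises.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import LinearConstraint, linprog, milp
from scipy.sparse import csr_matrix

from ._exactlp import solve_inequalities
from .exact import nullspace_basis
from .gordan import find_certificate
from .loops import SolverError, find_loop
from .model import (
    FluxDistribution,
    SignPattern,
    StoichiometricNetwork,
    ValidationError,
    internal_submatrix,
    sign_pattern,
)

Formulation = Literal["nullspace", "image"]

DEFAULT_BIG_M = 1000.0
DEFAULT_ENERGY_BOUND = 1000.0


class InfeasibleProblem(SolverError):
    """The MILP/LP has no feasible point under the given bounds."""


class UnboundedProblem(SolverError):
    """The objective is unbounded above."""


@dataclass
class LooplessProblem:
    """A built loopless-FBA MILP, ready for :func:`solve_loopless_fba`.

    Variable layout: v (n fluxes), then per internal reaction a binary
    direction indicator a and an energy G, then (image formulation only) one
    free potential y per metabolite.  ``a=1`` means forward: v ≥ 0 and G ≤ −1;
    ``a=0`` means backward: v ≤ 0 and G ≥ 1.
    """

    network: StoichiometricNetwork
    objective_reaction: str
    formulation: Formulation
    big_m: float
    energy_bound: float
    c: np.ndarray = field(repr=False)
    constraints: list[LinearConstraint] = field(repr=False)
    integrality: np.ndarray = field(repr=False)
    lb: np.ndarray = field(repr=False)
    ub: np.ndarray = field(repr=False)
    var_names: list[str] = field(repr=False)

    @property
    def n_variables(self) -> int:
        return len(self.c)

    @property
    def has_binaries(self) -> bool:
        return bool(self.integrality.any())

    def to_lp_string(self) -> str:
        """CPLEX LP-format text export for solver-independent debugging."""
        lines = ["Maximize", f" obj: {self.var_names[self.network.reaction_index(self.objective_reaction)]}"]
        lines.append("Subject To")
        cid = 0
        for con in self.constraints:
            A = con.A.toarray() if hasattr(con.A, "toarray") else np.atleast_2d(con.A)
            lo = np.atleast_1d(con.lb)
            hi = np.atleast_1d(con.ub)
            for i in range(A.shape[0]):
                terms = " ".join(
                    f"{'+' if a >= 0 else '-'} {abs(a):g} {self.var_names[j]}"
                    for j, a in enumerate(A[i])
                    if a != 0
                )
                if lo[i] == hi[i]:
                    lines.append(f" c{cid}: {terms} = {lo[i]:g}")
                else:
                    if np.isfinite(hi[i]):
                        lines.append(f" c{cid}u: {terms} <= {hi[i]:g}")
                    if np.isfinite(lo[i]):
                        lines.append(f" c{cid}l: {terms} >= {lo[i]:g}")
                cid += 1
        lines.append("Bounds")
        for name, lo, hi in zip(self.var_names, self.lb, self.ub):
            left = f"{lo:g}" if np.isfinite(lo) else "-inf"
            right = f"{hi:g}" if np.isfinite(hi) else "+inf"
            lines.append(f" {left} <= {name} <= {right}")
        binaries = [n for n, isint in zip(self.var_names, self.integrality) if isint]
        if binaries:
            lines.append("Binary")
            lines.extend(f" {n}" for n in binaries)
        lines.append("End")
        return "\n".join(lines) + "\n"


def build_loopless_milp(
    network: StoichiometricNetwork,
    objective: str,
    formulation: Formulation = "image",
    big_m: float = DEFAULT_BIG_M,
    energy_bound: float = DEFAULT_ENERGY_BOUND,
) -> LooplessProblem:
    """Assemble the loopless-FBA MILP for ``network`` maximizing ``objective``.

    With no internal reactions this degenerates to plain FBA (no binaries, no
    energy variables).  Under ``nullspace`` the energies satisfy N_intᵀ·G = 0;
    under ``image`` they are expressed as G = S_intᵀ·y with m extra free
    variables — typically fewer than the null-space rows when m < n.
    """
    if big_m <= 0 or energy_bound <= 0:
        raise ValidationError("big_m and energy_bound must be positive")
    obj_idx = network.reaction_index(objective)
    if max(
        (abs(b) for b in network.lower_bounds + network.upper_bounds if np.isfinite(b)),
        default=0.0,
    ) > big_m:
        warnings.warn(
            f"flux bounds exceed big-M = {big_m}; indicator coupling may truncate them",
            stacklevel=2,
        )

    n, m, n_int = network.n, network.m, network.n_int
    idx_int = network.internal_indices
    n_y = m if (formulation == "image" and n_int > 0) else 0
    nvar = n + 2 * n_int + n_y
    v_of = lambda j: j
    a_of = lambda k: n + k
    g_of = lambda k: n + n_int + k
    y_of = lambda i: n + 2 * n_int + i

    var_names = [f"v_{r}" for r in network.reaction_ids]
    var_names += [f"a_{network.reaction_ids[j]}" for j in idx_int]
    var_names += [f"G_{network.reaction_ids[j]}" for j in idx_int]
    var_names += [f"y_{met}" for met in network.metabolite_ids] if n_y else []

    lb = np.full(nvar, -np.inf)
    ub = np.full(nvar, np.inf)
    lb[:n] = network.lower_bounds
    ub[:n] = network.upper_bounds
    for k in range(n_int):
        lb[a_of(k)], ub[a_of(k)] = 0.0, 1.0
        lb[g_of(k)], ub[g_of(k)] = -energy_bound, energy_bound

    integrality = np.zeros(nvar)
    integrality[n : n + n_int] = 1.0

    c = np.zeros(nvar)
    c[obj_idx] = -1.0  # milp minimizes

    constraints: list[LinearConstraint] = []
    S = network.stoich_array()
    steady = np.zeros((m, nvar))
    steady[:, :n] = S
    constraints.append(LinearConstraint(csr_matrix(steady), 0.0, 0.0))

    if n_int:
        K = energy_bound
        rows, lo_list, hi_list = [], [], []
        for k, j in enumerate(idx_int):
            r = np.zeros(nvar)  # v_j − M·a_k ≤ 0  and  v_j − M·a_k ≥ −M
            r[v_of(j)] = 1.0
            r[a_of(k)] = -big_m
            rows.append(r)
            lo_list.append(-big_m)
            hi_list.append(0.0)
            r = np.zeros(nvar)  # G_k + (K+1)·a_k ∈ [1, K]
            r[g_of(k)] = 1.0
            r[a_of(k)] = K + 1.0
            rows.append(r)
            lo_list.append(1.0)
            hi_list.append(K)
        constraints.append(
            LinearConstraint(csr_matrix(np.array(rows)), np.array(lo_list), np.array(hi_list))
        )

        s_int = internal_submatrix(network)
        if formulation == "nullspace":
            N = nullspace_basis(s_int).as_array()  # rows span null(S_int)
            if N.shape[0]:
                ortho = np.zeros((N.shape[0], nvar))
                ortho[:, n + n_int : n + 2 * n_int] = N
                constraints.append(LinearConstraint(csr_matrix(ortho), 0.0, 0.0))
        elif formulation == "image":
            St = np.array([[float(x) for x in row] for row in s_int]).T  # n_int × m
            link = np.zeros((n_int, nvar))
            for k in range(n_int):
                link[k, g_of(k)] = 1.0
                link[k, n + 2 * n_int :] = -St[k]
            constraints.append(LinearConstraint(csr_matrix(link), 0.0, 0.0))
        else:
            raise ValidationError(f"unknown formulation {formulation!r}")

    return LooplessProblem(
        network=network,
        objective_reaction=objective,
        formulation=formulation,
        big_m=big_m,
        energy_bound=energy_bound,
        c=c,
        constraints=constraints,
        integrality=integrality,
        lb=lb,
        ub=ub,
        var_names=var_names,
    )


def _status_check(status: int, message: str) -> None:
    if status == 2:
        raise InfeasibleProblem(message or "problem is infeasible")
    if status == 3:
        raise UnboundedProblem(message or "objective is unbounded")


def solve_loopless_fba(problem: LooplessProblem) -> FluxDistribution:
    """Solve the MILP and return the optimal flux distribution.

    The loop-freeness of the result is asserted post hoc with
    :func:`looplaw.loops.find_loop`; a solver answer failing that check raises
    :class:`looplaw.loops.SolverError` rather than being returned.
    """
    from scipy.optimize import Bounds

    res = milp(
        problem.c,
        constraints=problem.constraints,
        integrality=problem.integrality,
        bounds=Bounds(problem.lb, problem.ub),
    )
    _status_check(res.status, res.message)
    if not res.success:
        raise SolverError(f"MILP solve failed: {res.message}")
    net = problem.network
    n = net.n
    flux = list(res.x[:n])
    # HiGHS integrality slack (~1e-6) times big-M lets a flux stray across the
    # half-line its direction binary asserts; clamp to the rounded binary's
    # half-line so the sign pattern matches the solver's own certificate.
    for k, j in enumerate(net.internal_indices):
        a = res.x[n + k]
        flux[j] = max(flux[j], 0.0) if a >= 0.5 else min(flux[j], 0.0)
    v = FluxDistribution(net.reaction_ids, tuple(flux), tolerance=1e-6)
    if find_loop(net, v) is not None:
        raise SolverError("MILP returned a flux distribution that fails exact loop re-verification")
    return v


def plain_fba(network: StoichiometricNetwork, objective: str) -> FluxDistribution:
    """Ordinary FBA: maximize the objective flux under S·v = 0 and bounds."""
    obj_idx = network.reaction_index(objective)
    c = np.zeros(network.n)
    c[obj_idx] = -1.0
    res = linprog(
        c,
        A_eq=network.stoich_array(),
        b_eq=np.zeros(network.m),
        bounds=list(zip(network.lower_bounds, network.upper_bounds)),
        method="highs",
    )
    _status_check(res.status, res.message)
    if not res.success:
        raise SolverError(f"FBA LP failed: {res.message}")
    return FluxDistribution(network.reaction_ids, tuple(res.x))


def _internal_pattern(network: StoichiometricNetwork, d: SignPattern) -> SignPattern:
    if len(d) == network.n_int:
        return d
    if len(d) == network.n:
        return SignPattern(tuple(d.signs[j] for j in network.internal_indices))
    raise ValueError(f"sign pattern length {len(d)} matches neither n={network.n} nor n_int={network.n_int}")


def check_formulation_equivalence(network: StoichiometricNetwork, d: SignPattern) -> bool:
    """Feasibility of G under the nullspace coupling iff under the image coupling.

    For the fixed sign pattern ``d`` over internal reactions, both feasibility
    systems (active components forced to sign −dᵢ with unit magnitude) are
    decided exactly; returns True when their verdicts agree.
    """
    if network.n_int < 1:
        raise ValidationError("network has no internal reactions")
    d_int = _internal_pattern(network, d)
    s_int = internal_submatrix(network)
    n_int = network.n_int

    # nullspace route: variables G with N·G = 0 and sign constraints
    basis = nullspace_basis(s_int).basis_vectors
    A_eq = [list(b) for b in basis]
    b_eq = [0] * len(A_eq)
    A_ub, b_ub = [], []
    for i, s in enumerate(d_int.signs):
        if s:
            row = [0] * n_int
            row[i] = s  # s·G_i ≤ −1  ⇔  sign(G_i) = −s with unit magnitude
            A_ub.append(row)
            b_ub.append(-1)
    ns_feasible = solve_inequalities(A_ub, b_ub, A_eq, b_eq) is not None

    # image route: variables y with sign constraints on (S_intᵀ·y)_i
    im_feasible = find_certificate(s_int, d_int, exact=True) is not None
    return ns_feasible == im_feasible


def flux_admissible(network: StoichiometricNetwork, v: FluxDistribution) -> bool:
    """True iff ``v`` survives the loopless constraints.

    Equivalent to the existence of a certificate for sign_pattern(v) on the
    internal submatrix — and, by the dichotomy, to ``find_loop(v) is None``.
    The zero flux distribution is (trivially) admissible.
    """
    v.check_against(network)
    d_int = _internal_pattern(network, sign_pattern(v))
    return find_certificate(internal_submatrix(network), d_int) is not None
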