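"""Exact rational feasibility of linear systems via Fourier–Motzkin elimination.

This is the arbiter behind the brute-force oracles: every decision is made in
:class:`fractions.Fraction` arithmetic, so "feasible" and "infeasible" are
exact verdicts, never tolerance calls.  Intended for small systems (the
combinatorial guards upstream keep variable counts ≤ ~16); no attempt is made
to scale beyond that.
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd

from ._rational import RatMat, RatVec, as_matrix, as_vector

_ZERO = Fraction(0)

# an inequality  a·z ≤ b  stored as (coeffs, b)
_Ineq = tuple[RatVec, Fraction]


def _normalize_ineq(coeffs: list[Fraction], b: Fraction) -> _Ineq:
    """Scale to coprime integer coefficients (positive scaling preserves ≤)."""
    denom_lcm = 1
    for x in coeffs:
        denom_lcm = denom_lcm * x.denominator // gcd(denom_lcm, x.denominator)
    denom_lcm = denom_lcm * b.denominator // gcd(denom_lcm, b.denominator)
    ints = [int(x * denom_lcm) for x in coeffs]
    bi = int(b * denom_lcm)
    g = abs(bi)
    for k in ints:
        g = gcd(g, abs(k))
    if g > 1:
        ints = [k // g for k in ints]
        bi //= g
    return tuple(Fraction(k) for k in ints), Fraction(bi)


def solve_inequalities(
    A_ub=(), b_ub=(), A_eq=(), b_eq=()
) -> RatVec | None:
    """Find an exact rational ``x`` with ``A_ub·x ≤ b_ub`` and ``A_eq·x = b_eq``.

    Returns a witness vector, or ``None`` when the system is infeasible.
    All inputs are coerced to exact rationals.
    """
    A_ub = as_matrix(A_ub)
    b_ub = as_vector(b_ub)
    A_eq = as_matrix(A_eq)
    b_eq = as_vector(b_eq)
    nvars = len(A_ub[0]) if A_ub else (len(A_eq[0]) if A_eq else 0)
    if nvars == 0:
        if any(b < 0 for b in b_ub) or any(b != 0 for b in b_eq):
            return None
        return ()

    # --- eliminate equalities by Gauss–Jordan, expressing pivot vars in free vars
    rows = [list(r) + [b] for r, b in zip(A_eq, b_eq)]
    pivot_cols: list[int] = []
    r = 0
    for c in range(nvars):
        piv = next((i for i in range(r, len(rows)) if rows[i][c] != 0), None)
        if piv is None:
            continue
        rows[r], rows[piv] = rows[piv], rows[r]
        inv = 1 / rows[r][c]
        rows[r] = [x * inv for x in rows[r]]
        for i in range(len(rows)):
            if i != r and rows[i][c] != 0:
                f = rows[i][c]
                rows[i] = [x - f * y for x, y in zip(rows[i], rows[r])]
        pivot_cols.append(c)
        r += 1
    for i in range(r, len(rows)):
        if rows[i][nvars] != 0:  # 0 = nonzero → inconsistent equalities
            return None

    free_cols = [c for c in range(nvars) if c not in set(pivot_cols)]
    col_of_free = {c: j for j, c in enumerate(free_cols)}
    nf = len(free_cols)

    # x_p = const_p - Σ_f coef_pf · z_f   for each pivot var p
    subst: dict[int, tuple[Fraction, list[Fraction]]] = {}
    for i, p in enumerate(pivot_cols):
        const = rows[i][nvars]
        coefs = [rows[i][c] for c in free_cols]
        subst[p] = (const, coefs)

    # --- rewrite inequalities over the free variables
    ineqs: list[_Ineq] = []
    seen: set[_Ineq] = set()
    for arow, b in zip(A_ub, b_ub):
        coeffs = [_ZERO] * nf
        rhs = b
        for c, a in enumerate(arow):
            if a == 0:
                continue
            if c in subst:
                const, coefs = subst[c]
                rhs -= a * const
                for j in range(nf):
                    coeffs[j] -= a * coefs[j]
            else:
                coeffs[col_of_free[c]] += a
        key = _normalize_ineq(coeffs, rhs)
        if all(x == 0 for x in key[0]):
            if key[1] < 0:
                return None
            continue
        if key not in seen:
            seen.add(key)
            ineqs.append(key)

    # --- Fourier–Motzkin elimination, recording frames for back-substitution
    remaining = list(range(nf))
    frames: list[tuple[int, list[_Ineq], list[_Ineq]]] = []
    while remaining:
        # pick the variable with the cheapest pos×neg product
        def cost(k: int) -> int:
            p = sum(1 for c, _ in ineqs if c[k] > 0)
            m = sum(1 for c, _ in ineqs if c[k] < 0)
            return p * m

        k = min(remaining, key=cost)
        remaining.remove(k)
        pos = [iq for iq in ineqs if iq[0][k] > 0]   # upper bounds on z_k
        neg = [iq for iq in ineqs if iq[0][k] < 0]   # lower bounds on z_k
        rest = [iq for iq in ineqs if iq[0][k] == 0]
        frames.append((k, pos, neg))
        new_seen: set[_Ineq] = set()
        new_ineqs: list[_Ineq] = []
        for iq in rest:
            if iq not in new_seen:
                new_seen.add(iq)
                new_ineqs.append(iq)
        for cp, bp in pos:
            for cn, bn in neg:
                # cp[k]·(lower comb) + |cn[k]|·(upper comb)
                ap, an = cp[k], -cn[k]
                comb = [an * x + ap * y for x, y in zip(cp, cn)]
                rhs = an * bp + ap * bn
                key = _normalize_ineq(comb, rhs)
                if all(x == 0 for x in key[0]):
                    if key[1] < 0:
                        return None
                    continue
                if key not in new_seen:
                    new_seen.add(key)
                    new_ineqs.append(key)
        ineqs = new_ineqs
    for coeffs, b in ineqs:  # only constants can remain
        if b < 0:
            return None

    # --- back-substitute a witness for the free variables
    z = [_ZERO] * nf
    for k, pos, neg in reversed(frames):
        ub = None
        for c, b in pos:
            val = (b - sum((c[j] * z[j] for j in range(nf) if j != k), _ZERO)) / c[k]
            ub = val if ub is None else min(ub, val)
        lb = None
        for c, b in neg:
            val = (b - sum((c[j] * z[j] for j in range(nf) if j != k), _ZERO)) / c[k]
            lb = val if lb is None else max(lb, val)
        if lb is not None and ub is not None:
            z[k] = (lb + ub) / 2
        elif ub is not None:
            z[k] = ub
        elif lb is not None:
            z[k] = lb

    # --- reconstruct the full solution
    x = [_ZERO] * nvars
    for j, c in enumerate(free_cols):
        x[c] = z[j]
    for p, (const, coefs) in subst.items():
        x[p] = const - sum((coefs[j] * z[j] for j in range(nf)), _ZERO)
    return tuple(x)
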