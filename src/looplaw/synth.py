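"""Synthetic test networks: the worked toy cycle, parametric cycles, and
seeded random networks with loops planted by construction.

All randomness flows through a generator owned by the call (never global
state), so regeneration with the same seed is bit-identical.  Planting
guarantees the *presence* of loops; absence is never assumed — callers certify
loop-freeness post hoc with the brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .loops import LoopVector, is_loop
from .model import SignPattern, StoichiometricNetwork

_EXCHANGE_BOUNDS = (0.0, 1000.0)
_INTERNAL_BOUNDS = (-1000.0, 1000.0)


@dataclass(frozen=True)
class PlantedNetwork:
    """A random network with loops known by construction."""

    network: StoichiometricNetwork
    planted_loops: tuple[LoopVector, ...]
    seed: int


def make_cycle_network(k: int) -> StoichiometricNetwork:
    """k metabolites in a directed cycle of k internal reactions, plus one exchange.

    The exchange reaction x₁ feeds M1; internal reaction x_{j+1} converts
    Mj → M(j mod k)+1.  The null space of the internal submatrix is spanned by
    the all-ones vector.
    """
    if k < 2:
        raise ValueError(f"cycle needs at least 2 metabolites, got k={k}")
    metabolites = tuple(f"M{i + 1}" for i in range(k))
    reactions = ("x1",) + tuple(f"x{j + 2}" for j in range(k))
    stoich = [[Fraction(0)] * (k + 1) for _ in range(k)]
    stoich[0][0] = Fraction(1)  # exchange: boundary → M1
    for j in range(k):
        stoich[j][j + 1] = Fraction(-1)        # consumes Mj
        stoich[(j + 1) % k][j + 1] = Fraction(1)  # produces M(j+1)
    internal = (False,) + (True,) * k
    lbs = tuple(_EXCHANGE_BOUNDS[0] if not b else _INTERNAL_BOUNDS[0] for b in internal)
    ubs = tuple(_EXCHANGE_BOUNDS[1] if not b else _INTERNAL_BOUNDS[1] for b in internal)
    return StoichiometricNetwork(metabolites, reactions, stoich, internal, lbs, ubs)


def figure2_network() -> StoichiometricNetwork:
    """The worked toy example: 3 metabolites, internal cycle x₂,x₃,x₄, exchange x₁.

    The internal submatrix has a one-dimensional null space spanned by (1,1,1).
    """
    return make_cycle_network(3)


def random_network(
    m: int,
    n_int: int,
    n_exch: int,
    n_planted_loops: int,
    seed: int,
    coeff_range: tuple[int, int] = (-2, 2),
) -> PlantedNetwork:
    """Random integer-stoichiometry network with ``n_planted_loops`` known cycles.

    Each planted loop is a closed directed cycle over 2–3 fresh internal
    reaction columns; remaining internal columns are noise with ≥ 2 nonzero
    entries.  Exchange columns have a single ±1 entry.  Planted loops are
    verified against :func:`looplaw.loops.is_loop` before returning.
    """
    if m < 2:
        raise ValueError("need m ≥ 2 metabolites")
    if n_int < 2 * n_planted_loops:
        raise ValueError(
            f"n_int = {n_int} cannot host {n_planted_loops} planted loops (need ≥ {2 * n_planted_loops})"
        )
    if n_int + n_exch < 1:
        raise ValueError("need at least one reaction")
    rng = np.random.default_rng(seed)
    lo, hi = coeff_range

    n = n_int + n_exch
    cols: list[list[int]] = []
    planted_supports: list[tuple[int, ...]] = []
    slot = 0
    for _ in range(n_planted_loops):
        max_len = min(3, m, n_int - slot - 2 * (n_planted_loops - len(planted_supports) - 1))
        length = int(rng.integers(2, max_len + 1)) if max_len > 2 else 2
        mets = rng.choice(m, size=length, replace=False)
        support = tuple(range(slot, slot + length))
        for t in range(length):
            col = [0] * m
            col[int(mets[t])] = -1
            col[int(mets[(t + 1) % length])] = 1
            cols.append(col)
        planted_supports.append(support)
        slot += length
    while slot < n_int:
        while True:
            col = [int(c) for c in rng.integers(lo, hi + 1, size=m)]
            if sum(1 for c in col if c) >= 2:
                break
        cols.append(col)
        slot += 1
    for _ in range(n_exch):
        col = [0] * m
        col[int(rng.integers(0, m))] = int(rng.choice([-1, 1]))
        cols.append(col)

    stoich = [[Fraction(cols[j][i]) for j in range(n)] for i in range(m)]
    reactions = tuple(f"R{j + 1}" for j in range(n_int)) + tuple(
        f"E{j + 1}" for j in range(n_exch)
    )
    metabolites = tuple(f"M{i + 1}" for i in range(m))
    internal = (True,) * n_int + (False,) * n_exch
    lbs = tuple(_INTERNAL_BOUNDS[0] if b else _EXCHANGE_BOUNDS[0] for b in internal)
    ubs = tuple(_INTERNAL_BOUNDS[1] if b else _EXCHANGE_BOUNDS[1] for b in internal)
    network = StoichiometricNetwork(metabolites, reactions, stoich, internal, lbs, ubs)

    loops = []
    for support in planted_supports:
        values = tuple(Fraction(1 if j in support else 0) for j in range(n))
        pattern = SignPattern(tuple(1 if j in support else 0 for j in range(n)))
        lv = LoopVector(values, pattern)
        if not is_loop(network, lv.values):  # construction guarantee, checked anyway
            raise AssertionError(f"planted loop on columns {support} failed exact verification")
        loops.append(lv)
    return PlantedNetwork(network, tuple(loops), seed)
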