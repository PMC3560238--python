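"""Exact rational vector/matrix helpers shared across the package.

Matrices are immutable tuples of row tuples of :class:`fractions.Fraction`;
vectors are tuples of Fractions.  Conversions accept ints, Fractions,
decimal/fraction strings and floats that are exactly representable
(``float.as_integer_ratio``).
"""

from __future__ import annotations

from fractions import Fraction
from math import gcd
from typing import Iterable, Sequence

RatVec = tuple[Fraction, ...]
RatMat = tuple[RatVec, ...]


def to_fraction(x) -> Fraction:
    """Coerce ``x`` to an exact Fraction (floats via their binary expansion)."""
    if isinstance(x, Fraction):
        return x
    if isinstance(x, (int, str)):
        return Fraction(x)
    if isinstance(x, float):
        return Fraction(*x.as_integer_ratio())
    # numpy scalars
    if hasattr(x, "item"):
        return to_fraction(x.item())
    raise TypeError(f"cannot convert {x!r} to Fraction")


def as_vector(v: Iterable) -> RatVec:
    return tuple(to_fraction(x) for x in v)


def as_matrix(rows: Iterable[Iterable]) -> RatMat:
    mat = tuple(as_vector(r) for r in rows)
    if mat and len({len(r) for r in mat}) != 1:
        raise ValueError("ragged matrix")
    return mat


def zeros(n: int) -> RatVec:
    return (Fraction(0),) * n


def dot(a: Sequence[Fraction], b: Sequence[Fraction]) -> Fraction:
    if len(a) != len(b):
        raise ValueError(f"dimension mismatch: {len(a)} vs {len(b)}")
    return sum((x * y for x, y in zip(a, b)), Fraction(0))


def mat_vec(A: RatMat, x: Sequence[Fraction]) -> RatVec:
    return tuple(dot(row, x) for row in A)


def transpose(A: RatMat) -> RatMat:
    return tuple(zip(*A)) if A else ()


def columns(A: RatMat) -> list[RatVec]:
    return [tuple(row[j] for row in A) for j in range(len(A[0]))] if A else []


def sign(x: Fraction) -> int:
    return (x > 0) - (x < 0)


def scale_to_integers(v: Sequence[Fraction]) -> RatVec:
    """Smallest integer form by *positive* scaling only — signs are preserved.

    The zero vector is returned unchanged.
    """
    v = as_vector(v)
    if not any(v):
        return v
    denom_lcm = 1
    for x in v:
        denom_lcm = denom_lcm * x.denominator // gcd(denom_lcm, x.denominator)
    ints = [int(x * denom_lcm) for x in v]
    g = 0
    for k in ints:
        g = gcd(g, k)
    return tuple(Fraction(k // g) for k in ints)


def normalize_integer(v: Sequence[Fraction]) -> RatVec:
    """Scale ``v`` to smallest integer form with first nonzero entry positive.

    The zero vector is returned unchanged.
    """
    v = scale_to_integers(v)
    if not any(v):
        return v
    first = next(x for x in v if x)
    if first < 0:
        v = tuple(-x for x in v)
    return v
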