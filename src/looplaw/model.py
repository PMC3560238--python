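"""Stoichiometric network data model.

Rows are metabolites, columns are reactions (standard COBRA orientation, so
the steady state reads ``S·v = 0``).  Stoichiometric coefficients are stored
as exact rationals; every vector is keyed by a stable id tuple so that column
order can never silently diverge between the matrix and a flux vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from ._rational import RatMat, as_matrix

DEFAULT_FLUX_TOLERANCE = 1e-9


class ValidationError(ValueError):
    """Raised when a network or vector violates a structural invariant."""


@dataclass(frozen=True)
class SignPattern:
    """Direction abstraction of a flux distribution: entries in {−1, 0, +1}."""

    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        bad = [s for s in self.signs if s not in (-1, 0, 1)]
        if bad:
            raise ValidationError(f"sign pattern entries must be in {{-1,0,1}}, got {bad}")
        object.__setattr__(self, "signs", tuple(int(s) for s in self.signs))

    def __len__(self) -> int:
        return len(self.signs)

    def __iter__(self):
        return iter(self.signs)

    def __neg__(self) -> "SignPattern":
        return SignPattern(tuple(-s for s in self.signs))

    @property
    def active(self) -> tuple[int, ...]:
        """Indices with nonzero sign."""
        return tuple(i for i, s in enumerate(self.signs) if s)


@dataclass(frozen=True)
class StoichiometricNetwork:
    """A metabolite × reaction stoichiometric matrix with an internal/exchange split.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Row and column identifiers; must be unique.
    stoich
        m × n matrix of exact rational coefficients (any input convertible by
        :func:`looplaw._rational.as_matrix`).
    internal_mask
        True for internal reactions; the submatrix they select is the matrix
        whose null space defines loops.
    lower_bounds, upper_bounds
        Per-reaction flux bounds, ``lower ≤ upper``.
    """

    metabolite_ids: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    stoich: RatMat
    internal_mask: tuple[bool, ...]
    lower_bounds: tuple[float, ...]
    upper_bounds: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolite_ids", tuple(self.metabolite_ids))
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "stoich", as_matrix(self.stoich))
        object.__setattr__(self, "internal_mask", tuple(bool(b) for b in self.internal_mask))
        object.__setattr__(self, "lower_bounds", tuple(float(b) for b in self.lower_bounds))
        object.__setattr__(self, "upper_bounds", tuple(float(b) for b in self.upper_bounds))
        m, n = len(self.metabolite_ids), len(self.reaction_ids)
        if m < 1 or n < 1:
            raise ValidationError("network needs at least one metabolite and one reaction")
        if len(set(self.metabolite_ids)) != m:
            raise ValidationError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != n:
            raise ValidationError("duplicate reaction ids")
        if len(self.stoich) != m or any(len(r) != n for r in self.stoich):
            raise ValidationError(f"stoichiometry must be {m}×{n}")
        for name in ("internal_mask", "lower_bounds", "upper_bounds"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} must have length {n}")
        for j, (lo, hi) in enumerate(zip(self.lower_bounds, self.upper_bounds)):
            if lo > hi:
                raise ValidationError(
                    f"reaction {self.reaction_ids[j]!r}: lower bound {lo} > upper bound {hi}"
                )
        for j, internal in enumerate(self.internal_mask):
            if internal and all(row[j] == 0 for row in self.stoich):
                raise ValidationError(
                    f"internal reaction {self.reaction_ids[j]!r} has an all-zero column"
                )

    # -- shape shortcuts -------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n(self) -> int:
        return len(self.reaction_ids)

    @property
    def n_int(self) -> int:
        return sum(self.internal_mask)

    @property
    def internal_indices(self) -> tuple[int, ...]:
        return tuple(j for j, b in enumerate(self.internal_mask) if b)

    @property
    def internal_reaction_ids(self) -> tuple[str, ...]:
        return tuple(self.reaction_ids[j] for j in self.internal_indices)

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"unknown reaction {reaction_id!r}") from None

    def stoich_array(self) -> np.ndarray:
        """Full matrix S as float array (m × n)."""
        return np.array([[float(x) for x in row] for row in self.stoich], dtype=float)


@dataclass(frozen=True)
class FluxDistribution:
    """A flux vector keyed by reaction ids, with a sign-classification tolerance."""

    reaction_ids: tuple[str, ...]
    values: tuple[float, ...]
    tolerance: float = DEFAULT_FLUX_TOLERANCE

    def __post_init__(self) -> None:
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        object.__setattr__(self, "values", tuple(float(x) for x in self.values))
        if len(self.reaction_ids) != len(self.values):
            raise ValidationError("reaction_ids and values length mismatch")
        if self.tolerance < 0:
            raise ValidationError("tolerance must be nonnegative")

    @classmethod
    def from_dict(
        cls,
        network: StoichiometricNetwork,
        values: Mapping[str, float],
        tolerance: float = DEFAULT_FLUX_TOLERANCE,
    ) -> "FluxDistribution":
        missing = [r for r in network.reaction_ids if r not in values]
        if missing:
            raise ValidationError(f"flux values missing for reactions: {missing}")
        extra = [r for r in values if r not in set(network.reaction_ids)]
        if extra:
            raise ValidationError(f"flux values for unknown reactions: {extra}")
        return cls(network.reaction_ids, tuple(values[r] for r in network.reaction_ids), tolerance)

    def __len__(self) -> int:
        return len(self.values)

    def check_against(self, network: StoichiometricNetwork) -> None:
        if self.reaction_ids != network.reaction_ids:
            raise ValidationError("flux distribution keys do not match the network")


def internal_submatrix(network: StoichiometricNetwork) -> RatMat:
    """Columns of S belonging to internal reactions, order preserved (m × n_int)."""
    idx = network.internal_indices
    return tuple(tuple(row[j] for j in idx) for row in network.stoich)


def sign_pattern(v: FluxDistribution) -> SignPattern:
    """Threshold each flux at ±tolerance: > tol → +1, < −tol → −1, else 0."""
    tol = v.tolerance
    return SignPattern(
        tuple(1 if x > tol else (-1 if x < -tol else 0) for x in v.values)
    )


def classify_reactions(
    stoich, reaction_ids: Sequence[str] | None = None
) -> tuple[bool, ...]:
    """Heuristic internal/exchange split for unlabeled input.

    A column with exactly one nonzero entry is an exchange reaction (it moves a
    metabolite across the system boundary); everything else is internal.  An
    all-zero column is rejected.  Callers with explicit labels must use those
    instead of calling this.
    """
    mat = as_matrix(stoich)
    if not mat or not mat[0]:
        raise ValidationError("empty stoichiometric matrix")
    n = len(mat[0])
    names = tuple(reaction_ids) if reaction_ids is not None else tuple(
        f"column {j}" for j in range(n)
    )
    mask = []
    for j in range(n):
        nnz = sum(1 for row in mat if row[j] != 0)
        if nnz == 0:
            raise ValidationError(f"reaction {names[j]!r} has an all-zero stoichiometry column")
        mask.append(nnz > 1)
    return tuple(mask)
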