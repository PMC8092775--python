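"""Sequence-space occupancy of motif classes.

A class of structure ``e`` over an ``A``-symbol alphabet covers
``prod_i e_i`` of the ``A^n`` length-``n`` sequences.  If every potential
class of that structure at specificity level ``k`` came into existence, the
covered fraction is the class occupancy times the (unfloored) class-count
bound; for ``k = 1`` the product telescopes to exactly 1 — every sequence
would be a motif instance.  No closed form exists at ``k = 0``, where
instances may belong to several classes at once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .combinatorics import _check_structure
from .motif_model import MotifStructure

__all__ = ["OccupancyResult", "class_occupancy", "occupancy", "potential_occupancy"]


def _class_occupancy_exact(e: MotifStructure, alphabet_size: int) -> Fraction:
    return Fraction(math.prod(e), alphabet_size ** len(e))


def class_occupancy(structure: Sequence[int], alphabet_size: int = 20,
                    exact: bool = False) -> "float | Fraction":
    """Fraction of all length-n sequences that are instances of one class:
    ``prod_i e_i / A^n``."""
    e = _check_structure(structure, alphabet_size)
    value = _class_occupancy_exact(e, alphabet_size)
    return value if exact else float(value)


def potential_occupancy(structure: Sequence[int], alphabet_size: int = 20,
                        k: int = 1, exact: bool = False) -> "float | Fraction":
    """Occupancy if all potential classes existed: class occupancy times the
    unfloored ``|M(k)|`` bound.

    The class-count factor is kept unfloored at every ``k`` so that the
    telescoping identity at ``k = 1`` (total occupancy exactly 1) and the
    ``k = 2`` closed form ``min_i e_i / A`` hold for structures of any
    length.  ``k = 0`` is rejected: with overlapping classes no product
    formula holds.
    """
    e = _check_structure(structure, alphabet_size)
    n = len(e)
    if k == 0:
        raise ValueError("no closed form for potential occupancy at k = 0 "
                         "(instances may belong to several classes)")
    if k < 0 or k > n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    kept = sorted(e, reverse=True)[: n - (k - 1)]
    classes = math.prod((Fraction(alphabet_size, ei) for ei in kept),
                        start=Fraction(1))
    value = _class_occupancy_exact(e, alphabet_size) * classes
    return value if exact else float(value)


@dataclass(frozen=True)
class OccupancyResult:
    """Occupancy of one structure at one specificity level."""

    structure: MotifStructure
    alphabet_size: int
    k: int
    class_occupancy: float
    potential_occupancy: float

    def to_dict(self) -> dict:
        return {"structure": list(self.structure),
                "alphabet_size": self.alphabet_size, "k": self.k,
                "class_occupancy": self.class_occupancy,
                "potential_occupancy": self.potential_occupancy}


def occupancy(structure: Sequence[int], alphabet_size: int = 20,
              k: int = 1) -> OccupancyResult:
    e = _check_structure(structure, alphabet_size)
    return OccupancyResult(
        e, alphabet_size, k,
        class_occupancy=class_occupancy(e, alphabet_size),
        potential_occupancy=potential_occupancy(e, alphabet_size, k),
    )
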