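"""Pairwise sequence specificity of motif classes.

Two classes of equal length are compared position by position: a
*motif-discriminating position* is one where both classes are fixed (allow at
most 10 residues) and their allowed sets are disjoint, so no amino acid can
match both regular expressions there.  Classes of unequal length are compared
over every no-overhang alignment of the shorter class against the longer one;
alignments without any fixed-fixed position pair are uninformative and
discarded, and the pair's mdp is the minimum over the informative alignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .motif_model import MotifClass, MotifDatabase

__all__ = [
    "FIXED_POSITION_THRESHOLD",
    "PairSpecificity",
    "PairwiseResult",
    "alignments",
    "alignval",
    "fixed_positions",
    "mdp_equal_length",
    "mdp_general",
    "pairwise_matrix",
]

#: A position is "fixed" when it allows at most this many residues.
FIXED_POSITION_THRESHOLD = 10

Positions = tuple[frozenset, ...]


def _positions(motif: "MotifClass | Sequence[frozenset]") -> Positions:
    if isinstance(motif, MotifClass):
        return motif.positions
    return tuple(motif)


@dataclass(frozen=True)
class PairSpecificity:
    """Specificity of one unordered pair of motif classes.

    ``mdp`` is 0 with ``informative=False`` when no alignment matches a pair
    of fixed positions, so such pairs fall in the "not separated" bin.
    """

    mdp: int
    informative: bool
    coincident: bool
    alignments_total: int
    alignments_informative: int


def fixed_positions(motif: "MotifClass | Sequence[frozenset]",
                    threshold: int = FIXED_POSITION_THRESHOLD) -> frozenset[int]:
    """1-based indices of positions allowing at most ``threshold`` residues."""
    return frozenset(
        i for i, allowed in enumerate(_positions(motif), start=1)
        if len(allowed) <= threshold)


def mdp_equal_length(a, b, threshold: int = FIXED_POSITION_THRESHOLD) -> int:
    """Count of positions where both classes are fixed and disjoint."""
    pa, pb = _positions(a), _positions(b)
    if len(pa) != len(pb):
        raise ValueError("classes differ in length; use mdp_general")
    return sum(
        1 for sa, sb in zip(pa, pb)
        if len(sa) <= threshold and len(sb) <= threshold and not (sa & sb))


def alignval(a, b, threshold: int = FIXED_POSITION_THRESHOLD) -> int:
    """1 iff some position is fixed in both classes (equal lengths)."""
    pa, pb = _positions(a), _positions(b)
    if len(pa) != len(pb):
        raise ValueError("classes differ in length; align first")
    return int(any(
        len(sa) <= threshold and len(sb) <= threshold for sa, sb in zip(pa, pb)))


def alignments(a, b) -> list[tuple[Positions, Positions]]:
    """The ``n - m + 1`` no-overhang alignments of the shorter class against
    contiguous windows of the longer one (lengths ``n >= m``)."""
    pa, pb = _positions(a), _positions(b)
    if len(pa) < len(pb):
        pa, pb = pb, pa
    m = len(pb)
    return [(pa[i:i + m], pb) for i in range(len(pa) - m + 1)]


def mdp_general(a, b, threshold: int = FIXED_POSITION_THRESHOLD) -> PairSpecificity:
    """Motif-discriminating positions for classes of any lengths.

    The mdp is the minimum of the per-alignment counts over informative
    alignments; symmetric in its arguments.  Coincidence (identical position
    lists) is defined for equal lengths only.
    """
    pa, pb = _positions(a), _positions(b)
    pairs = alignments(pa, pb)
    informative_values = [
        mdp_equal_length(wa, wb, threshold) for wa, wb in pairs
        if alignval(wa, wb, threshold)]
    informative = bool(informative_values)
    return PairSpecificity(
        mdp=min(informative_values) if informative else 0,
        informative=informative,
        coincident=len(pa) == len(pb) and pa == pb,
        alignments_total=len(pairs),
        alignments_informative=len(informative_values),
    )


@dataclass
class PairwiseResult:
    """All-pairs specificity of a database."""

    pairs: pd.DataFrame  # columns id_a, id_b, mdp, informative, coincident
    histogram: dict[int, int]  # mdp value -> number of pairs
    n_pairs: int
    frac_separated: float  # share of pairs with mdp >= 1
    frac_informative: float
    frac_coincident: float


def pairwise_matrix(db: MotifDatabase,
                    threshold: int = FIXED_POSITION_THRESHOLD) -> PairwiseResult:
    """Specificity records for all C(N,2) unordered class pairs."""
    if len(db) < 2:
        raise ValueError("need at least 2 classes for pairwise comparison")
    records = []
    for a, b in itertools.combinations(db.classes, 2):
        spec = mdp_general(a, b, threshold)
        records.append({"id_a": a.identifier, "id_b": b.identifier,
                        "mdp": spec.mdp, "informative": spec.informative,
                        "coincident": spec.coincident})
    pairs = pd.DataFrame.from_records(records)
    counts = pairs["mdp"].value_counts().sort_index()
    n = len(pairs)
    return PairwiseResult(
        pairs=pairs,
        histogram={int(k): int(v) for k, v in counts.items()},
        n_pairs=n,
        frac_separated=float((pairs["mdp"] >= 1).mean()),
        frac_informative=float(pairs["informative"].mean()),
        frac_coincident=float(pairs["coincident"].mean()),
    )
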