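"""Bounds and constructions for families of mutually discriminating motif classes.

For a structure ``e = (e_1, ..., e_n)`` over an alphabet of ``A`` symbols,
``M(k)`` denotes the maximal number of motif classes of that structure such
that every pair differs at ``k`` or more positions with disjoint allowed sets
(``k = 0``: every pair intersects at every position).  The closed forms are:

* ``k = 0``: at most ``prod_i C(A-1, e_i-1)`` (per-position Erdős–Ko–Rado);
* ``k = 1``: between ``prod_i floor(A/e_i)`` (a blockwise construction) and
  ``prod_i A/e_i`` (pigeonhole);
* ``1 <= k < n``: at most the product of ``A/e_i`` over the ``n-(k-1)``
  largest-``e`` positions (sorting ``e`` descending sharpens the bound);
* ``k = n``: exactly ``min_i floor(A/e_i)``.

An exhaustive maximum-clique oracle over all candidate classes is provided
for small instances.
"""

from __future__ import annotations

import itertools
import math
import sys
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

from .motif_model import Alphabet, MotifStructure

__all__ = [
    "BoundResult",
    "bounds",
    "build_1_discriminating_set",
    "ekr_valid",
    "exhaustive_max_discriminating",
    "m0_upper",
    "m1_lower",
    "mk_upper",
    "mk_lower",
    "mn_exact",
    "potential_classes",
]


def _check_structure(structure: Sequence[int], alphabet_size: int) -> MotifStructure:
    e = tuple(int(x) for x in structure)
    if not e:
        raise ValueError("structure must have at least one position")
    if any(x < 1 for x in e):
        raise ValueError("structure entries must be >= 1")
    if any(x > alphabet_size for x in e):
        raise ValueError(
            f"structure entry exceeds alphabet size {alphabet_size}: {e}")
    return e


def ekr_valid(structure: Sequence[int], alphabet_size: int = 20) -> bool:
    """True iff every position satisfies 2*e_i <= A, the regime where the
    Erdős–Ko–Rado bound applies as a theorem."""
    e = _check_structure(structure, alphabet_size)
    return all(2 * ei <= alphabet_size for ei in e)


def m0_upper(structure: Sequence[int], alphabet_size: int = 20) -> int:
    """Upper bound on 0-discriminating families: ``prod_i C(A-1, e_i-1)``.

    The binomial is evaluated as printed at every position; where
    ``2*e_i > A`` the Erdős–Ko–Rado theorem does not apply and a warning is
    issued (the factor then understates the true per-position maximum).
    """
    e = _check_structure(structure, alphabet_size)
    if not ekr_valid(e, alphabet_size):
        warnings.warn(
            "positions with 2*e_i > alphabet size: Erdős–Ko–Rado bound "
            "evaluated as printed but not guaranteed", stacklevel=2)
    return math.prod(math.comb(alphabet_size - 1, ei - 1) for ei in e)


def m1_lower(structure: Sequence[int], alphabet_size: int = 20) -> int:
    """Constructive lower bound on 1-discriminating families:
    ``prod_i floor(A/e_i)`` (per-factor floor)."""
    e = _check_structure(structure, alphabet_size)
    return math.prod(alphabet_size // ei for ei in e)


def mk_upper(structure: Sequence[int], alphabet_size: int = 20,
             k: int = 1) -> tuple[float, int]:
    """Pigeonhole upper bound on k-discriminating families, ``1 <= k <= n``.

    Sorts ``e`` descending and multiplies ``A/e_i`` over the first
    ``n-(k-1)`` entries; returns the real value and its floor (the floor is
    applied once, to the final product).
    """
    e = _check_structure(structure, alphabet_size)
    n = len(e)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    kept = sorted(e, reverse=True)[: n - (k - 1)]
    exact = math.prod((Fraction(alphabet_size, ei) for ei in kept),
                      start=Fraction(1))
    return float(exact), math.floor(exact)


def mk_lower(structure: Sequence[int], alphabet_size: int = 20,
             k: int = 1) -> int:
    """Per-factor-floored variant of the truncated product,
    ``prod floor(A/e_i)`` over the ``n-(k-1)`` largest-``e`` positions.

    For ``k = 1`` this is the constructive bound :func:`m1_lower`; for
    ``k = n`` it equals :func:`mn_exact`.
    """
    e = _check_structure(structure, alphabet_size)
    n = len(e)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    kept = sorted(e, reverse=True)[: n - (k - 1)]
    return math.prod(alphabet_size // ei for ei in kept)


def mn_exact(structure: Sequence[int], alphabet_size: int = 20) -> int:
    """Exact maximum of n-discriminating families: ``min_i floor(A/e_i)``."""
    e = _check_structure(structure, alphabet_size)
    return min(alphabet_size // ei for ei in e)


def potential_classes(structure: Sequence[int], alphabet_size: int = 20,
                      k: int = 1) -> int:
    """Number of potential motif classes ``|M(k)|`` for ``0 <= k <= n``.

    Dispatches to :func:`m0_upper` (k=0), the floored :func:`mk_upper`
    (1 <= k < n) and :func:`mn_exact` (k=n).
    """
    e = _check_structure(structure, alphabet_size)
    n = len(e)
    if k < 0 or k > n:
        raise ValueError(f"k must be in 0..{n}, got {k}")
    if k == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return m0_upper(e, alphabet_size)
    if k == n:
        return mn_exact(e, alphabet_size)
    return mk_upper(e, alphabet_size, k)[1]


@dataclass(frozen=True)
class BoundResult:
    """Lower/upper bounds on ``|M(k)|`` for one structure and alphabet."""

    structure: MotifStructure
    alphabet_size: int
    k: int
    lower: int | None
    upper_real: float
    upper_int: int
    exact: bool
    ekr_valid: bool

    def to_dict(self) -> dict:
        return {"structure": list(self.structure),
                "alphabet_size": self.alphabet_size, "k": self.k,
                "lower": self.lower, "upper_real": self.upper_real,
                "upper_int": self.upper_int, "exact": self.exact,
                "ekr_valid": self.ekr_valid}


def bounds(structure: Sequence[int], alphabet_size: int = 20,
           k: int = 1) -> BoundResult:
    """All applicable bounds on ``|M(k)|`` collected in one record."""
    e = _check_structure(structure, alphabet_size)
    n = len(e)
    valid = ekr_valid(e, alphabet_size)
    if k == 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            up = m0_upper(e, alphabet_size)
        return BoundResult(e, alphabet_size, k, None, float(up), up, False, valid)
    if k == n:
        exact = mn_exact(e, alphabet_size)
        return BoundResult(e, alphabet_size, k, exact, float(exact), exact,
                           True, valid)
    real, floored = mk_upper(e, alphabet_size, k)
    lower = m1_lower(e, alphabet_size) if k == 1 else None
    return BoundResult(e, alphabet_size, k, lower, real, floored,
                       lower == floored, valid)


# ---------------------------------------------------------------------------
# Constructive lower bound
# ---------------------------------------------------------------------------

def build_1_discriminating_set(structure: Sequence[int],
                               alphabet: "Alphabet | int" = 20,
                               ) -> list[tuple[frozenset[str], ...]]:
    """Blockwise construction of a 1-discriminating family.

    At each position ``i`` the alphabet is cut into ``floor(A/e_i)`` pairwise
    disjoint blocks of ``e_i`` consecutive symbols; the family is the
    Cartesian product of the per-position block choices, of size exactly
    :func:`m1_lower`.  Any two members differ in some coordinate, where their
    blocks are disjoint by construction.
    """
    if isinstance(alphabet, int):
        alphabet = Alphabet.of_size(alphabet)
    e = _check_structure(structure, alphabet.size)
    per_position = []
    for ei in e:
        blocks = [
            frozenset(alphabet.symbols[j * ei:(j + 1) * ei])
            for j in range(alphabet.size // ei)]
        per_position.append(blocks)
    return [tuple(choice) for choice in itertools.product(*per_position)]


# ---------------------------------------------------------------------------
# Exhaustive oracle for tiny instances
# ---------------------------------------------------------------------------

def _candidate_masks(alphabet_size: int, e: MotifStructure) -> list[tuple[int, ...]]:
    per = [
        [sum(1 << s for s in combo)
         for combo in itertools.combinations(range(alphabet_size), ei)]
        for ei in e]
    return list(itertools.product(*per))


def _adjacency(cand: list[tuple[int, ...]], k: int) -> list[int]:
    n = len(cand)
    adj = [0] * n
    for i in range(n):
        ci = cand[i]
        for j in range(i + 1, n):
            disjoint = sum(1 for a, b in zip(ci, cand[j]) if a & b == 0)
            if (disjoint == 0) if k == 0 else (disjoint >= k):
                adj[i] |= 1 << j
                adj[j] |= 1 << i
    return adj


def _max_clique(adj: list[int]) -> int:
    """Exact maximum clique size; branch and bound with greedy colouring,
    vertex sets as bit masks."""
    n = len(adj)
    if n == 0:
        return 0
    # cheap greedy seed for the initial bound
    best, seed = 0, (1 << n) - 1
    while seed:
        v = (seed & -seed).bit_length() - 1
        best += 1
        seed &= adj[v]

    limit = sys.getrecursionlimit()
    if limit < n + 100:
        sys.setrecursionlimit(n + 1000)

    def expand(pool: int, size: int) -> None:
        nonlocal best
        order, colours = [], []
        uncoloured, colour = pool, 0
        while uncoloured:
            colour += 1
            candidates = uncoloured
            while candidates:
                v = (candidates & -candidates).bit_length() - 1
                bit = 1 << v
                order.append(v)
                colours.append(colour)
                uncoloured ^= bit
                candidates &= ~bit & ~adj[v]
        for idx in range(len(order) - 1, -1, -1):
            if size + colours[idx] <= best:
                return
            v = order[idx]
            successors = pool & adj[v]
            if size + 1 > best:
                best = size + 1
            if successors:
                expand(successors, size + 1)
            pool &= ~(1 << v)

    expand((1 << n) - 1, 0)
    return best


def exhaustive_max_discriminating(structure: Sequence[int],
                                  alphabet_size: int = 4, k: int = 1,
                                  cap: int = 10_000) -> int:
    """Exact maximum size of a k-discriminating family by exhaustive search.

    Enumerates every candidate class of the structure (deterministic
    lexicographic order), builds the pairwise compatibility graph (``k = 0``:
    all coordinates intersect; ``k >= 1``: at least ``k`` disjoint
    coordinates) and solves maximum clique exactly.  Guarded by ``cap`` on
    the number of candidate classes ``prod_i C(A, e_i)``; above the cap use
    the closed-form bounds instead.  Beware that dense instances with
    several hundred candidates can already take impractically long.
    """
    e = _check_structure(structure, alphabet_size)
    if k < 0 or k > len(e):
        raise ValueError(f"k must be in 0..{len(e)}, got {k}")
    n_candidates = math.prod(math.comb(alphabet_size, ei) for ei in e)
    if n_candidates > cap:
        raise ValueError(
            f"{n_candidates} candidate classes exceed cap {cap}; "
            "use the closed-form bounds instead")
    cand = _candidate_masks(alphabet_size, e)
    return _max_clique(_adjacency(cand, k))
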