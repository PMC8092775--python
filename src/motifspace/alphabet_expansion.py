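"""Effective alphabet size under post-translational modification.

Post-translationally modified residues enlarge the amino acid alphabet, but
the >500 known modifications are used extremely unevenly.  The effective
number of modifications is the Hill number of order one, ``2^H`` for Shannon
entropy ``H`` (base 2) of the modification frequency mixture — the count of
equally frequent modification types with the same entropy.  Adding the
rounded effective count (and selenocysteine) to the 20 canonical amino acids
gives the expanded alphabet size used in the class-count bounds.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectiveNumber",
    "ModificationMixture",
    "effective_number",
    "expanded_alphabet_size",
    "load_ptm_fixture",
    "shannon_entropy",
]


@dataclass(frozen=True)
class ModificationMixture:
    """Named nonnegative counts (or relative frequencies) of modifications."""

    names: tuple[str, ...]
    counts: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.counts):
            raise ValueError("names and counts differ in length")
        if not self.names:
            raise ValueError("mixture must have at least one entry")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be nonnegative")
        if not any(c > 0 for c in self.counts):
            raise ValueError("mixture must have at least one positive entry")

    @property
    def frequencies(self) -> np.ndarray:
        """Counts normalized to sum 1."""
        counts = np.asarray(self.counts, dtype=float)
        return counts / counts.sum()

    @classmethod
    def from_tsv(cls, path: "str | Path") -> "ModificationMixture":
        """Read a 2-column (name, count) tab-separated table;
        '#'-prefixed lines are comments."""
        frame = pd.read_csv(path, sep="\t", comment="#")
        name_col, count_col = frame.columns[:2]
        return cls(tuple(frame[name_col].astype(str)),
                   tuple(frame[count_col].astype(float)))


def _freqs(mixture: "ModificationMixture | Sequence[float]") -> np.ndarray:
    if isinstance(mixture, ModificationMixture):
        return mixture.frequencies
    counts = np.asarray(mixture, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("expected a 1-d sequence of counts")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("mixture must have at least one positive entry")
    return counts / total


def shannon_entropy(mixture: "ModificationMixture | Sequence[float]") -> float:
    """Shannon entropy in bits of the normalized mixture
    (zero-frequency entries contribute nothing)."""
    return float(stats.entropy(_freqs(mixture), base=2))


class EffectiveNumber(NamedTuple):
    value: float  #: 2^H
    rounded: int  #: nearest integer, the reported effective count


def effective_number(mixture: "ModificationMixture | Sequence[float]",
                     ) -> EffectiveNumber:
    """Effective number of modifications ``2^H`` and its nearest-integer
    rounding.  Lies between 1 and the number of positive entries, with
    equality at the uniform mixture; invariant under count rescaling."""
    value = float(2.0 ** shannon_entropy(mixture))
    return EffectiveNumber(value, round(value))


def expanded_alphabet_size(base: int = 20, include_selenocysteine: bool = True,
                           effective_modifications: int = 0) -> int:
    """Expanded amino acid alphabet size:
    base + selenocysteine (optional) + effective modification count."""
    if base < 2 or effective_modifications < 0:
        raise ValueError("base must be >= 2 and modifications nonnegative")
    return base + int(include_selenocysteine) + effective_modifications


def load_ptm_fixture() -> ModificationMixture:
    """Packaged synthetic modification-frequency table.

    Twelve dominant modification types with illustrative counts spanning
    several orders of magnitude — test scaffolding mirroring the shape of a
    Swissprot-derived frequency table, not real curated abundances.
    """
    ref = resources.files("motifspace").joinpath("data/ptm_fixture_synthetic.tsv")
    with resources.as_file(ref) as path:
        return ModificationMixture.from_tsv(path)
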