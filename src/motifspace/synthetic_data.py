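"""Seeded generators for ELM-like motif databases and modification mixtures.

The generator emulates the marginal statistics of a curated linear-motif
class table: lengths concentrated on 4–7 positions, per-position allowed
counts that are bimodal (mostly 1–3 — fixed positions — or 19–20 — wildcards
and single-exclusion positions), heavy-tailed known-instance counts, and a
configurable fraction of planted same-name near-duplicate classes that the
curation step is expected to remove.  All sampling is deterministic under
the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .alphabet_expansion import ModificationMixture
from .motif_model import (
    CANONICAL_ALPHABET,
    Alphabet,
    MotifClass,
    MotifDatabase,
    canonical_regex,
)

__all__ = [
    "DEFAULT_LENGTH_DISTRIBUTION",
    "DEFAULT_POSITION_SIZE_DISTRIBUTION",
    "GeneratorConfig",
    "PREPROCESSING_EXAMPLES",
    "fixture_paper_examples",
    "sample_database",
    "sample_ptm_mixture",
]

#: Motif length distribution: mass concentrated on 3-10, mode 4-6.
DEFAULT_LENGTH_DISTRIBUTION: Mapping[int, float] = {
    3: 0.08, 4: 0.22, 5: 0.28, 6: 0.18, 7: 0.10, 8: 0.07, 9: 0.04, 10: 0.03,
}

#: Allowed-count distribution per position: bimodal, most positions allow
#: 1-3 residues (fixed) or 19-20 (wildcard / single exclusion).
DEFAULT_POSITION_SIZE_DISTRIBUTION: Mapping[int, float] = {
    1: 0.32, 2: 0.13, 3: 0.07, 4: 0.03, 5: 0.02, 6: 0.015, 7: 0.01,
    8: 0.008, 9: 0.006, 10: 0.006, 19: 0.09, 20: 0.295,
}


def _validate_distribution(dist: Mapping[int, float], name: str) -> None:
    if not dist:
        raise ValueError(f"{name} is empty")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative mass")
    if abs(sum(dist.values()) - 1.0) > 1e-9:
        raise ValueError(f"{name} does not sum to 1")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic motif database."""

    n_classes: int = 172
    length_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION))
    position_size_distribution: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_POSITION_SIZE_DISTRIBUTION))
    #: log-normal parameters (mean, sigma of log counts) of known instances
    instance_count_log_mean: float = 1.8
    instance_count_log_sigma: float = 1.3
    duplicate_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")
        _validate_distribution(self.length_distribution, "length_distribution")
        _validate_distribution(self.position_size_distribution,
                               "position_size_distribution")


def _sample_categorical(rng: np.random.Generator, dist: Mapping[int, float],
                        size: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys], dtype=float)
    return rng.choice(keys, size=size, p=probs / probs.sum())


def sample_database(config: GeneratorConfig = GeneratorConfig(),
                    alphabet: Alphabet = CANONICAL_ALPHABET) -> MotifDatabase:
    """Sample a motif database of ``config.n_classes`` classes.

    Each class draws its length and per-position allowed counts from the
    configured categorical distributions; the allowed set at a position is a
    uniform random subset of that size.  A ``duplicate_fraction`` share of
    the classes are near-duplicate clones of earlier classes: same group
    name, allowed sets widened at one position (hence zero discriminating
    positions against the original) and strictly fewer known instances.
    """
    if max(config.position_size_distribution) > alphabet.size:
        raise ValueError("position sizes exceed the alphabet size")
    rng = np.random.default_rng(config.seed)
    n_dup = int(round(config.duplicate_fraction * config.n_classes))
    n_base = config.n_classes - n_dup

    classes: list[MotifClass] = []
    lengths = _sample_categorical(rng, config.length_distribution, n_base)
    for i in range(n_base):
        sizes = _sample_categorical(
            rng, config.position_size_distribution, int(lengths[i]))
        positions = tuple(
            frozenset(alphabet.symbols[j]
                      for j in rng.choice(alphabet.size, size=int(e), replace=False))
            for e in sizes)
        count = max(1, int(round(rng.lognormal(
            config.instance_count_log_mean, config.instance_count_log_sigma))))
        regex = canonical_regex(positions, alphabet)
        classes.append(MotifClass(
            identifier=f"SYN{i:04d}", group_name=f"synthetic group {i:04d}",
            source_regex=regex, positions=positions, known_instances=count,
            alphabet=alphabet))

    if n_dup:
        targets = rng.choice(n_base, size=n_dup, replace=False)
        for j, t in enumerate(sorted(int(x) for x in targets)):
            original = classes[t]
            positions = list(original.positions)
            # widen one non-full position so every coordinate still intersects
            widenable = [i for i, p in enumerate(positions)
                         if len(p) < alphabet.size]
            if widenable:
                at = int(rng.choice(widenable))
                extra = str(rng.choice(
                    sorted(alphabet.symbol_set - positions[at],
                           key=alphabet.index)))
                positions[at] = positions[at] | {extra}
            dup_positions = tuple(positions)
            classes.append(MotifClass(
                identifier=f"SYN{t:04d}DUP{j}", group_name=original.group_name,
                source_regex=canonical_regex(dup_positions, alphabet),
                positions=dup_positions,
                known_instances=max(original.known_instances - 1, 0),
                alphabet=alphabet))

    return MotifDatabase(classes, alphabet, {
        "source": "motifspace.synthetic_data.sample_database",
        "seed": config.seed, "n_classes": config.n_classes,
        "duplicate_fraction": config.duplicate_fraction,
        "planted_duplicates": [c.identifier for c in classes[n_base:]],
    })


def sample_ptm_mixture(n_modifications: int = 522,
                       dynamic_range_orders: float = 5.0,
                       seed: int = 0) -> ModificationMixture:
    """Modification mixture with log-uniform counts spanning the requested
    number of orders of magnitude."""
    if n_modifications < 1:
        raise ValueError("n_modifications must be >= 1")
    rng = np.random.default_rng(seed)
    counts = 10.0 ** rng.uniform(0.0, dynamic_range_orders, n_modifications)
    names = tuple(f"modification {i:03d}" for i in range(n_modifications))
    return ModificationMixture(names, tuple(float(c) for c in counts))


#: Raw ELM-style regexes and their expected preprocessed forms: shortest
#: variable-length version, anchor stripping, selenocysteine rewriting and
#: wildcard-flank trimming.
PREPROCESSING_EXAMPLES: tuple[tuple[str, str], ...] = (
    ("[LIVMP].{0,2}(T)P..([ST])", "[LIVMP](T)P..([ST])"),
    ("F..F$", "F..F"),
    ("^M{0,1}([ED])", "([ED])"),
    ("[KR]R.", "[KR]R"),
    ("RV.PU", "RV.PC"),
)


def fixture_paper_examples() -> MotifDatabase:
    """Small worked-example database: the Rb pocket B ligand class
    [LI].C.[DE], the toy [FI].W class, the six blockwise (7,6) construction
    classes and the simplified forms of the preprocessing examples."""
    spec = [
        ("RB_LIG_1", "Rb pocket B binding ligand", "[LI].C.[DE]", 30),
        ("TOY_FIW", "toy FIW motif", "[FI].W", 5),
        ("BLOCK76_1", "blockwise (7,6) construction", "[ACDEFGH][ACDEFG]", 1),
        ("BLOCK76_2", "blockwise (7,6) construction", "[ACDEFGH][HIKLMN]", 1),
        ("BLOCK76_3", "blockwise (7,6) construction", "[ACDEFGH][PQRSTV]", 1),
        ("BLOCK76_4", "blockwise (7,6) construction", "[IKLMNPQ][ACDEFG]", 1),
        ("BLOCK76_5", "blockwise (7,6) construction", "[IKLMNPQ][HIKLMN]", 1),
        ("BLOCK76_6", "blockwise (7,6) construction", "[IKLMNPQ][PQRSTV]", 1),
        ("PRE_TP", "TP docking motif (simplified)", "[LIVMP](T)P..([ST])", 8),
        ("PRE_FF", "FF motif (simplified)", "F..F", 4),
        ("PRE_KRR", "basic KR motif (simplified)", "[KR]R", 12),
        ("PRE_RVP", "RVxP motif (simplified)", "RV.PC", 3),
    ]
    classes = [
        MotifClass.from_regex(identifier, regex, group_name=name,
                              known_instances=count)
        for identifier, name, regex, count in spec]
    return MotifDatabase(classes, CANONICAL_ALPHABET,
                         {"source": "motifspace.synthetic_data.fixture_paper_examples"})
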