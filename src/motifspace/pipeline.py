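"""Database-level analysis: curation, distributions, sweeps and robustness.

Operations here take a :class:`~motifspace.motif_model.MotifDatabase` and
aggregate the per-class combinatorial quantities into the database-level
summaries: redundancy removal, distributions of potential class counts and
occupancies with their survival-curve medians, alphabet-size sweeps, seeded
robustness experiments (subsampling, specificity split, mismatch tolerance)
and the back-of-envelope proteome arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import combinatorics, occupancy as occupancy_mod
from .motif_model import MotifClass, MotifDatabase
from .specificity import FIXED_POSITION_THRESHOLD, mdp_general

__all__ = [
    "DistributionSummary",
    "RobustnessReport",
    "alphabet_sweep",
    "deduplicate",
    "instances_from_residues",
    "mismatch_tolerance_experiment",
    "occupancy_distribution",
    "potential_distribution",
    "proteome_class_estimate",
    "specificity_split_experiment",
    "subsample_experiment",
]


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def deduplicate(db: MotifDatabase,
                threshold: int = FIXED_POSITION_THRESHOLD,
                ) -> tuple[MotifDatabase, list[str]]:
    """Remove redundant same-name minor-variant classes.

    Within each group of classes sharing a name, pairs with zero
    motif-discriminating positions are linked; in each connected component of
    such links only the class with the most known instances is kept (ties:
    earliest database order).  Returns the curated database and a removal
    log.  Idempotent.
    """
    order = {c.identifier: i for i, c in enumerate(db.classes)}
    parent = {c.identifier: c.identifier for c in db.classes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    by_name: dict[str, list[MotifClass]] = {}
    for c in db.classes:
        by_name.setdefault(c.group_name, []).append(c)
    for group in by_name.values():
        for i, a in enumerate(group):
            for b in group[i + 1:]:
                if mdp_general(a, b, threshold).mdp == 0:
                    parent[find(a.identifier)] = find(b.identifier)

    components: dict[str, list[MotifClass]] = {}
    for c in db.classes:
        components.setdefault(find(c.identifier), []).append(c)

    removed, log = set(), []
    for members in components.values():
        if len(members) == 1:
            continue
        keeper = max(members,
                     key=lambda c: (c.known_instances, -order[c.identifier]))
        for c in members:
            if c is not keeper:
                removed.add(c.identifier)
                log.append(
                    f"removed {c.identifier} ({c.known_instances} instances): "
                    f"no discriminating positions against {keeper.identifier} "
                    f"({keeper.known_instances} instances) in group "
                    f"{c.group_name!r}")
    kept = [c for c in db.classes if c.identifier not in removed]
    provenance = dict(db.provenance)
    provenance.setdefault("curation_log", []).extend(log)
    return MotifDatabase(kept, db.alphabet, provenance), log


# ---------------------------------------------------------------------------
# Distributions
# ---------------------------------------------------------------------------

@dataclass
class DistributionSummary:
    """Per-class values with the survival curve and its median.

    ``median`` follows the cumulative-probability convention: the largest
    value whose fraction of classes with value >= it is at least 0.5.  The
    standard interpolated median is reported alongside.
    """

    values: list[tuple[str, float]]
    cumulative_curve: list[tuple[float, float]]  # (threshold, frac >= threshold)
    median: float
    median_interpolated: float
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {"values": self.values,
                "cumulative_curve": self.cumulative_curve,
                "median": self.median,
                "median_interpolated": self.median_interpolated,
                "n_excluded": self.n_excluded}


def _summarize(values: list[tuple[str, float]], n_excluded: int = 0,
               ) -> DistributionSummary:
    if not values:
        raise ValueError("no classes contribute to the distribution")
    data = np.array([v for _, v in values], dtype=float)
    thresholds = np.unique(data)
    curve = [(float(t), float((data >= t).mean())) for t in thresholds]
    eligible = [t for t, frac in curve if frac >= 0.5]
    median = max(eligible)
    return DistributionSummary(
        values=values, cumulative_curve=curve, median=float(median),
        median_interpolated=float(np.median(data)), n_excluded=n_excluded)


def _per_class_potential(db: MotifDatabase, alphabet_size: int, k: int,
                         bound: str) -> tuple[list[tuple[str, float]], int]:
    values, excluded = [], 0
    for c in db:
        if len(c) < k:
            excluded += 1  # k discriminating positions undefined for n < k
            continue
        e = c.structure
        if bound == "upper":
            value = combinatorics.potential_classes(e, alphabet_size, k)
        elif bound == "lower":
            if k == 0:
                value = combinatorics.potential_classes(e, alphabet_size, 0)
            else:
                value = combinatorics.mk_lower(e, alphabet_size, k)
        else:
            raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")
        values.append((c.identifier, float(value)))
    return values, excluded


def potential_distribution(db: MotifDatabase, alphabet_size: int = 20,
                           k: int = 1, bound: str = "upper",
                           ) -> DistributionSummary:
    """Distribution of per-class potential class counts ``|M(k)|``.

    Classes shorter than ``k`` are excluded (counted in ``n_excluded``).
    ``bound`` selects the end-floored upper bound (default) or the
    per-factor-floored lower-bound variant.
    """
    if len(db) == 0:
        raise ValueError("empty database")
    values, excluded = _per_class_potential(db, alphabet_size, k, bound)
    return _summarize(values, excluded)


def occupancy_distribution(db: MotifDatabase, alphabet_size: int = 20,
                           k: int = 1) -> DistributionSummary:
    """Distribution of per-class potential sequence-space occupancy
    (``k >= 1``; at ``k = 1`` the median is exactly 1)."""
    if len(db) == 0:
        raise ValueError("empty database")
    if k < 1:
        raise ValueError("occupancy distribution requires k >= 1")
    values, excluded = [], 0
    for c in db:
        if len(c) < k:
            excluded += 1
            continue
        values.append((c.identifier, float(occupancy_mod.potential_occupancy(
            c.structure, alphabet_size, k))))
    return _summarize(values, excluded)


# ---------------------------------------------------------------------------
# Alphabet sweep
# ---------------------------------------------------------------------------

def alphabet_sweep(db: MotifDatabase, alphabet_sizes: Iterable[int] = range(20, 41),
                   ks: Iterable[int] = range(0, 5),
                   reference_size: int = 20) -> pd.DataFrame:
    """Median potential class count per (alphabet size, k) and the fold
    change against the reference alphabet size.

    Both the per-factor-floored lower-bound and end-floored upper-bound
    variants are computed and labelled in the ``bound`` column.  Structure
    entries equal to the full 20-symbol alphabet are taken as fully wildcard
    and scale with the alphabet (a ``.`` admits every symbol of the larger
    alphabet); other entries are kept as printed.
    """
    alphabet_sizes, ks = list(alphabet_sizes), list(ks)
    base_size = db.alphabet.size
    rows = []
    for size in alphabet_sizes:
        for k in ks:
            for bound in ("lower", "upper"):
                values, excluded = [], 0
                for c in db:
                    if len(c) < k:
                        excluded += 1
                        continue
                    e = tuple(size if ei == base_size else ei
                              for ei in c.structure)
                    if bound == "upper":
                        value = combinatorics.potential_classes(e, size, k)
                    elif k == 0:
                        value = combinatorics.potential_classes(e, size, 0)
                    else:
                        value = combinatorics.mk_lower(e, size, k)
                    values.append((c.identifier, float(value)))
                summary = _summarize(values, excluded)
                rows.append({"alphabet_size": size, "k": k, "bound": bound,
                             "median": summary.median,
                             "n_excluded": excluded})
    frame = pd.DataFrame(rows)
    reference = frame[frame["alphabet_size"] == reference_size].set_index(
        ["k", "bound"])["median"]
    frame["fold_change"] = [
        row["median"] / reference.loc[(row["k"], row["bound"])]
        if (row["k"], row["bound"]) in reference.index else np.nan
        for _, row in frame.iterrows()]
    return frame


# ---------------------------------------------------------------------------
# Robustness experiments
# ---------------------------------------------------------------------------

@dataclass
class RobustnessReport:
    """Result of one seeded robustness experiment."""

    kind: str
    parameters: dict
    medians: pd.DataFrame  # columns: replicate/part label, k, median
    full_medians: dict[int, float]
    fold_change: pd.DataFrame  # median fold change vs full database per k
    seed: int | None = None

    def to_dict(self) -> dict:
        return {"kind": self.kind, "parameters": self.parameters,
                "medians": self.medians.to_dict(orient="records"),
                "full_medians": self.full_medians,
                "fold_change": self.fold_change.to_dict(orient="records"),
                "seed": self.seed}


def _medians_per_k(db: MotifDatabase, alphabet_size: int,
                   ks: Sequence[int]) -> dict[int, float]:
    out = {}
    for k in ks:
        try:
            out[k] = potential_distribution(db, alphabet_size, k).median
        except ValueError:  # every class shorter than k
            out[k] = float("nan")
    return out


def _fold_frame(per_part: pd.DataFrame, full: dict[int, float]) -> pd.DataFrame:
    rows = []
    for k, group in per_part.groupby("k"):
        rows.append({"k": int(k),
                     "median_fold_change":
                         float(np.nanmedian(group["median"])) / full[k]
                         if full.get(k) else float("nan")})
    return pd.DataFrame(rows)


def subsample_experiment(db: MotifDatabase, alphabet_size: int = 20,
                         fraction: float = 0.25, replicates: int = 10,
                         seed: int = 0, ks: Sequence[int] = tuple(range(9)),
                         ) -> RobustnessReport:
    """Recompute potential-class medians on ``replicates`` subsampled
    databases drawing ``fraction`` of the classes without replacement."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = max(1, int(round(fraction * len(db))))
    full = _medians_per_k(db, alphabet_size, ks)
    rows = []
    for rep in range(replicates):
        chosen = rng.choice(len(db), size=n_keep, replace=False)
        sub = MotifDatabase([db.classes[i] for i in sorted(chosen)],
                            db.alphabet, {"subsample_of": id(db)})
        for k, median in _medians_per_k(sub, alphabet_size, ks).items():
            rows.append({"part": f"replicate {rep}", "k": k, "median": median})
    medians = pd.DataFrame(rows)
    return RobustnessReport(
        kind="subsample",
        parameters={"fraction": fraction, "replicates": replicates,
                    "alphabet_size": alphabet_size, "ks": list(ks)},
        medians=medians, full_medians=full,
        fold_change=_fold_frame(medians, full), seed=seed)


def specificity_split_experiment(db: MotifDatabase, alphabet_size: int = 20,
                                 ks: Sequence[int] = tuple(range(9)),
                                 ) -> RobustnessReport:
    """Split the database at the median number of potential instances and
    recompute the medians per half.

    Classes are sorted by instance count (specific classes admit fewer); for
    an odd count the middle class joins the more-specific half.
    """
    if len(db) < 4:
        raise ValueError("need at least 4 classes to split")
    ranked = sorted(db.classes,
                    key=lambda c: (math.prod(c.structure), c.identifier))
    cut = (len(ranked) + 1) // 2  # middle class goes to the specific half
    halves = {"specific": ranked[:cut], "unspecific": ranked[cut:]}
    full = _medians_per_k(db, alphabet_size, ks)
    rows = []
    for label, classes in halves.items():
        half = MotifDatabase(list(classes), db.alphabet, {"split": label})
        for k, median in _medians_per_k(half, alphabet_size, ks).items():
            rows.append({"part": label, "k": k, "median": median})
    medians = pd.DataFrame(rows)
    return RobustnessReport(
        kind="specificity_split",
        parameters={"alphabet_size": alphabet_size, "ks": list(ks)},
        medians=medians, full_medians=full,
        fold_change=_fold_frame(medians, full), seed=None)


def mismatch_tolerance_experiment(db: MotifDatabase, fraction: float = 0.5,
                                  seed: int = 0, alphabet_size: int = 20,
                                  ks: Sequence[int] = tuple(range(9)),
                                  ) -> RobustnessReport:
    """Simulate mismatch tolerance: in a seeded random share of the classes
    one uniformly chosen position is widened to the full alphabet, then the
    medians are recomputed.

    Perturbations are nested across fractions for a fixed seed: the classes
    touched at a lower fraction are a subset of those touched at a higher
    one and keep the same widened position, so the medians decrease
    monotonically with the tolerant fraction.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(db))
    widened_position = [int(rng.integers(len(c))) for c in db.classes]
    chosen = set(order[: int(round(fraction * len(db)))].tolist())
    full_set = db.alphabet.symbol_set
    modified = []
    for i, c in enumerate(db.classes):
        if i in chosen:
            positions = list(c.positions)
            positions[widened_position[i]] = full_set
            c = c.with_positions(positions)
        modified.append(c)
    new_db = MotifDatabase(modified, db.alphabet, {"mismatch_fraction": fraction})
    full = _medians_per_k(db, alphabet_size, ks)
    rows = [{"part": f"tolerant {fraction:.0%}", "k": k, "median": median}
            for k, median in _medians_per_k(new_db, alphabet_size, ks).items()]
    medians = pd.DataFrame(rows)
    return RobustnessReport(
        kind="mismatch_tolerance",
        parameters={"fraction": fraction, "alphabet_size": alphabet_size,
                    "ks": list(ks)},
        medians=medians, full_medians=full,
        fold_change=_fold_frame(medians, full), seed=seed)


# ---------------------------------------------------------------------------
# Proteome arithmetic
# ---------------------------------------------------------------------------

def instances_from_residues(residues: int, motif_length: int = 5) -> int:
    """Motif instances fitting into ``residues`` amino acids assuming
    non-overlapping motifs of ``motif_length`` (floor division)."""
    if motif_length <= 0:
        raise ValueError("motif_length must be positive")
    if residues < 0:
        raise ValueError("residues must be nonnegative")
    return residues // motif_length


def proteome_class_estimate(total_instances: int,
                            instances_per_class: int) -> int:
    """Estimated number of motif classes in a proteome: total instances over
    instances per class, rounded to the nearest integer."""
    if instances_per_class <= 0:
        raise ValueError("instances_per_class must be positive")
    if total_instances < 0:
        raise ValueError("total_instances must be nonnegative")
    return round(total_instances / instances_per_class)
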