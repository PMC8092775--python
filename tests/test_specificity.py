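"""Motif-discriminating positions: alignments, mdp, all-pairs matrix."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifspace import (
    MotifClass,
    MotifDatabase,
    alignments,
    alignval,
    fixed_positions,
    mdp_equal_length,
    mdp_general,
    pairwise_matrix,
    parse_regex,
)

small_positions = st.lists(
    st.frozensets(st.sampled_from("ACDEFG"), min_size=1),
    min_size=1, max_size=4).map(tuple)


def naive_mdp(pa, pb, threshold=10):
    """Independent recount: enumerate windows, recount disjoint fixed pairs."""
    if len(pa) < len(pb):
        pa, pb = pb, pa
    m = len(pb)
    per_window = []
    for start in range(len(pa) - m + 1):
        window = pa[start:start + m]
        fixed_pairs = [
            (sa, sb) for sa, sb in zip(window, pb)
            if len(sa) <= threshold and len(sb) <= threshold]
        if not fixed_pairs:
            continue
        per_window.append(sum(1 for sa, sb in fixed_pairs if not sa & sb))
    return min(per_window) if per_window else 0


# ---------------------------------------------------------------------------
# fixed positions
# ---------------------------------------------------------------------------

def test_fixed_positions_worked_example(rb):
    assert fixed_positions(rb) == {1, 3, 5}


def test_wildcardish_positions_are_not_fixed():
    assert fixed_positions(parse_regex("...")) == frozenset()
    assert fixed_positions(parse_regex("[^P]")) == frozenset()  # 19 > 10


# ---------------------------------------------------------------------------
# equal-length comparison
# ---------------------------------------------------------------------------

def test_mdp_equal_length_worked_example():
    a = parse_regex("[LI].C")
    b = parse_regex("[FI].W")
    assert mdp_equal_length(a, b) == 1  # C vs W disjoint; L/I vs F/I share I
    assert alignval(a, b) == 1


def test_mdp_of_class_with_itself_is_zero(rb):
    assert mdp_equal_length(rb, rb) == 0


def test_mdp_equal_length_requires_equal_lengths(rb, fiw):
    with pytest.raises(ValueError, match="length"):
        mdp_equal_length(rb, fiw)


def test_alignval_zero_without_fixed_fixed_match():
    middle = parse_regex(".C.")  # second window of [LI].C.[DE]
    assert alignval(middle, parse_regex("[FI].W")) == 0
    assert alignval(parse_regex("..."), parse_regex("...")) == 0


@given(small_positions, small_positions)
def test_mdp_general_matches_naive_recount(pa, pb):
    assert mdp_general(pa, pb).mdp == naive_mdp(pa, pb)


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def test_alignment_counts(rb, fiw):
    assert len(alignments(rb, fiw)) == 3  # lengths 5 vs 3
    assert len(alignments(rb, rb)) == 1
    assert len(alignments(parse_regex("." * 7), parse_regex("." * 3))) == 5


def test_alignments_have_no_overhangs(rb, fiw):
    for window, short in alignments(rb, fiw):
        assert len(window) == len(short) == len(fiw)


# ---------------------------------------------------------------------------
# general mdp
# ---------------------------------------------------------------------------

def test_worked_example_alignment_by_alignment(rb, fiw):
    """Three alignments: scores 1 and 2 for the outer two, middle discarded."""
    per_alignment = [
        (alignval(w, s), mdp_equal_length(w, s)) for w, s in alignments(rb, fiw)]
    assert per_alignment == [(1, 1), (0, 0), (1, 2)]
    spec = mdp_general(rb, fiw)
    assert spec.mdp == 1
    assert spec.alignments_total == 3
    assert spec.alignments_informative == 2
    assert spec.informative and not spec.coincident


def test_identical_classes_are_coincident(rb):
    spec = mdp_general(rb, rb)
    # fixed positions align against themselves, so the single alignment is
    # informative, yet no position is disjoint
    assert spec.mdp == 0 and spec.coincident and spec.informative


def test_all_wildcard_pair_is_uninformative(rb):
    spec = mdp_general(parse_regex("." * 5), rb)
    assert spec.mdp == 0 and not spec.informative and not spec.coincident


def test_unequal_lengths_are_never_coincident():
    assert not mdp_general(parse_regex("AC"), parse_regex("A")).coincident


@given(small_positions, small_positions)
def test_mdp_is_symmetric(pa, pb):
    assert mdp_general(pa, pb) == mdp_general(pb, pa)


@given(small_positions, small_positions)
def test_mdp_bounded_by_fixed_position_counts(pa, pb):
    spec = mdp_general(pa, pb)
    assert spec.mdp <= min(len(fixed_positions(pa)), len(fixed_positions(pb)))


@given(small_positions, small_positions, st.data())
def test_enlarging_a_set_never_increases_mdp(pa, pb, data):
    before = mdp_general(pa, pb).mdp
    index = data.draw(st.integers(0, len(pa) - 1))
    extra = data.draw(st.sampled_from("ACDEFGHIKLMNPQRSTVWY"))
    enlarged = list(pa)
    enlarged[index] = enlarged[index] | {extra}
    assert mdp_general(tuple(enlarged), pb).mdp <= before


# ---------------------------------------------------------------------------
# all-pairs matrix
# ---------------------------------------------------------------------------

def test_pairwise_matrix_counts(synth_db):
    sub = MotifDatabase(synth_db.classes[:20], synth_db.alphabet)
    result = pairwise_matrix(sub)
    assert result.n_pairs == 190  # C(20, 2)
    assert sum(result.histogram.values()) == 190
    assert 0.0 <= result.frac_separated <= 1.0
    assert result.frac_separated <= result.frac_informative


def test_pairwise_matrix_identical_pair():
    a = MotifClass.from_regex("A1", "[LI].C.[DE]")
    b = MotifClass.from_regex("A2", "[LI].C.[DE]")
    result = pairwise_matrix(MotifDatabase([a, b]))
    assert result.n_pairs == 1
    row = result.pairs.iloc[0]
    assert row["mdp"] == 0 and row["coincident"]


def test_pairwise_matrix_requires_two_classes():
    with pytest.raises(ValueError):
        pairwise_matrix(MotifDatabase([MotifClass.from_regex("X", "AC")]))
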