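"""Regex parsing, preprocessing, instance counting and class-table IO."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from motifspace import (
    Alphabet,
    MotifClass,
    MotifDatabase,
    ParseError,
    canonical_regex,
    count_instances,
    is_instance,
    parse_regex,
    preprocess,
    read_class_table,
    structure_of,
    write_class_table,
)
from motifspace.motif_model import CANONICAL_ALPHABET, enumerate_instances
from motifspace.synthetic_data import PREPROCESSING_EXAMPLES

FULL = CANONICAL_ALPHABET.symbol_set

positions_strategy = st.lists(
    st.frozensets(st.sampled_from(sorted(FULL)), min_size=1),
    min_size=1, max_size=6).map(tuple)


# ---------------------------------------------------------------------------
# parse_regex
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("regex, structure", [
    ("[LI].C.[DE]", (2, 20, 1, 20, 2)),
    ("A", (1,)),
    ("[^P]", (19,)),
    ("[^P]..", (19, 20, 20)),
    ("A{3}", (1, 1, 1)),
    ("(T)P", (1, 1)),
])
def test_parse_structures(regex, structure):
    assert structure_of(parse_regex(regex)) == structure


def test_parse_sets_match_worked_example():
    positions = parse_regex("[LI].C.[DE]")
    assert positions[0] == frozenset("LI")
    assert positions[1] == FULL
    assert positions[2] == frozenset("C")
    assert positions[4] == frozenset("DE")


def test_negated_class_is_complement():
    (allowed,) = parse_regex("[^P]")
    assert allowed == FULL - {"P"}


def test_symbol_map_applies_inside_parse():
    (allowed,) = parse_regex("U")
    assert allowed == frozenset("C")


@pytest.mark.parametrize("regex, needle", [
    ("A|B", "alternation"),
    ("A*", "unbounded"),
    ("A+", "unbounded"),
    ("(?=A)B", "lookaround"),
    ("A{2,}", "open-ended"),
    ("[AB", "unterminated"),
    ("A)", "unbalanced"),
])
def test_parse_rejects_unsupported_constructs(regex, needle):
    with pytest.raises(ParseError, match=needle):
        parse_regex(regex)


def test_parse_error_reports_offset():
    with pytest.raises(ParseError) as err:
        parse_regex("AC|D")
    assert err.value.offset == 2


def test_parse_rejects_unpreprocessed_input():
    with pytest.raises(ParseError, match="preprocess"):
        parse_regex("^AC")
    with pytest.raises(ParseError, match="preprocess"):
        parse_regex("A.{0,2}C")


def test_parse_rejects_unknown_symbol():
    with pytest.raises(ParseError, match="not in alphabet"):
        parse_regex("AXB", symbol_map={})


@given(positions_strategy)
def test_canonical_regex_round_trips(positions):
    assert parse_regex(canonical_regex(positions)) == positions


# ---------------------------------------------------------------------------
# preprocess
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("raw, expected", PREPROCESSING_EXAMPLES)
def test_preprocess_curation_examples(raw, expected):
    assert preprocess(raw).regex == expected


@pytest.mark.parametrize("raw", [r for r, _ in PREPROCESSING_EXAMPLES])
def test_preprocess_is_idempotent(raw):
    once = preprocess(raw).regex
    assert preprocess(once).regex == once


def test_preprocess_logs_applied_rules():
    result = preprocess("^[KR]R.$")
    assert any("anchor" in line for line in result.log)
    assert any("flank" in line for line in result.log)


def test_preprocess_fully_wildcard_errors():
    with pytest.raises(ParseError, match="fully wildcard"):
        preprocess("..[^P].")


def test_preprocess_trims_repeat_counts_one_position_at_a_time():
    # trailing .{3} is three wildcard flanks
    assert preprocess("AC.{3}").regex == "AC"


@given(positions_strategy)
def test_trimming_never_removes_specific_positions(positions):
    """Positions allowing <= 10 residues survive preprocessing."""
    try:
        result = preprocess(canonical_regex(positions))
    except ParseError:
        assert all(len(p) >= 11 for p in positions)
        return
    kept = parse_regex(result.regex)
    specific = [p for p in positions if len(p) <= 10]
    assert [p for p in kept if len(p) <= 10] == specific


# ---------------------------------------------------------------------------
# structures, instance counts, matching
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("structure, expected", [
    ((2, 20, 1, 20, 2), 1600),
    ((1, 1, 1), 1),
    ((3, 4), 12),
])
def test_count_instances(structure, expected):
    assert count_instances(structure) == expected


@pytest.mark.parametrize("sequence, expected", [
    ("IACDD", True),
    ("IACDP", False),
    ("LWCWE", True),
])
def test_is_instance_worked_example(sequence, expected, rb):
    assert is_instance(sequence, rb) is expected


def test_is_instance_wildcard_class_matches_everything():
    wild = MotifClass.from_regex("W3", "...")
    assert is_instance("ACD", wild)
    with pytest.raises(ValueError, match="length"):
        is_instance("AC", wild)


@given(st.lists(st.frozensets(st.sampled_from("ACDEFG"), min_size=1),
                min_size=1, max_size=3).map(tuple))
def test_count_instances_equals_exhaustive_enumeration(positions):
    motif = MotifClass("M", "", canonical_regex(positions), positions)
    instances = list(enumerate_instances(motif))
    assert len(instances) == len(set(instances)) == count_instances(motif)
    alphabet = CANONICAL_ALPHABET.symbols
    if count_instances(motif) <= 10 ** 4 and len(positions) <= 2:
        matching = sum(
            is_instance("".join(seq), motif)
            for seq in itertools.product(alphabet, repeat=len(positions)))
        assert matching == count_instances(motif)


# ---------------------------------------------------------------------------
# class-table IO
# ---------------------------------------------------------------------------

TOY_TSV = """# toy class table
identifier\tgroup_name\tregex\tknown_instances
RB\tRb ligand\t[LI].C.[DE]\t30
FIW\ttoy\t[FI].W\t5
"""


def test_read_toy_tsv(tmp_path):
    path = tmp_path / "classes.tsv"
    path.write_text(TOY_TSV)
    db = read_class_table(path)
    assert len(db) == 2
    assert db["RB"].structure == (2, 20, 1, 20, 2)
    assert db["FIW"].known_instances == 5


def test_read_accepts_elm_style_aliases(tmp_path):
    path = tmp_path / "elm.tsv"
    path.write_text("ELMIdentifier\tFunctionalSiteName\tRegex\t#Instances\n"
                    "LIG_X\tX site\t[LI].C.[DE]\t7\n")
    db = read_class_table(path)
    assert db["LIG_X"].group_name == "X site"
    assert db["LIG_X"].known_instances == 7


def test_read_missing_column_reports_found_columns(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("foo\tbar\n1\t2\n")
    with pytest.raises(ValueError, match="found columns"):
        read_class_table(path)


def test_strict_mode_raises_on_bad_regex(tmp_path):
    path = tmp_path / "classes.tsv"
    path.write_text("identifier\tregex\nBAD\tA|B\n")
    with pytest.raises(ValueError, match="BAD"):
        read_class_table(path)


def test_lenient_mode_collects_row_errors(tmp_path):
    path = tmp_path / "classes.tsv"
    path.write_text("identifier\tregex\nBAD\tA|B\nOK\tAC\n")
    db = read_class_table(path, strict=False)
    assert db.identifiers == ["OK"]
    assert len(db.provenance["row_errors"]) == 1


@pytest.mark.parametrize("format", ["tsv", "json"])
def test_round_trip_on_synthetic_database(tmp_path, synth_db, format):
    path = tmp_path / f"db.{format}"
    write_class_table(synth_db, path, format=format)
    loaded = read_class_table(path, format=format)
    assert loaded.alphabet == synth_db.alphabet
    assert len(loaded) == len(synth_db)
    for a, b in zip(loaded, synth_db):
        assert (a.identifier, a.group_name, a.positions, a.known_instances) == \
               (b.identifier, b.group_name, b.positions, b.known_instances)
        assert a.source_regex == b.source_regex


def test_database_rejects_duplicate_identifiers():
    c = MotifClass.from_regex("X", "AC")
    with pytest.raises(ValueError, match="duplicate"):
        MotifDatabase([c, c])


def test_alphabet_invariants():
    assert Alphabet.canonical().size == 20
    assert "".join(Alphabet.canonical()) == "ACDEFGHIKLMNPQRSTVWY"
    with pytest.raises(ValueError):
        Alphabet(("A",))
    with pytest.raises(ValueError):
        Alphabet(("A", "A"))
    assert Alphabet.of_size(33).size == 33
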