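"""Motif classes as sequences of allowed-amino-acid sets.

A linear motif class of length ``n`` is a sequence ``(A_1, ..., A_n)`` where
each ``A_i`` is a nonempty subset of the amino acid alphabet; a motif instance
is any sequence ``(a_1, ..., a_n)`` with ``a_i in A_i``.  Classes are written
and exchanged as a restricted regular-expression dialect: literal symbols,
bracketed classes ``[XY]``, negated classes ``[^X]``, the wildcard ``.``,
transparent capture parentheses and fixed repetition ``X{m}``.

This module provides the alphabet and class containers, the regex parser for
that dialect, the curation-style preprocessing of raw ELM regular expressions
(shortest variable-length version, anchor stripping, modified-residue
rewriting, wildcard flank trimming) and tab-separated / JSON database IO.
"""

from __future__ import annotations

import itertools
import json
import math
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "CANONICAL_AMINO_ACIDS",
    "DEFAULT_SYMBOL_MAP",
    "Alphabet",
    "MotifClass",
    "MotifDatabase",
    "MotifStructure",
    "ParseError",
    "PreprocessResult",
    "canonical_regex",
    "count_instances",
    "is_instance",
    "parse_regex",
    "preprocess",
    "read_class_table",
    "structure_of",
    "write_class_table",
]

#: The twenty canonical amino acids in alphabetical one-letter order.
CANONICAL_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default rewriting of nonstandard residue letters to canonical ones
#: (selenocysteine U is treated as cysteine).
DEFAULT_SYMBOL_MAP: Mapping[str, str] = {"U": "C"}

#: A motif structure: the tuple of allowed-set sizes (|A_1|, ..., |A_n|).
MotifStructure = tuple[int, ...]

#: Positions allowing more than this many residues count as wildcard flanks
#: and are trimmed from motif ends during preprocessing ("less than eleven").
FLANK_TRIM_THRESHOLD = 11


class ParseError(ValueError):
    """Raised for regex constructs outside the supported dialect."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


@dataclass(frozen=True)
class Alphabet:
    """An ordered finite symbol set, 20 canonical amino acids by default."""

    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.symbols) < 2:
            raise ValueError("alphabet needs at least 2 symbols")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if any(len(s) != 1 for s in self.symbols):
            raise ValueError("alphabet symbols must be single characters")

    @property
    def size(self) -> int:
        return len(self.symbols)

    @property
    def symbol_set(self) -> frozenset[str]:
        return frozenset(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbol_set

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    @classmethod
    def canonical(cls) -> "Alphabet":
        return cls(tuple(CANONICAL_AMINO_ACIDS))

    @classmethod
    def of_size(cls, size: int) -> "Alphabet":
        """An alphabet of ``size`` symbols: the 20 amino acids extended with
        lowercase letters standing in for modified residues."""
        pool = CANONICAL_AMINO_ACIDS + string.ascii_lowercase + string.digits
        if size > len(pool):
            raise ValueError(f"cannot build an alphabet of size {size}")
        return cls(tuple(pool[:size]))


CANONICAL_ALPHABET = Alphabet.canonical()


# ---------------------------------------------------------------------------
# Tokenizer for the supported regex dialect
# ---------------------------------------------------------------------------

_UNSUPPORTED = {
    "|": "alternation '|'",
    "*": "unbounded repetition '*'",
    "+": "unbounded repetition '+'",
    "?": "optional quantifier '?'",
}


@dataclass
class _Token:
    kind: str  # "literal" | "class" | "dot" | "anchor_start" | "anchor_end"
    offset: int
    members: tuple[str, ...] = ()  # literal char or class members, input order
    negated: bool = False
    grouped: bool = False  # wrapped in single-position capture parentheses
    repeat: tuple[int, int] | None = None  # (m, n) from {m} / {m,n}

    def render(self) -> str:
        if self.kind == "anchor_start":
            return "^"
        if self.kind == "anchor_end":
            return "$"
        if self.kind == "dot":
            body = "."
        elif self.kind == "literal":
            body = self.members[0]
        else:
            body = "[" + ("^" if self.negated else "") + "".join(self.members) + "]"
        if self.grouped:
            body = f"({body})"
        if self.repeat is not None:
            m, n = self.repeat
            body += f"{{{m}}}" if m == n else f"{{{m},{n}}}"
        return body

    def n_allowed(self, alphabet: Alphabet) -> int:
        """Number of amino acids this position admits."""
        if self.kind == "dot":
            return alphabet.size
        if self.kind == "literal":
            return 1
        k = len(set(self.members))
        return alphabet.size - k if self.negated else k


def _tokenize(regex: str) -> list[_Token]:
    tokens: list[_Token] = []
    i, n = 0, len(regex)
    while i < n:
        ch = regex[i]
        if ch in _UNSUPPORTED:
            raise ParseError(f"unsupported construct: {_UNSUPPORTED[ch]}", i)
        if ch == "^":
            if i != 0:
                raise ParseError("'^' only supported as a start anchor", i)
            tokens.append(_Token("anchor_start", i))
            i += 1
        elif ch == "$":
            if i != n - 1:
                raise ParseError("'$' only supported as an end anchor", i)
            tokens.append(_Token("anchor_end", i))
            i += 1
        elif ch == ".":
            tokens.append(_Token("dot", i))
            i += 1
        elif ch == "[":
            j = regex.find("]", i + 1)
            if j < 0:
                raise ParseError("unterminated character class", i)
            body = regex[i + 1 : j]
            negated = body.startswith("^")
            if negated:
                body = body[1:]
            if not body:
                raise ParseError("empty character class", i)
            if any(not c.isalpha() for c in body):
                raise ParseError(f"non-letter in character class: {body!r}", i)
            members = tuple(dict.fromkeys(body))  # dedupe, keep order
            tokens.append(_Token("class", i, members=members, negated=negated))
            i = j + 1
        elif ch == "(":
            if regex[i + 1 : i + 2] == "?":
                raise ParseError("unsupported construct: lookaround / flags group", i)
            depth, j = 1, i + 1
            while j < n and depth:
                depth += {"(": 1, ")": -1}.get(regex[j], 0)
                j += 1
            if depth:
                raise ParseError("unbalanced parenthesis", i)
            inner = _tokenize(regex[i + 1 : j - 1])
            if not inner:
                raise ParseError("empty group", i)
            if len(inner) == 1 and inner[0].kind in ("literal", "class", "dot"):
                tok = inner[0]
                tok.offset, tok.grouped = i, True
                tokens.append(tok)
            else:
                # multi-position group: parentheses are transparent
                for tok in inner:
                    tok.offset += i + 1
                    tokens.append(tok)
            i = j
        elif ch == "{":
            j = regex.find("}", i + 1)
            if j < 0:
                raise ParseError("unterminated repetition brace", i)
            body = regex[i + 1 : j].replace(" ", "")
            parts = body.split(",")
            if len(parts) == 2 and parts[1] == "":
                raise ParseError(
                    "unsupported construct: open-ended repetition {m,}", i)
            try:
                if len(parts) == 1:
                    m = n_rep = int(parts[0])
                elif len(parts) == 2:
                    m, n_rep = int(parts[0]), int(parts[1])
                else:
                    raise ValueError
            except ValueError:
                raise ParseError(f"malformed repetition {{{body}}}", i) from None
            if not tokens or tokens[-1].kind.startswith("anchor"):
                raise ParseError("repetition without a preceding position", i)
            if tokens[-1].repeat is not None:
                raise ParseError("double repetition", i)
            if n_rep < m:
                raise ParseError(f"repetition bounds out of order {{{body}}}", i)
            tokens[-1].repeat = (m, n_rep)
            i = j + 1
        elif ch == ")":
            raise ParseError("unbalanced parenthesis", i)
        elif ch.isalpha():
            tokens.append(_Token("literal", i, members=(ch,)))
            i += 1
        else:
            raise ParseError(f"unexpected character {ch!r}", i)
    return tokens


def _apply_symbol_map(tokens: list[_Token], alphabet: Alphabet,
                      symbol_map: Mapping[str, str]) -> list[str]:
    """Rewrite nonstandard letters in place; return a log of rewrites."""
    log = []
    for tok in tokens:
        if tok.kind not in ("literal", "class"):
            continue
        new = []
        for c in tok.members:
            if c not in alphabet and c in symbol_map:
                log.append(f"symbol map: {c} -> {symbol_map[c]} at position offset {tok.offset}")
                c = symbol_map[c]
            new.append(c)
        tok.members = tuple(dict.fromkeys(new))
    return log


# ---------------------------------------------------------------------------
# Preprocessing of raw ELM-style regexes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PreprocessResult:
    """A simplified regex together with the log of applied curation rules."""

    regex: str
    log: tuple[str, ...] = ()

    def __str__(self) -> str:  # convenient drop-in for the plain string
        return self.regex


def preprocess(regex: str, alphabet: Alphabet = CANONICAL_ALPHABET,
               symbol_map: Mapping[str, str] = DEFAULT_SYMBOL_MAP) -> PreprocessResult:
    """Simplify a raw ELM-style regular expression.

    Applies, in order: (1) variable-length repetitions ``{p,q}`` are replaced
    by their shortest version ``{p}`` (``{0,q}`` deletes the position);
    (2) terminal anchors ``^``/``$`` are stripped; (3) nonstandard residue
    letters are rewritten through ``symbol_map``; (4) flanking positions are
    trimmed from both ends while the terminal position allows eleven or more
    amino acids.

    Raises :class:`ParseError` if nothing but wildcard positions remains
    ("motif fully wildcard").
    """
    tokens = _tokenize(regex)
    log: list[str] = []

    # (1) shortest version of variable-length repetitions
    out: list[_Token] = []
    for tok in tokens:
        if tok.repeat is not None:
            m, n_rep = tok.repeat
            if m != n_rep:
                log.append(f"variable length {{{m},{n_rep}}} -> shortest {{{m}}}")
            if m == 0:
                log.append(f"dropped optional position {tok.render().split('{')[0]}")
                continue
            tok.repeat = None if m == 1 else (m, m)
        out.append(tok)
    tokens = out

    # (2) strip anchors
    kept = [t for t in tokens if not t.kind.startswith("anchor")]
    if len(kept) != len(tokens):
        log.append("stripped terminal anchor(s)")
    tokens = kept

    # (3) modified-residue letters
    log.extend(_apply_symbol_map(tokens, alphabet, symbol_map))

    # (4) trim wildcard-like flanks, one position at a time
    def trim_end(index: int) -> bool:
        if not tokens:
            return False
        tok = tokens[index]
        if tok.n_allowed(alphabet) < FLANK_TRIM_THRESHOLD:
            return False
        if tok.repeat is not None and tok.repeat[0] > 1:
            m = tok.repeat[0] - 1
            tok.repeat = None if m == 1 else (m, m)
        else:
            tokens.pop(index)
        return True

    while trim_end(0):
        log.append("trimmed leading wildcard flank")
    while tokens and trim_end(-1):
        log.append("trimmed trailing wildcard flank")

    if not tokens:
        raise ParseError("motif fully wildcard")
    return PreprocessResult("".join(t.render() for t in tokens), tuple(log))


# ---------------------------------------------------------------------------
# Parsing into allowed-symbol sets
# ---------------------------------------------------------------------------

def parse_regex(regex: str, alphabet: Alphabet = CANONICAL_ALPHABET,
                symbol_map: Mapping[str, str] = DEFAULT_SYMBOL_MAP,
                ) -> tuple[frozenset[str], ...]:
    """Parse a preprocessed motif regex into allowed-symbol sets.

    ``.`` maps to the full alphabet and ``[^X]`` to the complement set;
    nonstandard letters are rewritten through ``symbol_map`` before set
    construction.  Anchors and bounded repetitions ``{m,n}`` are rejected:
    they must already have been removed by :func:`preprocess`.
    """
    tokens = _tokenize(regex)
    _apply_symbol_map(tokens, alphabet, symbol_map)
    full = alphabet.symbol_set
    positions: list[frozenset[str]] = []
    for tok in tokens:
        if tok.kind.startswith("anchor"):
            raise ParseError("anchor present: run preprocess first", tok.offset)
        if tok.repeat is not None and tok.repeat[0] != tok.repeat[1]:
            raise ParseError("bounded repetition present: run preprocess first", tok.offset)
        if tok.kind == "dot":
            allowed = full
        else:
            unknown = [c for c in tok.members if c not in full]
            if unknown:
                raise ParseError(
                    f"symbol {unknown[0]!r} not in alphabet and not in symbol map",
                    tok.offset)
            allowed = frozenset(tok.members)
            if tok.negated:
                allowed = full - allowed
            if not allowed:
                raise ParseError("position allows no symbol", tok.offset)
        reps = tok.repeat[0] if tok.repeat else 1
        positions.extend([allowed] * reps)
    if not positions:
        raise ParseError("empty regular expression")
    return tuple(positions)


def canonical_regex(positions: Sequence[frozenset[str]],
                    alphabet: Alphabet = CANONICAL_ALPHABET) -> str:
    """Canonical regex for a position list: fixed symbol, bracketed class
    (alphabet order) or ``.`` for the full alphabet."""
    parts = []
    for allowed in positions:
        if len(allowed) == alphabet.size:
            parts.append(".")
        elif len(allowed) == 1:
            parts.append(next(iter(allowed)))
        else:
            parts.append("[" + "".join(s for s in alphabet if s in allowed) + "]")
    return "".join(parts)


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifClass:
    """A linear motif class: identifier, name, source regex and the ordered
    allowed-amino-acid sets."""

    identifier: str
    group_name: str
    source_regex: str
    positions: tuple[frozenset[str], ...]
    known_instances: int = 0
    alphabet: Alphabet = CANONICAL_ALPHABET
    preprocess_log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValueError("motif class needs at least one position")
        full = self.alphabet.symbol_set
        for i, allowed in enumerate(self.positions, start=1):
            if not allowed:
                raise ValueError(f"position {i} allows no symbol")
            if not allowed <= full:
                raise ValueError(f"position {i} uses symbols outside the alphabet")
        if self.known_instances < 0:
            raise ValueError("known_instances must be nonnegative")

    @classmethod
    def from_regex(cls, identifier: str, regex: str, *, group_name: str = "",
                   known_instances: int = 0,
                   alphabet: Alphabet = CANONICAL_ALPHABET,
                   symbol_map: Mapping[str, str] = DEFAULT_SYMBOL_MAP,
                   run_preprocess: bool = False) -> "MotifClass":
        log: tuple[str, ...] = ()
        parsed_regex = regex
        if run_preprocess:
            pre = preprocess(regex, alphabet, symbol_map)
            parsed_regex, log = pre.regex, pre.log
        positions = parse_regex(parsed_regex, alphabet, symbol_map)
        return cls(identifier, group_name, regex, positions,
                   known_instances, alphabet, log)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def structure(self) -> MotifStructure:
        return structure_of(self)

    @property
    def regex(self) -> str:
        """Canonical regex rendering of the position list."""
        return canonical_regex(self.positions, self.alphabet)

    def with_positions(self, positions: Sequence[frozenset[str]]) -> "MotifClass":
        return replace(self, positions=tuple(positions))


def structure_of(motif: "MotifClass | Sequence[frozenset[str]]") -> MotifStructure:
    """Structure of a class: the tuple of allowed-set sizes, order preserved."""
    positions = motif.positions if isinstance(motif, MotifClass) else motif
    return tuple(len(p) for p in positions)


def count_instances(structure: "MotifStructure | MotifClass") -> int:
    """Number of distinct instances of a class with the given structure
    (the product of per-position allowed counts)."""
    if isinstance(structure, MotifClass):
        structure = structure.structure
    if any(e < 1 for e in structure):
        raise ValueError("structure entries must be >= 1")
    return math.prod(structure)


def is_instance(sequence: str, motif: MotifClass) -> bool:
    """True iff every residue of ``sequence`` lies in the corresponding
    allowed set of ``motif``."""
    if len(sequence) != len(motif):
        raise ValueError(
            f"sequence length {len(sequence)} != motif length {len(motif)}")
    return all(a in allowed for a, allowed in zip(sequence, motif.positions))


def enumerate_instances(motif: MotifClass, limit: int = 10 ** 5) -> Iterator[str]:
    """Yield every instance of a class (guarded by ``limit``)."""
    if count_instances(motif) > limit:
        raise ValueError(f"class has more than {limit} instances")
    ordered = [sorted(p, key=motif.alphabet.index) for p in motif.positions]
    for combo in itertools.product(*ordered):
        yield "".join(combo)


@dataclass
class MotifDatabase:
    """Ordered collection of motif classes over one alphabet."""

    classes: list[MotifClass] = field(default_factory=list)
    alphabet: Alphabet = CANONICAL_ALPHABET
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [c.identifier for c in self.classes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate identifiers: {dup}")
        for c in self.classes:
            if c.alphabet != self.alphabet:
                raise ValueError(f"class {c.identifier} uses a different alphabet")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self) -> Iterator[MotifClass]:
        return iter(self.classes)

    def __getitem__(self, key: "int | str") -> MotifClass:
        if isinstance(key, int):
            return self.classes[key]
        for c in self.classes:
            if c.identifier == key:
                return c
        raise KeyError(key)

    @property
    def identifiers(self) -> list[str]:
        return [c.identifier for c in self.classes]

    def subset(self, identifiers: Iterable[str]) -> "MotifDatabase":
        wanted = set(identifiers)
        return MotifDatabase([c for c in self.classes if c.identifier in wanted],
                             self.alphabet, dict(self.provenance))


# ---------------------------------------------------------------------------
# Class-table IO
# ---------------------------------------------------------------------------

#: Column-name aliases accepted on read (lowercased match).
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "identifier": ("identifier", "elmidentifier", "accession", "id"),
    "group_name": ("group_name", "functionalsitename", "name"),
    "regex": ("regex", "pattern", "regular_expression"),
    "known_instances": ("known_instances", "#instances", "instances", "n_instances"),
}

_TSV_COLUMNS = ["identifier", "group_name", "regex", "known_instances"]


def _resolve_columns(columns: Sequence[str],
                     aliases: Mapping[str, tuple[str, ...]]) -> dict[str, str]:
    lookup = {c.lower().strip(): c for c in columns}
    resolved = {}
    for canonical, names in aliases.items():
        for name in names:
            if name in lookup:
                resolved[canonical] = lookup[name]
                break
    missing = [c for c in ("identifier", "regex") if c not in resolved]
    if missing:
        raise ValueError(
            f"missing required column(s) {missing}; found columns {list(columns)}")
    return resolved


def read_class_table(path: "str | Path", format: str = "tsv",
                     alphabet: Alphabet = CANONICAL_ALPHABET,
                     symbol_map: Mapping[str, str] = DEFAULT_SYMBOL_MAP,
                     *, strict: bool = True, run_preprocess: bool = False,
                     aliases: Mapping[str, tuple[str, ...]] = COLUMN_ALIASES,
                     ) -> MotifDatabase:
    """Read a motif class table (ELM-style TSV dialect or JSON dump).

    In strict mode any row that fails to parse raises; in lenient mode
    failing rows are skipped and reported in ``provenance['row_errors']``.
    With ``run_preprocess=True`` each regex is first passed through
    :func:`preprocess` (raw ELM ingestion); by default the table is taken
    as already curated so that ``read(write(db)) == db``.
    """
    path = Path(path)
    if format == "json":
        payload = json.loads(path.read_text())
        alphabet = Alphabet(tuple(payload["alphabet"]))
        classes, errors = [], []
        for idx, row in enumerate(payload["classes"]):
            try:
                positions = parse_regex(row["regex"], alphabet, symbol_map)
                classes.append(MotifClass(
                    str(row["identifier"]), str(row.get("group_name") or ""),
                    str(row.get("source_regex") or row["regex"]), positions,
                    int(row.get("known_instances") or 0), alphabet,
                    tuple(row.get("preprocess_log") or ())))
            except (ParseError, ValueError, KeyError) as exc:
                if strict:
                    raise ValueError(
                        f"row {idx + 1} ({row.get('identifier', '?')}): {exc}") from exc
                errors.append(f"row {idx + 1} ({row.get('identifier', '?')}): {exc}")
        provenance = dict(payload.get("provenance") or {})
        provenance.setdefault("source", str(path))
        if errors:
            provenance["row_errors"] = errors
        return MotifDatabase(classes, alphabet, provenance)
    if format == "tsv":
        # '#'-prefixed *lines* are metadata; a '#' inside a header cell
        # (e.g. the "#Instances" column) is data, so filter lines by hand.
        import io

        text = "\n".join(line for line in path.read_text().splitlines()
                         if not line.startswith("#"))
        frame = pd.read_csv(io.StringIO(text), sep="\t", dtype=str,
                            quotechar='"', keep_default_na=False)
        resolved = _resolve_columns(frame.columns, aliases)
        rows = [
            {canonical: row[actual] for canonical, actual in resolved.items()}
            for _, row in frame.iterrows()
        ]
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")

    classes, errors = [], []
    for idx, row in enumerate(rows):
        try:
            count = int(row.get("known_instances") or 0)
            regex = row.get("source_regex") or row["regex"]
            classes.append(MotifClass.from_regex(
                str(row["identifier"]), str(regex),
                group_name=str(row.get("group_name") or ""),
                known_instances=count, alphabet=alphabet,
                symbol_map=symbol_map, run_preprocess=run_preprocess))
        except (ParseError, ValueError, KeyError) as exc:
            if strict:
                raise ValueError(
                    f"row {idx + 1} ({row.get('identifier', '?')}): {exc}") from exc
            errors.append(f"row {idx + 1} ({row.get('identifier', '?')}): {exc}")
    provenance = {"source": str(path), "format": format,
                  "preprocessed": run_preprocess}
    if errors:
        provenance["row_errors"] = errors
    return MotifDatabase(classes, alphabet, provenance)


def write_class_table(db: MotifDatabase, path: "str | Path",
                      format: str = "tsv") -> None:
    """Write a motif database; lossless for the canonical columns."""
    path = Path(path)
    if format == "tsv":
        frame = pd.DataFrame(
            [{"identifier": c.identifier, "group_name": c.group_name,
              "regex": c.source_regex, "known_instances": c.known_instances}
             for c in db], columns=_TSV_COLUMNS)
        with path.open("w") as handle:
            handle.write("# motifspace class table\n")
            frame.to_csv(handle, sep="\t", index=False)
    elif format == "json":
        payload = {
            "alphabet": "".join(db.alphabet.symbols),
            "provenance": db.provenance,
            "classes": [
                {"identifier": c.identifier, "group_name": c.group_name,
                 "regex": c.regex, "source_regex": c.source_regex,
                 "known_instances": c.known_instances,
                 "structure": list(c.structure),
                 "preprocess_log": list(c.preprocess_log)}
                for c in db
            ],
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'json')")
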