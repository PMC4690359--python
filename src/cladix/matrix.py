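"""Character-matrix, age-table and area-table I/O.

Discrete morphological matrices are exchanged as TNT ``xread`` blocks or
NEXUS ``DATA``/``CHARACTERS`` blocks with ``DATATYPE=STANDARD``.  Cells
carry one of three meanings:

* ``observed`` — a non-empty set of integer states (a singleton for a
  normal coding, several states for a polymorphic taxon);
* ``missing`` (``?``) — the character could not be scored;
* ``inapplicable`` (``-`` or the typographic minus ``−``) — the
  character does not apply to the taxon.

The single-letter code ``a`` is accepted as shorthand for the
polymorphism ``{0,1}``; any other letter is a parse error.  General
observed sets are written as ``[01]`` groups in TNT and ``{01}`` groups
in NEXUS.  Missing and inapplicable cells are stored distinctly but both
behave as "any state" in parsimony scoring.

Age tables give each taxon's first-appearance interval as
``[oldest, youngest]`` in Ma before present (older = larger).  Area
tables assign each taxon exactly one of six continental areas.
"""

from __future__ import annotations

import csv
import io
import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

__all__ = [
    "AREAS",
    "AgeTable",
    "AreaTable",
    "CharacterMatrix",
    "MatrixParseError",
    "StateSet",
    "build_area_character",
    "parse_age_table",
    "parse_area_table",
    "parse_matrix",
    "write_age_table",
    "write_area_table",
    "write_matrix",
]

#: Continental areas used for the six-state geographic character.
AREAS: tuple[str, ...] = (
    "South America",
    "Africa",
    "Asia",
    "North America",
    "Europe",
    "Australia",
)

# Accept both the ASCII hyphen and the typographic minus for inapplicable.
_INAPPLICABLE_CHARS = {"-", "−"}


class MatrixParseError(ValueError):
    """Raised when a matrix or table cannot be parsed or fails validation."""


@dataclass(frozen=True)
class StateSet:
    """One cell of a character matrix.

    ``kind`` is ``observed``, ``missing`` or ``inapplicable``; ``states``
    is a non-empty frozenset of integer codes iff ``kind == 'observed'``.
    """

    kind: Literal["observed", "missing", "inapplicable"]
    states: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.kind == "observed":
            if not self.states:
                raise ValueError("observed StateSet must have at least one state")
            if not all(0 <= s <= 9 for s in self.states):
                raise ValueError(f"states must lie in 0..9, got {sorted(self.states)}")
        elif self.states:
            raise ValueError(f"{self.kind} StateSet cannot carry states")

    @property
    def is_observed(self) -> bool:
        return self.kind == "observed"

    @classmethod
    def observed(cls, states: Iterable[int]) -> "StateSet":
        return cls("observed", frozenset(states))

    @classmethod
    def missing(cls) -> "StateSet":
        return cls("missing")

    @classmethod
    def inapplicable(cls) -> "StateSet":
        return cls("inapplicable")

    def symbol(self) -> str:
        """Canonical one-token text form (``a`` for {0,1}, brackets for
        other polymorphisms; bracket style is chosen by the writer)."""
        if self.kind == "missing":
            return "?"
        if self.kind == "inapplicable":
            return "-"
        if len(self.states) == 1:
            return str(next(iter(self.states)))
        if self.states == frozenset({0, 1}):
            return "a"
        return "".join(str(s) for s in sorted(self.states))


class CharacterMatrix:
    """An ordered taxa × characters grid of :class:`StateSet` cells."""

    def __init__(self, taxon_names: Sequence[str],
                 cells: Sequence[Sequence[StateSet]]):
        names = list(taxon_names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise MatrixParseError(f"duplicate taxon names: {dupes}")
        if len(cells) != len(names):
            raise MatrixParseError(
                f"{len(names)} taxa but {len(cells)} rows of cells")
        rows = [list(r) for r in cells]
        if rows:
            nchar = len(rows[0])
            for name, row in zip(names, rows):
                if len(row) != nchar:
                    raise MatrixParseError(
                        f"taxon {name!r} has {len(row)} characters, "
                        f"expected {nchar}")
        self.taxon_names: list[str] = names
        self._cells: list[list[StateSet]] = rows
        self._index = {n: i for i, n in enumerate(names)}

    # -- basic accessors -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_names)

    @property
    def n_characters(self) -> int:
        return len(self._cells[0]) if self._cells else 0

    def cell(self, taxon: str | int, char: int) -> StateSet:
        """Cell for ``taxon`` (name or 0-based row) and 0-based character."""
        row = taxon if isinstance(taxon, int) else self._index[taxon]
        return self._cells[row][char]

    def row(self, taxon: str | int) -> list[StateSet]:
        i = taxon if isinstance(taxon, int) else self._index[taxon]
        return list(self._cells[i])

    def column(self, char: int) -> list[StateSet]:
        return [r[char] for r in self._cells]

    def state_universe(self, char: int) -> frozenset[int]:
        """States observed (in any cell, including polymorphisms) for a
        0-based character."""
        u: set[int] = set()
        for r in self._cells:
            if r[char].is_observed:
                u |= r[char].states
        return frozenset(u)

    def subset_characters(self, chars: Sequence[int]) -> "CharacterMatrix":
        """New matrix restricted to (possibly repeated) 0-based character
        indices — the bootstrap resampling primitive."""
        return CharacterMatrix(
            self.taxon_names,
            [[row[c] for c in chars] for row in self._cells])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxon_names == other.taxon_names
                and self._cells == other._cells)

    def __repr__(self) -> str:
        return (f"<CharacterMatrix {self.n_taxa} taxa x "
                f"{self.n_characters} characters>")


# ---------------------------------------------------------------------------
# matrix parsing


def _parse_cell_tokens(line: str, taxon: str, row_no: int,
                       allow_braces: bool) -> list[StateSet]:
    cells: list[StateSet] = []
    i = 0
    while i < len(line):
        ch = line[i]
        if ch.isspace():
            i += 1
            continue
        if ch.isdigit():
            cells.append(StateSet.observed({int(ch)}))
        elif ch == "?":
            cells.append(StateSet.missing())
        elif ch in _INAPPLICABLE_CHARS:
            cells.append(StateSet.inapplicable())
        elif ch == "a":
            cells.append(StateSet.observed({0, 1}))
        elif ch in "[{(" and (allow_braces or ch == "["):
            close = {"[": "]", "{": "}", "(": ")"}[ch]
            j = line.find(close, i)
            if j < 0:
                raise MatrixParseError(
                    f"unterminated state group in row for taxon {taxon!r} "
                    f"(row {row_no}, column {i + 1})")
            group = line[i + 1:j]
            if not group or not all(c.isdigit() for c in group):
                raise MatrixParseError(
                    f"bad state group {line[i:j + 1]!r} in row for taxon "
                    f"{taxon!r} (row {row_no}, column {i + 1})")
            cells.append(StateSet.observed({int(c) for c in group}))
            i = j
        else:
            raise MatrixParseError(
                f"unknown symbol {ch!r} in row for taxon {taxon!r} "
                f"(row {row_no}, column {i + 1})")
        i += 1
    return cells


def _parse_taxon_rows(lines: Iterable[tuple[int, str]], ntax: int, nchar: int,
                      allow_braces: bool) -> tuple[list[str], list[list[StateSet]]]:
    """Parse ``name  cells`` rows, concatenating interleaved blocks."""
    names: list[str] = []
    rows: dict[str, list[StateSet]] = {}
    for row_no, line in lines:
        m = re.match(r"\s*(?:'([^']+)'|\"([^\"]+)\"|(\S+))\s+(.*)$", line)
        if not m:
            raise MatrixParseError(f"cannot parse matrix row {row_no}: {line!r}")
        name = m.group(1) or m.group(2) or m.group(3)
        cells = _parse_cell_tokens(m.group(4), name, row_no, allow_braces)
        if name not in rows:
            names.append(name)
            rows[name] = []
        rows[name].extend(cells)
    if len(names) != ntax:
        raise MatrixParseError(
            f"header declares {ntax} taxa but {len(names)} rows were parsed")
    for name in names:
        if len(rows[name]) != nchar:
            raise MatrixParseError(
                f"taxon {name!r} has {len(rows[name])} characters, header "
                f"declares {nchar}")
    return names, [rows[n] for n in names]


def _parse_tnt(text: str) -> CharacterMatrix:
    m = re.search(r"\bxread\b", text, re.IGNORECASE)
    if not m:
        raise MatrixParseError("no xread block found in TNT input")
    body = text[m.end():]
    # optional quoted title
    body = re.sub(r"^\s*'[^']*'", "", body, count=1)
    hm = re.match(r"\s*(\d+)\s+(\d+)\s*\n?", body)
    if not hm:
        raise MatrixParseError("xread header must give nchar and ntax")
    nchar, ntax = int(hm.group(1)), int(hm.group(2))
    body = body[hm.end():]
    end = body.find(";")
    if end < 0:
        raise MatrixParseError("xread block is not terminated by ';'")
    data_lines = [
        (i + 1, ln) for i, ln in enumerate(body[:end].splitlines())
        if ln.strip() and not ln.strip().startswith("&")
    ]
    names, rows = _parse_taxon_rows(data_lines, ntax, nchar, allow_braces=False)
    return CharacterMatrix(names, rows)


def _parse_nexus(text: str) -> CharacterMatrix:
    bm = re.search(
        r"begin\s+(?:data|characters)\s*;(.*?)end\s*;",
        text, re.IGNORECASE | re.DOTALL)
    if not bm:
        raise MatrixParseError("no DATA/CHARACTERS block found in NEXUS input")
    block = bm.group(1)
    dm = re.search(r"dimensions([^;]*);", block, re.IGNORECASE)
    if not dm:
        raise MatrixParseError("NEXUS block lacks a DIMENSIONS command")
    dims = dict(re.findall(r"(ntax|nchar)\s*=\s*(\d+)", dm.group(1),
                           re.IGNORECASE))
    dims = {k.lower(): int(v) for k, v in dims.items()}
    if "ntax" not in dims or "nchar" not in dims:
        raise MatrixParseError("DIMENSIONS must declare NTAX and NCHAR")
    mm = re.search(r"matrix(.*?);", block, re.IGNORECASE | re.DOTALL)
    if not mm:
        raise MatrixParseError("NEXUS block lacks a MATRIX command")
    data_lines = [
        (i + 1, ln) for i, ln in enumerate(mm.group(1).splitlines())
        if ln.strip() and not ln.strip().startswith("[")
    ]
    names, rows = _parse_taxon_rows(data_lines, dims["ntax"], dims["nchar"],
                                    allow_braces=True)
    return CharacterMatrix(names, rows)


def parse_matrix(text: str, dialect: Literal["tnt", "nexus"] = "tnt"
                 ) -> CharacterMatrix:
    """Parse a TNT ``xread`` or NEXUS ``DATA``/``CHARACTERS`` block."""
    if dialect == "tnt":
        return _parse_tnt(text)
    if dialect == "nexus":
        return _parse_nexus(text)
    raise ValueError(f"unknown dialect {dialect!r}")


def _format_name(name: str, dialect: str) -> str:
    if re.search(r"\s", name):
        return f"'{name}'"
    return name


def _format_cell(cell: StateSet, dialect: str) -> str:
    sym = cell.symbol()
    if len(sym) > 1:  # general polymorphism group
        return ("[" + sym + "]") if dialect == "tnt" else ("{" + sym + "}")
    return sym


def write_matrix(matrix: CharacterMatrix,
                 dialect: Literal["tnt", "nexus"] = "tnt") -> str:
    """Serialize a matrix; ``parse_matrix(write_matrix(m))`` is ``m``."""
    name_w = max((len(_format_name(n, dialect)) for n in matrix.taxon_names),
                 default=1) + 2
    rows = [
        f"{_format_name(n, dialect):<{name_w}}"
        + "".join(_format_cell(c, dialect) for c in matrix.row(n))
        for n in matrix.taxon_names
    ]
    if dialect == "tnt":
        return (f"xread\n{matrix.n_characters} {matrix.n_taxa}\n"
                + "\n".join(rows) + "\n;\n")
    if dialect == "nexus":
        symbols = sorted({s for ch in range(matrix.n_characters)
                          for s in matrix.state_universe(ch)}) or [0]
        sym = "".join(str(s) for s in symbols)
        return (
            "#NEXUS\nBEGIN DATA;\n"
            f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};\n"
            f'FORMAT DATATYPE=STANDARD SYMBOLS="{sym}" MISSING=? GAP=-;\n'
            "MATRIX\n" + "\n".join(rows) + "\n;\nEND;\n")
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# age tables


@dataclass
class AgeTable:
    """First-appearance interval ``[oldest, youngest]`` (Ma) per taxon."""

    ages: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, (old, young) in self.ages.items():
            if old < young:
                raise MatrixParseError(
                    f"taxon {taxon!r}: oldest age {old} < youngest {young}")
            if young < 0:
                raise MatrixParseError(
                    f"taxon {taxon!r}: negative age {young}")

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.ages

    def oldest(self, taxon: str) -> float:
        return self.ages[taxon][0]

    def youngest(self, taxon: str) -> float:
        return self.ages[taxon][1]

    def midpoint(self, taxon: str) -> float:
        old, young = self.ages[taxon]
        return 0.5 * (old + young)

    def point(self, taxon: str, which: Literal["oldest", "youngest"]) -> float:
        return self.ages[taxon][0 if which == "oldest" else 1]

    def taxa(self) -> list[str]:
        return list(self.ages)

    def validate_against(self, taxa: Iterable[str]) -> None:
        missing = sorted(set(taxa) - set(self.ages))
        if missing:
            raise MatrixParseError(
                f"age table lacks {len(missing)} taxa: {missing}")


def parse_age_table(text: str) -> AgeTable:
    """Parse a CSV/TSV table ``taxon, oldest, youngest`` (header row
    required) or a JSON object ``{taxon: [oldest, youngest]}``."""
    stripped = text.lstrip()
    if stripped.startswith("{"):
        data = json.loads(text)
        return AgeTable({t: (float(v[0]), float(v[1]))
                         for t, v in data.items()})
    dialect = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=dialect)
    rows = [r for r in reader if r and any(f.strip() for f in r)]
    ages: dict[str, tuple[float, float]] = {}
    for r in rows[1:]:  # skip header
        if len(r) < 3:
            raise MatrixParseError(f"age row needs 3 columns: {r}")
        taxon = r[0].strip()
        if taxon in ages:
            raise MatrixParseError(f"duplicate taxon in age table: {taxon!r}")
        ages[taxon] = (float(r[1]), float(r[2]))
    return AgeTable(ages)


def write_age_table(table: AgeTable, fmt: Literal["csv", "json"] = "csv") -> str:
    if fmt == "json":
        return json.dumps({t: list(v) for t, v in table.ages.items()},
                          indent=1)
    out = ["taxon,oldest_ma,youngest_ma"]
    out += [f"{t},{old:g},{young:g}" for t, (old, young) in table.ages.items()]
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# area tables


@dataclass
class AreaTable:
    """Exactly one continental area per taxon."""

    areas: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, area in self.areas.items():
            if area not in AREAS:
                raise MatrixParseError(
                    f"taxon {taxon!r}: unknown area {area!r}; "
                    f"expected one of {list(AREAS)}")

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.areas

    def area(self, taxon: str) -> str:
        return self.areas[taxon]

    def state(self, taxon: str) -> int:
        """Integer state code of the taxon's area (index into AREAS)."""
        return AREAS.index(self.areas[taxon])

    def taxa(self) -> list[str]:
        return list(self.areas)


def parse_area_table(text: str) -> AreaTable:
    """Parse ``taxon, area`` CSV/TSV (header row) or JSON ``{taxon: area}``."""
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return AreaTable(dict(json.loads(text)))
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.reader(io.StringIO(text), delimiter=delim)
    rows = [r for r in reader if r and any(f.strip() for f in r)]
    areas: dict[str, str] = {}
    for r in rows[1:]:
        if len(r) < 2:
            raise MatrixParseError(f"area row needs 2 columns: {r}")
        taxon = r[0].strip()
        if taxon in areas:
            raise MatrixParseError(f"duplicate taxon in area table: {taxon!r}")
        areas[taxon] = r[1].strip()
    return AreaTable(areas)


def write_area_table(table: AreaTable, fmt: Literal["csv", "json"] = "csv"
                     ) -> str:
    if fmt == "json":
        return json.dumps(dict(table.areas), indent=1)
    out = ["taxon,area"]
    out += [f"{t},{a}" for t, a in table.areas.items()]
    return "\n".join(out) + "\n"


def build_area_character(areas: AreaTable, taxa: Sequence[str]
                         ) -> CharacterMatrix:
    """Single-character matrix encoding the six-state geographic character.

    State codes follow the fixed :data:`AREAS` order, so the taxon→state
    mapping is independent of taxon order.  Every taxon must have an area
    (no missing cells — each included species is known from one continent).
    """
    missing = sorted(set(taxa) - set(areas.areas))
    if missing:
        raise MatrixParseError(f"taxa without an area assignment: {missing}")
    cells = [[StateSet.observed({areas.state(t)})] for t in taxa]
    return CharacterMatrix(list(taxa), cells)
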