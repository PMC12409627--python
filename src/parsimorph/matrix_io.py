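"""Read and write character matrices in NEXUS and TNT dialects.

Token semantics follow common practice for morphological data:

* ``?`` and ``-`` (gap) both become MISSING -- a gap in a morphological
  matrix is inapplicability, treated as total ambiguity;
* polymorphism ``(ab)``, uncertainty ``{ab}`` and TNT's ``[ab]`` all become
  the state set ``{a, b}``: the most parsimonious member state is the one
  that ends up in any step count;
* ordered/additive flags come from a NEXUS ASSUMPTIONS ``TYPESET`` or a TNT
  ``ccode`` statement when present, else every character is unordered.

The writer emits canonical non-interleaved NEXUS (or TNT xread). Reading a
written file reproduces the cell grid and ordered flags exactly.
"""
from __future__ import annotations

import re

from .matrix import MISSING, MAX_STATES, CharacterMatrix, CharacterMeta


class MatrixParseError(ValueError):
    def __init__(self, message: str, line: int | None = None, col: int | None = None):
        loc = "" if line is None else f" (line {line}" + ("" if col is None else f", column {col}") + ")"
        super().__init__(message + loc)
        self.line = line
        self.col = col


def read_matrix(path, dialect: str = "nexus") -> CharacterMatrix:
    with open(path) as fh:
        text = fh.read()
    return parse_matrix(text, dialect)


def parse_matrix(text: str, dialect: str = "nexus") -> CharacterMatrix:
    if dialect == "nexus":
        return parse_nexus(text)
    if dialect == "tnt":
        return parse_tnt(text)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'nexus' or 'tnt')")


def write_matrix(m: CharacterMatrix, path, dialect: str = "nexus") -> None:
    text = nexus_text(m) if dialect == "nexus" else tnt_text(m)
    if dialect not in ("nexus", "tnt"):
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# shared cell tokenizer
# ---------------------------------------------------------------------------

_BRACKETS = {"(": ")", "{": "}", "[": "]"}


def _parse_cells(seq: str, line_no: int, col0: int, out: list) -> None:
    """Append cells parsed from one sequence fragment to ``out``."""
    i = 0
    while i < len(seq):
        ch = seq[i]
        col = col0 + i + 1
        if ch in " \t":
            i += 1
        elif ch.isdigit():
            out.append(frozenset({int(ch)}))
            i += 1
        elif ch in "?-":
            out.append(MISSING)
            i += 1
        elif ch in _BRACKETS:
            close = _BRACKETS[ch]
            j = seq.find(close, i + 1)
            if j < 0:
                raise MatrixParseError(f"unclosed {ch!r}", line_no, col)
            inner = seq[i + 1 : j].replace(" ", "").replace(",", "")
            if not inner or not inner.isdigit():
                raise MatrixParseError(
                    f"malformed state set {seq[i:j+1]!r}", line_no, col
                )
            out.append(frozenset(int(c) for c in inner))
            i = j + 1
        else:
            raise MatrixParseError(f"unexpected character {ch!r}", line_no, col)


def _rows_from_lines(lines, start_line: int):
    """Accumulate (taxon -> cells) from matrix lines, interleave-tolerant."""
    order: list[str] = []
    cells: dict[str, list] = {}
    for off, raw in enumerate(lines):
        line_no = start_line + off
        line = raw.strip()
        if not line or line == "&":
            continue
        if line.startswith("'"):
            end = line.find("'", 1)
            if end < 0:
                raise MatrixParseError("unterminated quoted taxon name", line_no, 1)
            name = line[1:end]
            rest = line[end + 1 :]
            rest_col = raw.index("'") + end + 1
        else:
            mt = re.match(r"(\S+)(\s*)(.*)$", line)
            name, rest = mt.group(1), mt.group(3)
            rest_col = raw.find(name) + len(name) + len(mt.group(2))
        if name not in cells:
            order.append(name)
            cells[name] = []
        elif len(cells[name]) == 0:
            raise MatrixParseError(f"duplicate taxon label {name!r}", line_no, 1)
        _parse_cells(rest, line_no, rest_col, cells[name])
    return order, cells


def _build(order, cells, ntax, nchar, ordered_idx, dialect):
    if ntax is not None and len(order) != ntax:
        raise MatrixParseError(
            f"expected {ntax} taxa, found {len(order)} in {dialect} matrix"
        )
    counts = {len(v) for v in cells.values()}
    if nchar is not None and counts != {nchar}:
        bad = {k: len(v) for k, v in cells.items() if len(v) != nchar}
        raise MatrixParseError(f"rows with wrong character count: {bad}")
    n = len(next(iter(cells.values())))
    meta = [CharacterMeta(j + 1, ordered=(j + 1) in ordered_idx) for j in range(n)]
    return CharacterMatrix(order, [cells[t] for t in order], meta)


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------

def _strip_nexus_comments(text: str) -> str:
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
            out.append(" ")
        elif ch == "]" and depth:
            depth -= 1
            out.append(" ")
        elif depth:
            out.append("\n" if ch == "\n" else " ")
        else:
            out.append(ch)
    return "".join(out)


def _find_block(text: str, names):
    """Return (block content, offset of content in text) or (None, 0)."""
    pat = re.compile(
        r"begin\s+(" + "|".join(names) + r")\s*;(.*?)\bend\s*;",
        re.IGNORECASE | re.DOTALL,
    )
    mt = pat.search(text)
    return (mt.group(2), mt.start(2)) if mt else (None, 0)


def _parse_index_list(spec: str) -> set[int]:
    out: set[int] = set()
    for item in spec.replace(",", " ").split():
        if "-" in item:
            a, b = item.split("-")
            out.update(range(int(a), int(b) + 1))
        else:
            out.add(int(item))
    return out


def parse_nexus(text: str) -> CharacterMatrix:
    clean = _strip_nexus_comments(text)
    block, block_off = _find_block(clean, ("data", "characters"))
    if block is None:
        raise MatrixParseError("no DATA or CHARACTERS block found")
    ntax = nchar = None
    mt = re.search(r"dimensions([^;]*);", block, re.IGNORECASE)
    if mt:
        dims = mt.group(1)
        m2 = re.search(r"ntax\s*=\s*(\d+)", dims, re.IGNORECASE)
        ntax = int(m2.group(1)) if m2 else None
        m2 = re.search(r"nchar\s*=\s*(\d+)", dims, re.IGNORECASE)
        nchar = int(m2.group(1)) if m2 else None
    mt = re.search(r"format([^;]*);", block, re.IGNORECASE)
    if mt:
        m2 = re.search(r"symbols\s*=\s*\"([^\"]*)\"", mt.group(1), re.IGNORECASE)
        if m2:
            symbols = m2.group(1).replace(" ", "")
            if not symbols.isdigit() or len(set(symbols)) > MAX_STATES:
                raise MatrixParseError(
                    f"unsupported symbol alphabet {symbols!r}: only digits 0-9 allowed"
                )
    mt = re.search(r"matrix(.*?);", block, re.IGNORECASE | re.DOTALL)
    if mt is None:
        raise MatrixParseError("no MATRIX statement in data block")
    # line numbers relative to the full file, for error messages
    start_line = clean[: block_off + mt.start(1)].count("\n") + 1
    order, cells = _rows_from_lines(mt.group(1).split("\n"), start_line)
    if not order:
        raise MatrixParseError("empty MATRIX statement")
    ordered_idx: set[int] = set()
    ablock, _ = _find_block(clean, ("assumptions",))
    if ablock:
        for m3 in re.finditer(r"typeset[^=;]*=([^;]*);", ablock, re.IGNORECASE):
            for part in m3.group(1).split(","):
                if ":" not in part:
                    continue
                kind, idx = part.split(":", 1)
                if kind.strip().lower() in ("ord", "ordered", "additive"):
                    ordered_idx |= _parse_index_list(idx)
    return _build(order, cells, ntax, nchar, ordered_idx, "NEXUS")


def _quote(name: str) -> str:
    return f"'{name}'" if re.search(r"\s", name) else name


def _cell_token(cell, multi="{}") -> str:
    if cell is MISSING:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return multi[0] + "".join(str(s) for s in sorted(cell)) + multi[1]


def nexus_text(m: CharacterMatrix) -> str:
    symbols = sorted({s for j in range(m.n_char) for s in m.observed_states(j)}) or [0]
    width = max(len(_quote(t)) for t in m.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_char};",
        'FORMAT DATATYPE=STANDARD MISSING=? GAP=- SYMBOLS="'
        + "".join(str(s) for s in symbols)
        + '";',
        "MATRIX",
    ]
    for taxon, row in zip(m.taxa, m.cells):
        lines.append(_quote(taxon).ljust(width) + "".join(_cell_token(c) for c in row))
    lines.append(";")
    lines.append("END;")
    ordered = [cm.index for cm in m.char_meta if cm.ordered]
    if ordered:
        unordered = [cm.index for cm in m.char_meta if not cm.ordered]
        parts = ["ord: " + " ".join(map(str, ordered))]
        if unordered:
            parts.append("unord: " + " ".join(map(str, unordered)))
        lines += [
            "BEGIN ASSUMPTIONS;",
            "TYPESET * default = " + ", ".join(parts) + ";",
            "END;",
        ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# TNT
# ---------------------------------------------------------------------------

def parse_tnt(text: str) -> CharacterMatrix:
    mt = re.search(r"\bxread\b", text, re.IGNORECASE)
    if mt is None:
        raise MatrixParseError("no xread statement found")
    rest = text[mt.end():]
    # optional quoted title
    rest = re.sub(r"^\s*'[^']*'", "", rest, count=1)
    m2 = re.match(r"\s*(\d+)\s+(\d+)\s*\n?", rest)
    if m2 is None:
        raise MatrixParseError("xread must be followed by 'nchar ntax'")
    nchar, ntax = int(m2.group(1)), int(m2.group(2))
    body = rest[m2.end():]
    end = body.find(";")
    if end < 0:
        raise MatrixParseError("unterminated xread matrix (missing ';')")
    start_line = text[: mt.end()].count("\n") + 1
    order, cells = _rows_from_lines(body[:end].split("\n"), start_line)
    if not order:
        raise MatrixParseError("empty xread matrix")
    ordered_idx: set[int] = set()
    for m3 in re.finditer(r"\bcc(?:ode)?\s+([^;]*);", text, re.IGNORECASE):
        mode = None
        for token in m3.group(1).replace(",", " ").split():
            if token in "+-[]":
                mode = token
            elif re.fullmatch(r"\d+(\.\d+)?", token):
                if "." in token:
                    a, b = (int(x) for x in token.split("."))
                    span = range(a, b + 1)
                else:
                    span = [int(token)]
                for i in span:  # TNT character numbers are 0-based
                    if mode == "+":
                        ordered_idx.add(i + 1)
                    elif mode == "-":
                        ordered_idx.discard(i + 1)
    return _build(order, cells, ntax, nchar, ordered_idx, "TNT")


def tnt_text(m: CharacterMatrix) -> str:
    width = max(len(_quote(t)) for t in m.taxa) + 2
    lines = ["xread", f"{m.n_char} {m.n_taxa}"]
    for taxon, row in zip(m.taxa, m.cells):
        lines.append(
            _quote(taxon).ljust(width) + "".join(_cell_token(c, "[]") for c in row)
        )
    lines.append(";")
    ordered = [cm.index - 1 for cm in m.char_meta if cm.ordered]
    if ordered:
        lines.append("ccode + " + " ".join(map(str, ordered)) + ";")
    lines.append("proc /;")
    return "\n".join(lines) + "\n"
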