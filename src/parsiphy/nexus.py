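"""NEXUS character-matrix input and output.

Supports the dialect used for mixed molecular/morphological parsimony
matrices: DATA/CHARACTERS blocks (sequential or interleaved, one block
per datatype or a single MrBayes-style ``DATATYPE=MIXED(...)`` block),
CHARSET statements in SETS/ASSUMPTIONS/program blocks, WTSET weights,
and TREES blocks.  PAUP/MrBayes command blocks are ignored.  Gap (``-``)
and missing (``?``) symbols both map to the missing cell; IUPAC
ambiguity codes expand to state sets; parenthesised or braced groups
become polymorphic cells.

Character indexing is 1-based in NEXUS text, 0-based in the API.
Multi-line (unlabelled continuation) sequences are not supported: each
matrix line must start with its taxon label, which is how this module's
own writer and the common mixed-matrix files are laid out.
"""

from __future__ import annotations

import re

import dendropy

from .matrix import CharacterMatrix, IUPAC, MISSING, MatrixError
from .tree import PhyloTree


class NexusError(MatrixError):
    pass


_DATATYPE_MAP = {
    "dna": "dna", "nucleotide": "dna", "rna": "dna",
    "standard": "standard", "restriction": "binary", "binary": "binary",
}


def _strip_comments(text: str) -> str:
    out = []
    depth = 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth:
                depth -= 1
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def _blocks(text: str):
    pat = re.compile(r"begin\s+(\w+)\s*;(.*?)\bend\s*;", re.I | re.S)
    for m in pat.finditer(text):
        yield m.group(1).lower(), m.group(2)


def _commands(block: str):
    for cmd in block.split(";"):
        cmd = cmd.strip()
        if cmd:
            yield cmd


def _parse_ranges(spec: str, nchar: int) -> list[int]:
    """1-based NEXUS position lists ("1-913 915 920-.") to 0-based indices."""
    out: list[int] = []
    for tok in spec.replace(",", " ").split():
        if "-" in tok and not tok.startswith("-"):
            lo, hi = tok.split("-", 1)
            lo_i = int(lo)
            hi_i = nchar if hi.strip() == "." else int(hi)
            out.extend(range(lo_i - 1, hi_i))
        else:
            out.append((nchar if tok == "." else int(tok)) - 1)
    return out


def _cell_from_symbol(sym: str, datatype: str, missing: str, gap: str,
                      char_index: int) -> frozenset:
    if sym == missing or sym == gap:
        return MISSING
    if datatype == "dna":
        expanded = IUPAC.get(sym.upper())
        if expanded is None:
            raise NexusError(
                f"character {char_index + 1}: unknown DNA symbol {sym!r}"
            )
        return frozenset(expanded)
    if not (sym.isalnum()):
        raise NexusError(
            f"character {char_index + 1}: unknown state symbol {sym!r}"
        )
    return frozenset((sym,))


def _parse_states(seq: str, start: int, datatypes: list[str],
                  missing: str, gap: str, taxon: str) -> list[frozenset]:
    cells: list[frozenset] = []
    i = 0
    j = start
    while i < len(seq):
        ch = seq[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "({":
            close = ")" if ch == "(" else "}"
            end = seq.find(close, i)
            if end < 0:
                raise NexusError(f"taxon {taxon!r}: unclosed {ch!r} group")
            group = [c for c in seq[i + 1:end] if not c.isspace()]
            if j >= len(datatypes):
                raise NexusError(f"taxon {taxon!r}: too many characters")
            cell = frozenset().union(
                *(_cell_from_symbol(c, datatypes[j], missing, gap, j)
                  for c in group)
            )
            cells.append(cell)
            j += 1
            i = end + 1
            continue
        if j >= len(datatypes):
            raise NexusError(f"taxon {taxon!r}: too many characters")
        cells.append(_cell_from_symbol(ch, datatypes[j], missing, gap, j))
        j += 1
        i += 1
    return cells


def _parse_matrix_block(body: str):
    """One DATA/CHARACTERS block -> (taxa, rows, datatypes)."""
    nchar = ntax = None
    datatype = "standard"
    mixed: list[tuple[str, str]] = []
    missing, gap = "?", "-"
    interleave = False
    matrix_text = None
    for cmd in _commands(body):
        head = cmd.split(None, 1)[0].lower()
        if head == "dimensions":
            m = re.search(r"nchar\s*=\s*(\d+)", cmd, re.I)
            if m:
                nchar = int(m.group(1))
            m = re.search(r"ntax\s*=\s*(\d+)", cmd, re.I)
            if m:
                ntax = int(m.group(1))
        elif head == "format":
            m = re.search(r"datatype\s*=\s*mixed\s*\(([^)]*)\)", cmd, re.I)
            if m:
                datatype = "mixed"
                for part in m.group(1).split(","):
                    name, rng = part.split(":", 1)
                    mixed.append((name.strip().lower(), rng.strip()))
            else:
                m = re.search(r"datatype\s*=\s*(\w+)", cmd, re.I)
                if m:
                    datatype = m.group(1).lower()
            m = re.search(r"missing\s*=\s*(\S)", cmd, re.I)
            if m:
                missing = m.group(1)
            m = re.search(r"gap\s*=\s*(\S)", cmd, re.I)
            if m:
                gap = m.group(1)
            if re.search(r"interleave(\s*=\s*yes)?\b", cmd, re.I) and not \
                    re.search(r"interleave\s*=\s*no\b", cmd, re.I):
                interleave = True
        elif head == "matrix":
            matrix_text = cmd.split(None, 1)[1] if len(cmd.split(None, 1)) > 1 else ""
    if matrix_text is None:
        return None
    if nchar is None:
        raise NexusError("DIMENSIONS NCHAR missing")

    if datatype == "mixed":
        datatypes = ["standard"] * nchar
        for name, rng in mixed:
            tag = _DATATYPE_MAP.get(name)
            if tag is None:
                raise NexusError(f"unsupported datatype {name!r} in MIXED")
            for j in _parse_ranges(rng, nchar):
                datatypes[j] = tag
    else:
        tag = _DATATYPE_MAP.get(datatype)
        if tag is None:
            raise NexusError(f"unsupported datatype {datatype!r}")
        datatypes = [tag] * nchar

    taxa: list[str] = []
    rows: dict[str, list[frozenset]] = {}
    for line in matrix_text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            m = re.match(r"'((?:[^']|'')*)'\s*(.*)", line)
            if not m:
                raise NexusError(f"unterminated quoted label: {line[:30]}")
            name = m.group(1).replace("''", "'")
            seq = m.group(2)
        else:
            parts = line.split(None, 1)
            name = parts[0]
            seq = parts[1] if len(parts) > 1 else ""
        if name not in rows:
            taxa.append(name)
            rows[name] = []
        elif not interleave and len(rows[name]) >= nchar:
            raise NexusError(f"duplicate taxon label {name!r}")
        start = len(rows[name])
        rows[name].extend(
            _parse_states(seq, start, datatypes, missing, gap, name)
        )
    for name in taxa:
        if len(rows[name]) != nchar:
            raise NexusError(
                f"taxon {name!r}: {len(rows[name])} characters read, "
                f"expected {nchar}"
            )
    if ntax is not None and len(taxa) != ntax:
        raise NexusError(f"{len(taxa)} taxa read, NTAX says {ntax}")
    return taxa, [rows[t] for t in taxa], datatypes


def parse_nexus(text: str) -> CharacterMatrix:
    """Parse a NEXUS document into a :class:`CharacterMatrix`.

    Multiple DATA/CHARACTERS blocks are concatenated column-wise (all
    must list the same taxa).  CHARSET statements anywhere in the file
    become named partitions; a WTSET statement sets character weights.
    """
    if not text.lstrip().lower().startswith("#nexus"):
        raise NexusError("not a NEXUS document (missing #NEXUS header)")
    text = _strip_comments(text)

    taxa = None
    rows: list[list[frozenset]] = []
    datatypes: list[str] = []
    for name, body in _blocks(text):
        if name not in ("data", "characters"):
            continue
        parsed = _parse_matrix_block(body)
        if parsed is None:
            continue
        btaxa, brows, btypes = parsed
        if taxa is None:
            taxa = btaxa
            rows = [list(r) for r in brows]
        else:
            if set(btaxa) != set(taxa):
                raise NexusError(
                    "CHARACTERS blocks list different taxa"
                )
            lut = {t: r for t, r in zip(btaxa, brows)}
            for i, t in enumerate(taxa):
                rows[i].extend(lut[t])
        datatypes.extend(btypes)
    if taxa is None:
        raise NexusError("no DATA/CHARACTERS block with a MATRIX found")
    nchar = len(datatypes)

    partitions: dict[str, list[int]] = {}
    for m in re.finditer(r"\bcharset\s+(\S+)\s*=\s*([^;]+);", text, re.I):
        partitions[m.group(1)] = _parse_ranges(m.group(2), nchar)

    weights = None
    m = re.search(r"\bwtset\s+\*?\s*\S+\s*=\s*([^;]+);", text, re.I)
    if m:
        weights = [1] * nchar
        for clause in m.group(1).split(","):
            w, pos = clause.split(":", 1)
            for j in _parse_ranges(pos, nchar):
                weights[j] = int(w)

    return CharacterMatrix(taxa, rows, datatypes, weights,
                           partitions or None)


def parse_nexus_trees(text: str) -> list[PhyloTree]:
    """Extract and parse trees from the TREES block(s) of a NEXUS file."""
    stripped = _strip_comments(text)
    trees_blocks = [
        body for name, body in _blocks(stripped) if name == "trees"
    ]
    out: list[PhyloTree] = []
    for body in trees_blocks:
        doc = "#NEXUS\nbegin trees;\n" + body + "\nend;\n"
        tl = dendropy.TreeList.get(data=doc, schema="nexus")
        out.extend(PhyloTree.from_dendropy(t) for t in tl)
    return out


# ----------------------------------------------------------------------
# writing

_REV_IUPAC = {frozenset(v): k for k, v in IUPAC.items()
              if k not in ("U", "X", "-", "?")}


def _symbol(cell: frozenset, datatype: str) -> str:
    if not cell:
        return "?"
    if datatype == "dna":
        sym = _REV_IUPAC.get(cell)
        if sym is None:
            raise NexusError(f"cannot encode DNA cell {sorted(cell)}")
        return sym
    states = sorted(cell)
    if len(states) == 1:
        return states[0]
    return "(" + "".join(states) + ")"


def _runs(datatypes) -> list[tuple[str, int, int]]:
    """Maximal runs of equal datatype as (tag, start, stop) 0-based."""
    runs = []
    start = 0
    for j in range(1, len(datatypes) + 1):
        if j == len(datatypes) or datatypes[j] != datatypes[start]:
            runs.append((datatypes[start], start, j))
            start = j
    return runs


_WRITE_NAME = {"dna": "DNA", "standard": "STANDARD", "binary": "RESTRICTION"}


def write_nexus(matrix: CharacterMatrix, style: str = "mixed") -> str:
    """Serialize a matrix to NEXUS text.

    ``style="mixed"`` (default) writes one DATA block with a MrBayes
    style ``DATATYPE=MIXED(...)`` declaration; ``style="separate"``
    writes one CHARACTERS block per contiguous datatype run.  Charsets
    and (non-unit) weights go to SETS and ASSUMPTIONS blocks.  The
    output round-trips through :func:`parse_nexus` exactly.
    """
    lines = ["#NEXUS", ""]
    runs = _runs(matrix.datatypes)
    pad = max((len(_fmt_name(t)) for t in matrix.taxa), default=0) + 2

    def matrix_lines(col_range):
        for i, t in enumerate(matrix.taxa):
            symbols = "".join(
                _symbol(matrix.cells[i][j], matrix.datatypes[j])
                for j in col_range
            )
            yield f"    {_fmt_name(t):<{pad}}{symbols}"

    if style == "mixed":
        spec = ",".join(
            f"{_WRITE_NAME[tag]}:{a + 1}-{b}" for tag, a, b in runs
        )
        lines += [
            "BEGIN DATA;",
            f"    DIMENSIONS NTAX={matrix.n_taxa} "
            f"NCHAR={matrix.n_characters};",
            f"    FORMAT DATATYPE=MIXED({spec}) MISSING=? GAP=-;",
            "    MATRIX",
            *matrix_lines(range(matrix.n_characters)),
            "    ;",
            "END;",
            "",
        ]
    elif style == "separate":
        for bi, (tag, a, b) in enumerate(runs):
            kind = "DATA" if bi == 0 else "CHARACTERS"
            lines += [
                f"BEGIN {kind};",
                f"    DIMENSIONS NTAX={matrix.n_taxa} NCHAR={b - a};",
                f"    FORMAT DATATYPE={_WRITE_NAME[tag]} MISSING=? GAP=-;",
                "    MATRIX",
                *matrix_lines(range(a, b)),
                "    ;",
                "END;",
                "",
            ]
    else:
        raise ValueError(f"unknown style {style!r}")

    if matrix.partitions:
        lines.append("BEGIN SETS;")
        for name, idx in matrix.partitions.items():
            lines.append(f"    CHARSET {name} = {_fmt_positions(idx)};")
        lines += ["END;", ""]

    if (matrix.weights != 1).any():
        clauses = {}
        for j, w in enumerate(matrix.weights):
            if w != 1:
                clauses.setdefault(int(w), []).append(j)
        body = ", ".join(
            f"{w}: {_fmt_positions(idx)}" for w, idx in sorted(clauses.items())
        )
        lines += ["BEGIN ASSUMPTIONS;", f"    WTSET * weights = {body};",
                  "END;", ""]
    return "\n".join(lines)


def _fmt_name(name: str) -> str:
    if re.search(r"[\s(){}\[\];,=']", name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _fmt_positions(idx) -> str:
    """0-based indices to compact 1-based NEXUS ranges."""
    idx = sorted(idx)
    parts = []
    start = prev = idx[0]
    for j in idx[1:] + [None]:
        if j is not None and j == prev + 1:
            prev = j
            continue
        parts.append(str(start + 1) if start == prev
                     else f"{start + 1}-{prev + 1}")
        if j is not None:
            start = prev = j
    return " ".join(parts)


def write_trees_nexus(trees, names=None) -> str:
    """TREES block with the given PhyloTrees (topology only)."""
    lines = ["#NEXUS", "", "BEGIN TREES;"]
    for i, t in enumerate(trees):
        name = names[i] if names else f"tree_{i + 1}"
        lines.append(f"    TREE {name} = [&U] {t.to_newick()}")
    lines += ["END;", ""]
    return "\n".join(lines)
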