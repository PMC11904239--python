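"""Protein folding variation matrix (PFVM).

One column per five-residue sliding window of the sequence; each column
ranks the fold codes ever observed (or backed off) for that window's
pentamer, most favoured first. The matrix is the single-sequence
summary of local fold variability: taking one code per column
enumerates conformation strings, and the exact number of such strings
is the big-integer product of the column depths — astronomically large
for real proteins, which is the point.
"""

from __future__ import annotations

import html as _html
import math
from dataclasses import dataclass

from .alphabet import PfscAlphabet, PfscString
from .errors import ValidationError
from .pentamer_db import PentamerDB, PentamerRecord, query_pentamer

WINDOW = 5


@dataclass
class PfvmColumn:
    position: int  # 1-based index of the window's first residue
    pentamer: str
    entries: list[tuple[str, int]]  # (code, count), rank order
    synthetic: bool = False

    @property
    def center(self) -> int:
        """1-based ordinal of the window's centre residue."""
        return self.position + 2

    @property
    def depth(self) -> int:
        return len(self.entries)

    def codes(self) -> str:
        return "".join(c for c, _ in self.entries)


@dataclass
class Pfvm:
    sequence: str
    columns: list[PfvmColumn]

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def depths(self) -> list[int]:
        return [c.depth for c in self.columns]


def build_pfvm(sequence: str, db: PentamerDB) -> Pfvm:
    """One ranked column per window of ``sequence`` (length >= 5).

    'X' residues are tolerated; their windows cannot be looked up and
    fall back on the background ranking, flagged synthetic.
    """
    sequence = sequence.upper()
    if len(sequence) < WINDOW:
        raise ValidationError(f"sequence of {len(sequence)} residues; need >= {WINDOW}")
    columns = []
    for i in range(len(sequence) - WINDOW + 1):
        pentamer = sequence[i:i + WINDOW]
        if "X" in pentamer:
            if not db.background:
                raise ValidationError("database has no background to cover 'X' windows")
            rec = PentamerRecord(pentamer, db.background[: db.k_backoff], synthetic=True)
        else:
            rec = query_pentamer(db, pentamer)
        columns.append(PfvmColumn(i + 1, pentamer, list(rec.patterns), rec.synthetic))
    return Pfvm(sequence=sequence, columns=columns)


def count_conformations(m: Pfvm) -> int:
    """Exact number of distinct conformation strings the matrix spans:
    the big-integer product of per-column depths."""
    return math.prod(c.depth for c in m.columns)


@dataclass
class MismatchRow:
    source_id: str
    mask: list[bool]
    count: int


def compare_to_reference(strings: list[PfscString], reference: PfscString) -> list[MismatchRow]:
    """Per-position mismatch mask and Hamming count of each string
    against a reference of equal length."""
    rows = []
    for s in strings:
        if len(s.codes) != len(reference.codes):
            raise ValidationError(
                f"length mismatch: {s.source_id!r} has {len(s.codes)}, "
                f"reference {len(reference.codes)}"
            )
        mask = [a != b for a, b in zip(s.codes, reference.codes)]
        rows.append(MismatchRow(s.source_id, mask, sum(mask)))
    return rows


@dataclass
class PfvmReport:
    text: str
    html: str


_CLASS_COLORS = {
    "helix": "#d62728",
    "alike-helix": "#ff9896",
    "strand": "#1f77b4",
    "alike-strand": "#aec7e8",
    "irregular": "#000000",
    "undefined": "#7f7f7f",
}


def render_pfvm(m: Pfvm, reference: PfscString | None = None,
                alphabet: PfscAlphabet | None = None,
                block_width: int = 60) -> PfvmReport:
    """Plain-text and HTML views of the matrix.

    Columns run left-to-right along the sequence, ranks top-to-bottom.
    Plain text marks classes per code in a legend and synthetic columns
    with '*'; HTML styles each cell by fold class and gives cells that
    disagree with the reference a yellow background.
    """
    alphabet = alphabet or PfscAlphabet()
    if reference is not None and len(reference.codes) != len(m.columns):
        raise ValidationError(
            f"reference length {len(reference.codes)} != {len(m.columns)} columns"
        )
    max_depth = max(c.depth for c in m.columns)

    # ---- plain text ----
    lines = [f"PFVM  sequence length {len(m.sequence)}  columns {len(m.columns)}"]
    for start in range(0, len(m.columns), block_width):
        block = m.columns[start:start + block_width]
        lines.append("")
        lines.append(f"window {block[0].position}..{block[-1].position}"
                     f"  (center {block[0].center}..{block[-1].center})")
        lines.append("seq    " + "".join(m.sequence[c.position - 1] for c in block))
        for r in range(max(c.depth for c in block)):
            row = "".join(c.entries[r][0] if r < c.depth else " " for c in block)
            lines.append(f"rank{r + 1:2d} " + row)
        lines.append("synth  " + "".join("*" if c.synthetic else "." for c in block))
        if reference is not None:
            ref_block = reference.codes[start:start + block_width]
            lines.append("ref    " + ref_block)
    legend = ", ".join(f"{cls}: "
                       + "".join(sorted(c for c in alphabet.codes
                                        if alphabet.classify(c) == cls))
                       for cls in _CLASS_COLORS)
    lines.append("")
    lines.append("classes  " + legend)
    text = "\n".join(lines) + "\n"

    # ---- HTML ----
    cells = []
    for r in range(max_depth):
        tds = []
        for c in m.columns:
            if r < c.depth:
                code = c.entries[r][0]
                cls = alphabet.classify(code)
                style = f"color:{_CLASS_COLORS[cls]}"
                if reference is not None and code != reference.codes[c.position - 1]:
                    style += ";background:#ffff00"
                mark = " pfvm-synthetic" if c.synthetic else ""
                tds.append(f'<td class="pfvm-{cls}{mark}" style="{style}">'
                           f"{_html.escape(code)}</td>")
            else:
                tds.append("<td></td>")
        cells.append("<tr>" + "".join(tds) + "</tr>")
    header = "<tr>" + "".join(
        f"<th>{m.sequence[c.position - 1]}</th>" for c in m.columns) + "</tr>"
    doc = (
        "<!DOCTYPE html><html><head><meta charset='utf-8'>"
        "<style>td,th{font-family:monospace;padding:0 1px}"
        ".pfvm-synthetic{font-style:italic}</style></head><body>"
        f"<table>{header}{''.join(cells)}</table></body></html>"
    )
    return PfvmReport(text=text, html=doc)


def read_pfvm_tsv(path) -> Pfvm:
    """Load a matrix from the long-form TSV written by
    :func:`pfvm_to_tsv` (also the interchange format for matrices
    published elsewhere and converted by hand)."""
    from pathlib import Path

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:4] != ["position", "center", "pentamer", "rank"]:
        raise ValidationError(f"{path} is not a PFVM TSV (bad header)")
    cols: dict[int, PfvmColumn] = {}
    for ln in lines[1:]:
        if not ln.strip():
            continue
        pos, _center, pentamer, rank, code, count, synth = ln.split("\t")
        pos = int(pos)
        col = cols.get(pos)
        if col is None:
            col = cols[pos] = PfvmColumn(pos, pentamer, [], bool(int(synth)))
        if int(rank) != len(col.entries) + 1:
            raise ValidationError(f"{path}: ranks of column {pos} are not consecutive")
        col.entries.append((code, int(count)))
    ordered = [cols[p] for p in sorted(cols)]
    if [c.position for c in ordered] != list(range(1, len(ordered) + 1)):
        raise ValidationError(f"{path}: column positions are not 1..N")
    sequence = "".join(c.pentamer[0] for c in ordered) + ordered[-1].pentamer[1:]
    return Pfvm(sequence=sequence, columns=ordered)


def pfvm_to_tsv(m: Pfvm) -> str:
    """Long-form TSV: position, center, pentamer, rank, code, count, synthetic."""
    rows = ["position\tcenter\tpentamer\trank\tcode\tcount\tsynthetic"]
    for c in m.columns:
        for r, (code, count) in enumerate(c.entries, start=1):
            rows.append(f"{c.position}\t{c.center}\t{c.pentamer}\t{r}\t{code}\t{count}"
                        f"\t{int(c.synthetic)}")
    return "\n".join(rows) + "\n"
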