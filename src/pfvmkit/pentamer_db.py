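"""Pentamer -> fold-pattern database.

Every five-residue window of every corpus chain contributes one
(pentamer sequence, fold code) observation; per pentamer the observed
codes are ranked by count (descending, ties broken lexicographically).
20^5 = 3,200,000 pentamer sequences exist; a desk-scale corpus covers
only a sliver of them, so queries for unseen pentamers fall back on the
corpus-wide background ranking truncated to ``k_backoff`` codes, and
such records are flagged ``synthetic`` so downstream reports can mark
columns that rest on no direct observation.

The database persists losslessly as XML
(``<db><meta/><rec p="AAAAA"><pat c="A" n="16"/></rec>...</db>``) or as
an equivalent JSON document.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree as ET

from .alphabet import PfscAlphabet
from .encoder import encode_chain
from .errors import FormatError, ValidationError
from .structures_io import AA20, read_structure

log = logging.getLogger(__name__)

PENTAMER_LEN = 5
DEFAULT_K_BACKOFF = 5


def enumerate_pentamer_space(alphabet_size: int = 20, length: int = PENTAMER_LEN) -> int:
    """Number of pentamer sequences over the amino-acid alphabet."""
    return alphabet_size ** length


def _rank(counter: Counter) -> list[tuple[str, int]]:
    return sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass
class PentamerRecord:
    pentamer: str
    patterns: list[tuple[str, int]]  # (code, count), count desc / code asc
    synthetic: bool = False

    def codes(self) -> str:
        return "".join(c for c, _ in self.patterns)


@dataclass
class PentamerDB:
    records: dict[str, PentamerRecord] = field(default_factory=dict)
    corpus_manifest: list[str] = field(default_factory=list)
    background: list[tuple[str, int]] = field(default_factory=list)
    k_backoff: int = DEFAULT_K_BACKOFF

    def __eq__(self, other):
        if not isinstance(other, PentamerDB):
            return NotImplemented
        return (
            {k: (v.patterns, v.synthetic) for k, v in self.records.items()}
            == {k: (v.patterns, v.synthetic) for k, v in other.records.items()}
            and self.corpus_manifest == other.corpus_manifest
            and self.background == other.background
            and self.k_backoff == other.k_backoff
        )

    @property
    def total_observations(self) -> int:
        return sum(n for _, n in self.background)


def _validate_pentamer(pentamer: str) -> None:
    if len(pentamer) != PENTAMER_LEN or any(c not in AA20 for c in pentamer):
        raise ValidationError(
            f"pentamer must be 5 characters over the 20-letter alphabet, got {pentamer!r}"
        )


def build_db(corpus: list[str | Path], alphabet: PfscAlphabet | None = None,
             k_backoff: int = DEFAULT_K_BACKOFF) -> PentamerDB:
    """Tally (pentamer, code) pairs over every window of every corpus
    chain. Windows encoding '$' or containing a non-standard residue are
    skipped. Unreadable files are logged and skipped; if every file is
    unreadable an IOError is raised."""
    if not corpus:
        raise ValidationError("corpus must not be empty")
    alphabet = alphabet or PfscAlphabet()
    tallies: dict[str, Counter] = {}
    background: Counter = Counter()
    manifest = []
    n_ok = 0
    for path in sorted(Path(p) for p in corpus):
        try:
            traces = read_structure(path)
        except (FormatError, IndexError) as exc:
            log.warning("skipping %s: %s", path, exc)
            continue
        n_ok += 1
        for trace in traces:
            if len(trace) < 5:
                continue
            string = encode_chain(trace, alphabet)
            seq = trace.sequence
            manifest.append(trace.source_id)
            for i, code in enumerate(string.codes):
                pentamer = seq[i:i + PENTAMER_LEN]
                if code == alphabet.undefined_code or "X" in pentamer:
                    continue
                tallies.setdefault(pentamer, Counter())[code] += 1
                background[code] += 1
    if n_ok == 0:
        raise IOError("no corpus file could be read")
    records = {
        p: PentamerRecord(p, _rank(cnt)) for p, cnt in sorted(tallies.items())
    }
    return PentamerDB(records=records, corpus_manifest=sorted(manifest),
                      background=_rank(background), k_backoff=k_backoff)


def query_pentamer(db: PentamerDB, pentamer: str) -> PentamerRecord:
    """Stored record for an observed pentamer; for an unseen one, the
    background ranking truncated to db.k_backoff, flagged synthetic."""
    _validate_pentamer(pentamer)
    rec = db.records.get(pentamer)
    if rec is not None:
        return rec
    if not db.background:
        raise ValidationError("cannot back off: database has no observations")
    return PentamerRecord(pentamer, db.background[: db.k_backoff], synthetic=True)


# -- persistence ----------------------------------------------------------

def save_db(db: PentamerDB, path: str | Path, format: str | None = None) -> Path:
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "xml")
    if fmt == "xml":
        root = ET.Element("db")
        meta = ET.SubElement(root, "meta", k_backoff=str(db.k_backoff))
        for sid in db.corpus_manifest:
            ET.SubElement(meta, "src", id=sid)
        bg = ET.SubElement(root, "background")
        for code, n in db.background:
            ET.SubElement(bg, "pat", c=code, n=str(n))
        for p, rec in sorted(db.records.items()):
            el = ET.SubElement(root, "rec", p=p)
            for code, n in rec.patterns:
                ET.SubElement(el, "pat", c=code, n=str(n))
        ET.indent(root)
        Path(path).write_bytes(ET.tostring(root, xml_declaration=True, encoding="utf-8"))
    elif fmt == "json":
        payload = {
            "k_backoff": db.k_backoff,
            "corpus_manifest": db.corpus_manifest,
            "background": [[c, n] for c, n in db.background],
            "records": {p: [[c, n] for c, n in rec.patterns]
                        for p, rec in sorted(db.records.items())},
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        raise ValidationError(f"unknown format {fmt!r}")
    return path


def load_db(path: str | Path) -> PentamerDB:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    text = path.read_text()
    if text.lstrip().startswith("{"):
        try:
            payload = json.loads(text)
            records = {
                p: PentamerRecord(p, [(c, int(n)) for c, n in pats])
                for p, pats in payload["records"].items()
            }
            return PentamerDB(
                records=records,
                corpus_manifest=list(payload["corpus_manifest"]),
                background=[(c, int(n)) for c, n in payload["background"]],
                k_backoff=int(payload["k_backoff"]),
            )
        except (KeyError, ValueError, TypeError) as exc:
            raise FormatError(f"malformed JSON database {path}: {exc}") from exc
    try:
        root = ET.fromstring(text)
        if root.tag != "db":
            raise FormatError(f"{path}: root element is not <db>")
        meta = root.find("meta")
        records = {}
        for el in root.findall("rec"):
            p = el.get("p")
            pats = [(pat.get("c"), int(pat.get("n"))) for pat in el.findall("pat")]
            records[p] = PentamerRecord(p, pats)
        return PentamerDB(
            records=records,
            corpus_manifest=[s.get("id") for s in meta.findall("src")],
            background=[(pat.get("c"), int(pat.get("n")))
                        for pat in root.find("background").findall("pat")],
            k_backoff=int(meta.get("k_backoff")),
        )
    except (ET.ParseError, AttributeError, ValueError, TypeError) as exc:
        raise FormatError(f"malformed XML database {path}: {exc}") from exc
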