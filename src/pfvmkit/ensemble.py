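"""Conformation strings drawn from a fold-variation matrix.

The rank-1 code of every column concatenates into the single most
favoured conformation string (named PFVM-01). Each column is treated as
an independent categorical distribution with probabilities proportional
to the observation counts, so a whole string is scored by the sum of
per-column log-probabilities; further members of an ensemble are either
single-column substitutions of PFVM-01 (ranks 2..max_rank) or the exact
top-k strings of the column-product distribution. Because columns are
independent, keeping the k best partial strings while sweeping the
columns left to right yields the exact top-k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .alphabet import PfscString
from .errors import ValidationError
from .pfvm import Pfvm


@dataclass(frozen=True)
class ConformationMember:
    name: str
    string: PfscString
    log_score: float


@dataclass
class ConformationSet:
    members: list[ConformationMember]
    pfvm_id: str = ""

    def __len__(self) -> int:
        return len(self.members)

    def strings(self) -> list[PfscString]:
        return [m.string for m in self.members]


def top_string(m: Pfvm) -> PfscString:
    """PFVM-01: the rank-1 code of every column."""
    return PfscString(
        codes="".join(c.entries[0][0] for c in m.columns),
        source_id="PFVM-01",
        offset=1,
    )


def string_log_score(m: Pfvm, s: PfscString) -> float:
    """Sum over columns of log(count of the chosen code / column total).

    Raises if the string is not column-wise contained in the matrix.
    """
    if len(s.codes) != len(m.columns):
        raise ValidationError(f"string length {len(s.codes)} != {len(m.columns)} columns")
    total = 0.0
    for col, code in zip(m.columns, s.codes):
        counts = dict(col.entries)
        if code not in counts:
            raise ValidationError(
                f"code {code!r} not available in column {col.position} "
                f"(pentamer {col.pentamer})"
            )
        total += math.log(counts[code] / sum(counts.values()))
    return total


def _column_log_probs(m: Pfvm, max_rank: int) -> list[list[tuple[float, str]]]:
    cols = []
    for col in m.columns:
        denom = sum(n for _, n in col.entries)
        cols.append([
            (math.log(n / denom), code) for code, n in col.entries[:max_rank]
        ])
    return cols


def generate_variants(m: Pfvm, k: int = 10, max_rank: int = 3,
                      mode: str = "beam") -> ConformationSet:
    """Build an ensemble of conformation strings.

    single_sub: PFVM-01 plus every string differing from it in exactly
    one column (substituting ranks 2..max_rank), ordered by score.
    beam: the k highest-scoring distinct strings over the rank-capped
    columns; PFVM-01 is always the first member. Deterministic — ties
    are broken by column index, then code.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if max_rank < 1:
        raise ValidationError("max_rank must be >= 1")
    if mode not in ("single_sub", "beam"):
        raise ValidationError(f"unknown mode {mode!r}")

    best = top_string(m)
    best_score = string_log_score(m, best)

    if mode == "single_sub":
        variants: list[tuple[float, int, str, str]] = []
        for ci, col in enumerate(m.columns):
            denom = sum(n for _, n in col.entries)
            base = math.log(col.entries[0][1] / denom)
            for code, n in col.entries[1:max_rank]:
                codes = best.codes[:ci] + code + best.codes[ci + 1:]
                score = best_score - base + math.log(n / denom)
                variants.append((score, ci, code, codes))
        variants.sort(key=lambda v: (-v[0], v[1], v[2]))
        ordered = [(best_score, best.codes)] + [(s, c) for s, _, _, c in variants]
    else:
        cols = _column_log_probs(m, max_rank)
        # exact top-k over the product distribution: sweep columns keeping
        # the k best (score, codes) partials; suffix contributions are
        # identical for every partial, so the best k completions extend
        # the best k partials.
        beam: list[tuple[float, str]] = [(0.0, "")]
        for col in cols:
            ext = [(sc + lp, codes + code) for sc, codes in beam for lp, code in col]
            ext.sort(key=lambda v: (-v[0], v[1]))
            beam = ext[:k]
        ordered = beam
        if ordered[0][1] != best.codes:  # ties may reorder; pin PFVM-01 first
            ordered = [(best_score, best.codes)] + [
                v for v in ordered if v[1] != best.codes][:k - 1]

    ordered = ordered[:k]
    if len(ordered) < k:
        warnings.warn(
            f"requested {k} strings but only {len(ordered)} distinct strings are "
            f"reachable in mode {mode!r} at max_rank={max_rank}; returning all",
            stacklevel=2)
    members = [
        ConformationMember(f"PFVM-{i + 1:02d}",
                           PfscString(codes, source_id=f"PFVM-{i + 1:02d}"), score)
        for i, (score, codes) in enumerate(ordered)
    ]
    return ConformationSet(members=members, pfvm_id=f"pfvm:{len(m.columns)}cols")


def write_pfsc(conformations: ConformationSet, path) -> None:
    """Multi-record .pfsc text file: '>name score' header + string."""
    lines = []
    for mem in conformations.members:
        lines.append(f">{mem.name} log_score={mem.log_score:.6f}")
        lines.append(mem.string.codes)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_pfsc(path) -> ConformationSet:
    members = []
    name, score, codes = None, 0.0, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    members.append(ConformationMember(
                        name, PfscString("".join(codes), source_id=name), score))
                fields = line[1:].split()
                name = fields[0]
                score = 0.0
                for f in fields[1:]:
                    if f.startswith("log_score="):
                        score = float(f.split("=", 1)[1])
                codes = []
            elif line.strip():
                codes.append(line.strip())
    if name is not None:
        members.append(ConformationMember(
            name, PfscString("".join(codes), source_id=name), score))
    if not members:
        raise ValidationError(f"no records in {path}")
    return ConformationSet(members=members)
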