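"""Protein folding structural alignment (PFSA) of fold-code strings.

Two conformation strings are compared symbol by symbol. A pair of
aligned symbols is weighted by how similar the local folds they name
are: identical symbol 1.0; different symbols of the same fold class
0.8; a typical fold against its "alike" neighbour class (helix vs
alike-helix, strand vs alike-strand) 0.5; anything else, including the
undefined symbol against any different symbol, 0.0 (two identical
symbols always weigh 1.0, so the identity endpoint is exact). The normalized score is the mean
weight over the alignment length, so it lives in [0, 1]: 1.00 means an
identical conformation, and scores above 0.70 are treated downstream as
accepted conformational homologs.

Equal-length strings are compared position by position. Strings of
unequal length are globally aligned (affine gap penalties, Gotoh
recursion) to maximize the summed weights; gapped positions contribute
weight 0 and the score is normalized by the longer length, which keeps
the 0.70 acceptance threshold meaningful for partial matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import (
    CLASS_ALIKE_HELIX,
    CLASS_ALIKE_STRAND,
    CLASS_HELIX,
    CLASS_STRAND,
    CLASS_UNDEFINED,
    PfscAlphabet,
    PfscString,
)
from .errors import ValidationError

_ALIKE_PAIRS = {
    frozenset((CLASS_HELIX, CLASS_ALIKE_HELIX)),
    frozenset((CLASS_STRAND, CLASS_ALIKE_STRAND)),
}


@dataclass
class SimilarityModel:
    """Class-level weights and gap penalties of the alignment score."""

    w_identical: float = 1.0
    w_same_class: float = 0.8
    w_alike_class: float = 0.5
    gap_open: float = -0.5
    gap_extend: float = -0.1
    alphabet: PfscAlphabet = field(default_factory=PfscAlphabet)

    def weight(self, a: str, b: str) -> float:
        # identical symbols always weigh 1.0 — the identity endpoint of
        # the score must be exact even for strings holding '$' windows;
        # '$' against any different symbol carries no fold information.
        if a == b:
            self.alphabet.classify(a)  # still reject unknown symbols
            return self.w_identical
        ca = self.alphabet.classify(a)
        cb = self.alphabet.classify(b)
        if CLASS_UNDEFINED in (ca, cb):
            return 0.0
        if ca == cb:
            return self.w_same_class
        if frozenset((ca, cb)) in _ALIKE_PAIRS:
            return self.w_alike_class
        return 0.0


@dataclass
class AlignmentResult:
    score: float
    aligned_pairs: list[tuple[int | None, int | None]]  # 0-based; None = gap
    per_position_weight: list[float]


def _positionwise(a: str, b: str, model: SimilarityModel) -> AlignmentResult:
    weights = [model.weight(x, y) for x, y in zip(a, b)]
    return AlignmentResult(
        score=float(np.mean(weights)),
        aligned_pairs=[(i, i) for i in range(len(a))],
        per_position_weight=weights,
    )


def _global_affine(a: str, b: str, model: SimilarityModel) -> AlignmentResult:
    n, m = len(a), len(b)
    w = np.array([[model.weight(x, y) for y in b] for x in a])
    neg = -np.inf
    go, ge = model.gap_open, model.gap_extend
    M = np.full((n + 1, m + 1), neg)  # a[i-1] aligned to b[j-1]
    X = np.full((n + 1, m + 1), neg)  # gap in b (a residue unmatched)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = go + ge * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i, j] = w[i - 1, j - 1] + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge)
            Y[i, j] = max(M[i, j - 1] + go, Y[i, j - 1] + ge)
    # traceback
    pairs: list[tuple[int | None, int | None]] = []
    weights: list[float] = []
    i, j = n, m
    state = int(np.argmax([M[n, m], X[n, m], Y[n, m]]))
    while i > 0 or j > 0:
        if state == 0 and i > 0 and j > 0:
            pairs.append((i - 1, j - 1))
            weights.append(float(w[i - 1, j - 1]))
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1 and i > 0:
            pairs.append((i - 1, None))
            weights.append(0.0)
            state = 0 if np.isclose(X[i, j], M[i - 1, j] + go) else 1
            i -= 1
        elif state == 2 and j > 0:
            pairs.append((None, j - 1))
            weights.append(0.0)
            state = 0 if np.isclose(Y[i, j], M[i, j - 1] + go) else 2
            j -= 1
        else:  # exhausted one string
            state = 1 if i > 0 else 2
    pairs.reverse()
    weights.reverse()
    matched = sum(wt for wt in weights)
    score = float(np.clip(matched / max(n, m), 0.0, 1.0))
    return AlignmentResult(score=score, aligned_pairs=pairs, per_position_weight=weights)


def pfsa_score(a: PfscString | str, b: PfscString | str,
               model: SimilarityModel | None = None) -> AlignmentResult:
    """Normalized fold-alignment score of two conformation strings."""
    model = model or SimilarityModel()
    sa = a.codes if isinstance(a, PfscString) else a
    sb = b.codes if isinstance(b, PfscString) else b
    if not sa or not sb:
        raise ValidationError("cannot align an empty conformation string")
    if len(sa) == len(sb):
        return _positionwise(sa, sb, model)
    return _global_affine(sa, sb, model)


def pairwise_matrix(strings: list[PfscString], model: SimilarityModel | None = None) -> np.ndarray:
    """Symmetric matrix of alignment scores with a unit diagonal."""
    if len(strings) < 2:
        raise ValidationError("need at least two strings")
    model = model or SimilarityModel()
    n = len(strings)
    mat = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = pfsa_score(strings[i], strings[j], model).score
            mat[i, j] = mat[j, i] = s
    return mat


def matrix_to_tsv(strings: list[PfscString], mat: np.ndarray) -> str:
    names = [s.source_id or f"s{i}" for i, s in enumerate(strings)]
    lines = ["\t" + "\t".join(names)]
    for name, row in zip(names, mat):
        lines.append(name + "\t" + "\t".join(f"{v:.4f}" for v in row))
    return "\n".join(lines) + "\n"


def alignment_view(a: PfscString, b: PfscString, result: AlignmentResult,
                   model: SimilarityModel | None = None) -> str:
    """Three-line text view: string a, match markers, string b.

    '|' identical, ':' same class, '.' alike classes, ' ' otherwise.
    """
    model = model or SimilarityModel()
    la, lb, marks = [], [], []
    for i, j in result.aligned_pairs:
        x = a.codes[i] if i is not None else "-"
        y = b.codes[j] if j is not None else "-"
        la.append(x)
        lb.append(y)
        if i is None or j is None:
            marks.append(" ")
        else:
            wt = model.weight(x, y)
            marks.append("|" if wt == model.w_identical and x == y
                         else ":" if wt == model.w_same_class
                         else "." if wt == model.w_alike_class
                         else " ")
    return "\n".join(("".join(la), "".join(marks), "".join(lb))) + "\n"
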