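"""Cα trace -> fold-code string.

A five-residue window starting at chain ordinal i (1-based) is reduced
to three internal descriptors — pseudo-torsions tau1 = Cα(i..i+3) and
tau2 = Cα(i+1..i+4), and the bend angle theta at Cα(i+2) spanned by
Cα(i), Cα(i+2), Cα(i+4) — and quantized by the alphabet into one
symbol. Sliding the window one residue at a time over a chain of N
residues yields a string of N - 4 symbols. Windows touching a missing
Cα or an internal chain break encode as the undefined symbol '$'.
Descriptors are internal coordinates, so the encoding is invariant
under rigid motion of the chain.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._geometry import bend_angle, dihedral
from .alphabet import PfscAlphabet, PfscString
from .errors import ValidationError
from .structures_io import CaTrace

WINDOW = 5


@dataclass(frozen=True)
class WindowDescriptor:
    tau1: float
    tau2: float
    theta: float


def compute_window_descriptors(trace: CaTrace, i: int) -> WindowDescriptor | None:
    """Descriptors of the window at 1-based start ordinal i, or None when
    the window is undefined (missing Cα or internal chain break)."""
    n = len(trace)
    if not (1 <= i <= n - WINDOW + 1):
        raise IndexError(f"window start {i} out of range 1..{n - WINDOW + 1}")
    block = trace.residues[i - 1:i + WINDOW - 1]
    if any(not r.has_ca for r in block):
        return None
    flags = trace.break_flags()
    if any(flags[j] for j in range(i - 1, i + WINDOW - 2)):
        return None
    ca = [r.ca_xyz for r in block]
    return WindowDescriptor(
        tau1=dihedral(ca[0], ca[1], ca[2], ca[3]),
        tau2=dihedral(ca[1], ca[2], ca[3], ca[4]),
        theta=bend_angle(ca[0], ca[2], ca[4]),
    )


def encode_chain(trace: CaTrace, alphabet: PfscAlphabet | None = None) -> PfscString:
    """Encode a chain of N >= 5 residues into its N - 4 symbol string."""
    alphabet = alphabet or PfscAlphabet()
    n = len(trace)
    if n < WINDOW:
        raise ValidationError(f"chain {trace.source_id!r} has {n} residues; need >= {WINDOW}")
    flags = trace.break_flags()  # computed once; windows only index into it
    res = trace.residues
    out = []
    for i in range(1, n - WINDOW + 2):
        block = res[i - 1:i + WINDOW - 1]
        if any(not r.has_ca for r in block) or any(flags[i - 1:i + WINDOW - 2]):
            out.append(alphabet.undefined_code)
            continue
        ca = [r.ca_xyz for r in block]
        out.append(alphabet.code_for_descriptors(
            dihedral(ca[0], ca[1], ca[2], ca[3]),
            dihedral(ca[1], ca[2], ca[3], ca[4]),
            bend_angle(ca[0], ca[2], ca[4]),
        ))
    return PfscString(codes="".join(out), source_id=trace.source_id, offset=1)


def classify_code(code: str, alphabet: PfscAlphabet | None = None) -> str:
    """Class label (helix / alike-helix / strand / alike-strand /
    irregular / undefined) of one symbol."""
    return (alphabet or PfscAlphabet()).classify(code)
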