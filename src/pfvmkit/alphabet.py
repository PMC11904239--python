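"""The 27-symbol protein folding shape code (PFSC) alphabet.

Each symbol names the local fold of five consecutive residues. The local
fold is summarised by three Cα-geometry descriptors — two consecutive
pseudo-torsions (tau1 over residues i..i+3, tau2 over i+1..i+4) and the
bend angle theta at the centre residue over Cα(i), Cα(i+2), Cα(i+4) —
and each descriptor is quantized into three bins. The 3 x 3 x 3 = 27
cells of that cube are mapped bijectively onto 26 letters plus '$':

* the cell holding the canonical alpha-helix geometry is 'A';
* the cell holding the canonical beta-strand geometry is 'B';
* the degenerate cell (near-zero torsions with a near-straight bend,
  where collinear windows land) is merged with the undefined symbol '$',
  which is also emitted for windows with missing atoms or chain breaks;
* the remaining 24 cells are 'C'..'Z' in lexicographic cell order.

Symbols are grouped into six classes: helix, alike-helix (cells one bin
step away from the helix cell), strand, alike-strand, irregular
(everything else), and undefined ('$'). The class of a symbol drives
both report styling and alignment weights.

Bin boundaries are configuration, not constants. Pseudo-torsions are
periodic, so tau bins are defined by three cyclic cut points; the
defaults keep the canonical helix (tau ~ +51.5 deg) and strand
(tau ~ +178.7 deg) geometries far from every cut so that small angular
jitter does not change the encoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ValidationError

CLASS_HELIX = "helix"
CLASS_ALIKE_HELIX = "alike-helix"
CLASS_STRAND = "strand"
CLASS_ALIKE_STRAND = "alike-strand"
CLASS_IRREGULAR = "irregular"
CLASS_UNDEFINED = "undefined"

CLASSES = (
    CLASS_HELIX,
    CLASS_ALIKE_HELIX,
    CLASS_STRAND,
    CLASS_ALIKE_STRAND,
    CLASS_IRREGULAR,
    CLASS_UNDEFINED,
)

UNDEFINED_CODE = "$"


@dataclass(frozen=True)
class QuantizerConfig:
    """Bin boundaries of the descriptor quantizer.

    tau_cuts are three cyclic cut points (degrees) on the torsion circle;
    bin b spans (tau_cuts[b], tau_cuts[(b+1) % 3]] going counter-clockwise.
    theta_cuts are two interior edges splitting [0, 180] into three bins.
    """

    tau_cuts: tuple[float, float, float] = (-130.0, -10.0, 110.0)
    theta_cuts: tuple[float, float] = (40.0, 140.0)

    def tau_bin(self, tau: float) -> int:
        lo = self.tau_cuts[0]
        t = (tau - lo) % 360.0 + lo  # wrap into (lo, lo + 360]
        if t <= self.tau_cuts[1]:
            return 0
        if t <= self.tau_cuts[2]:
            return 1
        return 2

    def theta_bin(self, theta: float) -> int:
        if theta < self.theta_cuts[0]:
            return 0
        if theta < self.theta_cuts[1]:
            return 1
        return 2

    def cell(self, tau1: float, tau2: float, theta: float) -> tuple[int, int, int]:
        return (self.tau_bin(tau1), self.tau_bin(tau2), self.theta_bin(theta))


# Canonical descriptor triples measured once on the noise-free ideal
# fixtures (helix phi/psi = -57/-47, strand -139/+135) and frozen.
HELIX_DESCRIPTORS = (51.51, 51.51, 71.67)
STRAND_DESCRIPTORS = (178.71, 178.71, 179.99)
# Collinear windows: torsions default to 0, bend angle is 180.
DEGENERATE_DESCRIPTORS = (0.0, 0.0, 180.0)


class PfscAlphabet:
    """The 27-code fold alphabet induced by a :class:`QuantizerConfig`."""

    def __init__(self, config: QuantizerConfig | None = None):
        self.config = config or QuantizerConfig()
        helix_cell = self.config.cell(*HELIX_DESCRIPTORS)
        strand_cell = self.config.cell(*STRAND_DESCRIPTORS)
        degenerate_cell = self.config.cell(*DEGENERATE_DESCRIPTORS)
        cells = {helix_cell, strand_cell, degenerate_cell}
        if len(cells) != 3:
            raise ValidationError(
                "quantizer config does not separate helix, strand and the "
                f"degenerate cell: {helix_cell}, {strand_cell}, {degenerate_cell}"
            )
        self.helix_cell = helix_cell
        self.strand_cell = strand_cell
        self.degenerate_cell = degenerate_cell

        code_of: dict[tuple[int, int, int], str] = {
            helix_cell: "A",
            strand_cell: "B",
            degenerate_cell: UNDEFINED_CODE,
        }
        letters = iter("CDEFGHIJKLMNOPQRSTUVWXYZ")
        for cell in self._all_cells():
            if cell not in code_of:
                code_of[cell] = next(letters)
        self.code_of_cell = code_of
        self.cell_of_code = {c: cell for cell, c in code_of.items()}
        self._class_of = {code: self._derive_class(cell) for cell, code in code_of.items()}

    @staticmethod
    def _all_cells():
        for a in range(3):
            for b in range(3):
                for c in range(3):
                    yield (a, b, c)

    def _derive_class(self, cell: tuple[int, int, int]) -> str:
        if cell == self.degenerate_cell:
            return CLASS_UNDEFINED
        if cell == self.helix_cell:
            return CLASS_HELIX
        if cell == self.strand_cell:
            return CLASS_STRAND
        d_helix = sum(x != y for x, y in zip(cell, self.helix_cell))
        d_strand = sum(x != y for x, y in zip(cell, self.strand_cell))
        if d_helix == 1:
            return CLASS_ALIKE_HELIX
        if d_strand == 1:
            return CLASS_ALIKE_STRAND
        return CLASS_IRREGULAR

    # -- public surface ---------------------------------------------------

    @property
    def codes(self) -> str:
        """All 27 symbols, 'A'..'Z' then '$'."""
        letters = sorted(c for c in self._class_of if c != UNDEFINED_CODE)
        return "".join(letters) + UNDEFINED_CODE

    @property
    def helix_code(self) -> str:
        return self.code_of_cell[self.helix_cell]

    @property
    def strand_code(self) -> str:
        return self.code_of_cell[self.strand_cell]

    @property
    def undefined_code(self) -> str:
        return UNDEFINED_CODE

    def classify(self, code: str) -> str:
        """Return the class label of one symbol."""
        try:
            return self._class_of[code]
        except KeyError:
            raise ValidationError(f"unknown PFSC symbol: {code!r}") from None

    def code_for_descriptors(self, tau1: float, tau2: float, theta: float) -> str:
        return self.code_of_cell[self.config.cell(tau1, tau2, theta)]

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "tau_cuts": list(self.config.tau_cuts),
            "theta_cuts": list(self.config.theta_cuts),
        }
        path.write_text(json.dumps(payload, indent=1) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PfscAlphabet":
        payload = json.loads(Path(path).read_text())
        cfg = QuantizerConfig(
            tau_cuts=tuple(payload["tau_cuts"]),
            theta_cuts=tuple(payload["theta_cuts"]),
        )
        return cls(cfg)


@dataclass(frozen=True)
class PfscString:
    """A fold-code string for one conformation.

    offset is the 1-based chain ordinal of the first window's first
    residue (1 for strings covering a whole chain).
    """

    codes: str
    source_id: str = ""
    offset: int = 1

    def __len__(self) -> int:
        return len(self.codes)

    def __str__(self) -> str:
        return self.codes
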