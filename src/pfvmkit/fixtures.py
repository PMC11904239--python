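"""Synthetic backbones with known geometry.

Chains are grown from canonical (phi, psi) torsions — helix -57/-47,
strand -139/+135, coil drawn uniformly from a broad allowed region —
with ideal bond geometry and trans peptides, then reduced to the Cα
trace (virtual Cα-Cα bond ~3.8 Å). Gaussian jitter on the torsions
emulates thermal/experimental noise. A small library of mixed-segment
chains written as PDB files stands in for a structure corpus so that
database building, searching and assembly are all testable offline.
Drawing chain sequences from a reduced ``seq_alphabet`` makes pentamer
sequences recur across chains in different conformations, which is what
gives fold-variation columns depth > 1 at desk scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import build_backbone
from .errors import ValidationError
from .structures_io import AA20, ONE_TO_THREE, CaTrace, ResidueRecord, write_ca_model

CANONICAL_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
}
# Broad allowed region sampled uniformly for coil residues.
COIL_PHI_RANGE = (-160.0, -45.0)
COIL_PSI_RANGE = (-80.0, 170.0)

SEGMENT_KINDS = ("helix", "strand", "coil")


@dataclass(frozen=True)
class BackboneSpec:
    """Recipe for one synthetic chain."""

    segments: tuple[tuple[str, int], ...]
    sequence: str | None = None  # None: drawn from seq_alphabet with `seed`
    noise_deg: float = 0.0
    seed: int = 0
    seq_alphabet: str = AA20

    def __post_init__(self):
        for kind, length in self.segments:
            if kind not in SEGMENT_KINDS:
                raise ValidationError(f"unknown segment kind {kind!r}")
            if length < 1:
                raise ValidationError("segment length must be >= 1")
        if self.noise_deg < 0:
            raise ValidationError("noise_deg must be >= 0")
        if self.sequence is not None and len(self.sequence) != self.total_length:
            raise ValidationError("sequence length must match total segment length")

    @property
    def total_length(self) -> int:
        return sum(n for _, n in self.segments)


def make_ideal_backbone(spec: BackboneSpec) -> CaTrace:
    """Build the Cα trace for a :class:`BackboneSpec` (deterministic for a
    fixed seed)."""
    n = spec.total_length
    if n < 5:
        raise ValidationError("need at least 5 residues for an encodable chain")
    rng = np.random.default_rng(spec.seed)
    phi_psi = []
    for kind, length in spec.segments:
        for _ in range(length):
            if kind == "coil":
                phi = rng.uniform(*COIL_PHI_RANGE)
                psi = rng.uniform(*COIL_PSI_RANGE)
            else:
                phi, psi = CANONICAL_PHI_PSI[kind]
            phi_psi.append((phi, psi))
    if spec.noise_deg > 0:
        phi_psi = [
            (phi + rng.normal(0.0, spec.noise_deg), psi + rng.normal(0.0, spec.noise_deg))
            for phi, psi in phi_psi
        ]
    ca = build_backbone(phi_psi)[:, 1]
    if spec.sequence is not None:
        seq = spec.sequence
    else:
        seq = "".join(rng.choice(list(spec.seq_alphabet), size=n))
    kinds = "".join(k[0] * ln for k, ln in spec.segments)
    residues = [
        ResidueRecord("A", i + 1, ONE_TO_THREE.get(seq[i], "UNK"), seq[i], ca[i].copy())
        for i in range(n)
    ]
    return CaTrace("A", residues, source_id=f"fixture-{kinds}-s{spec.seed}")


def random_spec(rng: np.random.Generator, min_len: int = 30, max_len: int = 120,
                noise_deg: float = 2.0, seq_alphabet: str = AA20) -> BackboneSpec:
    """Draw a mixed-segment spec: 2-5 segments, total length in
    [min_len, max_len], mild torsional jitter."""
    n_seg = int(rng.integers(2, 6))
    kinds = [SEGMENT_KINDS[int(rng.integers(0, 3))] for _ in range(n_seg)]
    total = int(rng.integers(min_len, max_len + 1))
    cuts = np.sort(rng.choice(np.arange(1, total), size=n_seg - 1, replace=False))
    lengths = np.diff(np.concatenate(([0], cuts, [total])))
    segments = tuple(
        (k, int(ln)) for k, ln in zip(kinds, lengths) if ln > 0
    )
    return BackboneSpec(segments=segments, noise_deg=noise_deg,
                        seed=int(rng.integers(0, 2**31 - 1)), seq_alphabet=seq_alphabet)


def make_fixture_library(n_chains: int, seed: int, out_dir: str | Path,
                         seq_alphabet: str = AA20) -> list[Path]:
    """Write n_chains mixed-segment PDB files plus a manifest.json into
    out_dir; byte-identical output for a fixed seed."""
    if n_chains < 1:
        raise ValidationError("n_chains must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    paths = []
    manifest = {"seed": seed, "n_chains": n_chains, "entries": []}
    for k in range(n_chains):
        spec = random_spec(rng, seq_alphabet=seq_alphabet)
        trace = make_ideal_backbone(spec)
        name = f"fix{k:03d}.pdb"
        path = write_ca_model(trace, out_dir / name)
        paths.append(path)
        manifest["entries"].append({
            "file": name,
            "length": len(trace),
            "segments": [[kind, ln] for kind, ln in spec.segments],
            "spec_seed": spec.seed,
            "noise_deg": spec.noise_deg,
        })
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return paths
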