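"""Conformation-homology search and Cα-trace assembly.

A structure library holds every chain of a corpus together with its
fold-code string, indexed by code k-grams for fast candidate lookup. A
query conformation string is cut into fragments of about 40-50 residues
(long strings rarely find a whole-length homolog above the acceptance
threshold); each fragment retrieves same-length source windows whose
alignment score exceeds the threshold, and the winning fragments are
spliced into a single Cα trace by rigid least-squares superposition
over the shared overlap residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._geometry import superpose
from .alphabet import PfscAlphabet, PfscString
from .align import SimilarityModel, pfsa_score
from .encoder import WINDOW, encode_chain
from .ensemble import ConformationSet
from .errors import AssemblyError, FormatError, PipelineError, ValidationError
from .structures_io import CaTrace, ResidueRecord, read_structure, ONE_TO_THREE

log = logging.getLogger(__name__)

DEFAULT_KGRAM = 8
DEFAULT_THRESHOLD = 0.70
DEFAULT_TARGET_LEN = 45
DEFAULT_OVERLAP = 4
# when a span finds nothing above the threshold, retry down this ladder
RELAX_LADDER = (0.60, 0.50)


@dataclass
class LibraryEntry:
    source_id: str
    string: PfscString
    trace: CaTrace


@dataclass
class StructureLibrary:
    entries: list[LibraryEntry]
    kgram: int = DEFAULT_KGRAM
    index: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def build_index(self) -> None:
        self.index = {}
        for e_idx, entry in enumerate(self.entries):
            s = entry.string.codes
            for pos in range(len(s) - self.kgram + 1):
                self.index.setdefault(s[pos:pos + self.kgram], []).append((e_idx, pos))


def index_library(corpus: list[str | Path], alphabet: PfscAlphabet | None = None,
                  kgram: int = DEFAULT_KGRAM) -> StructureLibrary:
    """Encode and k-gram-index every chain of every corpus file."""
    if not corpus:
        raise ValidationError("corpus must not be empty")
    alphabet = alphabet or PfscAlphabet()
    entries = []
    for path in sorted(Path(p) for p in corpus):
        try:
            traces = read_structure(path)
        except (FormatError, IndexError) as exc:
            log.warning("skipping %s: %s", path, exc)
            continue
        for trace in traces:
            if len(trace) < WINDOW:
                continue
            entries.append(LibraryEntry(trace.source_id, encode_chain(trace, alphabet), trace))
    if not entries:
        raise ValidationError("no encodable chains in corpus")
    entries.sort(key=lambda e: e.source_id)
    lib = StructureLibrary(entries=entries, kgram=kgram)
    lib.build_index()
    return lib


def split_into_fragments(s: PfscString, target_len: int = DEFAULT_TARGET_LEN,
                         overlap: int = DEFAULT_OVERLAP) -> list[tuple[int, int]]:
    """Residue spans (1-based, inclusive) covering the chain behind a
    whole-chain string: consecutive spans of target_len stepping by
    target_len - overlap, the last span right-aligned onto the tail."""
    if overlap < 4:
        raise ValidationError("overlap must be >= 4 residues")
    if target_len <= overlap:
        raise ValidationError("target_len must exceed overlap")
    n_res = len(s.codes) + WINDOW - 1
    if n_res <= target_len:
        return [(1, n_res)]
    step = target_len - overlap
    spans = []
    start = 1
    while start + target_len - 1 < n_res:
        spans.append((start, start + target_len - 1))
        start += step
    last = (n_res - target_len + 1, n_res)
    if last != spans[-1]:
        spans.append(last)
    return spans


@dataclass
class FragmentHit:
    query_span: tuple[int, int]
    source_id: str
    source_span: tuple[int, int]
    score: float
    trace_fragment: CaTrace


def _span_substring(s: PfscString, span: tuple[int, int]) -> str:
    start, end = span
    lo = start - s.offset
    hi = end - WINDOW + 1 - s.offset + 1
    if lo < 0 or hi > len(s.codes) or end - start + 1 < WINDOW:
        raise ValidationError(f"span {span} not covered by string of {len(s.codes)} windows")
    return s.codes[lo:hi]


def search_fragments(lib: StructureLibrary, s: PfscString, span: tuple[int, int],
                     model: SimilarityModel | None = None,
                     threshold: float = DEFAULT_THRESHOLD) -> list[FragmentHit]:
    """Source windows conformation-homologous to one query span.

    Candidates are seeded through the k-gram index (every k-gram of the
    query fragment votes for the source windows it occurs in) and each
    candidate window is scored with the positionwise alignment; windows
    scoring strictly above the threshold are returned ranked by score,
    then source id, then position.
    """
    if not (0.0 < threshold <= 1.0):
        if threshold > 1.0:  # unreachable threshold is allowed; nothing can pass
            return []
        raise ValidationError("threshold must be in (0, 1]")
    model = model or SimilarityModel()
    q = _span_substring(s, span)
    nq = len(q)
    candidates: set[tuple[int, int]] = set()
    if nq < lib.kgram:
        for e_idx, entry in enumerate(lib.entries):
            for pos in range(len(entry.string.codes) - nq + 1):
                candidates.add((e_idx, pos))
    else:
        for qpos in range(nq - lib.kgram + 1):
            for e_idx, pos in lib.index.get(q[qpos:qpos + lib.kgram], ()):
                start = pos - qpos
                if 0 <= start <= len(lib.entries[e_idx].string.codes) - nq:
                    candidates.add((e_idx, start))
    hits = []
    for e_idx, pos in candidates:
        entry = lib.entries[e_idx]
        window = entry.string.codes[pos:pos + nq]
        score = pfsa_score(q, window, model).score
        if score > threshold:
            res_start = pos + 1
            res_end = pos + nq + WINDOW - 1
            hits.append(FragmentHit(
                query_span=span,
                source_id=entry.source_id,
                source_span=(res_start, res_end),
                score=score,
                trace_fragment=entry.trace.slice(res_start, res_end),
            ))
    hits.sort(key=lambda h: (-h.score, h.source_id, h.source_span))
    return hits


@dataclass
class AssembledModel:
    trace: CaTrace
    junction_rmsds: list[float]


def assemble_model(hits_per_span: list[FragmentHit], overlap: int = DEFAULT_OVERLAP) -> AssembledModel:
    """Splice one fragment per span into a single trace.

    Fragments are chained left to right; each incoming fragment is
    rigidly superposed onto the growing model over the residues the two
    spans share, then its new residues are appended. The least-squares
    residual of every junction is reported, not enforced.
    """
    if not hits_per_span:
        raise ValidationError("no fragments to assemble")
    hits = sorted(hits_per_span, key=lambda h: h.query_span)
    first = hits[0]
    coords = [c.copy() for c in first.trace_fragment.coords()]
    residues = list(first.trace_fragment.residues)
    model_start = first.query_span[0]
    model_end = first.query_span[1]
    rmsds: list[float] = []
    for hit in hits[1:]:
        q0, q1 = hit.query_span
        shared = model_end - q0 + 1
        if shared < 3:
            raise AssemblyError(
                f"spans ...{model_end} and {q0}.. share {max(shared, 0)} residues; "
                "rigid superposition needs >= 3")
        frag = hit.trace_fragment.coords()
        target = np.array(coords[q0 - model_start:model_end - model_start + 1])
        mobile = frag[:shared]
        if np.isnan(target).any() or np.isnan(mobile).any():
            raise AssemblyError("missing Cα inside an overlap region")
        r, t, rmsd = superpose(mobile, target)
        rmsds.append(rmsd)
        moved = frag @ r.T + t
        for k in range(shared, len(moved)):
            coords.append(moved[k])
            residues.append(hit.trace_fragment.residues[k])
        model_end = q1
    out = [
        ResidueRecord("A", i + 1, r.resname, r.aa1, np.asarray(c))
        for i, (r, c) in enumerate(zip(residues, coords))
    ]
    return AssembledModel(CaTrace("A", out, source_id="assembled"), rmsds)


@dataclass
class BuildParams:
    target_len: int = DEFAULT_TARGET_LEN
    overlap: int = DEFAULT_OVERLAP
    threshold: float = DEFAULT_THRESHOLD
    relax_ladder: tuple[float, ...] = RELAX_LADDER
    sequence: str | None = None  # residue identities stamped onto models


@dataclass
class BuiltModel:
    name: str
    trace: CaTrace
    fragments: list[FragmentHit]
    junction_rmsds: list[float]


def build_ensemble(lib: StructureLibrary, conformations: ConformationSet,
                   params: BuildParams | None = None,
                   model: SimilarityModel | None = None) -> list[BuiltModel]:
    """Build one Cα-trace model per conformation string.

    Each string is split into spans; every span takes the top-ranked
    hit above the acceptance threshold (relaxing down the configured
    ladder when a span retrieves nothing); the chosen fragments are
    spliced. Members whose spans stay empty at the floor are dropped
    with a logged reason; if every member fails, a pipeline error
    carrying the diagnostics is raised.
    """
    params = params or BuildParams()
    model = model or SimilarityModel()
    built = []
    failures = []
    for member in conformations.members:
        spans = split_into_fragments(member.string, params.target_len, params.overlap)
        chosen = []
        failed = None
        for span in spans:
            hit = None
            for thr in (params.threshold, *params.relax_ladder):
                found = search_fragments(lib, member.string, span, model, thr)
                if found:
                    hit = found[0]
                    break
            if hit is None:
                failed = f"span {span}: no hit at or above floor {params.relax_ladder[-1]}"
                break
            chosen.append(hit)
        if failed:
            log.warning("member %s dropped: %s", member.name, failed)
            failures.append((member.name, failed))
            continue
        assembled = assemble_model(chosen, params.overlap)
        trace = assembled.trace
        if params.sequence is not None:
            if len(params.sequence) != len(trace):
                raise ValidationError("sequence length does not match model length")
            for r, aa in zip(trace.residues, params.sequence):
                r.aa1 = aa
                r.resname = ONE_TO_THREE.get(aa, "UNK")
        built.append(BuiltModel(member.name, trace, chosen, assembled.junction_rmsds))
    if not built:
        raise PipelineError(f"every ensemble member failed: {failures}")
    return built


def validate_ensemble(strings: list[PfscString], given: PfscString,
                      model: SimilarityModel | None = None) -> tuple[float, int]:
    """Best alignment score of any ensemble member against a given
    conformation, and the index of the member attaining it."""
    if not strings:
        raise ValidationError("ensemble must not be empty")
    model = model or SimilarityModel()
    scores = [pfsa_score(s, given, model).score for s in strings]
    best = int(np.argmax(scores))
    return scores[best], best


def provenance_tsv(models: list[BuiltModel]) -> str:
    lines = ["member\tquery_span\tsource_id\tsource_span\tscore\tjunction_rmsd"]
    for bm in models:
        for i, hit in enumerate(bm.fragments):
            rmsd = f"{bm.junction_rmsds[i - 1]:.4f}" if i >= 1 else ""
            lines.append(
                f"{bm.name}\t{hit.query_span[0]}-{hit.query_span[1]}\t{hit.source_id}"
                f"\t{hit.source_span[0]}-{hit.source_span[1]}\t{hit.score:.4f}\t{rmsd}")
    return "\n".join(lines) + "\n"
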