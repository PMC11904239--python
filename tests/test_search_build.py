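import numpy as np
import pytest

from pfvmkit import (
    AssemblyError,
    BuildParams,
    PfscString,
    SimilarityModel,
    ValidationError,
    assemble_model,
    build_ensemble,
    encode_chain,
    index_library,
    pfsa_score,
    read_structure,
    search_fragments,
    split_into_fragments,
    validate_ensemble,
)
from pfvmkit._geometry import superpose
from pfvmkit.ensemble import ConformationMember, ConformationSet


@pytest.fixture(scope="module")
def model(alphabet):
    return SimilarityModel(alphabet=alphabet)


class TestIndexLibrary:
    def test_one_entry_per_chain_with_window_law_lengths(self, corpus_library, corpus_paths):
        assert len(corpus_library.entries) == len(corpus_paths)
        for entry in corpus_library.entries:
            assert len(entry.string.codes) == len(entry.trace) - 4

    def test_indexing_is_insensitive_to_file_order(self, corpus_paths, corpus_library, alphabet):
        shuffled = list(reversed(corpus_paths))
        lib = index_library(shuffled, alphabet)
        assert [e.source_id for e in lib.entries] == [
            e.source_id for e in corpus_library.entries]
        assert lib.index == corpus_library.index

    def test_empty_corpus_is_rejected(self, alphabet):
        with pytest.raises(ValidationError):
            index_library([], alphabet)


class TestSplitIntoFragments:
    def test_189_residues_at_45_4_give_5_covering_spans(self):
        s = PfscString("A" * 185)  # 189 residues
        spans = split_into_fragments(s, target_len=45, overlap=4)
        assert len(spans) == 5
        assert spans[0] == (1, 45) and spans[-1] == (145, 189)

    def test_short_query_is_a_single_full_span(self):
        spans = split_into_fragments(PfscString("A" * 26), target_len=45, overlap=4)
        assert spans == [(1, 30)]

    @pytest.mark.parametrize("n_res", [46, 50, 83, 100, 137, 200])
    def test_spans_cover_everything_with_enough_overlap(self, n_res):
        spans = split_into_fragments(PfscString("A" * (n_res - 4)), 45, 4)
        covered = set()
        for start, end in spans:
            covered.update(range(start, end + 1))
        assert covered == set(range(1, n_res + 1))
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert a1 - b0 + 1 >= 4

    def test_invalid_geometry_parameters(self):
        s = PfscString("A" * 50)
        with pytest.raises(ValidationError):
            split_into_fragments(s, target_len=45, overlap=3)
        with pytest.raises(ValidationError):
            split_into_fragments(s, target_len=4, overlap=4)


class TestSearchFragments:
    def test_verbatim_query_retrieves_its_source_with_score_one(
            self, corpus_library, alphabet, model):
        entry = corpus_library.entries[0]
        enc = entry.string
        span = (1, min(45, len(entry.trace)))
        hits = search_fragments(corpus_library, enc, span, model)
        assert hits[0].source_id == entry.source_id
        assert hits[0].score == 1.0
        assert hits[0].source_span == span

    def test_unreachable_threshold_gives_no_hits(self, corpus_library, model):
        entry = corpus_library.entries[0]
        span = (1, min(45, len(entry.trace)))
        assert search_fragments(corpus_library, entry.string, span, model,
                                threshold=1.01) == []

    def test_hits_match_an_exhaustive_window_scan(self, corpus_library, model):
        entry = corpus_library.entries[3]
        span = (1, min(40, len(entry.trace)))
        got = search_fragments(corpus_library, entry.string, span, model, threshold=0.70)
        q = entry.string.codes[: span[1] - 4]
        expect = []
        for e in corpus_library.entries:
            s = e.string.codes
            for pos in range(len(s) - len(q) + 1):
                score = pfsa_score(q, s[pos:pos + len(q)], model).score
                if score > 0.70:
                    expect.append((-score, e.source_id, (pos + 1, pos + len(q) + 4)))
        expect.sort()
        assert [(-h.score, h.source_id, h.source_span) for h in got] == expect


class TestAssembleModel:
    def _hits_from_source(self, corpus_library, model, entry_idx=0, target_len=45):
        entry = corpus_library.entries[entry_idx]
        spans = split_into_fragments(entry.string, target_len, 4)
        return entry, [search_fragments(corpus_library, entry.string, sp, model)[0]
                       for sp in spans]

    def test_identity_splice_reproduces_the_source_trace(self, corpus_library, model):
        entry = max(corpus_library.entries, key=lambda e: len(e.trace))
        spans = split_into_fragments(entry.string, 45, 4)
        assert len(spans) > 1
        hits = [search_fragments(corpus_library, entry.string, sp, model)[0]
                for sp in spans]
        assembled = assemble_model(hits)
        assert len(assembled.trace) == len(entry.trace)
        _, _, rmsd = superpose(assembled.trace.coords(), entry.trace.coords())
        assert rmsd < 0.1
        assert all(r < 0.1 for r in assembled.junction_rmsds)

    def test_single_fragment_is_returned_unchanged(self, corpus_library, model):
        entry = corpus_library.entries[0]
        span = (1, len(entry.trace))
        hit = search_fragments(corpus_library, entry.string, span, model)[0]
        assembled = assemble_model([hit])
        assert np.allclose(assembled.trace.coords(), entry.trace.coords())
        assert assembled.junction_rmsds == []

    def test_reported_junction_rmsds_match_recomputation(self, corpus_library, model):
        entry = max(corpus_library.entries, key=lambda e: len(e.trace))
        spans = split_into_fragments(entry.string, 45, 4)
        hits = [search_fragments(corpus_library, entry.string, sp, model)[0]
                for sp in spans]
        assembled = assemble_model(hits)
        for (h_prev, h_next), reported in zip(zip(hits, hits[1:]),
                                              assembled.junction_rmsds):
            shared = h_prev.query_span[1] - h_next.query_span[0] + 1
            out = assembled.trace.coords()[
                h_next.query_span[0] - 1:h_prev.query_span[1]]
            frag = h_next.trace_fragment.coords()[:shared]
            _, _, rmsd = superpose(frag, out)
            assert rmsd == pytest.approx(reported, abs=1e-6)

    def test_insufficient_overlap_is_an_assembly_error(self, corpus_library, model):
        entry = max(corpus_library.entries, key=lambda e: len(e.trace))
        spans = split_into_fragments(entry.string, 45, 4)
        hits = [search_fragments(corpus_library, entry.string, sp, model)[0]
                for sp in spans[:2]]
        # pull the second span rightwards so only 2 residues are shared
        far = hits[1]
        far.query_span = (hits[0].query_span[1] - 1, hits[0].query_span[1] + 43)
        with pytest.raises(AssemblyError):
            assemble_model([hits[0], far])


class TestBuildAndValidateEnsemble:
    def _conformations(self, corpus_library, n=3):
        members = [
            ConformationMember(f"PFVM-{i + 1:02d}", e.string, 0.0)
            for i, e in enumerate(corpus_library.entries[:n])
        ]
        return ConformationSet(members=members)

    @staticmethod
    def _self_retrieving(corpus_library, model):
        """Entries whose every span's top hit is the verbatim self-hit.

        Repetitive fold strings (long pure-helix runs) can recur verbatim
        elsewhere in the library and tie at score 1.0, in which case any
        of the tied sources is an equally valid conformational homolog;
        exact coordinate reproduction is only guaranteed when retrieval
        is unambiguous.
        """
        out = []
        for entry in corpus_library.entries:
            spans = split_into_fragments(entry.string, 45, 4)
            tops = [search_fragments(corpus_library, entry.string, sp, model)[0]
                    for sp in spans]
            if all(h.source_id == entry.source_id and h.source_span == sp
                   for h, sp in zip(tops, spans)):
                out.append(entry)
        return out

    def test_library_conformations_rebuild_their_own_traces(self, corpus_library, model):
        unique = self._self_retrieving(corpus_library, model)
        assert len(unique) >= 2  # the corpus must exercise the property
        conformations = ConformationSet(members=[
            ConformationMember(f"PFVM-{i + 1:02d}", e.string, 0.0)
            for i, e in enumerate(unique)
        ])
        built = build_ensemble(corpus_library, conformations, BuildParams(), model)
        assert len(built) == len(unique)
        for bm, entry in zip(built, unique):
            assert len(bm.trace) == len(entry.trace)
            _, _, rmsd = superpose(bm.trace.coords(), entry.trace.coords())
            assert rmsd < 0.1

    def test_provenance_records_every_fragment_source_and_score(self, corpus_library, model):
        built = build_ensemble(corpus_library, self._conformations(corpus_library),
                               BuildParams(), model)
        for bm in built:
            spans = split_into_fragments(
                corpus_library.entries[int(bm.name[-2:]) - 1].string, 45, 4)
            assert len(bm.fragments) == len(spans)
            for hit in bm.fragments:
                assert hit.score > 0.5
                assert hit.source_id in {e.source_id for e in corpus_library.entries}

    def test_model_length_is_string_length_plus_4(self, corpus_library, model):
        built = build_ensemble(corpus_library, self._conformations(corpus_library),
                               BuildParams(), model)
        for bm, mem in zip(built, self._conformations(corpus_library).members):
            assert len(bm.trace) == len(mem.string.codes) + 4

    def test_validate_finds_the_exact_member_with_score_one(self, corpus_library, model):
        strings = [e.string for e in corpus_library.entries[:5]]
        given = corpus_library.entries[3].string
        score, idx = validate_ensemble(strings, given, model)
        assert score == 1.0 and idx == 3

    def test_validate_is_a_max_reduction(self, corpus_library, model):
        strings = [e.string for e in corpus_library.entries[:5]]
        given = corpus_library.entries[0].string
        score, idx = validate_ensemble(strings, given, model)
        brute = [pfsa_score(s, given, model).score for s in strings]
        assert score == max(brute) and idx == int(np.argmax(brute))

    def test_singleton_ensemble_returns_its_own_score(self, corpus_library, model):
        a, b = corpus_library.entries[0].string, corpus_library.entries[1].string
        score, idx = validate_ensemble([a], b, model)
        assert idx == 0
        assert score == pytest.approx(pfsa_score(a, b, model).score)


class TestSuperpositionCrossCheck:
    def test_kabsch_rmsd_matches_scipy_rotation_align_vectors(self):
        """Rigid superposition must agree with an independent
        least-squares rotation fit."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(8)
        for _ in range(10):
            target = rng.normal(size=(12, 3)) * 5
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            q *= np.linalg.det(q)
            mobile = (target - target.mean(0)) @ q.T + rng.normal(size=3) \
                + rng.normal(scale=0.3, size=(12, 3))
            _, _, rmsd = superpose(mobile, target)
            rot, ssd = Rotation.align_vectors(
                target - target.mean(0), mobile - mobile.mean(0))
            expect = np.sqrt(ssd**2 / 12)
            assert rmsd == pytest.approx(float(expect), abs=1e-6)
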