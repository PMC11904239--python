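import numpy as np
import pytest

from pfvmkit import (
    BackboneSpec,
    CaTrace,
    PfscAlphabet,
    ResidueRecord,
    ValidationError,
    classify_code,
    compute_window_descriptors,
    encode_chain,
    make_ideal_backbone,
)
from pfvmkit.fixtures import random_spec

# Reference descriptor triple of the ideal-helix window, computed once
# from the noise-free generator and frozen as a regression constant.
HELIX_TRIPLE = (51.51, 51.51, 71.67)


def _chain_from_coords(coords, seq=None):
    n = len(coords)
    seq = seq or "A" * n
    residues = [ResidueRecord("A", i + 1, "ALA", seq[i], np.asarray(c, float))
                for i, c in enumerate(coords)]
    return CaTrace("A", residues, "inline")


class TestWindowDescriptors:
    def test_ideal_helix_interior_windows_match_the_frozen_triple(self):
        trace = make_ideal_backbone(BackboneSpec(segments=(("helix", 12),)))
        for i in range(1, len(trace) - 3):
            d = compute_window_descriptors(trace, i)
            assert (d.tau1, d.tau2, d.theta) == pytest.approx(HELIX_TRIPLE, abs=0.01)

    def test_collinear_points_give_straight_bend_and_zero_torsions(self):
        trace = _chain_from_coords([[3.8 * i, 0, 0] for i in range(5)])
        d = compute_window_descriptors(trace, 1)
        assert d.theta == pytest.approx(180.0)
        assert d.tau1 == d.tau2 == 0.0

    def test_missing_ca_or_internal_break_yields_the_undefined_sentinel(self):
        trace = make_ideal_backbone(BackboneSpec(segments=(("helix", 10),)))
        trace.residues[4].ca_xyz = None
        assert compute_window_descriptors(trace, 2) is None
        broken = make_ideal_backbone(BackboneSpec(segments=(("helix", 10),)))
        for r in broken.residues[5:]:
            r.ca_xyz = r.ca_xyz + 40.0
        assert compute_window_descriptors(broken, 3) is None

    def test_out_of_range_window_start(self):
        trace = make_ideal_backbone(BackboneSpec(segments=(("helix", 8),)))
        with pytest.raises(IndexError):
            compute_window_descriptors(trace, 5)


class TestEncodeChain:
    def test_noise_free_helix_is_a_constant_string_of_the_helix_code(self, alphabet):
        trace = make_ideal_backbone(BackboneSpec(segments=(("helix", 20),)))
        s = encode_chain(trace, alphabet)
        assert s.codes == alphabet.helix_code * 16

    def test_window_count_law_holds_on_random_fixtures(self, alphabet):
        rng = np.random.default_rng(42)
        for _ in range(25):
            trace = make_ideal_backbone(random_spec(rng))
            assert len(encode_chain(trace, alphabet).codes) == len(trace) - 4

    def test_103_residue_chain_encodes_to_99_symbols(self, alphabet):
        spec = BackboneSpec(segments=(("coil", 50), ("helix", 53)), seed=2)
        assert len(encode_chain(make_ideal_backbone(spec), alphabet).codes) == 99

    def test_chains_shorter_than_a_window_are_rejected(self, alphabet):
        trace = _chain_from_coords([[3.8 * i, 0.1 * i * i, 0] for i in range(4)])
        with pytest.raises(ValidationError):
            encode_chain(trace, alphabet)

    def test_rigid_motion_leaves_the_string_unchanged(self, alphabet):
        rng = np.random.default_rng(7)
        trace = make_ideal_backbone(random_spec(rng))
        s0 = encode_chain(trace, alphabet)
        # random proper rotation + translation
        q = rng.normal(size=(3, 3))
        r, _ = np.linalg.qr(q)
        r *= np.linalg.det(r)
        moved = _chain_from_coords(trace.coords() @ r.T + [10.0, -5.0, 3.0],
                                   trace.sequence)
        assert encode_chain(moved, alphabet).codes == s0.codes

    def test_windows_touching_a_missing_ca_encode_as_undefined(self, alphabet):
        trace = make_ideal_backbone(BackboneSpec(segments=(("helix", 14),)))
        trace.residues[6].ca_xyz = None
        codes = encode_chain(trace, alphabet).codes
        assert all(c == alphabet.undefined_code for c in codes[2:7])
        assert all(c == alphabet.helix_code for c in codes[:2] + codes[7:])

    def test_agrees_with_brute_force_descriptor_lookup_on_7mers(self, alphabet):
        from pfvmkit._geometry import bend_angle, dihedral
        rng = np.random.default_rng(13)
        for _ in range(30):
            spec = random_spec(rng, min_len=7, max_len=7, noise_deg=10.0)
            trace = make_ideal_backbone(spec)
            got = encode_chain(trace, alphabet).codes
            ca = trace.coords()
            expect = "".join(
                alphabet.code_of_cell[alphabet.config.cell(
                    dihedral(ca[i], ca[i + 1], ca[i + 2], ca[i + 3]),
                    dihedral(ca[i + 1], ca[i + 2], ca[i + 3], ca[i + 4]),
                    bend_angle(ca[i], ca[i + 2], ca[i + 4]),
                )]
                for i in range(3)
            )
            assert got == expect


class TestMutationLocality:
    def test_residue_identity_never_affects_the_encoding(self, alphabet):
        trace = make_ideal_backbone(BackboneSpec(segments=(("helix", 10), ("strand", 10))))
        s0 = encode_chain(trace, alphabet)
        for r in trace.residues:
            r.aa1 = "W"
            r.resname = "TRP"
        assert encode_chain(trace, alphabet).codes == s0.codes

    def test_perturbing_one_ca_changes_at_most_5_consecutive_symbols(self, alphabet):
        rng = np.random.default_rng(99)
        for _ in range(10):
            trace = make_ideal_backbone(random_spec(rng, noise_deg=0.0))
            s0 = encode_chain(trace, alphabet).codes
            k = int(rng.integers(0, len(trace)))
            trace.residues[k].ca_xyz = trace.residues[k].ca_xyz + rng.normal(0, 0.8, 3)
            s1 = encode_chain(trace, alphabet).codes
            diff = [i for i, (a, b) in enumerate(zip(s0, s1)) if a != b]
            assert len(diff) <= 5
            if diff:
                assert diff[-1] - diff[0] <= 4  # consecutive window span


class TestClassifyCode:
    def test_class_labels_of_the_anchor_codes(self, alphabet):
        assert classify_code(alphabet.helix_code, alphabet) == "helix"
        assert classify_code(alphabet.strand_code, alphabet) == "strand"
        assert classify_code("$", alphabet) == "undefined"

    def test_every_code_has_a_class_and_all_classes_are_populated(self, alphabet):
        labels = {c: classify_code(c, alphabet) for c in alphabet.codes}
        assert len(labels) == 27
        assert set(labels.values()) == {
            "helix", "alike-helix", "strand", "alike-strand", "irregular", "undefined",
        }

    def test_unknown_symbol_is_rejected(self, alphabet):
        with pytest.raises(ValidationError):
            classify_code("?", alphabet)
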