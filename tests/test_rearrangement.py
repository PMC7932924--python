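"""Translation, productivity logic, identity keys — with a brute-force
frame-and-stop oracle for complete V-J joints."""

import numpy as np
import pytest
from Bio.Seq import Seq

import clonemark as cm
from clonemark.annotate import SegmentAlignment, _diagonal_align, build_rearrangement
from clonemark.classes import CLASS_BY_LABEL
from clonemark.rearrangement import (
    PRODUCTIVE,
    UNKNOWN,
    UNPRODUCTIVE,
    FrameError,
    Rearrangement,
    determine_productivity,
    identity_key,
    translate_junction,
)


class TestTranslateJunction:
    @pytest.mark.parametrize("nt,frame,aa", [
        ("TGTGCCAGC", 0, "CAS"),
        ("TGA", 0, "*"),
        ("TGTGC", 0, "C"),     # trailing partial codon dropped
        ("ATGTGCC", 1, "CA"),
        ("AT", 0, ""),
    ])
    def test_examples(self, nt, frame, aa):
        assert translate_junction(nt, frame) == aa

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            translate_junction("ACGN", 0)

    def test_bad_frame_rejected(self):
        with pytest.raises(ValueError):
            translate_junction("ACG", 3)


def _rearr(label, **kw):
    base = dict(junction_class=CLASS_BY_LABEL[label], five_gene="X",
                three_gene="Y", five_del=0, ndn_length=0, three_del=0)
    base.update(kw)
    return Rearrangement(**base)


class TestDetermineProductivity:
    def test_complete_in_frame_no_stop_is_productive(self):
        r = _rearr("Vk-Jk", junction_aa="CASSL", in_frame=True)
        assert determine_productivity(r) == "productive"

    def test_complete_frameshift_is_unproductive(self):
        r = _rearr("Vh-(Dh)-Jh", junction_aa="CASSL", in_frame=False)
        assert determine_productivity(r) == "unproductive"

    def test_complete_stop_is_unproductive(self):
        r = _rearr("Vb-(Db)-Jb", junction_aa="CA*SL", in_frame=True)
        assert determine_productivity(r) == "unproductive"

    def test_dj_without_stop_potentially_productive(self):
        r = _rearr("Dh-Jh", junction_aa="GYW")
        assert determine_productivity(r) == "potentially_productive"

    def test_dj_with_stop_unproductive(self):
        r = _rearr("Db-Jb", junction_aa="G*W")
        assert determine_productivity(r) == "unproductive"

    def test_damaged_is_unknown(self):
        r = _rearr("Vk-Jk", five_del=None, ndn_length=None, three_del=None,
                   damaged=True)
        assert determine_productivity(r) == "unknown"

    @pytest.mark.parametrize("label", ["Vk-Kde", "intron-Kde", "Va-Dd",
                                       "Dd2-Dd3", "Vb-Db"])
    def test_non_coding_classes_unknown(self, label):
        assert determine_productivity(_rearr(label)) == "unknown"

    def test_complete_without_frame_verdict_raises(self):
        with pytest.raises(FrameError):
            determine_productivity(_rearr("Vg-Jg", junction_aa="CAS"))


class TestIdentityKey:
    def test_count_not_part_of_key(self):
        a = _rearr("Vg-Jg", junction_aa="CAS", in_frame=True, count=1)
        b = _rearr("Vg-Jg", junction_aa="CAS", in_frame=True, count=7)
        assert identity_key(a) == identity_key(b)

    def test_ndn_difference_changes_key(self):
        a = _rearr("Vg-Jg", ndn_length=4, junction_aa="CAS", in_frame=True)
        b = _rearr("Vg-Jg", ndn_length=5, junction_aa="CAS", in_frame=True)
        assert identity_key(a) != identity_key(b)

    def test_damaged_key_is_partial_and_does_not_match_intact(self, toy_ref, rng):
        params = cm.SimulationParams()
        truth = cm.simulate_rearrangement(toy_ref, "Vg-Jg", rng, params)
        intact = truth.rearrangement
        damaged = Rearrangement(
            junction_class=intact.junction_class, five_gene=intact.five_gene,
            three_gene=intact.three_gene, five_del=None, ndn_length=None,
            three_del=None, damaged=True)
        assert identity_key(damaged).is_partial
        assert not identity_key(intact).is_partial
        assert identity_key(damaged) != identity_key(intact)
        # an intact copy of the same joint does match
        assert identity_key(intact) == identity_key(
            Rearrangement(**{**intact.__dict__}))


def brute_force_complete_vj(truth) -> str:
    """Independent oracle: translate the whole V->J coding span in the V
    frame and test frame continuity and stop-freedom."""
    in_frame = (truth.j_anchor_pos - truth.v_anchor_pos) % 3 == 0
    span = truth.full_sequence[truth.v_anchor_pos:]
    span = span[:len(span) - len(span) % 3]
    aa = str(Seq(span).translate())
    return PRODUCTIVE if in_frame and "*" not in aa else UNPRODUCTIVE


COMPLETE_CLASSES = ["Vh-(Dh)-Jh", "Vk-Jk", "Vl-Jl", "Va-Ja", "Va-Jd",
                    "Vd-(Dd)-Ja", "Vb-(Db)-Jb", "Vd-(Dd)-Jd", "Vg-Jg"]


class TestProductivityOracle:
    def test_agrees_with_brute_force_on_random_joints(self, toy_ref):
        rng = np.random.default_rng(424242)
        params = cm.SimulationParams()
        n = 0
        for _ in range(300):
            label = COMPLETE_CLASSES[int(rng.integers(len(COMPLETE_CLASSES)))]
            truth = cm.simulate_rearrangement(toy_ref, label, rng, params)
            assert truth.rearrangement.productivity == brute_force_complete_vj(truth)
            n += 1
        assert n == 300

    def test_frameshift_closure(self, toy_ref):
        """Inserting one base into the junction of a productive joint
        always yields an unproductive joint."""
        rng = np.random.default_rng(99)
        params = cm.SimulationParams()
        checked = 0
        while checked < 25:
            truth = cm.simulate_rearrangement(toy_ref, "Vk-Jk", rng, params)
            if truth.rearrangement.productivity != PRODUCTIVE:
                continue
            five = toy_ref[truth.rearrangement.five_gene]
            three = toy_ref[truth.rearrangement.three_gene]
            v_len = five.length - truth.raw_five_del
            pos = v_len + len(truth.raw_ndn) // 2
            mutated = (truth.full_sequence[:pos] + "A"
                       + truth.full_sequence[pos:])
            f_res = _diagonal_align(mutated, five.sequence, 0)
            diag3 = v_len + len(truth.raw_ndn) + 1 - truth.raw_three_del
            t_res = _diagonal_align(mutated, three.sequence, diag3)
            f_aln = SegmentAlignment(five, 0, f_res[1], f_res[2], f_res[1],
                                     f_res[2], f_res[0], f_res[3])
            t_aln = SegmentAlignment(three, 0, t_res[1], t_res[2],
                                     t_res[1] - diag3, t_res[2] - diag3,
                                     t_res[0], t_res[3])
            r = build_rearrangement([mutated], f_aln, t_aln)
            assert r.productivity == UNPRODUCTIVE
            checked += 1


class TestRearrangementInvariants:
    def test_damaged_with_junction_aa_rejected(self):
        with pytest.raises(ValueError):
            _rearr("Vk-Jk", damaged=True, junction_aa="CAS")

    def test_negative_segmentation_rejected(self):
        with pytest.raises(ValueError):
            _rearr("Vk-Jk", five_del=-1)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError):
            _rearr("Vk-Jk", count=0)
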