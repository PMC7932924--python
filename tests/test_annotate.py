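"""Read annotation: merging, segment alignment, junction recovery, dedup."""

import numpy as np
import pytest

import clonemark as cm
from clonemark.annotate import (
    AnnotatedRead,
    AnnotationParams,
    align_segment,
    deduplicate,
    merge_pair,
    revcomp,
)
from clonemark.rearrangement import identity_key
from clonemark.simulate import DEFAULT_TUBES, simulate_dnaamp_reads


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


class TestMergePair:
    def test_overlapping_mates_merge_to_fragment(self, rng):
        frag = _random_seq(rng, 120)
        r1, r2 = frag[:75], revcomp(frag[-75:])
        assert merge_pair(("f/1", r1), ("f/2", r2)) == frag

    def test_distant_mates_stay_unmerged(self, rng):
        frag = _random_seq(rng, 400)
        assert merge_pair(("f/1", frag[:75]), ("f/2", revcomp(frag[-75:]))) is None

    def test_conflicting_overlap_stays_unmerged(self, rng):
        frag = _random_seq(rng, 120)
        r2 = list(revcomp(frag[-75:]))
        # the 30 nt mate overlap maps to the tail of the raw second read
        for i in (50, 56, 62, 68):
            r2[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2[i]]
        assert merge_pair(("f/1", frag[:75]), ("f/2", "".join(r2)),
                          max_mismatch=2) is None

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            merge_pair(("a/1", "ACGT"), ("b/2", "ACGT"))


class TestAlignSegment:
    def test_exact_substring_full_identity(self, toy_ref, rng):
        seg = toy_ref["IGHV1-1"]
        read = _random_seq(rng, 20) + seg.sequence[40:100] + _random_seq(rng, 20)
        aln = align_segment(read, [seg])
        assert aln.gene == "IGHV1-1"
        assert aln.identity == 1.0
        assert aln.length >= 60

    def test_minus_strand_hit_found(self, toy_ref, rng):
        seg = toy_ref["TRGV1-1"]
        read = revcomp(_random_seq(rng, 15) + seg.sequence[:60])
        aln = align_segment(read, [seg])
        assert aln is not None and aln.strand == "-"

    def test_random_reads_rarely_hit(self, toy_ref):
        rng = np.random.default_rng(77)
        candidates = list(toy_ref.segments.values())
        hits = sum(
            align_segment(_random_seq(rng, 150), candidates) is not None
            for _ in range(500))
        assert hits / 500 < 0.01

    def test_score_tie_prefers_smaller_gene_name(self, toy_ref, rng):
        body = _random_seq(rng, 60)
        a = cm.GeneSegment("TRGV9", "TRG", "V", body, 0)
        b = cm.GeneSegment("TRGV2", "TRG", "V", body, 0)
        aln = align_segment(body, [a, b])
        assert aln.gene == "TRGV2"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            align_segment("ACGT", [])


class TestAnnotateRead:
    def test_truth_key_recovered_from_amplicons(self, toy_ref, annotator):
        params = cm.SimulationParams(background_size=10,
                                     dnaamp_depth_per_tube=50)
        rng = np.random.default_rng(13)
        case = cm.simulate_case(toy_ref, params, rng, "caseA")
        by_id = {t.truth_id: t for t in case.truth}
        by_tube = simulate_dnaamp_reads(case, DEFAULT_TUBES, params, rng)
        n = ok = 0
        for reads in by_tube.values():
            for _, comment, seq in reads:
                truth = by_id[comment.split("|")[2]]
                res = annotator.annotate_read(seq)
                n += 1
                ok += (res.assigned
                       and identity_key(res.rearrangement) == truth.key)
        assert n >= 300
        assert ok / n >= 0.99

    def test_strand_symmetric(self, toy_ref, annotator, rng):
        truth = cm.simulate_rearrangement(toy_ref, "Vb-(Db)-Jb", rng,
                                          cm.SimulationParams())
        fwd = annotator.annotate_read(truth.full_sequence)
        rev = annotator.annotate_read(revcomp(truth.full_sequence))
        assert fwd.assigned and rev.assigned
        assert fwd.rearrangement == rev.rearrangement

    def test_v_only_read_unassigned_no_3prime(self, toy_ref, annotator):
        seg = toy_ref["IGHV1-1"]
        res = annotator.annotate_read(seg.sequence[:120])
        assert not res.assigned and res.reason == "no_3prime"

    def test_j_only_read_unassigned_no_5prime(self, toy_ref, annotator):
        res = annotator.annotate_read(toy_ref["IGLJ1"].sequence)
        assert not res.assigned and res.reason == "no_5prime"

    def test_wrong_order_reported(self, toy_ref, annotator, rng):
        # J sequence upstream of V sequence: elements present, order invalid
        seq = (toy_ref["TRGJ1"].sequence + _random_seq(rng, 5)
               + toy_ref["TRGV1-1"].sequence[:80])
        res = annotator.annotate_read(seq)
        assert not res.assigned and res.reason in ("wrong_order", "cross_class")

    def test_mid_fragment_junction_gives_damaged_record(self, toy_ref,
                                                        annotator, rng):
        """Unmerged pair whose junction lies in the uncovered middle."""
        params = cm.SimulationParams()
        while True:  # need generous V context and J tail for this geometry
            truth = cm.simulate_rearrangement(toy_ref, "Vg-Jg", rng, params)
            v_end, j_start = truth.five_span[1], truth.three_span[0]
            if v_end >= 255 and len(truth.full_sequence) - j_start >= 40:
                break
        ctx = (_random_seq(rng, 300) + truth.full_sequence
               + _random_seq(rng, 300))
        w_mid = 300 + (truth.window_start + truth.window_end) // 2
        # 400 nt fragment, junction ~300 nt in: V in mate 1, J in mate 2,
        # the junction window itself in the uncovered middle
        frag = ctx[w_mid - 300:w_mid + 100]
        res = annotator.annotate_pair(("f/1", frag[:75]),
                                      ("f/2", revcomp(frag[-75:])))
        assert res.assigned
        r = res.rearrangement
        assert r.damaged
        assert r.junction_aa == "" and r.productivity == "unknown"
        assert r.ndn_length is None
        assert identity_key(r).is_partial

    def test_annotation_deterministic(self, toy_ref, annotator, rng):
        truth = cm.simulate_rearrangement(toy_ref, "Va-Ja", rng,
                                          cm.SimulationParams())
        first = annotator.annotate_read(truth.full_sequence)
        again = annotator.annotate_read(truth.full_sequence)
        assert first.rearrangement == again.rearrangement


def _annotated(read_id, platform, rearr, fragment_key=None, tube="TRG"):
    return AnnotatedRead(read_id=read_id, case_id="caseA", platform=platform,
                         tube=tube, rearrangement=rearr,
                         fragment_key=fragment_key)


class TestDeduplicate:
    @pytest.fixture()
    def joint(self, toy_ref, rng):
        return cm.simulate_rearrangement(toy_ref, "Vg-Jg", rng,
                                         cm.SimulationParams()).rearrangement

    def test_rnaseq_counts_unique_fragments(self, joint):
        recs = [_annotated(f"r{i}", "RNAseq", joint, fragment_key="frag1")
                for i in range(5)]
        out = deduplicate(recs)
        assert len(out) == 1
        assert out[0].rearrangement.count == 1

    def test_dnaamp_counts_reads(self, joint):
        recs = [_annotated(f"r{i}", "DNAamp", joint) for i in range(5)]
        out = deduplicate(recs)
        assert len(out) == 1
        assert out[0].rearrangement.count == 5

    def test_empty_input_empty_output(self):
        assert deduplicate([]) == []

    def test_order_independent(self, toy_ref, rng):
        joints = [cm.simulate_rearrangement(toy_ref, "Vk-Jk", rng,
                                            cm.SimulationParams()).rearrangement
                  for _ in range(6)]
        recs = [_annotated(f"r{i}", "DNAamp", j)
                for i, j in enumerate(joints * 3)]
        a = deduplicate(recs)
        b = deduplicate(list(reversed(recs)))
        assert [(identity_key(x.rearrangement), x.rearrangement.count)
                for x in a] == \
               [(identity_key(x.rearrangement), x.rearrangement.count)
                for x in b]


class TestAnnotationParams:
    def test_seed_kmer_bounded_by_min_j_match(self):
        with pytest.raises(ValueError):
            AnnotationParams(seed_kmer=15, min_j_match=12)

    def test_negative_band_rejected(self):
        with pytest.raises(ValueError):
            AnnotationParams(band=-1)
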