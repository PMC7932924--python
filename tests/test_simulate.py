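"""Simulator: ground-truth construction, abundance models, read geometry."""

import numpy as np
import pytest
from scipy import stats

import clonemark as cm
from clonemark.rearrangement import PRODUCTIVE, UNKNOWN, UNPRODUCTIVE
from clonemark.simulate import (
    DEFAULT_TUBES,
    DNAAMP_DETECTABLE_CLASSES,
    ClonalSpec,
    simulate_dnaamp_reads,
    simulate_rnaseq_reads,
)


class TestSimulateRearrangement:
    def test_kde_joint_is_non_coding(self, toy_ref):
        rng = np.random.default_rng(7)
        t = cm.simulate_rearrangement(toy_ref, "Vk-Kde", rng,
                                      cm.SimulationParams())
        assert t.rearrangement.productivity == UNKNOWN
        assert t.rearrangement.junction_aa == ""

    def test_degenerate_parameters_give_germline_abutment(self, toy_ref, rng):
        params = cm.SimulationParams(deletion_max=0, ndn_mean=0.0)
        t = cm.simulate_rearrangement(toy_ref, "Vg-Jg", rng, params)
        r = t.rearrangement
        assert (r.five_del, r.ndn_length, r.three_del) == (0, 0, 0)
        five = toy_ref[r.five_gene]
        three = toy_ref[r.three_gene]
        assert t.full_sequence == five.sequence + three.sequence

    def test_unknown_class_rejected(self, toy_ref, rng):
        with pytest.raises(ValueError, match="unknown junction class"):
            cm.simulate_rearrangement(toy_ref, "Vx-Jx", rng,
                                      cm.SimulationParams())

    def test_truth_annotation_self_consistent(self, toy_ref, annotator):
        """Re-annotating a truth record's own full sequence reproduces its
        identity key."""
        rng = np.random.default_rng(11)
        params = cm.SimulationParams()
        for label in ("Vh-(Dh)-Jh", "Dh-Jh", "Vk-Kde", "Dd2-Dd3", "Vg-Jg"):
            for _ in range(10):
                t = cm.simulate_rearrangement(toy_ref, label, rng, params)
                res = annotator.annotate_read(t.full_sequence)
                assert res.assigned
                assert cm.identity_key(res.rearrangement) == t.key

    def test_productive_fraction_matches_monte_carlo_oracle(self, toy_ref):
        """The simulator's complete-V-J productive fraction agrees with an
        independent Monte-Carlo draw scored by brute-force translation."""
        from test_rearrangement import brute_force_complete_vj
        params = cm.SimulationParams()
        n = 700
        rng_a = np.random.default_rng(101)
        obs = np.mean([
            cm.simulate_rearrangement(toy_ref, "Vk-Jk", rng_a, params)
            .rearrangement.productivity == PRODUCTIVE
            for _ in range(n)])
        rng_b = np.random.default_rng(202)
        exp = np.mean([
            brute_force_complete_vj(
                cm.simulate_rearrangement(toy_ref, "Vk-Jk", rng_b, params))
            == PRODUCTIVE
            for _ in range(n)])
        se = np.sqrt(exp * (1 - exp) / n * 2)
        assert abs(obs - exp) <= 3 * se


class TestSimulateCase:
    def test_default_plan_contents(self, toy_ref, rng):
        case = cm.simulate_case(toy_ref, cm.SimulationParams(background_size=10),
                                rng, "caseA")
        clonal = case.clonal()
        labels = [t.rearrangement.junction_class.label for t in clonal]
        assert labels.count("Vh-(Dh)-Jh") == 2
        assert "Vk-Kde" in labels
        keys = [t.key for t in clonal]
        assert len(set(keys)) == len(keys)

    def test_background_fully_productive_at_boundary(self, toy_ref, rng):
        params = cm.SimulationParams(background_size=300,
                                     background_productive_fraction=1.0)
        case = cm.simulate_case(toy_ref, params, rng, "caseA")
        bg = [t for t in case.truth if not t.is_clonal]
        assert len(bg) == 300
        assert all(t.rearrangement.productivity != UNPRODUCTIVE for t in bg)

    def test_igh_clonal_unproductive_fraction_near_seventy_percent(self, toy_ref):
        """Across many cases the forced unproductive probability of clonal
        complete IGH joints is honored (binomial 99% CI)."""
        params = cm.SimulationParams(
            background_size=0,
            clonal_plan=(ClonalSpec("Vh-(Dh)-Jh", 2, 0.7),))
        draws = []
        for i, (rng_t, _, _) in enumerate(
                cm.simulate.case_rngs(params, 50)):
            case = cm.simulate_case(toy_ref, params, rng_t, f"c{i}")
            draws += [t.rearrangement.productivity == UNPRODUCTIVE
                      for t in case.clonal()]
        n, p = len(draws), 0.7
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p) / n
        assert lo <= np.mean(draws) <= hi


class TestExpressionLevel:
    def test_three_tier_rates(self, toy_ref, rng):
        params = cm.SimulationParams(sterile_rate=0.01, incomplete_rate=0.001)
        t = cm.simulate_rearrangement(toy_ref, "Vb-(Db)-Jb", rng, params)
        expected = 1.0 if t.rearrangement.productivity == PRODUCTIVE else 0.01
        assert cm.expression_level(t, params) == expected
        kde = cm.simulate_rearrangement(toy_ref, "Vk-Kde", rng, params)
        assert cm.expression_level(kde, params) == 0.001

    def test_zero_incomplete_rate_excludes_dd_joints(self, toy_ref, rng):
        params = cm.SimulationParams(incomplete_rate=0.0)
        t = cm.simulate_rearrangement(toy_ref, "Dd2-Dd3", rng, params)
        assert cm.expression_level(t, params) == 0.0


def _small_case(toy_ref, seed=5, **kw):
    defaults = dict(background_size=20, dnaamp_depth_per_tube=200,
                    rnaseq_fragments=400)
    defaults.update(kw)
    params = cm.SimulationParams(**defaults)
    rng = np.random.default_rng(seed)
    return cm.simulate_case(toy_ref, params, rng, "caseA"), params


class TestDnaampReads:
    def test_igl_clonal_in_no_tube(self, toy_ref):
        plan = cm.DEFAULT_CLONAL_PLAN + (ClonalSpec("Vl-Jl", 1),)
        params = cm.SimulationParams(background_size=0, clonal_plan=plan,
                                     dnaamp_depth_per_tube=50)
        rng = np.random.default_rng(3)
        case = cm.simulate_case(toy_ref, params, rng, "caseA")
        igl_ids = {t.truth_id for t in case.truth
                   if t.rearrangement.junction_class.label == "Vl-Jl"}
        assert igl_ids
        assert "Vl-Jl" not in DNAAMP_DETECTABLE_CLASSES
        with pytest.warns(UserWarning):
            by_tube = simulate_dnaamp_reads(case, DEFAULT_TUBES, params, rng)
        for reads in by_tube.values():
            for _, comment, _ in reads:
                assert comment.split("|")[2] not in igl_ids

    def test_zero_depth_gives_empty_fastqs(self, toy_ref):
        case, params = _small_case(toy_ref, dnaamp_depth_per_tube=0)
        rng = np.random.default_rng(1)
        by_tube = simulate_dnaamp_reads(case, DEFAULT_TUBES, params, rng)
        assert set(by_tube) == {t.name for t in DEFAULT_TUBES}
        assert all(len(reads) == 0 for reads in by_tube.values())

    def test_clonal_share_multinomial(self, toy_ref):
        case, params = _small_case(toy_ref, dnaamp_depth_per_tube=10_000)
        rng = np.random.default_rng(2)
        by_tube = simulate_dnaamp_reads(case, DEFAULT_TUBES, params, rng)
        clonal_ids = {t.truth_id for t in case.clonal()}
        reads = by_tube["IGHV-IGHD-IGHJ"]
        n_clonal = sum(r[1].split("|")[2] in clonal_ids for r in reads)
        depth, bf = len(reads), case.blast_fraction
        assert depth == 10_000
        sigma = np.sqrt(depth * bf * (1 - bf))
        assert abs(n_clonal - bf * depth) <= 3 * sigma

    def test_reads_cover_junction_window(self, toy_ref, annotator):
        """Amplicon contract: every DNAamp read yields an undamaged record."""
        case, params = _small_case(toy_ref, dnaamp_depth_per_tube=30)
        rng = np.random.default_rng(8)
        by_tube = simulate_dnaamp_reads(case, DEFAULT_TUBES, params, rng)
        n = 0
        for reads in by_tube.values():
            for _, _, seq in reads[:10]:
                res = annotator.annotate_read(seq)
                assert res.assigned and not res.rearrangement.damaged
                n += 1
        assert n > 0


class TestRnaseqReads:
    def test_same_seed_identical_output(self, toy_ref):
        case, params = _small_case(toy_ref)
        p1, f1 = simulate_rnaseq_reads(case, params, np.random.default_rng(4))
        p2, f2 = simulate_rnaseq_reads(case, params, np.random.default_rng(4))
        assert p1 == p2 and f1 == f2
        d1 = simulate_dnaamp_reads(case, DEFAULT_TUBES, params,
                                   np.random.default_rng(4))
        d2 = simulate_dnaamp_reads(case, DEFAULT_TUBES, params,
                                   np.random.default_rng(4))
        assert d1 == d2

    def test_short_fragments_never_damaged(self, toy_ref):
        case, params = _small_case(toy_ref, fragment_length_mean=70.0,
                                   fragment_length_sd=0.0,
                                   fragment_length_min=70)
        _, frags = simulate_rnaseq_reads(case, params, np.random.default_rng(6))
        assert frags
        assert not any(f["damaged"] for f in frags)

    def test_zero_rates_restrict_to_productive_sources(self, toy_ref):
        case, params = _small_case(toy_ref, sterile_rate=0.0,
                                   incomplete_rate=0.0)
        by_id = {t.truth_id: t for t in case.truth}
        _, frags = simulate_rnaseq_reads(case, params, np.random.default_rng(6))
        assert frags
        for f in frags:
            assert by_id[f["truth_id"]].rearrangement.productivity == PRODUCTIVE

    def test_all_zero_rates_warns_and_empty(self, toy_ref):
        case, params = _small_case(toy_ref, sterile_rate=0.0,
                                   incomplete_rate=0.0, productive_rate=0.0)
        for t in case.truth:
            t.expression_rate = cm.expression_level(t, params)
        with pytest.warns(UserWarning, match="zero"):
            pairs, frags = simulate_rnaseq_reads(case, params,
                                                 np.random.default_rng(6))
        assert pairs == [] and frags == []

    def test_damaged_fraction_monotone_in_fragment_length(self, toy_ref):
        fracs = []
        for mean in (180.0, 300.0, 450.0):
            case, params = _small_case(
                toy_ref, fragment_length_mean=mean, fragment_length_sd=10.0,
                rnaseq_fragments=1500)
            _, frags = simulate_rnaseq_reads(case, params,
                                             np.random.default_rng(9))
            contained = [f for f in frags if f["contains_junction"]]
            fracs.append(np.mean([not f["window_covered"] for f in contained]))
        assert fracs[0] <= fracs[1] <= fracs[2]

    def test_read_ids_resolve_to_truth(self, toy_ref):
        case, params = _small_case(toy_ref)
        by_id = {t.truth_id: t for t in case.truth}
        pairs, frags = simulate_rnaseq_reads(case, params,
                                             np.random.default_rng(10))
        frag_ids = {f["fragment_id"] for f in frags}
        for (id1, c1, _), (id2, c2, _) in pairs:
            assert id1[:-2] == id2[:-2] and id1[:-2] in frag_ids
            assert c1.split("|")[2] in by_id


class TestParamsValidation:
    @pytest.mark.parametrize("kw", [
        {"background_productive_fraction": 1.5},
        {"read_length": 20},
        {"deletion_max": -1},
        {"n_cases": 0},
        {"sterile_rate": -0.1},
    ])
    def test_invalid_rejected(self, kw):
        with pytest.raises(ValueError):
            cm.SimulationParams(**kw)
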