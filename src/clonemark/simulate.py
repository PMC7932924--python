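"""Synthetic cases, clones and platform reads.

The generator emulates the data this pipeline is designed for: leukemic
cases carrying a handful of clonal IG/TR rearrangements (the default plan
is a B-ALL-like profile: two complete IGH joints of which ~70% are
unproductive, one incomplete IGH D-J, one IGK V-J, one Kde joint, and one
clonal TRB, TRG and TRD joint each) on top of a polyclonal background whose
coding rearrangements are >98% productive.

Two read platforms are simulated from the same ground truth:

* **DNAamp** — amplicon reads per primer-set tube.  Each tube multinomially
  samples reads over the rearrangements its primer set can amplify,
  proportional to clonal/background abundance; every amplicon read fully
  covers its junction window (amplicon contract: never damaged).
* **RNAseq** — paired 2x75 bp fragments whose abundance follows a
  three-tier transcription model (productive complete joints at rate 1,
  unproductive complete joints at a low *sterile* rate, incomplete and
  non-coding joints lower still).  Fragments are drawn from a
  junction-centered transcript context with truncated-normal lengths and
  uniform placement, so a fragment longer than its read coverage can leave
  junctional residues unsequenced — the *damaged* records of real
  whole-transcriptome data.

Ground-truth annotations are derived by running the assembled rearranged
sequence through the same junction-building code path as the read
annotator, so truth identity keys are canonical by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .annotate import (
    SegmentAlignment,
    _diagonal_align,
    build_rearrangement,
    revcomp,
)
from .classes import (
    CLASS_BY_LABEL,
    COMPLETE_VJ,
    INCOMPLETE_DJ,
    D,
    INTRON_RSS,
    J,
    KDE,
    V,
)
from .germline import GermlineReference
from .rearrangement import (
    POTENTIALLY_PRODUCTIVE,
    PRODUCTIVE,
    UNPRODUCTIVE,
    Rearrangement,
    identity_key,
    junction_window,
)

DNAAMP = "DNAamp"
RNASEQ = "RNAseq"

_BASES = np.array(list("ACGT"))

#: minimum germline bases a segment keeps after junctional trimming, so that
#: every simulated joint remains seedable and alignable
_MIN_SEGMENT_KEEP = 12


# --------------------------------------------------------------------------
# parameters

@dataclass(frozen=True)
class ClonalSpec:
    """One entry of the clonal plan: how many clonal joints of a class a
    case carries, optionally forcing the unproductive fraction of complete
    joints (None leaves productivity to the junction lottery)."""

    class_label: str
    count: int = 1
    unproductive_prob: float | None = None


DEFAULT_CLONAL_PLAN: tuple[ClonalSpec, ...] = (
    ClonalSpec("Vh-(Dh)-Jh", 2, 0.7),
    ClonalSpec("Dh-Jh", 1),
    ClonalSpec("Vk-Jk", 1),
    ClonalSpec("Vk-Kde", 1),
    ClonalSpec("Vb-(Db)-Jb", 1),
    ClonalSpec("Vg-Jg", 1),
    ClonalSpec("Vd-(Dd)-Jd", 1),
)

#: background class mix: dominated by complete V-J joints across the loci,
#: with a thin tail of incomplete and non-coding joints
DEFAULT_BACKGROUND_WEIGHTS: dict[str, float] = {
    "Vh-(Dh)-Jh": 0.12, "Vk-Jk": 0.12, "Vl-Jl": 0.12, "Va-Ja": 0.12,
    "Vb-(Db)-Jb": 0.12, "Vg-Jg": 0.12, "Vd-(Dd)-Jd": 0.12,
    "Va-Jd": 0.005, "Vd-(Dd)-Ja": 0.005,
    "Dh-Jh": 0.02, "Db-Jb": 0.02, "Dd-Ja": 0.02, "Dd2-Jd1": 0.02,
    "Dd3-Jd": 0.02,
    "Vk-Kde": 0.0125, "intron-Kde": 0.0125, "Va-Dd": 0.00625,
    "Vb-Db": 0.00625, "Db-Db": 0.00625, "Vd-Dd3": 0.00625,
    "Dd2-Dd3": 0.00625, "Dd3-Dd2": 0.00625,
}


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for the synthetic cohort."""

    rng_seed: int = 0
    n_cases: int = 20
    clonal_plan: tuple[ClonalSpec, ...] = DEFAULT_CLONAL_PLAN
    background_size: int = 150
    background_productive_fraction: float = 0.98
    background_class_weights: tuple[tuple[str, float], ...] = tuple(
        DEFAULT_BACKGROUND_WEIGHTS.items()
    )
    deletion_max: int = 10
    ndn_mean: float = 8.0
    blast_fraction: float = 0.9
    blast_concentration: float = 100.0
    dnaamp_depth_per_tube: int = 300
    rnaseq_fragments: int = 3000
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 50.0
    fragment_length_min: int = 150
    read_length: int = 75
    context_length: int = 600
    amplicon_flank: int = 40
    sterile_rate: float = 0.01
    incomplete_rate: float = 0.001
    productive_rate: float = 1.0
    error_rate: float = 0.0
    merge_min_overlap: int = 20  # mirrors the annotator's mate-merge threshold

    def __post_init__(self):
        for name in ("background_productive_fraction", "blast_fraction",
                     "error_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("sterile_rate", "incomplete_rate", "productive_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if self.deletion_max < 0 or self.ndn_mean < 0:
            raise ValueError("deletion_max and ndn_mean must be >= 0")
        if self.n_cases < 1 or self.background_size < 0:
            raise ValueError("n_cases >= 1 and background_size >= 0 required")


@dataclass(frozen=True)
class TubeDefinition:
    """One DNAamp primer-set tube and the junction classes it amplifies."""

    name: str
    target_classes: frozenset[str]


#: The eight amplicon tubes.  IGL and TRA V-J joints belong to no tube; the
#: TRD tube covers the TRD-segment joints plus the cross-locus TRA/TRD
#: hybrids that its primers reach.
DEFAULT_TUBES: tuple[TubeDefinition, ...] = (
    TubeDefinition("IGHV-IGHD-IGHJ", frozenset({"Vh-(Dh)-Jh"})),
    TubeDefinition("IGHD-IGHJ", frozenset({"Dh-Jh"})),
    TubeDefinition("IGKV-IGKJ/Kde", frozenset({"Vk-Jk", "Vk-Kde"})),
    TubeDefinition("intronRSS-Kde", frozenset({"intron-Kde"})),
    TubeDefinition("TRBV-TRBD-TRBJ", frozenset({"Vb-(Db)-Jb"})),
    TubeDefinition("TRBD-TRBJ", frozenset({"Db-Jb"})),
    TubeDefinition("TRG", frozenset({"Vg-Jg"})),
    TubeDefinition("TRD", frozenset({"Vd-(Dd)-Jd", "Dd2-Jd1", "Vd-Dd3",
                                     "Dd2-Dd3", "Vd-(Dd)-Ja", "Dd-Ja",
                                     "Va-Jd"})),
)

DNAAMP_DETECTABLE_CLASSES: frozenset[str] = frozenset().union(
    *(t.target_classes for t in DEFAULT_TUBES)
)


# --------------------------------------------------------------------------
# ground truth containers

@dataclass
class GroundTruthRearrangement:
    """One simulated rearrangement with its canonical truth annotation."""

    truth_id: str
    case_id: str
    rearrangement: Rearrangement
    full_sequence: str
    context_sequence: str = ""
    context_offset: int = 0      # position of full_sequence within context
    window_start: int = 0        # junction window, full_sequence coords
    window_end: int = 0
    is_clonal: bool = False
    cell_fraction: float = 0.0
    expression_rate: float = 0.0
    raw_five_del: int = 0
    raw_ndn: str = ""
    raw_three_del: int = 0
    v_anchor_pos: int | None = None  # abs position of the V frame anchor
    j_anchor_pos: int | None = None  # abs position of the J frame anchor
    five_span: tuple[int, int] = (0, 0)   # canonical 5'-segment alignment span
    three_span: tuple[int, int] = (0, 0)  # canonical 3'-segment alignment span
    five_type: str = ""
    three_type: str = ""

    @property
    def key(self):
        return identity_key(self.rearrangement)


@dataclass
class SimulatedCase:
    """Ground truth for one patient-like case."""

    case_id: str
    truth: list[GroundTruthRearrangement] = field(default_factory=list)
    blast_fraction: float = 0.9

    def clonal(self) -> list[GroundTruthRearrangement]:
        return [t for t in self.truth if t.is_clonal]


# --------------------------------------------------------------------------
# class recipes: which germline roles each junction class joins

_RECIPES: dict[str, tuple[tuple[str, str, str | None],
                          tuple[str, str, str | None], str | None]] = {
    "Vh-(Dh)-Jh": (("IGH", V, None), ("IGH", J, None), "IGH"),
    "Dh-Jh": (("IGH", D, None), ("IGH", J, None), None),
    "Vk-Jk": (("IGK", V, None), ("IGK", J, None), None),
    "Vk-Kde": (("IGK", V, None), ("IGK", KDE, None), None),
    "intron-Kde": (("IGK", INTRON_RSS, None), ("IGK", KDE, None), None),
    "Vl-Jl": (("IGL", V, None), ("IGL", J, None), None),
    "Va-Ja": (("TRA", V, None), ("TRA", J, None), None),
    "Va-Jd": (("TRA", V, None), ("TRD", J, None), None),
    "Vd-(Dd)-Ja": (("TRD", V, None), ("TRA", J, None), "TRD"),
    "Dd-Ja": (("TRD", D, None), ("TRA", J, None), None),
    "Va-Dd": (("TRA", V, None), ("TRD", D, None), None),
    "Vb-(Db)-Jb": (("TRB", V, None), ("TRB", J, None), "TRB"),
    "Db-Jb": (("TRB", D, None), ("TRB", J, None), None),
    "Vb-Db": (("TRB", V, None), ("TRB", D, None), None),
    "Db-Db": (("TRB", D, None), ("TRB", D, None), None),
    "Vd-(Dd)-Jd": (("TRD", V, None), ("TRD", J, None), "TRD"),
    "Dd2-Jd1": (("TRD", D, "TRDD2"), ("TRD", J, "TRDJ1"), None),
    "Dd3-Jd": (("TRD", D, "TRDD3"), ("TRD", J, None), None),
    "Vd-Dd3": (("TRD", V, None), ("TRD", D, "TRDD3"), None),
    "Dd2-Dd3": (("TRD", D, "TRDD2"), ("TRD", D, "TRDD3"), None),
    "Dd3-Dd2": (("TRD", D, "TRDD3"), ("TRD", D, "TRDD2"), None),
    "Vg-Jg": (("TRG", V, None), ("TRG", J, None), None),
}


def _random_bases(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _draw_ndn_length(rng: np.random.Generator, mean: float) -> int:
    # geometric on {0, 1, ...} with the requested mean
    if mean <= 0:
        return 0
    return int(rng.geometric(1.0 / (mean + 1.0))) - 1


def _draw_deletion(rng: np.random.Generator, seg_len: int, deletion_max: int) -> int:
    cap = min(deletion_max, max(0, seg_len - _MIN_SEGMENT_KEEP))
    if cap <= 0:
        return 0
    return int(rng.integers(0, cap + 1))


def simulate_rearrangement(ref: GermlineReference, class_label: str,
                           rng: np.random.Generator,
                           params: SimulationParams) -> GroundTruthRearrangement:
    """Draw one rearrangement of the given junction class.

    Genes are picked uniformly among eligible segments, junctional trimming
    uniformly on [0, deletion_max] (never cutting a segment below its
    alignable minimum), the inserted N region geometrically with the
    configured mean; complete V(D)J classes embed a doubly-trimmed D slice
    inside the N region, whose bases count toward ndn_length.  The truth
    annotation (canonical segmentation, junction, productivity) is derived
    by the annotator's own junction builder on the assembled sequence.
    """
    if class_label not in _RECIPES:
        raise ValueError(f"unknown junction class {class_label!r}")
    (l5, t5, p5), (l3, t3, p3), d_locus = _RECIPES[class_label]
    fives = ref.select(locus=l5, segment_type=t5, name_prefix=p5)
    threes = ref.select(locus=l3, segment_type=t3, name_prefix=p3)
    if not fives or not threes:
        raise ValueError(
            f"reference lacks segments for class {class_label}"
        )
    five = fives[int(rng.integers(len(fives)))]
    three_pool = [s for s in threes if s.name != five.name] or threes
    three = three_pool[int(rng.integers(len(three_pool)))]

    f_del = _draw_deletion(rng, five.length, params.deletion_max)
    t_del = _draw_deletion(rng, three.length, params.deletion_max)

    if d_locus is not None:
        d_pool = ref.select(locus=d_locus, segment_type=D)
        d_seg = d_pool[int(rng.integers(len(d_pool)))]
        d5 = int(rng.integers(0, params.deletion_max + 1))
        d3 = int(rng.integers(0, params.deletion_max + 1))
        d_slice = d_seg.sequence[d5:max(d5, d_seg.length - d3)]
        half = params.ndn_mean / 2.0
        ndn_seq = (_random_bases(rng, _draw_ndn_length(rng, half)) + d_slice
                   + _random_bases(rng, _draw_ndn_length(rng, half)))
    else:
        ndn_seq = _random_bases(rng, _draw_ndn_length(rng, params.ndn_mean))

    v_part = five.sequence[:five.length - f_del]
    j_part = three.sequence[t_del:]
    assembled = v_part + ndn_seq + j_part

    five_res = _diagonal_align(assembled, five.sequence, 0)
    diag3 = len(v_part) + len(ndn_seq) - t_del
    three_res = _diagonal_align(assembled, three.sequence, diag3)
    if five_res is None or three_res is None:  # pragma: no cover - by construction
        raise RuntimeError("truth alignment failed")
    five_aln = SegmentAlignment(five, 0, five_res[1], five_res[2],
                                five_res[1], five_res[2], five_res[0],
                                five_res[3])
    three_aln = SegmentAlignment(three, 0, three_res[1], three_res[2],
                                 three_res[1] - diag3, three_res[2] - diag3,
                                 three_res[0], three_res[3])
    rearr = build_rearrangement([assembled], five_aln, three_aln)
    if rearr.damaged:  # pragma: no cover - by construction
        raise RuntimeError("truth annotation unexpectedly damaged")

    # junction window in assembled coordinates, for read placement
    raw_gap = three_aln.read_start - five_aln.read_end
    v_end = five_aln.read_end
    j_start = three_aln.read_start if raw_gap >= 0 else five_aln.read_end
    v_phase = None
    if rearr.junction_class.category == COMPLETE_VJ:
        v_phase = five.frame_anchor % 3
    ws, we = junction_window(v_end, j_start, v_phase)

    return GroundTruthRearrangement(
        truth_id="", case_id="",
        rearrangement=rearr,
        full_sequence=assembled,
        window_start=ws, window_end=we,
        raw_five_del=f_del, raw_ndn=ndn_seq, raw_three_del=t_del,
        v_anchor_pos=five.frame_anchor if five.segment_type == V else None,
        j_anchor_pos=(diag3 + three.frame_anchor
                      if three.segment_type == J else None),
        five_span=(five_aln.read_start, five_aln.read_end),
        three_span=(three_aln.read_start, three_aln.read_end),
        five_type=five.segment_type,
        three_type=three.segment_type,
    )


def expression_level(truth: GroundTruthRearrangement | Rearrangement,
                     params: SimulationParams) -> float:
    """Relative transcription rate of a rearrangement.

    Productive complete joints transcribe at ``productive_rate``;
    unproductive complete joints at the sterile rate; incomplete, "other"
    and non-coding joints at the incomplete rate.
    """
    r = truth.rearrangement if isinstance(truth, GroundTruthRearrangement) else truth
    if r.junction_class.category == COMPLETE_VJ:
        if r.productivity == PRODUCTIVE:
            return params.productive_rate
        return params.sterile_rate
    return params.incomplete_rate


def _add_context(truth: GroundTruthRearrangement, rng: np.random.Generator,
                 context_length: int) -> None:
    """Pad the assembled sequence into a junction-centered transcript context."""
    wc = (truth.window_start + truth.window_end) // 2
    up = max(0, context_length // 2 - wc)
    down = max(0, context_length - up - len(truth.full_sequence))
    truth.context_sequence = (_random_bases(rng, up) + truth.full_sequence
                              + _random_bases(rng, down))
    truth.context_offset = up


def _conditioned_rearrangement(ref, label, rng, params,
                               want: str | None) -> GroundTruthRearrangement:
    """Draw a rearrangement, resampling until productivity matches `want`."""
    for _ in range(2000):
        truth = simulate_rearrangement(ref, label, rng, params)
        if want is None or truth.rearrangement.productivity == want:
            return truth
    raise RuntimeError(  # pragma: no cover - astronomically unlikely
        f"could not draw a {want} rearrangement of class {label}"
    )


def simulate_case(ref: GermlineReference, params: SimulationParams,
                  rng: np.random.Generator, case_id: str) -> SimulatedCase:
    """Simulate the ground truth of one case: clonal joints per the clonal
    plan plus a polyclonal background with the configured productive
    fraction among coding joints.  Clonal identity keys are distinct
    within the case."""
    case = SimulatedCase(case_id=case_id,
                         blast_fraction=_draw_blast(rng, params))
    seen_keys: set = set()
    idx = 0
    for spec in params.clonal_plan:
        jc = CLASS_BY_LABEL[spec.class_label]
        for _ in range(spec.count):
            want = None
            if (spec.unproductive_prob is not None
                    and jc.category == COMPLETE_VJ):
                want = (UNPRODUCTIVE
                        if rng.random() < spec.unproductive_prob
                        else PRODUCTIVE)
            for _ in range(200):
                truth = _conditioned_rearrangement(ref, spec.class_label, rng,
                                                   params, want)
                if truth.key not in seen_keys:
                    break
            seen_keys.add(truth.key)
            truth.truth_id = f"{case_id}.c{idx:03d}"
            truth.case_id = case_id
            truth.is_clonal = True
            truth.cell_fraction = case.blast_fraction
            idx += 1
            case.truth.append(truth)

    labels = [label for label, _ in params.background_class_weights]
    weights = np.array([w for _, w in params.background_class_weights])
    weights = weights / weights.sum()
    bpf = params.background_productive_fraction
    n_bg = params.background_size
    for b in range(n_bg):
        label = labels[int(rng.choice(len(labels), p=weights))]
        jc = CLASS_BY_LABEL[label]
        want = None
        if jc.category == COMPLETE_VJ:
            want = PRODUCTIVE if rng.random() < bpf else UNPRODUCTIVE
        elif jc.category == INCOMPLETE_DJ:
            want = (POTENTIALLY_PRODUCTIVE if rng.random() < bpf
                    else UNPRODUCTIVE)
        truth = _conditioned_rearrangement(ref, label, rng, params, want)
        truth.truth_id = f"{case_id}.b{b:03d}"
        truth.case_id = case_id
        truth.is_clonal = False
        truth.cell_fraction = (1.0 - case.blast_fraction) / max(1, n_bg)
        case.truth.append(truth)

    for truth in case.truth:
        truth.expression_rate = expression_level(truth, params)
        _add_context(truth, rng, params.context_length)
    return case


def _draw_blast(rng: np.random.Generator, params: SimulationParams) -> float:
    b0, c = params.blast_fraction, params.blast_concentration
    if b0 <= 0 or b0 >= 1:
        return float(b0)
    return float(rng.beta(b0 * c, (1 - b0) * c))


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        alts = [b for b in "ACGT" if b != cur]
        arr[i] = alts[int(rng.integers(3))].encode()
    return arr.tobytes().decode()


# --------------------------------------------------------------------------
# platform read simulation

def simulate_dnaamp_reads(case: SimulatedCase,
                          tubes: tuple[TubeDefinition, ...],
                          params: SimulationParams,
                          rng: np.random.Generator
                          ) -> dict[str, list[tuple[str, str, str]]]:
    """Per-tube amplicon reads: {tube name: [(id, comment, sequence)]}.

    Reads are sampled multinomially over the tube's amplifiable
    rearrangements: the case's blast fraction is split over clonal joints
    and the remainder over background joints.  Every read covers the full
    junction window plus a fixed amplicon flank; strand is random.  Read
    comments carry ``case|tube|truth_id``.
    """
    out: dict[str, list[tuple[str, str, str]]] = {}
    for tube in tubes:
        eligible = [t for t in case.truth
                    if t.rearrangement.junction_class.label in tube.target_classes]
        reads: list[tuple[str, str, str]] = []
        out[tube.name] = reads
        if not eligible:
            warnings.warn(f"tube {tube.name}: no eligible rearrangement in "
                          f"case {case.case_id}", stacklevel=2)
            continue
        if params.dnaamp_depth_per_tube <= 0:
            continue
        clonal = [t for t in eligible if t.is_clonal]
        background = [t for t in eligible if not t.is_clonal]
        bf = case.blast_fraction if clonal and background else (
            1.0 if clonal else 0.0)
        w = np.array(
            [bf / len(clonal) if t.is_clonal
             else (1.0 - bf) / max(1, len(background))
             for t in eligible])
        w = w / w.sum()
        counts = rng.multinomial(params.dnaamp_depth_per_tube, w)
        safe_tube = tube.name.replace("/", "+")
        for truth, n in zip(eligible, counts):
            if n == 0:
                continue
            lo = max(0, truth.window_start - params.amplicon_flank)
            hi = min(len(truth.full_sequence),
                     truth.window_end + params.amplicon_flank)
            amplicon = truth.full_sequence[lo:hi]
            flips = rng.random(n) < 0.5
            for i in range(n):
                seq = amplicon
                if params.error_rate > 0:
                    seq = _mutate(seq, rng, params.error_rate)
                if flips[i]:
                    seq = revcomp(seq)
                rid = f"{case.case_id}:{safe_tube}:{truth.truth_id}:{i}"
                comment = f"{case.case_id}|{tube.name}|{truth.truth_id}"
                reads.append((rid, comment, seq))
    return out


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _fragment_truth(truth: GroundTruthRearrangement, s: int, L: int, R: int,
                    merge_min_overlap: int, min5: int, min3: int) -> dict:
    """Per-fragment coverage/observability truth.

    ``window_covered`` is pure geometry: the junction window lies inside a
    single read (or inside the fragment when the mates overlap enough to
    merge).  ``damaged`` additionally emulates the score-maximizing
    aligner: each read region scores by how much of the canonical 5'/3'
    segment spans it contains, the best acceptable (5', 3') region pair is
    chosen, and the fragment counts as intact only when that pair sits in
    one region that also contains the whole window.  Fragments with no
    acceptable pair are unobservable and carry damaged=False (vacuous).
    """
    off = truth.context_offset
    w0, w1 = truth.window_start + off, truth.window_end + off
    v0, v1 = truth.five_span[0] + off, truth.five_span[1] + off
    j0, j1 = truth.three_span[0] + off, truth.three_span[1] + off

    contains = w0 >= s and w1 <= s + L
    merged = 2 * R - L >= merge_min_overlap
    if merged:
        regions = [(s, s + L)]
    else:
        regions = [(s, s + min(L, R)), (s + max(0, L - R), s + L)]
    covered_single = any(w0 >= r0 and w1 <= r1 for r0, r1 in regions)
    window_covered = covered_single or (merged and contains)

    best = None  # (score, resolved)
    for ai, (a0, a1) in enumerate(regions):
        vlen = _overlap(v0, v1, a0, a1)
        if vlen < min5:
            continue
        for bi in range(ai, len(regions)):
            b0, b1 = regions[bi]
            jlen = _overlap(j0, j1, b0, b1)
            if jlen < min3:
                continue
            resolved = ai == bi and w0 >= a0 and w1 <= a1
            cand = (vlen + jlen, resolved)
            if best is None or cand > best:
                best = cand
    observable = best is not None
    damaged = observable and not best[1]
    return {"contains_junction": contains, "window_covered": window_covered,
            "observable": observable, "damaged": damaged}


def simulate_rnaseq_reads(case: SimulatedCase, params: SimulationParams,
                          rng: np.random.Generator,
                          ann_params=None):
    """Paired RNAseq reads plus a per-fragment truth table.

    Returns ``(pairs, fragments)`` where ``pairs`` is a list of
    ``((id1, comment, seq1), (id2, comment, seq2))`` and ``fragments`` a
    list of dicts recording, per fragment, whether it contains the
    junction window, whether the window is inside read coverage, and the
    truth *damaged* flag (see :func:`_fragment_truth`).  ``ann_params``
    supplies the aligner's acceptance minima the observability emulation
    mirrors (defaults match the annotator's defaults).
    """
    weights = np.array([t.cell_fraction * t.expression_rate
                        for t in case.truth])
    total = weights.sum()
    pairs = []
    fragments = []
    if total <= 0 or params.rnaseq_fragments <= 0:
        if total <= 0:
            warnings.warn(f"case {case.case_id}: all transcription rates are "
                          "zero; no RNAseq output", stacklevel=2)
        return pairs, fragments
    if ann_params is None:
        from .annotate import AnnotationParams
        ann_params = AnnotationParams()
    counts = rng.multinomial(params.rnaseq_fragments, weights / total)
    R = params.read_length
    frag_idx = 0
    for truth, n in zip(case.truth, counts):
        ctx = truth.context_sequence
        min5 = ann_params.min_match(truth.five_type)
        min3 = ann_params.min_match(truth.three_type)
        for _ in range(n):
            L = 0
            while L < params.fragment_length_min:
                L = int(round(rng.normal(params.fragment_length_mean,
                                         params.fragment_length_sd)))
            L = min(L, len(ctx))
            s = int(rng.integers(0, len(ctx) - L + 1))
            frag = ctx[s:s + L]
            if params.error_rate > 0:
                frag = _mutate(frag, rng, params.error_rate)
            r1 = frag[:R]
            r2 = revcomp(frag[max(0, L - R):])
            flags = _fragment_truth(truth, s, L, R,
                                    params.merge_min_overlap, min5, min3)
            fid = f"{case.case_id}:rna:{frag_idx:06d}"
            comment = f"{case.case_id}|RNAseq|{truth.truth_id}"
            pairs.append(((f"{fid}/1", comment, r1), (f"{fid}/2", comment, r2)))
            fragments.append({"fragment_id": fid, "truth_id": truth.truth_id,
                              "start": s, "length": L, **flags})
            frag_idx += 1
    return pairs, fragments


def simulate_cohort(ref: GermlineReference,
                    params: SimulationParams) -> list[SimulatedCase]:
    """Simulate the ground truth for all cases of the cohort."""
    cases = []
    for i, (rng_truth, _, _) in enumerate(case_rngs(params, params.n_cases)):
        cases.append(simulate_case(ref, params, rng_truth, f"case{i + 1:03d}"))
    return cases


def case_rngs(params: SimulationParams, n_cases: int):
    """Per-case (truth, dnaamp, rnaseq) generators from the single seed,
    so pipeline stages are individually re-runnable with stable results."""
    root = np.random.SeedSequence(params.rng_seed)
    out = []
    for child in root.spawn(n_cases):
        sub = child.spawn(3)
        out.append(tuple(np.random.default_rng(s) for s in sub))
    return out
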