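# Methods

This note documents the models, conventions and numerical choices behind
`clonemark`, in enough detail to reproduce or deliberately change them.

## Rearrangement model

A rearrangement joins a 5' germline element to a 3' germline element with
junctional processing between them: exonucleolytic trimming of each
segment end and insertion of non-templated (N) nucleotides, plus — for
complete V(D)J joints — a doubly-trimmed D-segment slice whose bases are
counted inside the N-(D)-N length rather than called as a separate gene.
Twenty-two junction classes over the seven loci are recognized (see
`classes.py`); the TRD D-gene-specific classes dispatch on gene name
(TRDD2 vs TRDD3, TRDJ1), and the cross-locus TRA/TRD hybrid joints form
the `TRA+D` group.

**Identity key.** `(class, 5' gene, 5' deletions, N-(D)-N length,
3' deletions, 3' gene, junction amino acids)`. The key deliberately
excludes the junction nucleotide string (amino acids are what the
downstream comparisons key on; nucleotides are retained in tables for
diagnostics) and excludes abundance.

**Junction window.** The junction nucleotide sequence spans from 3 codons
upstream of the 5' segment's last aligned base to 3 codons downstream of
the 3' segment's first aligned base. For V-anchored (complete) joints the
window start is shifted down to a codon boundary of the V reading frame
and the end padded up to a codon boundary, so translating the window at
offset 0 reads the V frame. A fixed, platform-independent window makes
identity keys reproducible across amplicon and RNAseq data.

**Frame anchors.** V and J segments carry an explicit 0-based offset of
their reading frame. A complete joint is in frame iff the V-anchor and
J-anchor positions are congruent mod 3 in the assembled sequence. Anchors
are stored rather than inferred from conserved residues because synthetic
segments have no biological Cys/Trp motifs; converting a curated germline
set to this format is a documented one-off transformation.

**Productivity.** Complete V-J: productive iff in frame and the junction
window is stop-free, else unproductive. Incomplete D-J: potentially
productive iff the window is stop-free in the J frame, else unproductive.
V-D, D-D and the non-coding IGK joints (Vk-Kde, intron-Kde), and all
damaged records: unknown. The toy reference generates V and J bodies
stop-free in their anchored frames, so any stop in a simulated joint
necessarily involves junctional bases — which the window provably
contains; the window rule is therefore exactly equivalent to translating
the whole V→J span (the test suite checks this equivalence against a
brute-force translation oracle).

## Synthetic cohort

The generator's defaults are the study conditions for every test.

* **Clonal plan** (per case): 2× complete IGH (unproductive with
  probability 0.7 — the hallmark of ALL clones), 1× IGH D-J, 1× IGK V-J,
  1× Vk-Kde, 1× complete TRB, TRG and TRD each. The plan is a plausible
  B-ALL-like profile, fully configurable; it is not a cohort estimate.
* **Background**: 150 polyclonal rearrangements per case, ~85% complete
  V-J across the loci with a thin tail of incomplete and non-coding
  joints; coding background is productive (complete) or potentially
  productive (D-J) with probability 0.98, matching the observation that
  the vast majority of non-leukemic background is productive.
  Productivity conditioning is by rejection sampling, so junction
  statistics stay those of the unconditioned model.
* **Junction statistics**: deletions uniform on [0, 10] per segment end
  (never trimming a segment below 12 alignable nt), N-region length
  geometric with mean 8 (split around the embedded D slice for complete
  joints), N bases uniform over ACGT.
* **Abundance**: each case draws a blast fraction from Beta(90, 10)
  (mean 0.9); clonal joints share it, background shares the rest.
* **DNAamp**: 300 reads per primer tube, multinomial over the tube's
  amplifiable joints; each amplicon covers the junction window plus a
  40 nt flank on both sides (so reads are never damaged), random strand.
  Tube definitions mirror the standard eight-tube multiplex design; IGL
  and TRA V-J joints belong to no tube, and the TRD tube carries the
  TRD-segment joints plus the cross-locus hybrids its primers reach
  (Vd-(Dd)-Ja, Dd-Ja, Va-Jd). Dd3-Jd, Dd3-Dd2 and Va-Dd are treated as
  amplicon-undetectable.
* **RNAseq**: three-tier transcription — productive complete joints at
  rate 1.0, unproductive complete joints at the *sterile* rate 0.01,
  incomplete/other/non-coding joints at 0.001. The direction (sterile and
  incomplete transcription are weak) is biology; the magnitudes are model
  choices made once so that the simulated cohort reproduces the
  qualitative platform contrast. 3000 fragments per case are drawn
  proportional to cell fraction × rate from a 600 nt junction-centered
  transcript context, with truncated-normal lengths (mean 250, sd 50,
  min 150) and uniform placement; 2×75 bp mates are cut from the fragment
  ends. Sequencing error is off by default (an optional uniform
  substitution rate exists); indels are not modeled.
* **Damaged truth.** Each fragment records (a) whether it contains the
  junction window, (b) whether the window lies inside single-read
  coverage (pure geometry; used for the analytic coverage checks), and
  (c) an *observability* flag that emulates the score-maximizing aligner:
  each mate scores by how much of the canonical 5'/3' segment span it
  covers, the best acceptable pair of mates is chosen, and the fragment
  is intact only if that pair lies in one mate that contains the whole
  window. Flag (c) is the simulator's truth for the annotator's damaged
  flag; agreement is evaluated over fragments annotated to their true
  class and gene pair, because a fragment annotated to a different joint
  (e.g. the D-J portion of a V(D)J fragment whose V lies outside
  coverage) describes a different junction.

Ground-truth annotations are derived by running the assembled sequence
through the annotator's own junction builder, so the truth key is
*canonical*: junctional bases that happen to match the germline
continuation of a segment are assigned to that segment the same way the
aligner assigns them on reads. Without this, chance matches at junction
boundaries would make truth and read-derived keys disagree on a few
percent of joints.

## Annotation

* **Seeding**: exact 10-mers against all germline segments; a diagonal
  needs ≥ 3 seed hits (i.e. a ≥ 12 nt exact stretch) to be evaluated,
  which keeps the false-positive rate on random 150-mers below 1%.
* **Scoring**: gapless local alignment along the seeded diagonal
  (+1 match, −2 mismatch), maximal stretch by a Kadane scan with
  strictly-improving maxima. Endpoints are therefore independent of how
  much matching context precedes the stretch — the property that keeps
  truth and read annotations consistent. Gapless scoring is exact for
  the substitution-only error model; the `band` parameter is reserved
  for future indel-tolerant extension.
* **Acceptance**: identity ≥ 0.9 and role minima — V ≥ 20 nt,
  J/Kde/intronRSS ≥ 12 nt, D ≥ 12 nt (the simulator never trims a
  segment below 12 nt, so every simulated joint stays alignable).
* **Pair selection**: among classifiable (5', 3') candidates in valid
  order, maximize total score, then total length, then category priority
  (complete > D-J > V-D > other), then lexicographic gene names.
* **Micro-homology**: when the 5' and 3' alignments overlap on the read,
  the shared bases are ceded to the 5' segment — N-(D)-N clamps to 0 and
  the 3' deletion grows by the overlap. The same canonicalization runs in
  the simulator's truth derivation.
* **Strand and mates**: both strands are tried (a cheap seed-count screen
  picks the orientation, evaluating both on ties); mates merge when they
  overlap ≥ 20 nt with ≤ 2 mismatches, otherwise they are annotated
  jointly with the 5' element allowed on mate 1 and the 3' on mate 2.
* **Damaged records**: when the junction window is not fully inside one
  covered region the record is damaged: empty junction, unknown
  productivity, and segmentation fields set only where the coverage
  determined them (a partial identity key).
* **De-duplication**: DNAamp counts reads per key; RNAseq counts distinct
  fragments (identified by the mate sequence pair). Damaged and intact
  records never merge. Output order: descending count, then key — fully
  deterministic and independent of input order.

## Markers and concordance

* The 5% abundance denominator is the tube's total annotated,
  uniqueness-surviving reads (the definition is stated here because the
  wording "5% of reads per tube" leaves the denominator open; totals are
  stored alongside fractions). Bounds are inclusive: exactly 10 reads or
  exactly 5% passes. Thresholds apply jointly per tube, not per class.
* The uniqueness filter runs per platform over undamaged keys; damaged
  records carry partial keys and are exempt (they neither trigger nor
  suffer removal). The filter is idempotent.
* RNAseq candidates are collected at any abundance by default; when the
  amplicon thresholds are switched on for the per-case comparison, the
  denominator is the key's locus group (RNAseq has no tubes). Damaged
  records are never candidates.
* Matching is exact-key by default. The permissive mode
  (`allow_damaged_partial`) additionally accepts a damaged record
  agreeing on class, both genes and every determined segmentation field;
  it exists to quantify how much partial junctions could contribute, not
  to guess any particular production pipeline's behavior. Whether two
  platforms have "identical marker profiles" is evaluated as set equality
  of identity keys.
* Percentages are reported to one decimal; classes no tube amplifies
  render as `na`.

## Problem sizes and determinism

The default study conditions — 20 cases, 150 background joints, 300 reads
per tube, 3000 RNAseq fragments per case — are the sizes at which the
test suite and `scripts/acceptance.py` run the cohort analysis; they give
~32k clonal amplicon reads and ~21k comparable RNAseq fragments, enough
for the recovery and agreement statistics to be stable at the percent
level. All randomness flows from one seed through spawned per-case,
per-stage generators, so each pipeline stage is individually re-runnable
and every artifact is byte-reproducible; identical configurations yield
identical manifests up to timestamps.

## Limitations

* The toy germline reference is random sequence: no somatic
  hypermutation, no allelic series, no conserved junction motifs, and no
  cross-segment homology. Passing tests demonstrate the pipeline's
  internal correctness and the direction of platform effects, not
  performance on curated human references or real reads.
* The aligner is substitution-only; indel sequencing errors and gapped
  alignment are out of scope.
* The transcription model has three flat tiers; real sterile transcription
  varies by locus and developmental stage.
* PCR amplification bias, chimeras, UMIs and quality-score realism are
  not modeled; amplicon depth is multinomial.
* Marker quality grading (e.g. V-gene mutation risk) and assay
  sensitivity prediction are out of scope.
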