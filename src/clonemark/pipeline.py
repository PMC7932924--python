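"""Pipeline orchestration: simulate -> annotate -> markers -> compare.

Each stage consumes only the configuration and the previous stage's files
in the run directory, so stages are individually re-runnable.  A manifest
records the configuration hash, seed, package versions and per-stage row
counts; with a fixed seed the entire run directory is reproducible
byte-for-byte (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import AnnotatedRead, AnnotationParams, Annotator
from .concordance import (
    EXACT_KEY,
    MATCH_MODES,
    marker_count_histogram,
    match_markers,
    render_class_table,
    summarize_by_class,
    summarize_per_case,
)
from .germline import GermlineReference, build_toy_reference, load_germline_reference
from .io import (
    frame_to_tsv,
    read_fastq,
    records_to_frame,
    truth_to_frame,
    tsv_to_frame,
    write_fastq,
)
from .markers import (
    MarkerThresholds,
    apply_uniqueness_filter,
    identify_dnaamp_markers,
    identify_rnaseq_rearrangements,
)
from .simulate import (
    DEFAULT_TUBES,
    DNAAMP,
    RNASEQ,
    SimulationParams,
    case_rngs,
    simulate_case,
    simulate_dnaamp_reads,
    simulate_rnaseq_reads,
)

log = logging.getLogger("clonemark")

STAGES = ("simulate", "annotate", "markers", "compare")


class PipelineError(RuntimeError):
    """A stage failed or its inputs are missing."""


@dataclass
class RunConfig:
    """Everything a full run needs."""

    out_dir: str
    reference_path: str | None = None  # None -> toy reference from the seed
    toy_segments_per_type: int = 3
    seed: int = 0
    sim: SimulationParams = field(default_factory=SimulationParams)
    ann: AnnotationParams = field(default_factory=AnnotationParams)
    thresholds: MarkerThresholds = field(default_factory=MarkerThresholds)
    match_mode: str = EXACT_KEY
    plot: bool = False  # also write the per-class marker bar chart
    log_level: str = "INFO"

    def __post_init__(self):
        if self.match_mode not in MATCH_MODES:
            raise ValueError(f"unknown match mode {self.match_mode!r}")
        self.sim = replace(self.sim, rng_seed=self.seed)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        for key, typ in (("sim", SimulationParams), ("ann", AnnotationParams),
                         ("thresholds", MarkerThresholds)):
            if key in raw and isinstance(raw[key], dict):
                sub = raw[key]
                if key == "sim" and "clonal_plan" in sub:
                    from .simulate import ClonalSpec
                    sub["clonal_plan"] = tuple(
                        ClonalSpec(**e) for e in sub["clonal_plan"])
                if key == "sim" and "background_class_weights" in sub:
                    sub["background_class_weights"] = tuple(
                        (k, float(v))
                        for k, v in sub["background_class_weights"].items())
                try:
                    raw[key] = typ(**sub)
                except TypeError as e:
                    raise PipelineError(f"config section {key!r}: {e}") from e
        try:
            return cls(**raw)
        except TypeError as e:
            raise PipelineError(f"config: {e}") from e

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tube_filename(tube_name: str) -> str:
    return tube_name.replace("/", "+")


def _tube_from_filename(stem: str) -> str:
    return stem.replace("+", "/")


def _case_dirs(out: Path) -> list[Path]:
    reads = out / "reads"
    if not reads.is_dir():
        return []
    return sorted(p for p in reads.iterdir() if p.is_dir())


def _load_reference(config: RunConfig, out: Path) -> GermlineReference:
    ref_fa = out / "reference.fasta"
    if ref_fa.exists():
        return load_germline_reference(ref_fa)
    if config.reference_path:
        return load_germline_reference(config.reference_path)
    return build_toy_reference(config.seed, config.toy_segments_per_type)


# --------------------------------------------------------------------------
# stages

def _stage_simulate(config: RunConfig, out: Path, counts: dict) -> None:
    ref = (load_germline_reference(config.reference_path)
           if config.reference_path
           else build_toy_reference(config.seed, config.toy_segments_per_type))
    ref.save(out / "reference.fasta")
    params = config.sim
    n_truth = n_reads = 0
    for i, (rng_t, rng_d, rng_r) in enumerate(case_rngs(params, params.n_cases)):
        case_id = f"case{i + 1:03d}"
        case = simulate_case(ref, params, rng_t, case_id)
        cdir = out / "reads" / case_id
        cdir.mkdir(parents=True, exist_ok=True)
        frame_to_tsv(truth_to_frame(case), cdir / "truth.tsv")
        by_tube = simulate_dnaamp_reads(case, DEFAULT_TUBES, params, rng_d)
        for tube_name, reads in by_tube.items():
            write_fastq(reads, cdir / f"dnaamp_{_tube_filename(tube_name)}.fastq")
            n_reads += len(reads)
        pairs, fragments = simulate_rnaseq_reads(case, params, rng_r)
        write_fastq([p[0] for p in pairs], cdir / "rnaseq_R1.fastq")
        write_fastq([p[1] for p in pairs], cdir / "rnaseq_R2.fastq")
        pd.DataFrame(fragments).to_csv(cdir / "fragments.tsv", sep="\t",
                                       index=False)
        n_truth += len(case.truth)
        n_reads += 2 * len(pairs)
        log.info("simulated %s: %d truth records, %d RNAseq fragments",
                 case_id, len(case.truth), len(pairs))
    counts["simulate"] = {"truth_records": n_truth, "reads": n_reads,
                          "cases": params.n_cases}


def _stage_annotate(config: RunConfig, out: Path, counts: dict) -> None:
    cdirs = _case_dirs(out)
    if not cdirs:
        raise PipelineError("annotate: no simulated reads found "
                            "(run the simulate stage first)")
    ref = _load_reference(config, out)
    annotator = Annotator(ref, config.ann)
    adir = out / "annotated"
    adir.mkdir(parents=True, exist_ok=True)
    n_rows = 0
    for cdir in cdirs:
        case_id = cdir.name
        dna_records: list[AnnotatedRead] = []
        for fq in sorted(cdir.glob("dnaamp_*.fastq")):
            tube = _tube_from_filename(fq.stem[len("dnaamp_"):])
            for rid, _comment, seq in read_fastq(fq):
                res = annotator.annotate_read(seq)
                dna_records.append(AnnotatedRead(
                    read_id=rid, case_id=case_id, platform=DNAAMP, tube=tube,
                    rearrangement=res.rearrangement, reason=res.reason))
        rna_records: list[AnnotatedRead] = []
        r1_path, r2_path = cdir / "rnaseq_R1.fastq", cdir / "rnaseq_R2.fastq"
        if r1_path.exists():
            r1 = read_fastq(r1_path)
            r2 = read_fastq(r2_path)
            for (id1, _c1, s1), (id2, _c2, s2) in zip(r1, r2):
                res = annotator.annotate_pair((id1, s1), (id2, s2))
                rna_records.append(AnnotatedRead(
                    read_id=id1, case_id=case_id, platform=RNASEQ, tube=None,
                    rearrangement=res.rearrangement, reason=res.reason,
                    fragment_key=f"{s1}|{s2}"))
        from .annotate import deduplicate
        dna_df = records_to_frame(deduplicate(dna_records))
        rna_df = records_to_frame(deduplicate(rna_records))
        frame_to_tsv(dna_df, adir / f"{case_id}.dnaamp.tsv")
        frame_to_tsv(rna_df, adir / f"{case_id}.rnaseq.tsv")
        n_rows += len(dna_df) + len(rna_df)
        log.info("annotated %s: %d DNAamp / %d RNAseq rearrangements",
                 case_id, len(dna_df), len(rna_df))
    counts["annotate"] = {"rearrangement_rows": n_rows, "cases": len(cdirs)}


def _load_annotated(out: Path, platform: str,
                    subdir: str = "annotated") -> dict[str, pd.DataFrame]:
    adir = out / subdir
    suffix = ".dnaamp.tsv" if platform == DNAAMP else ".rnaseq.tsv"
    tables = {}
    for path in sorted(adir.glob(f"*{suffix}")):
        tables[path.name[:-len(suffix)]] = tsv_to_frame(path)
    return tables


def _stage_markers(config: RunConfig, out: Path, counts: dict) -> None:
    if not (out / "annotated").is_dir():
        raise PipelineError("markers: no annotated tables found "
                            "(run the annotate stage first)")
    mdir = out / "markers"
    fdir = out / "filtered"
    mdir.mkdir(parents=True, exist_ok=True)
    fdir.mkdir(parents=True, exist_ok=True)
    n_markers = 0
    for platform, suffix in ((DNAAMP, "dnaamp"), (RNASEQ, "rnaseq")):
        tables = _load_annotated(out, platform)
        filtered, removal_log = apply_uniqueness_filter(tables)
        frame_to_tsv(removal_log, mdir / f"removal_log.{suffix}.tsv")
        for case_id, df in filtered.items():
            frame_to_tsv(df, fdir / f"{case_id}.{suffix}.tsv")
            if platform == DNAAMP:
                cand = identify_dnaamp_markers(df, DEFAULT_TUBES,
                                               config.thresholds)
                frame_to_tsv(cand, mdir / f"{case_id}.dnaamp_markers.tsv")
            else:
                cand = identify_rnaseq_rearrangements(df, config.thresholds)
                frame_to_tsv(cand, mdir / f"{case_id}.rnaseq_candidates.tsv")
            n_markers += len(cand)
    counts["markers"] = {"candidate_rows": n_markers}


def _stage_compare(config: RunConfig, out: Path, counts: dict) -> None:
    mdir = out / "markers"
    if not mdir.is_dir():
        raise PipelineError("compare: no marker tables found "
                            "(run the markers stage first)")
    dna_tables = _load_annotated(out, DNAAMP, "filtered")
    rna_tables = _load_annotated(out, RNASEQ, "filtered")
    verdict_frames = []
    rna_candidates = {}
    for case_id, rna_df in rna_tables.items():
        marker_path = mdir / f"{case_id}.dnaamp_markers.tsv"
        if not marker_path.exists():
            raise PipelineError(f"compare: missing {marker_path.name}")
        markers_df = tsv_to_frame_markers(marker_path)
        verdict_frames.append(match_markers(markers_df, rna_df,
                                            config.match_mode))
        rna_candidates[case_id] = tsv_to_frame_markers(
            mdir / f"{case_id}.rnaseq_candidates.tsv")
    verdicts = (pd.concat(verdict_frames, ignore_index=True)
                if verdict_frames else pd.DataFrame())
    summary = summarize_by_class(dna_tables, rna_tables, verdicts)
    per_case = summarize_per_case(verdicts, rna_candidates,
                                  sorted(rna_tables))
    gdir = out / "concordance"
    gdir.mkdir(parents=True, exist_ok=True)
    summary.per_class.reset_index().to_csv(gdir / "per_class.tsv", sep="\t",
                                           index=False)
    per_case.to_csv(gdir / "per_case.tsv", sep="\t", index=False)
    overall = dict(summary.overall)
    overall["dnaamp_marker_histogram"] = marker_count_histogram(
        per_case, "dnaamp_markers")
    overall["recovered_marker_histogram"] = marker_count_histogram(
        per_case, "recovered_markers")
    with open(gdir / "overall.json", "w") as fh:
        json.dump(overall, fh, indent=2, default=float)
    summary.per_case = per_case
    with open(gdir / "class_table.txt", "w") as fh:
        fh.write(render_class_table(summary) + "\n")
    if config.plot:
        from .concordance import plot_class_recovery
        plot_class_recovery(summary, gdir / "class_recovery.png")
    counts["compare"] = {"markers": int(summary.overall["dnaamp_markers"]),
                         "recovered": int(summary.overall["rnaseq_recovered"])}


def tsv_to_frame_markers(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"junction_aa": str, "tube": str,
                                            "case_id": str})
    for c in ("five_del", "np_total", "three_del"):
        if c in df.columns:
            df[c] = df[c].astype("Int64")
    if "junction_aa" in df.columns:
        df["junction_aa"] = df["junction_aa"].fillna("")
    return df


def run_pipeline(config: RunConfig,
                 stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in order; returns the run directory."""
    bad = set(stages) - set(STAGES)
    if bad:
        raise PipelineError(f"unknown stage(s): {sorted(bad)}")
    logging.basicConfig(stream=sys.stderr,
                        level=getattr(logging, config.log_level.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    runners = {"simulate": _stage_simulate, "annotate": _stage_annotate,
               "markers": _stage_markers, "compare": _stage_compare}
    for stage in STAGES:
        if stage in stages:
            log.info("stage %s", stage)
            runners[stage](config, out, counts)
    manifest_path = out / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest.setdefault("stage_counts", {}).update(counts)
    manifest.update({
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "versions": {
            "clonemark": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    })
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return out
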