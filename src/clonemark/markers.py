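"""Candidate MRD marker identification.

A clone-specific rearrangement is usable as a minimal-residual-disease
marker when it is abundant at diagnosis and not an artefact.  Two filters
implement this:

* **Uniqueness across cases** — any identity key observed in more than one
  case of a cohort is removed from every case, to guard against
  contamination and recurrent artefacts.
* **Abundance thresholds** (amplicon data) — a candidate needs at least
  ``min_reads`` reads *and* at least ``min_fraction`` of all annotated
  reads of its primer-set tube (defaults 10 reads and 5%, inclusive).

RNAseq rearrangements are by default collected at any abundance (the
denominator question for whole-transcriptome marker screening is open);
optionally the same thresholds can be applied with per-locus denominators,
since RNAseq has no primer tubes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import row_key
from .simulate import DEFAULT_TUBES, TubeDefinition


@dataclass(frozen=True)
class MarkerThresholds:
    """Abundance thresholds for marker candidacy (inclusive bounds)."""

    min_reads: int = 10
    min_fraction: float = 0.05
    apply_to_rnaseq: bool = False

    def __post_init__(self):
        if self.min_reads < 0:
            raise ValueError("min_reads must be >= 0")
        if not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must be in [0, 1]")


MARKER_COLUMNS = [
    "case_id", "platform", "tube", "junction_class", "five_gene", "five_del",
    "np_total", "three_del", "three_gene", "junction_aa", "count", "fraction",
]


def apply_uniqueness_filter(
    tables: dict[str, pd.DataFrame],
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Remove identity keys observed in more than one case.

    `tables` maps case id to that case's rearrangement table (one
    platform).  Damaged records carry partial keys and are exempt: they
    neither trigger nor suffer removal.  Returns the filtered tables and a
    removal log (one row per removed key with the cases involved).
    The filter is idempotent.
    """
    key_cases: dict = {}
    for case_id, df in tables.items():
        for _, row in df.iterrows():
            if row["damaged"]:
                continue
            key_cases.setdefault(row_key(row), set()).add(case_id)
    shared = {k for k, cases in key_cases.items() if len(cases) > 1}

    filtered = {}
    removed_rows = []
    for case_id, df in tables.items():
        if not len(df):
            filtered[case_id] = df.copy()
            continue
        keep = []
        for _, row in df.iterrows():
            k = row_key(row)
            drop = (not row["damaged"]) and k in shared
            keep.append(not drop)
        filtered[case_id] = df[pd.Series(keep, index=df.index)].reset_index(drop=True)
    for k in sorted(shared, key=lambda k: tuple("" if c is None else str(c) for c in k)):
        removed_rows.append({
            "junction_class": k.junction_class, "five_gene": k.five_gene,
            "five_del": k.five_del, "np_total": k.ndn_length,
            "three_del": k.three_del, "three_gene": k.three_gene,
            "junction_aa": k.junction_aa,
            "cases": ",".join(sorted(key_cases[k])),
        })
    log = pd.DataFrame(removed_rows, columns=[
        "junction_class", "five_gene", "five_del", "np_total", "three_del",
        "three_gene", "junction_aa", "cases"])
    return filtered, log


def _candidate_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MARKER_COLUMNS)
    for c in ("five_del", "np_total", "three_del"):
        df[c] = df[c].astype("Int64")
    if len(df):
        df = df.sort_values(
            ["fraction", "count", "junction_class", "five_gene", "three_gene"],
            ascending=[False, False, True, True, True],
        ).reset_index(drop=True)
    return df


def identify_dnaamp_markers(
    case_table: pd.DataFrame,
    tubes: tuple[TubeDefinition, ...] = DEFAULT_TUBES,
    thresholds: MarkerThresholds = MarkerThresholds(),
) -> pd.DataFrame:
    """Marker candidates of one case from its amplicon table.

    Fractions are computed within each key's tube, over all annotated
    reads of that tube surviving the uniqueness filter.  Both bounds are
    inclusive: exactly ``min_reads`` reads or exactly ``min_fraction`` of
    the tube passes.
    """
    known = {t.name for t in tubes}
    rows = []
    if len(case_table):
        bad = set(case_table["tube"].unique()) - known
        if bad:
            raise ValueError(f"unknown tube label(s): {sorted(bad)}")
        for tube, sub in case_table.groupby("tube"):
            total = int(sub["duplicate_count"].sum())
            if total == 0:
                continue
            for _, row in sub.iterrows():
                if row["damaged"]:
                    continue  # amplicon reads are never damaged by contract
                count = int(row["duplicate_count"])
                fraction = count / total
                if count >= thresholds.min_reads and fraction >= thresholds.min_fraction:
                    k = row_key(row)
                    rows.append({
                        "case_id": row["case_id"], "platform": "DNAamp",
                        "tube": tube, "junction_class": k.junction_class,
                        "five_gene": k.five_gene, "five_del": k.five_del,
                        "np_total": k.ndn_length, "three_del": k.three_del,
                        "three_gene": k.three_gene, "junction_aa": k.junction_aa,
                        "count": count, "fraction": fraction,
                    })
    return _candidate_frame(rows)


def identify_rnaseq_rearrangements(
    case_table: pd.DataFrame,
    thresholds: MarkerThresholds = MarkerThresholds(),
) -> pd.DataFrame:
    """RNAseq rearrangement candidates of one case.

    With ``apply_to_rnaseq=False`` every undamaged key is returned at any
    abundance; otherwise the amplicon thresholds are applied with
    per-locus denominators.  Damaged records are never candidates (their
    keys are partial); they participate only in permissive concordance
    matching.
    """
    rows = []
    if len(case_table):
        for locus, sub in case_table.groupby("locus"):
            total = int(sub.loc[~sub["damaged"], "duplicate_count"].sum())
            for _, row in sub.iterrows():
                if row["damaged"]:
                    continue
                count = int(row["duplicate_count"])
                fraction = count / total if total else 0.0
                if thresholds.apply_to_rnaseq:
                    if count < thresholds.min_reads or fraction < thresholds.min_fraction:
                        continue
                elif count < 1:  # pragma: no cover - counts are >= 1
                    continue
                k = row_key(row)
                rows.append({
                    "case_id": row["case_id"], "platform": "RNAseq",
                    "tube": locus, "junction_class": k.junction_class,
                    "five_gene": k.five_gene, "five_del": k.five_del,
                    "np_total": k.ndn_length, "three_del": k.three_del,
                    "three_gene": k.three_gene, "junction_aa": k.junction_aa,
                    "count": count, "fraction": fraction,
                })
    return _candidate_frame(rows)
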