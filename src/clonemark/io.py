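"""Tabular and read I/O.

Rearrangement tables are exchanged as AIRR-flavored TSV with one row per
de-duplicated rearrangement: identity-key columns (junction_class,
five_gene, five_del, np_total, three_del, three_gene, junction_aa) plus
locus, junction nucleotides, productivity, the damaged flag, the
de-duplicated count and provenance (case, platform, tube).  Missing
segmentation fields of damaged records are empty cells (nullable ints in
memory).
"""

from __future__ import annotations

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .annotate import AnnotatedRead
from .classes import CLASS_BY_LABEL
from .rearrangement import IdentityKey, Rearrangement

#: column order of the rearrangement TSV
COLUMNS = [
    "sequence_id", "case_id", "platform", "tube", "locus", "junction_class",
    "five_gene", "five_del", "np_total", "three_del", "three_gene",
    "junction", "junction_aa", "productivity", "damaged", "duplicate_count",
]

_INT_COLS = ["five_del", "np_total", "three_del"]


def write_fastq(reads, path) -> None:
    """Write reads given as (id, comment, sequence) triples; constant Q40."""
    with open(path, "w") as fh:
        for rid, comment, seq in reads:
            title = f"{rid} {comment}" if comment else rid
            fh.write(f"@{title}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str, str]]:
    """Read a FASTQ into (id, comment, sequence) triples."""
    out = []
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            rid, _, comment = title.partition(" ")
            out.append((rid, comment, seq))
    return out


def records_to_frame(records: list[AnnotatedRead]) -> pd.DataFrame:
    """De-duplicated annotated reads -> rearrangement table."""
    rows = []
    for rec in records:
        r = rec.rearrangement
        rows.append({
            "sequence_id": rec.read_id,
            "case_id": rec.case_id,
            "platform": rec.platform,
            "tube": rec.tube if rec.tube is not None else "",
            "locus": r.junction_class.locus_group,
            "junction_class": r.junction_class.label,
            "five_gene": r.five_gene,
            "five_del": r.five_del,
            "np_total": r.ndn_length,
            "three_del": r.three_del,
            "three_gene": r.three_gene,
            "junction": r.junction_nt,
            "junction_aa": r.junction_aa,
            "productivity": r.productivity,
            "damaged": r.damaged,
            "duplicate_count": r.count,
        })
    df = pd.DataFrame(rows, columns=COLUMNS)
    for c in _INT_COLS:
        df[c] = df[c].astype("Int64")
    if len(df):
        df["damaged"] = df["damaged"].astype(bool)
    return df


def frame_to_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def tsv_to_frame(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"junction": str, "junction_aa": str,
                            "tube": str, "case_id": str})
    for c in _INT_COLS:
        if c in df.columns:
            df[c] = df[c].astype("Int64")
    if "damaged" in df.columns and len(df):
        df["damaged"] = df["damaged"].astype(bool)
    for c in ("junction", "junction_aa", "tube"):
        if c in df.columns:
            df[c] = df[c].fillna("")
    return df


def row_key(row) -> IdentityKey:
    """Identity key of one table row (pd.NA segmentation -> None)."""
    def _i(v):
        return None if pd.isna(v) else int(v)
    aa = row["junction_aa"]
    return IdentityKey(
        row["junction_class"], row["five_gene"], _i(row["five_del"]),
        _i(row["np_total"]), _i(row["three_del"]), row["three_gene"],
        "" if pd.isna(aa) else str(aa),
    )


def frame_keys(df: pd.DataFrame) -> list[IdentityKey]:
    return [row_key(row) for _, row in df.iterrows()]


def rearrangement_from_row(row) -> Rearrangement:
    """Rebuild a Rearrangement object from a table row."""
    key = row_key(row)
    return Rearrangement(
        junction_class=CLASS_BY_LABEL[key.junction_class],
        five_gene=key.five_gene,
        three_gene=key.three_gene,
        five_del=key.five_del,
        ndn_length=key.ndn_length,
        three_del=key.three_del,
        junction_nt=row.get("junction", "") or "",
        junction_aa=key.junction_aa,
        productivity=row["productivity"],
        damaged=bool(row["damaged"]),
        count=int(row["duplicate_count"]),
    )


def truth_to_frame(case) -> pd.DataFrame:
    """Ground-truth table of a simulated case (one row per rearrangement)."""
    rows = []
    for t in case.truth:
        r = t.rearrangement
        rows.append({
            "case_id": t.case_id,
            "truth_id": t.truth_id,
            "is_clonal": t.is_clonal,
            "junction_class": r.junction_class.label,
            "five_gene": r.five_gene,
            "five_del": r.five_del,
            "np_total": r.ndn_length,
            "three_del": r.three_del,
            "three_gene": r.three_gene,
            "junction_aa": r.junction_aa,
            "productivity": r.productivity,
            "cell_fraction": t.cell_fraction,
            "expression_rate": t.expression_rate,
        })
    return pd.DataFrame(rows)
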