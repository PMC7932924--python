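"""DNAamp-vs-RNAseq marker concordance.

The amplicon assay is the benchmark: each of a case's DNAamp marker
candidates is searched for in the same case's RNAseq rearrangement table
(at any abundance).  Per-class and per-case summaries mirror the standard
report: average rearrangements per case per platform, damaged and
productive counts, marker counts, recovered markers and recovery
percentages.

Matching modes:

* ``exact_key`` (default) — a marker is recovered iff an undamaged RNAseq
  record with the identical 7-component identity key exists;
* ``allow_damaged_partial`` — additionally accepts a damaged RNAseq record
  agreeing on class, both genes and every segmentation statistic its read
  coverage determined.  Recovery under this mode is by construction a
  superset of exact-key recovery; it quantifies how much the partial
  junctions of whole-transcriptome data could contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classes import JUNCTION_CLASSES
from .io import row_key
from .rearrangement import UNPRODUCTIVE, IdentityKey
from .simulate import DNAAMP_DETECTABLE_CLASSES

EXACT_KEY = "exact_key"
ALLOW_DAMAGED_PARTIAL = "allow_damaged_partial"
MATCH_MODES = (EXACT_KEY, ALLOW_DAMAGED_PARTIAL)

_KEY_COLS = ["junction_class", "five_gene", "five_del", "np_total",
             "three_del", "three_gene", "junction_aa"]


@dataclass
class ConcordanceSummary:
    """Per-class, per-case and overall marker recovery."""

    per_class: pd.DataFrame
    per_case: pd.DataFrame
    overall: dict


def _partial_matches(marker_row, damaged_row) -> bool:
    if marker_row["junction_class"] != damaged_row["junction_class"]:
        return False
    if (marker_row["five_gene"] != damaged_row["five_gene"]
            or marker_row["three_gene"] != damaged_row["three_gene"]):
        return False
    for col in ("five_del", "np_total", "three_del"):
        v = damaged_row[col]
        if pd.isna(v):
            continue  # undetermined by the damaged record's coverage
        if pd.isna(marker_row[col]) or int(v) != int(marker_row[col]):
            return False
    return True


def match_markers(dnaamp_markers: pd.DataFrame, rnaseq_table: pd.DataFrame,
                  mode: str = EXACT_KEY) -> pd.DataFrame:
    """Per-marker matched/unmatched verdicts against one case's RNAseq table.

    Both inputs must come from the same case (post uniqueness filter).
    Returns the marker frame extended with ``matched``, ``via_damaged``
    and ``match_count`` columns.
    """
    if mode not in MATCH_MODES:
        raise ValueError(f"unknown match mode {mode!r}")
    cases_m = set(dnaamp_markers["case_id"].unique()) if len(dnaamp_markers) else set()
    cases_r = set(rnaseq_table["case_id"].unique()) if len(rnaseq_table) else set()
    if len(cases_m | cases_r) > 1:
        raise ValueError(f"case mismatch: markers {cases_m} vs RNAseq {cases_r}")

    intact = rnaseq_table[~rnaseq_table["damaged"]] if len(rnaseq_table) else rnaseq_table
    damaged = rnaseq_table[rnaseq_table["damaged"]] if len(rnaseq_table) else rnaseq_table
    intact_keys = {}
    for _, row in intact.iterrows():
        intact_keys[row_key(row)] = int(row["duplicate_count"])

    out = dnaamp_markers.copy()
    matched, via_damaged, match_count = [], [], []
    for _, m in out.iterrows():
        key = (m["junction_class"], m["five_gene"],
               None if pd.isna(m["five_del"]) else int(m["five_del"]),
               None if pd.isna(m["np_total"]) else int(m["np_total"]),
               None if pd.isna(m["three_del"]) else int(m["three_del"]),
               m["three_gene"],
               "" if pd.isna(m["junction_aa"]) else str(m["junction_aa"]))
        hit = intact_keys.get(IdentityKey(*key))
        dmg = False
        if hit is None and mode == ALLOW_DAMAGED_PARTIAL and len(damaged):
            for _, drow in damaged.iterrows():
                if _partial_matches(m, drow):
                    hit = int(drow["duplicate_count"])
                    dmg = True
                    break
        matched.append(hit is not None)
        via_damaged.append(dmg)
        match_count.append(0 if hit is None else hit)
    out["matched"] = pd.Series(matched, index=out.index, dtype=bool) if len(out) else False
    out["via_damaged"] = pd.Series(via_damaged, index=out.index, dtype=bool) if len(out) else False
    out["match_count"] = pd.Series(match_count, index=out.index, dtype="int64") if len(out) else 0
    if not len(out):
        out["matched"] = pd.Series(dtype=bool)
        out["via_damaged"] = pd.Series(dtype=bool)
        out["match_count"] = pd.Series(dtype="int64")
    return out


def summarize_by_class(dnaamp_tables: dict[str, pd.DataFrame],
                       rnaseq_tables: dict[str, pd.DataFrame],
                       verdicts: pd.DataFrame) -> ConcordanceSummary:
    """Per-class report over all cases, plus overall totals.

    Rows follow the canonical 22-class order.  ``dnaamp_per_case`` is NaN
    ("na" in the rendered table) for classes no primer tube amplifies.
    The overall block also carries the unproductive fraction among
    detected rearrangements per platform, a key biological contrast
    between the two platforms.
    """
    n_cases = max(len(dnaamp_tables), len(rnaseq_tables), 1)

    def class_counts(tables, predicate=None):
        c = {jc.label: 0 for jc in JUNCTION_CLASSES}
        for df in tables.values():
            if not len(df):
                continue
            sub = df if predicate is None else df[predicate(df)]
            for label, n in sub.groupby("junction_class").size().items():
                c[label] += int(n)
        return c

    dna_counts = class_counts(dnaamp_tables)
    rna_counts = class_counts(rnaseq_tables)
    rna_damaged = class_counts(rnaseq_tables, lambda d: d["damaged"])
    rna_productive = class_counts(
        rnaseq_tables, lambda d: d["productivity"] == "productive")

    markers_by_class = {jc.label: 0 for jc in JUNCTION_CLASSES}
    recovered_by_class = {jc.label: 0 for jc in JUNCTION_CLASSES}
    if len(verdicts):
        for label, sub in verdicts.groupby("junction_class"):
            markers_by_class[label] = int(len(sub))
            recovered_by_class[label] = int(sub["matched"].sum())

    rows = []
    for jc in JUNCTION_CLASSES:
        nm = markers_by_class[jc.label]
        nr = recovered_by_class[jc.label]
        detectable = jc.label in DNAAMP_DETECTABLE_CLASSES
        rows.append({
            "junction_class": jc.label,
            "locus_group": jc.locus_group,
            "category": jc.category,
            "dnaamp_per_case": (dna_counts[jc.label] / n_cases
                                if detectable else np.nan),
            "rnaseq_per_case": rna_counts[jc.label] / n_cases,
            "rnaseq_damaged_per_case": rna_damaged[jc.label] / n_cases,
            "rnaseq_productive_per_case": rna_productive[jc.label] / n_cases,
            "dnaamp_markers": nm,
            "rnaseq_recovered": nr,
            "recovery_pct": round(100.0 * nr / nm, 1) if nm else np.nan,
        })
    per_class = pd.DataFrame(rows).set_index("junction_class")

    total_m = int(per_class["dnaamp_markers"].sum())
    total_r = int(per_class["rnaseq_recovered"].sum())

    def unproductive_fraction(tables):
        n = unp = 0
        for df in tables.values():
            if not len(df):
                continue
            n += len(df)
            unp += int((df["productivity"] == UNPRODUCTIVE).sum())
        return unp / n if n else np.nan

    overall = {
        "n_cases": n_cases,
        "dnaamp_markers": total_m,
        "rnaseq_recovered": total_r,
        "recovery_pct": round(100.0 * total_r / total_m, 1) if total_m else np.nan,
        "dnaamp_rearrangements_per_case":
            sum(dna_counts.values()) / n_cases,
        "rnaseq_rearrangements_per_case":
            sum(rna_counts.values()) / n_cases,
        "rnaseq_damaged_per_case": sum(rna_damaged.values()) / n_cases,
        "dnaamp_unproductive_fraction": unproductive_fraction(dnaamp_tables),
        "rnaseq_unproductive_fraction": unproductive_fraction(rnaseq_tables),
    }
    return ConcordanceSummary(per_class=per_class, per_case=pd.DataFrame(),
                              overall=overall)


def summarize_per_case(verdicts: pd.DataFrame,
                       rnaseq_candidates: dict[str, pd.DataFrame],
                       case_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-case marker counts and recovery.

    ``rnaseq_candidates`` holds each case's RNAseq candidate list (built
    with or without the amplicon thresholds, as the comparison requires).
    Flags mark whether each platform yields the >=2 markers most clinical
    MRD protocols require.
    """
    if case_ids is None:
        case_ids = sorted(set(rnaseq_candidates)
                          | (set(verdicts["case_id"].unique())
                             if len(verdicts) else set()))
    rows = []
    for cid in case_ids:
        sub = verdicts[verdicts["case_id"] == cid] if len(verdicts) else verdicts
        nd = int(len(sub))
        nr = int(sub["matched"].sum()) if len(sub) else 0
        rna = rnaseq_candidates.get(cid)
        nn = int(len(rna)) if rna is not None else 0
        rows.append({
            "case_id": cid,
            "dnaamp_markers": nd,
            "rnaseq_markers": nn,
            "recovered_markers": nr,
            "ge2_dnaamp": nd >= 2,
            "ge2_rnaseq": nn >= 2,
            "ge2_recovered": nr >= 2,
        })
    return pd.DataFrame(rows)


def marker_count_histogram(per_case: pd.DataFrame,
                           column: str) -> dict[str, int]:
    """Cohort histogram of marker counts (0 / 1 / 2 / 3 / >=4)."""
    bins = {"0": 0, "1": 0, "2": 0, "3": 0, ">=4": 0}
    for v in per_case[column]:
        v = int(v)
        bins[str(v) if v < 4 else ">=4"] += 1
    return bins


def plot_class_recovery(summary: ConcordanceSummary, path) -> None:
    """Per-class bar chart: amplicon markers vs RNAseq-recovered markers."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pc = summary.per_class
    x = np.arange(len(pc))
    fig, ax = plt.subplots(figsize=(11, 4))
    ax.bar(x - 0.2, pc["dnaamp_markers"], width=0.4, label="DNAamp markers")
    ax.bar(x + 0.2, pc["rnaseq_recovered"], width=0.4,
           label="recovered by RNAseq")
    ax.set_xticks(x)
    ax.set_xticklabels(pc.index, rotation=75, ha="right", fontsize=8)
    ax.set_ylabel("markers")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def render_class_table(summary: ConcordanceSummary) -> str:
    """Plain-text per-class report in the canonical 22-row order."""
    lines = [
        f"{'junction class':<14} {'DNAamp/case':>12} {'RNAseq/case (dmg)':>18} "
        f"{'RNAseq prod':>12} {'DNAamp mk':>10} {'RNAseq mk':>10} {'RNAseq %':>9}"
    ]
    for label, row in summary.per_class.iterrows():
        def fmt(v, spec=".1f"):
            return "na" if pd.isna(v) else format(v, spec)
        dna = fmt(row["dnaamp_per_case"])
        rna = f"{row['rnaseq_per_case']:.1f} ({row['rnaseq_damaged_per_case']:.1f})"
        detectable = not pd.isna(row["dnaamp_per_case"])
        mk = f"{row['dnaamp_markers']:d}" if detectable else "na"
        rec = f"{row['rnaseq_recovered']:d}" if detectable else "na"
        pct = fmt(row["recovery_pct"])
        lines.append(f"{label:<14} {dna:>12} {rna:>18} "
                     f"{row['rnaseq_productive_per_case']:>12.1f} {mk:>10} "
                     f"{rec:>10} {pct:>9}")
    o = summary.overall
    lines.append("")
    lines.append(
        f"overall: {o['dnaamp_markers']} DNAamp markers, "
        f"{o['rnaseq_recovered']} recovered by RNAseq "
        f"({o['recovery_pct'] if o['dnaamp_markers'] else 'na'}%)"
    )
    return "\n".join(lines)
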