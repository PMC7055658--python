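"""Consensus localization calls, peripheral-IM resolution and mismatch detection.

A protein gets a high-confidence call when (a) its per-replicate clusterings
agree at the localization level and (b) the ratio-threshold method and the
cluster-mapping method assign the same class. Everything else is excluded
with a reason code. High-confidence calls then resolve the dual-annotated
IM-cyto proteins to IM or soluble and flag proteins whose call conflicts with
their benchmark annotation group — candidate misannotations or proteins whose
interactions drag them across the gradient (transenvelope complexes, partners
of membrane machines).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import AnnotationTable, LocalizationCalls

log = logging.getLogger(__name__)

REASON_DISAGREEMENT = "method-disagreement"
REASON_REPLICATE = "replicate-inconsistency"
REASON_INCOMPLETE = "incomplete"


@dataclass
class ConsensusReport:
    """Counts and cross-tabulations summarizing one pipeline run."""

    n_total: int
    n_replicate_consistent: int
    n_method_agreement: int
    n_high_confidence: int
    class_counts: dict
    venn_counts: dict  # class -> {"both", "ratio_only", "cluster_only"}
    imcyto_resolution: dict  # resolved class -> count
    mismatches: pd.DataFrame

    def validate(self) -> None:
        both_total = sum(v["both"] for v in self.venn_counts.values())
        if both_total != self.n_high_confidence:
            raise ValidationError(
                "sum of per-class 'both' counts must equal the high-confidence total"
            )


def consensus_call(
    ratio_call: pd.Series,
    cluster_call: pd.Series,
    replicate_consistent: pd.Series,
) -> pd.DataFrame:
    """Combine the two methods into consensus calls with reason codes.

    Returns a frame with ``consensus_call`` (a localization or "excluded"),
    ``high_confidence`` and ``exclusion_reason`` (incomplete |
    replicate-inconsistency | method-disagreement).
    """
    index = ratio_call.index
    rc = ratio_call.reindex(index)
    cc = cluster_call.reindex(index)
    cons = replicate_consistent.reindex(index).fillna(False).astype(bool)
    has_both = rc.notna() & cc.notna()
    agree = has_both & (rc == cc)
    hc = agree & cons
    reason = pd.Series(None, index=index, dtype=object)
    reason[~has_both] = REASON_INCOMPLETE
    reason[has_both & ~cons] = REASON_REPLICATE
    reason[has_both & cons & ~agree] = REASON_DISAGREEMENT
    consensus = pd.Series("excluded", index=index, dtype=object)
    consensus[hc] = rc[hc]
    return pd.DataFrame(
        {
            "consensus_call": consensus,
            "high_confidence": hc,
            "exclusion_reason": reason,
        }
    )


def resolve_dual_annotation(
    ann: AnnotationTable, calls: LocalizationCalls
) -> tuple[pd.DataFrame, dict]:
    """Resolve high-confidence IM-cyto proteins to their observed class.

    Peripheral-IM proteins carry a dual cytoplasm/IM prior; their consensus
    call assigns the predominant localization. IM and soluble resolutions are
    expected; an OM resolution is recorded but flagged anomalous.
    """
    f = calls.frame
    imcyto = [p for p in f.index if ann.category_for(p) == "IM-cyto"]
    rows = []
    for pid in imcyto:
        hc = bool(f.at[pid, "high_confidence"])
        resolved = f.at[pid, "consensus_call"] if hc else None
        rows.append(
            {
                "protein_id": pid,
                "resolved": resolved if hc else "unresolved",
                "anomalous": bool(hc and resolved == "OM"),
            }
        )
    table = pd.DataFrame(rows, columns=["protein_id", "resolved", "anomalous"])
    if len(table):
        table = table.set_index("protein_id")
    counts = {
        cls: int((table["resolved"] == cls).sum()) if len(table) else 0
        for cls in ("IM", "soluble", "OM")
    }
    return table, counts


def detect_mismatches(ann: AnnotationTable, calls: LocalizationCalls) -> pd.DataFrame:
    """High-confidence proteins whose call conflicts with their annotation group.

    IM-cyto proteins are never mismatches (either resolution is compatible
    with the dual prior); "other" and unannotated proteins are skipped; a
    secondary prior category compatible with the call suppresses the flag.
    Each row keeps both labels for downstream manual curation, plus an empty
    free-text ``scenario`` slot.
    """
    f = calls.frame
    rows = []
    for pid in f.index[f["high_confidence"].fillna(False).astype(bool)]:
        cat = ann.category_for(pid)
        if cat is None or cat in ("IM-cyto", "other"):
            continue
        group = ann.group_of(cat)
        if group in ("IM-cyto", "other"):
            continue
        call = f.at[pid, "consensus_call"]
        if call == group:
            continue
        if ann.secondary is not None and pid in ann.secondary.index:
            sec = ann.secondary.loc[pid]
            if pd.notna(sec) and ann.group_of(sec) == call:
                continue  # dual prior annotation compatible with the call
        rows.append(
            {
                "protein_id": pid,
                "annotation_category": cat,
                "annotation_group": group,
                "consensus_call": call,
                "scenario": "",
            }
        )
    cols = ["protein_id", "annotation_category", "annotation_group", "consensus_call", "scenario"]
    table = pd.DataFrame(rows, columns=cols)
    return table.set_index("protein_id") if len(table) else table


def annotation_match_column(ann: AnnotationTable, calls_frame: pd.DataFrame) -> pd.Series:
    """Per-protein annotation agreement: match | mismatch | partial | unannotated.

    Only high-confidence proteins are scored; the rest stay missing. IM-cyto
    and secondary-compatible calls are "partial".
    """
    out = pd.Series(None, index=calls_frame.index, dtype=object)
    hc = calls_frame["high_confidence"].fillna(False).astype(bool)
    for pid in calls_frame.index:
        cat = ann.category_for(pid)
        if cat is None:
            out[pid] = "unannotated"
            continue
        if not hc[pid]:
            continue
        group = ann.group_of(cat)
        call = calls_frame.at[pid, "consensus_call"]
        if group in ("IM-cyto", "other"):
            out[pid] = "partial"
        elif call == group:
            out[pid] = "match"
        elif (
            ann.secondary is not None
            and pid in ann.secondary.index
            and pd.notna(ann.secondary.loc[pid])
            and ann.group_of(ann.secondary.loc[pid]) == call
        ):
            out[pid] = "partial"
        else:
            out[pid] = "mismatch"
    return out


def venn_counts(
    ratio_call: pd.Series,
    cluster_call: pd.Series,
    replicate_consistent: pd.Series,
) -> dict:
    """Per-class method overlap among replicate-consistent proteins with both calls."""
    cons = replicate_consistent.reindex(ratio_call.index).fillna(False).astype(bool)
    rc = ratio_call[cons]
    cc = cluster_call.reindex(rc.index)
    has_both = rc.notna() & cc.notna()
    rc, cc = rc[has_both], cc[has_both]
    out = {}
    for cls in ("IM", "OM", "soluble"):
        out[cls] = {
            "both": int(((rc == cls) & (cc == cls)).sum()),
            "ratio_only": int(((rc == cls) & (cc != cls)).sum()),
            "cluster_only": int(((rc != cls) & (cc == cls)).sum()),
        }
    return out


def benchmark_performance(
    ann: AnnotationTable,
    calls: LocalizationCalls,
    category_universe: pd.Series | None = None,
) -> dict:
    """Confusion matrix and true-positive rates against the benchmark annotation.

    The overlap set is the high-confidence proteins; the nonoverlap set is the
    replicate-consistent proteins where the two methods disagree, scored over
    both methods' calls. A call is "true" when it matches the protein's
    benchmark group (IM-cyto / other / unannotated proteins are not scored).
    If ``category_universe`` (category -> number of annotated proteins) is
    given, per-category detection coverage is reported too.
    """
    f = calls.frame
    group = pd.Series(
        {pid: ann.group_of(ann.category_for(pid)) for pid in f.index if ann.category_for(pid)},
        dtype=object,
    )
    scored = group[group.isin(["IM", "OM", "soluble"])]
    if scored.empty:
        raise ValidationError("no benchmark-annotated proteins among the calls")

    hc = f["high_confidence"].fillna(False).astype(bool)
    overlap = scored.index[hc.reindex(scored.index).fillna(False)]
    confusion = pd.crosstab(
        scored.loc[overlap].rename("annotation"),
        f.loc[overlap, "consensus_call"].rename("call"),
        dropna=False,
    )
    tpr_overlap = (
        float((f.loc[overlap, "consensus_call"] == scored.loc[overlap]).mean())
        if len(overlap)
        else np.nan
    )

    cons = f["replicate_consistent"].fillna(False).astype(bool)
    disagree = scored.index[
        cons.reindex(scored.index).fillna(False)
        & f.loc[scored.index, "ratio_call"].notna()
        & f.loc[scored.index, "cluster_call"].notna()
        & (f.loc[scored.index, "ratio_call"] != f.loc[scored.index, "cluster_call"])
    ]
    if len(disagree):
        hits = (f.loc[disagree, "ratio_call"] == scored.loc[disagree]).sum() + (
            f.loc[disagree, "cluster_call"] == scored.loc[disagree]
        ).sum()
        tpr_nonoverlap = float(hits / (2 * len(disagree)))
    else:
        tpr_nonoverlap = np.nan

    out = {
        "confusion": confusion,
        "tpr_overlap": tpr_overlap,
        "tpr_nonoverlap": tpr_nonoverlap,
        "n_overlap": int(len(overlap)),
        "n_nonoverlap": int(len(disagree)),
    }
    if category_universe is not None:
        detected = ann.categories.reindex(f.index).dropna()
        coverage = {}
        for cat, n_annotated in category_universe.items():
            n_det = int((detected == cat).sum())
            coverage[cat] = n_det / n_annotated if n_annotated else np.nan
        out["coverage"] = coverage
    return out


def build_report(
    calls: LocalizationCalls,
    ann: AnnotationTable,
) -> ConsensusReport:
    """Assemble the run-level consensus report from a finished calls table."""
    f = calls.frame
    hc = f["high_confidence"].fillna(False).astype(bool)
    cons = f["replicate_consistent"].fillna(False).astype(bool)
    agree = f["ratio_call"].notna() & (f["ratio_call"] == f["cluster_call"])
    _, imcyto_counts = resolve_dual_annotation(ann, calls)
    report = ConsensusReport(
        n_total=len(f),
        n_replicate_consistent=int(cons.sum()),
        n_method_agreement=int((agree & cons).sum()),
        n_high_confidence=int(hc.sum()),
        class_counts={
            cls: int((f.loc[hc, "consensus_call"] == cls).sum())
            for cls in ("IM", "OM", "soluble")
        },
        venn_counts=venn_counts(
            f["ratio_call"], f["cluster_call"], f["replicate_consistent"]
        ),
        imcyto_resolution=imcyto_counts,
        mismatches=detect_mismatches(ann, calls),
    )
    report.validate()
    return report
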