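"""Consensus calls, IM-cyto resolution, mismatch detection and benchmark metrics."""

import numpy as np
import pandas as pd
import pytest

import gradloc as gl
from gradloc.consensus import (
    REASON_DISAGREEMENT,
    REASON_INCOMPLETE,
    REASON_REPLICATE,
    annotation_match_column,
    venn_counts,
)
from tests.conftest import SMALL_CLASSES, mem_config, method_accuracy


class TestConsensusCall:
    @pytest.mark.parametrize(
        "ratio,cluster,consistent,expected_call,expected_reason",
        [
            ("IM", "IM", True, "IM", None),
            ("OM", "OM", True, "OM", None),
            ("IM", "soluble", True, "excluded", REASON_DISAGREEMENT),
            ("OM", "OM", False, "excluded", REASON_REPLICATE),
            (None, "IM", True, "excluded", REASON_INCOMPLETE),
            ("IM", None, False, "excluded", REASON_INCOMPLETE),
        ],
    )
    def test_rule_table(self, ratio, cluster, consistent, expected_call, expected_reason):
        out = gl.consensus_call(
            pd.Series({"P": ratio}, dtype=object),
            pd.Series({"P": cluster}, dtype=object),
            pd.Series({"P": consistent}),
        )
        assert out.loc["P", "consensus_call"] == expected_call
        if expected_reason is None:
            assert pd.isna(out.loc["P", "exclusion_reason"])
        else:
            assert out.loc["P", "exclusion_reason"] == expected_reason
        assert out.loc["P", "high_confidence"] == (expected_call != "excluded")


def calls_from(rows: dict) -> gl.LocalizationCalls:
    """Build a LocalizationCalls from {pid: (ratio, cluster, consistent)}."""
    ratio = pd.Series({p: v[0] for p, v in rows.items()}, dtype=object)
    cluster = pd.Series({p: v[1] for p, v in rows.items()}, dtype=object)
    consistent = pd.Series({p: v[2] for p, v in rows.items()})
    cons = gl.consensus_call(ratio, cluster, consistent)
    frame = pd.DataFrame(
        {
            "sucrose_ratio": 0.0,
            "ratio_call": ratio,
            "cluster_rep1": pd.array([1] * len(rows), dtype="Int64"),
            "cluster_rep2": pd.array([1] * len(rows), dtype="Int64"),
            "cluster_avg": pd.array([1] * len(rows), dtype="Int64"),
            "cluster_call": cluster,
            "replicate_consistent": consistent,
            "consensus_call": cons["consensus_call"],
            "high_confidence": cons["high_confidence"],
            "exclusion_reason": cons["exclusion_reason"],
            "annotation_category": None,
            "annotation_match": None,
        },
        index=list(rows),
    )
    return gl.LocalizationCalls(frame=frame)


class TestResolveDualAnnotation:
    def make(self):
        ann = gl.AnnotationTable(
            categories=pd.Series(
                {"A": "IM-cyto", "B": "IM-cyto", "C": "IM-cyto", "D": "OMP"}, dtype=object
            )
        )
        calls = calls_from(
            {
                "A": ("IM", "IM", True),
                "B": ("soluble", "IM", True),  # excluded: disagreement
                "C": ("OM", "OM", True),
                "D": ("OM", "OM", True),
            }
        )
        return ann, calls

    def test_resolution_counts_and_anomaly(self):
        ann, calls = self.make()
        table, counts = gl.resolve_dual_annotation(ann, calls)
        assert table.loc["A", "resolved"] == "IM"
        assert table.loc["B", "resolved"] == "unresolved"
        assert table.loc["C", "resolved"] == "OM" and table.loc["C", "anomalous"]
        assert counts == {"IM": 1, "soluble": 0, "OM": 1}
        assert "D" not in table.index


class TestDetectMismatches:
    def test_compatibility_matrix(self):
        ann = gl.AnnotationTable(
            categories=pd.Series(
                {
                    "peri": "periplasmic",
                    "imcyto": "IM-cyto",
                    "omp": "OMP",
                    "oth": "other",
                    "trans": "IM-integral",
                },
                dtype=object,
            )
        )
        calls = calls_from(
            {
                "peri": ("OM", "OM", True),  # soluble annotation vs OM call
                "imcyto": ("soluble", "soluble", True),  # dual prior: compatible
                "omp": ("OM", "OM", True),  # match
                "oth": ("IM", "IM", True),  # ambiguous category: skipped
                "trans": ("soluble", "soluble", True),  # transenvelope-style mismatch
            }
        )
        mm = gl.detect_mismatches(ann, calls)
        assert set(mm.index) == {"peri", "trans"}
        assert mm.loc["peri", "consensus_call"] == "OM"

    def test_secondary_category_suppresses_flag(self):
        ann = gl.AnnotationTable(
            categories=pd.Series({"fecb": "periplasmic"}, dtype=object),
            secondary=pd.Series({"fecb": "IM-peri"}, dtype=object),
        )
        calls = calls_from({"fecb": ("IM", "IM", True)})
        assert len(gl.detect_mismatches(ann, calls)) == 0

    def test_match_column_vocabulary(self):
        ann = gl.AnnotationTable(
            categories=pd.Series({"a": "OMP", "b": "periplasmic", "c": "IM-cyto"}, dtype=object)
        )
        calls = calls_from(
            {"a": ("OM", "OM", True), "b": ("IM", "IM", True), "c": ("IM", "IM", True),
             "unk": ("IM", "IM", True)}
        )
        col = annotation_match_column(ann, calls.frame)
        assert col["a"] == "match" and col["b"] == "mismatch"
        assert col["c"] == "partial" and col["unk"] == "unannotated"


class TestBenchmarkPerformance:
    def test_perfect_calls_have_unit_tpr(self):
        ann = gl.AnnotationTable(
            categories=pd.Series(
                {"a": "OMP", "b": "IM-integral", "c": "periplasmic"}, dtype=object
            )
        )
        calls = calls_from(
            {"a": ("OM", "OM", True), "b": ("IM", "IM", True), "c": ("soluble", "soluble", True)}
        )
        metrics = gl.benchmark_performance(ann, calls)
        assert metrics["tpr_overlap"] == 1.0
        assert metrics["n_nonoverlap"] == 0  # no disagreement set exists

    def test_nonoverlap_scores_both_methods(self):
        ann = gl.AnnotationTable(categories=pd.Series({"a": "OMP", "b": "OMP"}, dtype=object))
        calls = calls_from({"a": ("OM", "soluble", True), "b": ("IM", "soluble", True)})
        metrics = gl.benchmark_performance(ann, calls)
        # four method-calls on the disagreement set, one of which is correct
        assert metrics["tpr_nonoverlap"] == pytest.approx(0.25)

    def test_detection_coverage(self):
        ann = gl.AnnotationTable(categories=pd.Series({"a": "OMP", "b": "OMP", "c": "OMP"}, dtype=object))
        calls = calls_from({"a": ("OM", "OM", True), "b": ("OM", "OM", True), "c": ("OM", "OM", True)})
        metrics = gl.benchmark_performance(
            ann, calls, category_universe=pd.Series({"OMP": 4})
        )
        assert metrics["coverage"]["OMP"] == pytest.approx(0.75)


class TestRunLevelInvariants:
    def test_conservation_and_reason_partition(self, small_result):
        f = small_result.calls.frame
        hc = f["high_confidence"].astype(bool)
        assert len(f) == hc.sum() + (~hc).sum()
        assert f.loc[~hc, "exclusion_reason"].notna().all()
        assert f.loc[hc, "exclusion_reason"].isna().all()

    def test_venn_structure_consistent(self, small_result):
        f = small_result.calls.frame
        counts = venn_counts(f["ratio_call"], f["cluster_call"], f["replicate_consistent"])
        for cls, c in counts.items():
            cons = f["replicate_consistent"].astype(bool)
            both_called = cons & f["ratio_call"].notna() & f["cluster_call"].notna()
            union = (
                (f.loc[both_called, "ratio_call"] == cls)
                | (f.loc[both_called, "cluster_call"] == cls)
            ).sum()
            assert c["both"] + c["ratio_only"] + c["cluster_only"] == union
        assert small_result.report.n_high_confidence == sum(
            c["both"] for c in counts.values()
        )

    def test_consensus_dominates_single_methods_across_seeds(self):
        """High-confidence consensus accuracy >= each method alone, on average."""
        accs = {"ratio_call": [], "cluster_call": [], "consensus_call": []}
        for seed in range(20):
            data = gl.simulate_dataset(gl.GeneratorConfig(seed=100 + seed, **SMALL_CLASSES))
            res = gl.analyze(*data.replicates, data.annotation, mem_config(seed=seed))
            for col in accs:
                accs[col].append(method_accuracy(res, data.truth, col))
        mean = {k: np.mean(v) for k, v in accs.items()}
        assert mean["consensus_call"] >= mean["ratio_call"]
        assert mean["consensus_call"] >= mean["cluster_call"]
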