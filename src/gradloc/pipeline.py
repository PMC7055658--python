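"""End-to-end orchestration: signals in, localization calls and run summary out.

``analyze`` is the library workhorse operating on in-memory objects;
``run_pipeline`` wraps it with file I/O and a resolved, fully serializable
configuration that is echoed into the JSON run summary. The stage order is:

    peptide filter -> replicate intersection -> batch removal -> normalization
    -> per-replicate logFC -> per-replicate clustering + consistency filter
    -> replicate averaging -> sucrose ratio + percentile cutoffs + ratio calls
    -> averaged-profile clustering + localization mapping -> consensus
    -> IM-cyto resolution -> mismatch report -> benchmark metrics
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _version
from .clustering import (
    DEFAULT_K,
    DEFAULT_N_INIT,
    choose_k,
    kmeans_cluster,
    map_clusters_to_localization,
    replicate_consistency_filter,
    run_pca,
)
from .consensus import (
    ConsensusReport,
    annotation_match_column,
    benchmark_performance,
    build_report,
    consensus_call,
    resolve_dual_annotation,
)
from .errors import ConfigurationError, ValidationError
from .io_formats import (
    AnnotationTable,
    LocalizationCalls,
    SignalMatrix,
    filter_min_peptides,
    intersect_replicates,
    read_annotation,
    read_signal_matrix,
    write_calls,
)
from .normalize import (
    apply_normalization,
    fit_vsn,
    median_log2_normalize,
    remove_batch_effect,
)
from .profiles import (
    average_replicates,
    compute_logfc,
    compute_sucrose_ratio,
    replicate_correlation,
)
from .ratio_classifier import build_benchmark_groups, classify_by_ratio, derive_cutoffs

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (fully serializable)."""

    rep1_path: str
    rep2_path: str
    annotation_path: str
    out_dir: str
    normalization: str = "vsn"  # vsn | median_log2 | none
    ratio_mode: str = "mean_of_logs"
    k: int = DEFAULT_K
    seed: int = 0
    n_init: int = DEFAULT_N_INIT
    min_peptides: int | None = 2
    include_imlp: bool = False
    vsn_trim: float = 0.1
    vsn_max_iter: int = 50
    vsn_tol: float = 1e-8
    make_plots: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    calls: LocalizationCalls
    report: ConsensusReport
    summary: dict
    profiles_avg: object
    profiles_rep: tuple
    cutoffs: object
    cluster_model: object
    cluster_map: object
    pca: object
    imcyto_table: pd.DataFrame
    metrics: dict


def _normalize(rep1, rep2, cfg) -> tuple[SignalMatrix, SignalMatrix, dict]:
    info: dict = {"method": cfg.normalization}
    if cfg.normalization == "vsn":
        batch_cleaned = remove_batch_effect([rep1, rep2])
        model = fit_vsn(
            batch_cleaned, trim=cfg.vsn_trim, max_iter=cfg.vsn_max_iter, tol=cfg.vsn_tol
        )
        info.update({"vsn_iterations": model.n_iter, "vsn_trim": cfg.vsn_trim})
        n1 = apply_normalization(batch_cleaned[0], model)
        n2 = apply_normalization(batch_cleaned[1], model)
        return n1, n2, info
    if cfg.normalization == "median_log2":
        n1, n2 = median_log2_normalize([rep1, rep2])
        return n1, n2, info
    if cfg.normalization == "none":
        return rep1, rep2, info
    raise ConfigurationError(f"unknown normalization method {cfg.normalization!r}")


def analyze(
    rep1: SignalMatrix,
    rep2: SignalMatrix,
    ann: AnnotationTable,
    cfg: RunConfig,
    category_universe: pd.Series | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory inputs."""
    funnel: dict = {"input": {"rep1": rep1.n_proteins, "rep2": rep2.n_proteins}}
    if cfg.min_peptides is not None and rep1.unique_peptides is not None:
        rep1 = filter_min_peptides(rep1, cfg.min_peptides)
        rep2 = filter_min_peptides(rep2, cfg.min_peptides)
        funnel["peptide_filter"] = {"rep1": rep1.n_proteins, "rep2": rep2.n_proteins}
    rep1, rep2 = intersect_replicates(rep1, rep2)
    funnel["common_proteins"] = rep1.n_proteins
    log.info("replicate intersection: %d common proteins", rep1.n_proteins)

    n1, n2, norm_info = _normalize(rep1, rep2, cfg)
    p1, p2 = compute_logfc(n1), compute_logfc(n2)
    rep_r, rep_n = replicate_correlation(p1, p2)

    # per-replicate clustering for the consistency filter
    seed = int(cfg.seed) % (2**31)
    rep_calls = []
    for i, prof in enumerate((p1, p2)):
        model_i = kmeans_cluster(prof, cfg.k, seed=(seed + 1 + i) % (2**31), n_init=cfg.n_init)
        map_i = map_clusters_to_localization(model_i, ann, include_imlp=cfg.include_imlp)
        rep_calls.append((model_i, map_i.localize(model_i.assignments)))
    consistency = replicate_consistency_filter(rep_calls[0][1], rep_calls[1][1])
    consistency = consistency.reindex(rep1.protein_ids)
    consistency["replicate_consistent"] = consistency["replicate_consistent"].fillna(False)
    consistency.loc[consistency["reason"].isna() & ~consistency["replicate_consistent"], "reason"] = (
        "incomplete"
    )
    funnel["replicate_consistent"] = int(consistency["replicate_consistent"].sum())

    # averaged profiles: ratio method
    avg = average_replicates(p1, p2)
    ratios = compute_sucrose_ratio(avg, mode=cfg.ratio_mode)
    groups = build_benchmark_groups(ann, ratios.index, include_imlp=cfg.include_imlp)
    cutoffs = derive_cutoffs(ratios, groups)
    ratio_call = classify_by_ratio(ratios, cutoffs)

    # averaged profiles: clustering method
    pca = run_pca(avg)
    k = choose_k(pca, cfg.k)
    model = kmeans_cluster(avg, k, seed=seed, n_init=cfg.n_init)
    cmap = map_clusters_to_localization(model, ann, include_imlp=cfg.include_imlp)
    cluster_call = cmap.localize(model.assignments).reindex(ratios.index)

    cons = consensus_call(ratio_call, cluster_call, consistency["replicate_consistent"])
    frame = pd.DataFrame(
        {
            "sucrose_ratio": ratios,
            "ratio_call": ratio_call,
            "cluster_rep1": rep_calls[0][0].assignments.reindex(ratios.index).astype("Int64"),
            "cluster_rep2": rep_calls[1][0].assignments.reindex(ratios.index).astype("Int64"),
            "cluster_avg": model.assignments.reindex(ratios.index).astype("Int64"),
            "cluster_call": cluster_call,
            "replicate_consistent": consistency["replicate_consistent"].astype(bool),
            "consensus_call": cons["consensus_call"],
            "high_confidence": cons["high_confidence"].astype(bool),
            "exclusion_reason": cons["exclusion_reason"],
            "annotation_category": pd.Series(
                {p: ann.category_for(p) for p in ratios.index}, dtype=object
            ),
        },
        index=ratios.index,
    )
    frame["annotation_match"] = annotation_match_column(ann, frame)
    calls = LocalizationCalls(frame=frame)
    report = build_report(calls, ann)
    imcyto_table, _ = resolve_dual_annotation(ann, calls)
    metrics = benchmark_performance(ann, calls, category_universe=category_universe)

    summary = {
        "gradloc_version": _version,
        "config": cfg.to_dict(),
        "normalization": norm_info,
        "funnel": funnel,
        "replicate_pearson_r": rep_r,
        "replicate_pairs": rep_n,
        "cutoffs": {
            "im_upper": cutoffs.im_upper,
            "om_lower": cutoffs.om_lower,
            "n_im": cutoffs.n_im,
            "n_om": cutoffs.n_om,
            "n_soluble": cutoffs.n_soluble,
            "percentile_convention": cutoffs.percentile_convention,
        },
        "pca_variance_fractions": [float(v) for v in pca.variance_fractions[:4]],
        "k": k,
        "cluster_sizes": {
            int(c): int((model.assignments == c).sum()) for c in range(1, k + 1)
        },
        "cluster_localization": {int(c): l for c, l in cmap.mapping.items()},
        "counts": {
            "n_total": report.n_total,
            "n_replicate_consistent": report.n_replicate_consistent,
            "n_method_agreement": report.n_method_agreement,
            "n_high_confidence": report.n_high_confidence,
            "class_counts": report.class_counts,
            "venn": report.venn_counts,
            "imcyto_resolution": report.imcyto_resolution,
            "n_mismatches": int(len(report.mismatches)),
        },
        "benchmark": {
            "tpr_overlap": metrics["tpr_overlap"],
            "tpr_nonoverlap": metrics["tpr_nonoverlap"],
            "n_overlap": metrics["n_overlap"],
            "n_nonoverlap": metrics["n_nonoverlap"],
        },
    }
    return PipelineResult(
        calls=calls,
        report=report,
        summary=summary,
        profiles_avg=avg,
        profiles_rep=(p1, p2),
        cutoffs=cutoffs,
        cluster_model=model,
        cluster_map=cmap,
        pca=pca,
        imcyto_table=imcyto_table,
        metrics=metrics,
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Read inputs per ``cfg``, run the analysis, write outputs to ``cfg.out_dir``."""
    for path, name in (
        (cfg.rep1_path, "replicate 1 signals"),
        (cfg.rep2_path, "replicate 2 signals"),
        (cfg.annotation_path, "annotation"),
    ):
        if not os.path.exists(path):
            raise ValidationError(f"{name} file not found: {path}")
    rep1 = read_signal_matrix(cfg.rep1_path, "rep1")
    rep2 = read_signal_matrix(cfg.rep2_path, "rep2")
    ann = read_annotation(cfg.annotation_path)
    result = analyze(rep1, rep2, ann, cfg)

    os.makedirs(cfg.out_dir, exist_ok=True)
    write_calls(result.calls, os.path.join(cfg.out_dir, "calls.tsv"))
    if len(result.report.mismatches):
        result.report.mismatches.to_csv(os.path.join(cfg.out_dir, "mismatches.tsv"), sep="\t")
    with open(os.path.join(cfg.out_dir, "summary.json"), "w", encoding="utf-8") as fh:
        json.dump(result.summary, fh, indent=2, sort_keys=True)
    if cfg.make_plots:
        report_figures(result, cfg.out_dir)
    return result


def report_figures(result: PipelineResult, out_dir: str) -> list[str]:
    """Export diagnostic figures; skipped with a warning if plotting is unavailable.

    Produces a ratio-density panel per annotation group with the calibrated
    cutoffs, a cluster heatmap of the averaged profiles, mean cluster
    profiles, and a TSV of the per-class method-overlap counts.
    """
    written: list[str] = []
    os.makedirs(out_dir, exist_ok=True)
    venn_path = os.path.join(out_dir, "venn_counts.tsv")
    venn_rows = [
        {"class": cls, **counts} for cls, counts in result.report.venn_counts.items()
    ]
    pd.DataFrame(venn_rows).to_csv(venn_path, sep="\t", index=False)
    written.append(venn_path)
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except Exception as exc:  # pragma: no cover - plotting backend missing
        log.warning("plotting unavailable (%s); figures skipped", exc)
        return written

    calls = result.calls.frame
    # 1. ratio densities by annotation group
    fig, ax = plt.subplots(figsize=(7, 4))
    groups = calls.groupby(calls["annotation_category"].fillna("unannotated"))
    for name, sub in groups:
        vals = sub["sucrose_ratio"].dropna()
        if len(vals) < 2 or vals.nunique() < 2:
            ax.plot(vals, np.zeros(len(vals)), "|", label=f"{name} (n={len(vals)})")
            continue
        from scipy.stats import gaussian_kde

        xs = np.linspace(vals.min() - 0.5, vals.max() + 0.5, 200)
        ax.plot(xs, gaussian_kde(vals)(xs), label=f"{name} (n={len(vals)})")
    ax.axvline(result.cutoffs.im_upper, color="b", ls="-", lw=1)
    ax.axvline(result.cutoffs.om_lower, color="r", ls="-", lw=1)
    ax.set_xlabel("sucrose gradient ratio (log2)")
    ax.set_ylabel("density")
    ax.legend(fontsize=6)
    path = os.path.join(out_dir, "ratio_densities.png")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # 2. clustered profile heatmap
    model = result.cluster_model
    ordered = model.assignments.sort_values().index
    mat = result.profiles_avg.logfc.loc[ordered]
    fig, ax = plt.subplots(figsize=(5, 6))
    im = ax.imshow(mat.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(mat.shape[1]), mat.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_ylabel("proteins (sorted by cluster)")
    fig.colorbar(im, ax=ax, label="logFC vs total membrane")
    path = os.path.join(out_dir, "cluster_heatmap.png")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    # 3. mean profile per cluster
    fig, axes = plt.subplots(1, model.k, figsize=(3 * model.k, 2.5), sharey=True)
    axes = np.atleast_1d(axes)
    for c, ax in zip(range(1, model.k + 1), axes):
        members = model.assignments.index[model.assignments == c]
        prof = result.profiles_avg.logfc.loc[members]
        ax.plot(prof.to_numpy().T, color="0.8", lw=0.3)
        ax.plot(prof.mean(axis=0).to_numpy(), color="tab:blue", lw=2)
        loc = result.cluster_map.mapping[c]
        ax.set_title(f"cluster {c} ({loc}, n={len(members)})", fontsize=8)
        ax.set_xticks(range(10), prof.columns, rotation=90, fontsize=5)
    path = os.path.join(out_dir, "cluster_profiles.png")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
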