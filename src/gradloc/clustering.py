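"""Unsupervised clustering of fractionation patterns and its localization mapping.

k-means (Lloyd's algorithm, squared Euclidean distance, best of ``n_init``
random restarts) groups the 10-dimensional logFC profiles; k defaults to 4,
a choice justified by PCA of the profiles rather than detected automatically.
Clusters are then labelled IM / OM / soluble by *relative enrichment* of
benchmark-annotated members — the share of a cluster contributed by a
benchmark group divided by that group's overall prevalence — because soluble
proteins outnumber OM proteins roughly 6:1 and a raw majority vote would
swallow a genuine OM cluster. Downstream logic only ever sees the mapped
localization labels, never raw cluster ids, which also makes the per-replicate
consistency filter invariant to arbitrary cluster numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import CalibrationError, ConfigurationError, ValidationError
from .io_formats import FRACTIONS, AnnotationTable
from .profiles import ProfileSet
from .ratio_classifier import build_benchmark_groups

log = logging.getLogger(__name__)

DEFAULT_K = 4
DEFAULT_N_INIT = 50


@dataclass
class PCAResult:
    """Principal components of complete 10-d profiles."""

    variance_fractions: np.ndarray
    scores: pd.DataFrame
    n_dropped: int


@dataclass
class ClusterModel:
    """A fitted k-means solution on complete profiles."""

    k: int
    centroids: pd.DataFrame  # k x 10, indexed 1..k
    assignments: pd.Series  # protein -> cluster id in 1..k
    inertia: float
    seed: int
    n_init: int


@dataclass
class ClusterLocalizationMap:
    """Cluster id -> localization label plus the enrichment table behind it."""

    mapping: dict[int, str]
    enrichment: pd.DataFrame  # per cluster x group: counts and relative enrichment

    def localize(self, assignments: pd.Series) -> pd.Series:
        return assignments.map(self.mapping).rename("cluster_call").astype(object)


def run_pca(p: ProfileSet, n_components: int | None = None) -> PCAResult:
    """PCA of the complete-profile rows (proteins with any missing fraction dropped)."""
    complete = p.complete()
    n_dropped = len(p.logfc) - len(complete)
    if n_dropped:
        log.info("PCA: dropped %d incomplete profile(s)", n_dropped)
    if len(complete) < 2:
        raise ValidationError("need at least 2 complete profiles for PCA")
    k = n_components or min(len(FRACTIONS), len(complete))
    pca = PCA(n_components=k)
    scores = pca.fit_transform(complete.to_numpy(dtype=float))
    return PCAResult(
        variance_fractions=pca.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(
            scores, index=complete.index, columns=[f"PC{i+1}" for i in range(scores.shape[1])]
        ),
        n_dropped=n_dropped,
    )


def choose_k(pca: PCAResult, k: int = DEFAULT_K) -> int:
    """Return the configured cluster count, logging the variance table behind it.

    The number of clusters is a visual choice from the PCA structure, not an
    automatic elbow fit; the variance-explained fractions are logged so the
    choice is auditable.
    """
    if k < 2:
        raise ConfigurationError(f"number of clusters must be >= 2 (got {k})")
    top = ", ".join(
        f"PC{i+1}={v:.1%}" for i, v in enumerate(pca.variance_fractions[:4])
    )
    log.info("choose_k: k=%d (variance explained: %s)", k, top)
    return k


def kmeans_cluster(
    p: ProfileSet, k: int, seed: int, n_init: int = DEFAULT_N_INIT
) -> ClusterModel:
    """Lloyd's k-means on complete profiles, best of ``n_init`` random starts."""
    if k < 2:
        raise ConfigurationError(f"number of clusters must be >= 2 (got {k})")
    if n_init < 1:
        raise ConfigurationError("n_init must be >= 1")
    complete = p.complete()
    if len(complete) < k:
        raise ValidationError(
            f"only {len(complete)} complete profiles for k={k} clusters"
        )
    X = complete.to_numpy(dtype=float)
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_init,
        random_state=seed % (2**31),
        algorithm="lloyd",
    ).fit(X)
    assignments = pd.Series(km.labels_ + 1, index=complete.index, name="cluster")
    centroids = pd.DataFrame(
        km.cluster_centers_, index=pd.RangeIndex(1, k + 1, name="cluster"),
        columns=list(FRACTIONS),
    )
    return ClusterModel(
        k=k,
        centroids=centroids,
        assignments=assignments,
        inertia=float(km.inertia_),
        seed=seed,
        n_init=n_init,
    )


def map_clusters_to_localization(
    model: ClusterModel,
    ann: AnnotationTable,
    include_imlp: bool = False,
) -> ClusterLocalizationMap:
    """Label each cluster by the benchmark group most enriched in it.

    Enrichment of group g in cluster c = (share of c's benchmark members that
    are g) / (g's prevalence among all clustered benchmark proteins). Ties and
    clusters without benchmark members fall back to soluble. The map must
    contain at least one IM and one OM cluster.
    """
    groups = build_benchmark_groups(ann, model.assignments.index, include_imlp=include_imlp)
    group_of = {}
    for g, members in groups.items():
        for pid in members:
            group_of[pid] = g
    bench = model.assignments[model.assignments.index.map(group_of.__contains__)]
    if bench.empty:
        raise CalibrationError("no benchmark-annotated proteins among clustered proteins")
    labels = bench.index.map(group_of)
    n_total = len(bench)
    prevalence = {g: (labels == g).sum() / n_total for g in groups}
    for g, prev in prevalence.items():
        if prev == 0:
            raise CalibrationError(f"benchmark group {g!r} absent from all clusters")
    rows = []
    mapping: dict[int, str] = {}
    for c in range(1, model.k + 1):
        in_c = bench == c
        size_c = int(in_c.sum())
        row: dict = {"cluster": c, "n_benchmark": size_c}
        if size_c == 0:
            log.warning("cluster %d has no benchmark-annotated members; mapped to soluble", c)
            mapping[c] = "soluble"
            for g in groups:
                row[f"n_{g}"] = 0
                row[f"enrichment_{g}"] = np.nan
            rows.append(row)
            continue
        best_g, best_e = "soluble", -np.inf
        for g in ("IM", "OM", "soluble"):
            n_cg = int((in_c & (labels == g)).sum())
            enrich = (n_cg / size_c) / prevalence[g]
            row[f"n_{g}"] = n_cg
            row[f"enrichment_{g}"] = enrich
            if enrich > best_e + 1e-12:  # ties break toward soluble (checked last wins only if greater)
                best_g, best_e = g, enrich
            elif abs(enrich - best_e) <= 1e-12 and g == "soluble":
                best_g = g
        mapping[c] = best_g
        rows.append(row)
    mapped = set(mapping.values())
    for required in ("IM", "OM"):
        if required not in mapped:
            raise CalibrationError(
                f"no cluster maps to {required}; enrichment table: {rows}"
            )
    enrichment = pd.DataFrame(rows).set_index("cluster")
    enrichment["localization"] = [mapping[c] for c in enrichment.index]
    return ClusterLocalizationMap(mapping=mapping, enrichment=enrichment)


def replicate_consistency_filter(
    calls_rep1: pd.Series, calls_rep2: pd.Series
) -> pd.DataFrame:
    """Flag proteins whose two replicates map to different localizations.

    Comparison happens at the localization level (IM/OM/soluble after cluster
    mapping), never on raw cluster ids. A protein missing a call in either
    replicate is inconsistent with reason "incomplete".
    """
    index = calls_rep1.index.union(calls_rep2.index)
    c1 = calls_rep1.reindex(index)
    c2 = calls_rep2.reindex(index)
    has_both = c1.notna() & c2.notna()
    agree = has_both & (c1 == c2)
    reason = pd.Series(None, index=index, dtype=object)
    reason[~has_both] = "incomplete"
    reason[has_both & ~agree] = "replicate-inconsistency"
    return pd.DataFrame(
        {"replicate_consistent": agree, "reason": reason},
        index=index,
    )
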