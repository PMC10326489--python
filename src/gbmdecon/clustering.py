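"""Graph-based clustering, cluster annotation and reference balancing.

Cells are clustered by the standard scRNA-seq recipe: highly variable
gene selection, PCA, a kNN graph in PC space (Euclidean) and
resolution-parameterized Leiden community detection. Clusters are then
annotated by cross-tabulating against transferred per-cell labels and
applying a majority rule; clusters that cannot be resolved (typically
TAM vs microglia and T vs NK cells, whose transcriptomes overlap) are
isolated and re-clustered on their own variable genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)

UNRESOLVED = "UNRESOLVED"
UNKNOWN = "UNKNOWN"

#: Published per-class cell counts of the capped, class-balanced GBM
#: single-cell reference (ten classes at the 458-cell cap; mast cells and
#: OPC fall below it).
GBM_REFERENCE_CLASS_SIZES: dict[str, int] = {
    "AC": 458,
    "B cells": 458,
    "DC": 458,
    "Mast cells": 88,
    "MES": 458,
    "Microglia": 458,
    "Monocytes": 458,
    "NK-cells": 458,
    "NPC": 458,
    "OPC": 407,
    "T-cells": 458,
    "TAM": 458,
}

DEFAULT_CLASS_CAP = 458


@dataclass
class ClusterParams:
    """Knobs of the clustering recipe.

    ``n_pcs``/``k`` defaults follow common practice for graph clustering
    of scRNA-seq (30 PCs, 20 neighbors); ``resolution`` 0.7 gives
    immune-subtype-level granularity.
    """

    n_hvg: int = 2000
    n_pcs: int = 30
    k: int = 20
    resolution: float = 0.7
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.n_pcs <= self.n_hvg):
            raise ValueError("need 0 < n_pcs <= n_hvg")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass
class ClusterAssignment:
    """Per-cell cluster IDs (contiguous ints from 0) plus the params used."""

    clusters: pd.Series  # cell -> int
    params: ClusterParams

    def __post_init__(self) -> None:
        ids = np.sort(self.clusters.unique())
        if len(ids) and not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError(f"cluster IDs not contiguous from 0: {ids}")

    @property
    def n_clusters(self) -> int:
        return int(self.clusters.nunique())


@dataclass
class AnnotationResult:
    """Cluster -> cell-type label mapping with the supporting cross-tab."""

    labels: dict[int, str]
    cross_tab: pd.DataFrame  # clusters x transferred labels (counts)
    majority_frac: float = 0.5

    def unresolved_clusters(self) -> list[int]:
        return [c for c, l in self.labels.items() if l == UNRESOLVED]

    def cell_labels(self, assignment: ClusterAssignment) -> pd.Series:
        return assignment.clusters.map(self.labels)


def cluster_cells(
    norm: ExpressionMatrix, params: ClusterParams
) -> ClusterAssignment:
    """HVG -> PCA -> kNN graph -> Leiden, deterministic for a fixed seed."""
    if norm.scale != "log":
        raise ValueError("cluster_cells expects log-scale expression")
    n_cells = norm.n_obs
    if n_cells < params.k + 1:
        raise ValueError(
            f"need at least k+1={params.k + 1} cells, got {n_cells}"
        )
    X = norm.values.to_numpy(dtype=float).T  # cells x genes

    gene_var = X.var(axis=0)
    n_hvg = min(params.n_hvg, X.shape[1])
    hvg_idx = np.argsort(-gene_var, kind="stable")[:n_hvg]
    # PCA rank is limited by both the cell count and the HVG count
    n_pcs = min(params.n_pcs, n_hvg, n_cells - 1)
    if n_pcs < params.n_pcs:
        logger.info("reducing n_pcs from %d to %d", params.n_pcs, n_pcs)

    adata = ad.AnnData(X[:, hvg_idx])
    sc.pp.pca(adata, n_comps=n_pcs, svd_solver="arpack",
              random_state=params.seed)
    sc.pp.neighbors(adata, n_neighbors=params.k, use_rep="X_pca",
                    random_state=params.seed)
    import warnings

    with warnings.catch_warnings():
        # scanpy warns about a future default change even when the
        # leidenalg flavor is requested explicitly
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            adata,
            resolution=params.resolution,
            random_state=params.seed,
            flavor="leidenalg",
            key_added="leiden",
        )
    raw = adata.obs["leiden"].astype(int).to_numpy()
    # renumber by decreasing cluster size, ties by first appearance
    order = pd.Series(raw).value_counts(sort=True).index
    remap = {old: new for new, old in enumerate(order)}
    clusters = pd.Series([remap[c] for c in raw], index=norm.obs_ids,
                         name="cluster")
    return ClusterAssignment(clusters, params)


def annotate_clusters(
    assignment: ClusterAssignment,
    transferred_labels: pd.Series,
    majority_frac: float = 0.5,
) -> AnnotationResult:
    """Label each cluster by majority vote over transferred labels.

    A cluster gets label L iff count(L) / count(non-UNKNOWN) exceeds
    ``majority_frac`` for exactly one L; otherwise it is UNRESOLVED.
    """
    labels = transferred_labels.reindex(assignment.clusters.index)
    if labels.isna().any():
        missing = labels.index[labels.isna()]
        raise ValueError(f"cells without transferred label: {list(missing[:5])}")
    cross = pd.crosstab(assignment.clusters, labels)
    cross = cross.reindex(range(assignment.n_clusters), fill_value=0)
    result: dict[int, str] = {}
    for cluster_id, row in cross.iterrows():
        known = row.drop(UNKNOWN, errors="ignore")
        total_known = known.sum()
        if total_known == 0:
            logger.warning("cluster %d has only UNKNOWN labels", cluster_id)
            result[cluster_id] = UNRESOLVED
            continue
        winners = known[known / total_known > majority_frac]
        if len(winners) == 1:
            result[cluster_id] = str(winners.index[0])
        else:
            result[cluster_id] = UNRESOLVED
    return AnnotationResult(result, cross, majority_frac)


def subcluster_unresolved(
    norm: ExpressionMatrix,
    assignment: ClusterAssignment,
    annotation: AnnotationResult,
    transferred_labels: pd.Series,
    params: ClusterParams | None = None,
    max_rounds: int = 2,
) -> tuple[ClusterAssignment, AnnotationResult]:
    """Iteratively re-cluster unresolved clusters on their own HVGs.

    Cells of all UNRESOLVED clusters are isolated and sent back through
    the same pipeline (fresh HVG selection and PCA on the subset), then
    re-annotated; resolved sub-clusters are merged back with new cluster
    IDs. Labels of already-resolved clusters never change. Clusters that
    remain unresolved after ``max_rounds`` are retained as UNRESOLVED and
    should be excluded from marker derivation.
    """
    params = params or assignment.params
    clusters = assignment.clusters.copy()
    labels = dict(annotation.labels)
    cross = annotation.cross_tab

    for round_idx in range(max_rounds):
        unresolved = [c for c, l in labels.items() if l == UNRESOLVED]
        if not unresolved:
            break
        cells = clusters.index[clusters.isin(unresolved)]
        if len(cells) < params.k + 1:
            logger.warning(
                "only %d unresolved cells, too few to sub-cluster", len(cells)
            )
            break
        sub_norm = norm.subset_obs(cells)
        sub_assign = cluster_cells(sub_norm, params)
        sub_annot = annotate_clusters(
            sub_assign, transferred_labels.loc[cells], annotation.majority_frac
        )
        # merge: new contiguous IDs appended after the surviving clusters
        keep_ids = sorted(set(labels) - set(unresolved))
        remap_old = {old: new for new, old in enumerate(keep_ids)}
        next_id = len(keep_ids)
        new_clusters = clusters.map(lambda c: remap_old.get(c, -1))
        new_labels = {remap_old[c]: labels[c] for c in keep_ids}
        for sub_id in range(sub_assign.n_clusters):
            gid = next_id + sub_id
            members = sub_assign.clusters.index[sub_assign.clusters == sub_id]
            new_clusters.loc[members] = gid
            new_labels[gid] = sub_annot.labels[sub_id]
        clusters = new_clusters
        labels = new_labels
        cross = pd.crosstab(
            clusters, transferred_labels.reindex(clusters.index)
        ).reindex(range(len(labels)), fill_value=0)
        logger.info(
            "sub-clustering round %d: %d clusters, %d unresolved",
            round_idx + 1,
            len(labels),
            len([l for l in labels.values() if l == UNRESOLVED]),
        )
    still = [c for c, l in labels.items() if l == UNRESOLVED]
    if still:
        logger.warning("clusters still UNRESOLVED after sub-clustering: %s", still)
    return (
        ClusterAssignment(clusters, params),
        AnnotationResult(labels, cross, annotation.majority_frac),
    )


def balance_classes(
    labels: pd.Series, cap: int = DEFAULT_CLASS_CAP, seed: int = 1
) -> list[str]:
    """Capped class-balanced downsampling of a labeled cell population.

    Classes at or below ``cap`` are kept entirely; larger classes are
    sampled without replacement down to exactly ``cap`` cells.
    Deterministic for a fixed seed; kept cells preserve their original
    order.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if labels.isna().any():
        raise ValueError("every cell must be labeled")
    rng = np.random.default_rng(seed)
    keep_mask = pd.Series(False, index=labels.index)
    for cls in sorted(labels.unique()):
        members = labels.index[labels == cls]
        if len(members) <= cap:
            keep_mask.loc[members] = True
        else:
            chosen = rng.choice(len(members), size=cap, replace=False)
            keep_mask.loc[members[np.sort(chosen)]] = True
    return list(keep_mask.index[keep_mask])
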