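"""Marker-gene derivation by pairwise differential expression.

For every ordered pair of annotated clusters, each gene is tested for
up-regulation in the first cluster with both a Welch t-test and a
Wilcoxon rank-sum test (one-sided; asymptotic normal approximation with
tie correction). Per focal cluster the pairwise results are combined two
ways: the best rank a gene attains against *any* partner (a gene highly
up against at least one other cluster) and the worst p-value against
*all* partners (a gene up against every other cluster). The two test
statistics are merged pessimistically — a gene is only as good as its
worse test — and the top genes per cluster with strictly positive
minimum log-fold-change become that cell type's markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .types import ExpressionMatrix, MarkerTable

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass
class MarkerParams:
    n_top: int = 25
    min_lfc_filter: float = 0.0   # markers must exceed this vs every partner
    require_unique: bool = True   # a gene may serve only one cell type

    def __post_init__(self) -> None:
        if self.n_top < 1:
            raise ValueError("n_top must be >= 1")


@dataclass
class PairwiseDEResult:
    """Per ordered cluster pair (A, B): genes x {lfc, p_t, p_w} where lfc
    is mean log-expression in A minus B and p-values test up-regulation
    in A."""

    tables: dict[tuple[str, str], pd.DataFrame]
    clusters: list[str]
    genes: pd.Index

    def table(self, a, b) -> pd.DataFrame:
        return self.tables[(a, b)]


def _one_sided_tests(
    xa: np.ndarray, xb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-gene Welch t and Wilcoxon one-sided ('greater in A')
    p-values plus the mean difference."""
    lfc = xa.mean(axis=1) - xb.mean(axis=1)

    t_res = scipy.stats.ttest_ind(
        xa, xb, axis=1, equal_var=False, alternative="greater"
    )
    p_t = np.asarray(t_res.pvalue, dtype=float)
    # zero variance in both groups: scipy yields NaN; decide by the means
    nan_mask = ~np.isfinite(p_t)
    p_t[nan_mask & (lfc > 0)] = P_FLOOR
    p_t[nan_mask & (lfc <= 0)] = 1.0

    w_res = scipy.stats.mannwhitneyu(
        xa, xb, axis=1, alternative="greater", method="asymptotic"
    )
    p_w = np.asarray(w_res.pvalue, dtype=float)
    p_w[~np.isfinite(p_w)] = 1.0

    # fully constant genes carry no signal at all
    const = (np.ptp(xa, axis=1) == 0) & (np.ptp(xb, axis=1) == 0) & (lfc == 0)
    p_t[const] = 1.0
    p_w[const] = 1.0
    p_t = np.clip(p_t, P_FLOOR, 1.0)
    p_w = np.clip(p_w, P_FLOOR, 1.0)
    return lfc, p_t, p_w


def pairwise_de(norm: ExpressionMatrix, labels: pd.Series) -> PairwiseDEResult:
    """All ordered cluster-pair DE tables on log-scale expression."""
    if norm.scale != "log":
        raise ValueError("pairwise DE expects log-scale expression")
    labels = labels.reindex(norm.obs_ids)
    if labels.isna().any():
        raise ValueError("every cell needs a cluster label")
    sizes = labels.value_counts()
    small = sizes[sizes < 3]
    if len(small):
        raise ValueError(
            f"clusters with fewer than 3 cells: {small.index.tolist()}"
        )
    clusters = sorted(map(str, sizes.index))
    groups = {
        c: norm.values.loc[:, labels.astype(str) == c].to_numpy(dtype=float)
        for c in clusters
    }
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            lfc, p_t, p_w = _one_sided_tests(groups[a], groups[b])
            tables[(a, b)] = pd.DataFrame(
                {"lfc": lfc, "p_t": p_t, "p_w": p_w}, index=norm.gene_ids
            )
            # the reverse direction reuses the data with flipped hypotheses
            lfc_r, p_t_r, p_w_r = _one_sided_tests(groups[b], groups[a])
            tables[(b, a)] = pd.DataFrame(
                {"lfc": lfc_r, "p_t": p_t_r, "p_w": p_w_r}, index=norm.gene_ids
            )
    return PairwiseDEResult(tables, clusters, norm.gene_ids)


def combine_pairwise(de: PairwiseDEResult, focal: str) -> pd.DataFrame:
    """Combine a focal cluster's pairwise tables into marker statistics.

    Per test statistic: within each pairwise comparison genes are ranked
    by p ascending (average ranks on ties); ``rank_any`` is the minimum
    rank over partners and ``p_all`` the maximum p over partners. Across
    the two tests the pessimistic combination is taken (max of ranks, max
    of p). ``min_lfc`` is the worst log-fold-change over partners.
    """
    focal = str(focal)
    if len(de.clusters) < 2:
        raise ValueError("need at least 2 clusters")
    if focal not in de.clusters:
        raise ValueError(f"focal cluster {focal!r} absent from DE result")
    partners = [c for c in de.clusters if c != focal]
    rank_any = {"p_t": None, "p_w": None}
    p_all = {"p_t": None, "p_w": None}
    min_lfc = None
    for b in partners:
        tab = de.table(focal, b)
        for test in ("p_t", "p_w"):
            ranks = scipy.stats.rankdata(tab[test].to_numpy(), method="average")
            rank_any[test] = (
                ranks if rank_any[test] is None
                else np.minimum(rank_any[test], ranks)
            )
            p_all[test] = (
                tab[test].to_numpy() if p_all[test] is None
                else np.maximum(p_all[test], tab[test].to_numpy())
            )
        lfc = tab["lfc"].to_numpy()
        min_lfc = lfc if min_lfc is None else np.minimum(min_lfc, lfc)
    return pd.DataFrame(
        {
            "rank_any": np.maximum(rank_any["p_t"], rank_any["p_w"]),
            "p_all": np.maximum(p_all["p_t"], p_all["p_w"]),
            "min_lfc": min_lfc,
        },
        index=de.genes,
    )


def derive_marker_set(
    stats: dict[str, pd.DataFrame], params: MarkerParams | None = None
) -> MarkerTable:
    """Top-N marker selection per cluster from combined statistics.

    Genes must be up-regulated against every partner (``min_lfc``
    strictly above ``min_lfc_filter``); ordering is (combined rank asc,
    combined p asc, gene ID). With ``require_unique`` a gene claimed by
    several clusters goes to the cluster where its rank is best (ties
    drop it everywhere).
    """
    params = params or MarkerParams()
    candidates: dict[str, pd.DataFrame] = {}
    for cluster, tab in stats.items():
        keep = tab[tab["min_lfc"] > params.min_lfc_filter].copy()
        keep["_gene"] = keep.index
        keep = keep.sort_values(
            ["rank_any", "p_all", "_gene"], kind="stable"
        ).head(params.n_top)
        candidates[cluster] = keep

    if params.require_unique:
        claims: dict[str, list[tuple[str, float]]] = {}
        for cluster, tab in candidates.items():
            for gene, row in tab.iterrows():
                claims.setdefault(gene, []).append((cluster, row["rank_any"]))
        for gene, owners in claims.items():
            if len(owners) < 2:
                continue
            best = min(r for _, r in owners)
            winners = [c for c, r in owners if r == best]
            keep_in = winners[0] if len(winners) == 1 else None
            for cluster, _ in owners:
                if cluster != keep_in:
                    candidates[cluster] = candidates[cluster].drop(index=gene)

    rows = []
    for cluster in sorted(candidates):
        tab = candidates[cluster]
        if tab.empty:
            raise ValueError(f"cluster {cluster!r} yields no markers")
        if len(tab) < params.n_top:
            logger.warning(
                "cluster %s has only %d of %d requested markers",
                cluster, len(tab), params.n_top,
            )
        for rank, (gene, row) in enumerate(tab.iterrows(), start=1):
            rows.append(
                {"gene": gene, "cell_type": cluster, "rank": rank,
                 "effect_size": row["min_lfc"]}
            )
    return MarkerTable(pd.DataFrame(rows))


def filter_tumor_intrinsic(
    markers: MarkerTable,
    excluded_genes,
    applies_to,
) -> MarkerTable:
    """Drop non-tumor-intrinsic genes from neoplastic marker lists.

    Genes of the neoplastic cell states that are also expressed by the
    tumor microenvironment would pick up signal from non-cancer cells in
    bulk tissue, so they are removed from the lists named in
    ``applies_to``; other cell types are untouched.
    """
    excluded = set(excluded_genes)
    applies_to = set(applies_to)
    missing = applies_to - set(markers.cell_types)
    if missing:
        raise ValueError(f"applies_to labels not in marker table: {sorted(missing)}")
    ent = markers.entries
    drop = ent["cell_type"].isin(applies_to) & ent["gene"].isin(excluded)
    if drop.any():
        logger.info("tumor-intrinsic filter removed %d marker entries",
                    int(drop.sum()))
    kept = ent[~drop].reset_index(drop=True)
    emptied = applies_to - set(kept["cell_type"])
    if emptied:
        raise ValueError(
            f"tumor-intrinsic filtering removed every marker for {sorted(emptied)}"
        )
    return MarkerTable(kept)
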