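"""Per-cell quality control and normalization for single-cell counts.

QC metrics follow standard droplet scRNA-seq practice: total UMIs,
detected genes, mitochondrial and ribosomal count fractions, and a
complexity statistic log10(nGene)/log10(nUMI) that separates
low-complexity droplets (ambient RNA, dying cells) from intact cells.
Normalization is log-CPM: ln(1 + count * scale_factor / cell_total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .types import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Filtering thresholds; any field left ``None`` is not applied."""

    min_umi: float | None = None
    min_gene: float | None = None
    max_mito_ratio: float | None = None
    max_ribo_ratio: float | None = None
    min_complexity: float | None = None

    def __post_init__(self) -> None:
        for name in ("min_umi", "min_gene", "max_mito_ratio",
                     "max_ribo_ratio", "min_complexity"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        for name in ("max_mito_ratio", "max_ribo_ratio"):
            v = getattr(self, name)
            if v is not None and v > 1:
                raise ValueError(f"{name} is a fraction, got {v}")


def genes_with_prefix(gene_ids: Iterable[str], prefixes: Iterable[str]) -> set[str]:
    """Select genes by symbol prefix, e.g. ``MT-`` or ``RPS``/``RPL``."""
    prefixes = tuple(prefixes)
    return {g for g in gene_ids if g.startswith(prefixes)}


def compute_qc_metrics(
    counts: ExpressionMatrix,
    mito_genes: Iterable[str] = (),
    ribo_genes: Iterable[str] = (),
) -> pd.DataFrame:
    """Compute per-cell QC metrics from raw counts.

    Returns a DataFrame indexed by cell with columns ``n_umi``,
    ``n_gene``, ``mito_ratio``, ``ribo_ratio`` and ``complexity``.
    Complexity is NaN when a cell has <= 1 total counts (log10(nUMI)
    would be zero or undefined).
    """
    if counts.scale != "counts":
        raise ValueError(f"QC metrics need raw counts, got scale={counts.scale!r}")
    arr = counts.values.to_numpy()
    n_umi = arr.sum(axis=0)
    n_gene = (arr > 0).sum(axis=0)

    def _ratio(gene_set: Iterable[str], name: str) -> np.ndarray:
        genes = [g for g in gene_set if g in counts.gene_ids]
        if not genes and list(gene_set):
            logger.warning("no %s genes found in matrix; ratios set to 0", name)
        if not genes:
            return np.zeros_like(n_umi, dtype=float)
        sub = counts.values.loc[genes].to_numpy().sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_umi > 0, sub / n_umi, 0.0)

    mito_ratio = _ratio(mito_genes, "mitochondrial")
    ribo_ratio = _ratio(ribo_genes, "ribosomal")
    with np.errstate(invalid="ignore", divide="ignore"):
        complexity = np.where(
            n_umi > 1, np.log10(np.maximum(n_gene, 1)) / np.log10(n_umi), np.nan
        )
    return pd.DataFrame(
        {
            "n_umi": n_umi,
            "n_gene": n_gene,
            "mito_ratio": mito_ratio,
            "ribo_ratio": ribo_ratio,
            "complexity": complexity,
        },
        index=counts.obs_ids,
    )


def filter_cells(metrics: pd.DataFrame, thresholds: QCThresholds) -> pd.Series:
    """Boolean keep-mask: a cell passes iff it satisfies every supplied
    threshold. Cells with undefined complexity fail any ``min_complexity``
    test."""
    keep = pd.Series(True, index=metrics.index)
    criteria: list[tuple[str, pd.Series]] = []
    if thresholds.min_umi is not None:
        criteria.append(("min_umi", metrics["n_umi"] >= thresholds.min_umi))
    if thresholds.min_gene is not None:
        criteria.append(("min_gene", metrics["n_gene"] >= thresholds.min_gene))
    if thresholds.max_mito_ratio is not None:
        criteria.append(
            ("max_mito_ratio", metrics["mito_ratio"] <= thresholds.max_mito_ratio)
        )
    if thresholds.max_ribo_ratio is not None:
        criteria.append(
            ("max_ribo_ratio", metrics["ribo_ratio"] <= thresholds.max_ribo_ratio)
        )
    if thresholds.min_complexity is not None:
        criteria.append(
            (
                "min_complexity",
                metrics["complexity"].notna()
                & (metrics["complexity"] >= thresholds.min_complexity),
            )
        )
    for name, mask in criteria:
        removed = int((~mask & keep).sum())
        if removed:
            logger.info("QC %s removed %d cells", name, removed)
        keep &= mask
    if not keep.any():
        logger.warning("QC filtering removed every cell")
    return keep


def normalize_log_cpm(
    counts: ExpressionMatrix, scale_factor: float = 1e4
) -> ExpressionMatrix:
    """Depth-normalize and log-transform: ln(1 + count * sf / cell_total).

    Satisfies sum_g (exp(v_g) - 1) = scale_factor for every cell, which
    makes cells comparable regardless of sequencing depth.
    """
    if counts.scale != "counts":
        raise ValueError("normalize_log_cpm expects raw counts")
    arr = counts.values.to_numpy(dtype=float)
    totals = arr.sum(axis=0)
    if (totals == 0).any():
        bad = counts.obs_ids[totals == 0]
        raise ValueError(
            f"all-zero cells present ({list(bad[:5])}); run filter_cells first"
        )
    values = np.log1p(arr * scale_factor / totals)
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.gene_ids, columns=counts.obs_ids),
        scale="log",
        obs_meta=counts.obs_meta,
    )
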