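"""Marker-based deconvolution scoring and its regression comparator.

The scoring engine assigns each cell type, in each bulk sample, the
arithmetic mean of the log2 expression of that type's marker genes — an
MCP-counter-style prevalence score. Scores are comparable across samples
within a cell type, never across cell types within a sample: marker sets
differ in size and baseline expression, so the absolute score level is
arbitrary per type.

A non-negative least squares (NNLS) deconvolver over a signature matrix
is provided as a regression-based comparator that *does* return
per-sample proportions; it is a deliberately simple stand-in for
signature-matrix tools so the marker-vs-signature comparison can be run
end-to-end.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .types import ExpressionMatrix, MarkerTable, ScoreMatrix

logger = logging.getLogger(__name__)


def score_mcp(
    bulk: ExpressionMatrix,
    markers: MarkerTable,
    min_coverage_warn: float = 0.5,
) -> ScoreMatrix:
    """Marker-mean prevalence score per cell type per sample.

    Linear-scale input is transformed to log2(x+1); log-scale input is
    used as given. Markers absent from the bulk matrix are skipped (the
    present subset is averaged — absent genes are not imputed as zeros,
    which would bias scores downward in gene-filtered matrices); the
    per-type fraction found is reported as coverage.
    """
    if bulk.scale == "counts":
        raise ValueError(
            "score_mcp expects linear or log expression, not raw counts"
        )
    if bulk.scale == "linear":
        values = np.log2(bulk.values.to_numpy(dtype=float) + 1.0)
    elif bulk.scale == "log":
        values = bulk.values.to_numpy(dtype=float)
    else:  # pragma: no cover - guarded by ExpressionMatrix
        raise ValueError(f"unknown scale {bulk.scale!r}")
    log_df = pd.DataFrame(values, index=bulk.gene_ids, columns=bulk.obs_ids)

    rows = {}
    coverage = {}
    for cell_type in markers.cell_types:
        genes = markers.genes_for(cell_type)
        present = [g for g in genes if g in log_df.index]
        cov = len(present) / len(genes)
        if not present:
            raise ValueError(
                f"no marker genes of {cell_type!r} present in the bulk matrix"
            )
        if cov < min_coverage_warn:
            logger.warning(
                "cell type %s: only %.0f%% of markers present",
                cell_type, 100 * cov,
            )
        rows[cell_type] = log_df.loc[present].mean(axis=0)
        coverage[cell_type] = cov
    scores = pd.DataFrame(rows).T
    scores.index.name = "cell_type"
    return ScoreMatrix(scores, pd.Series(coverage))


def build_signature(
    reference: ExpressionMatrix,
    labels: pd.Series,
    markers: MarkerTable,
) -> pd.DataFrame:
    """Genes x cell-types signature of mean linear-scale expression.

    Log-scale references are mapped back to linear via expm1 before
    averaging; the signature is restricted to the union of marker genes.
    """
    labels = labels.reindex(reference.obs_ids)
    if labels.isna().any():
        raise ValueError("every reference cell needs a type label")
    genes = sorted({g for ct in markers.cell_types
                    for g in markers.genes_for(ct)})
    missing = [g for g in genes if g not in reference.gene_ids]
    if missing:
        raise ValueError(f"marker genes absent from reference: {missing[:5]}")
    sub = reference.values.loc[genes]
    arr = sub.to_numpy(dtype=float)
    if reference.scale == "log":
        arr = np.expm1(arr)
    cols = {}
    for cell_type in sorted(labels.unique()):
        mask = (labels == cell_type).to_numpy()
        if mask.sum() == 0:
            raise ValueError(f"cell type {cell_type!r} has no cells")
        cols[cell_type] = arr[:, mask].mean(axis=1)
    return pd.DataFrame(cols, index=genes)


def nnls_deconvolve(
    bulk: ExpressionMatrix, signature: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample NNLS proportions of bulk expression on a signature.

    Returns (proportions: samples x cell types summing to 1, residual
    norm per sample). Coefficients that solve min ||S p - x||, p >= 0 are
    renormalized to the simplex; an all-zero solution falls back to a
    uniform vector with a warning.
    """
    if bulk.scale != "linear":
        raise ValueError("NNLS deconvolution expects linear-scale bulk")
    shared = [g for g in signature.index if g in bulk.gene_ids]
    n_types = signature.shape[1]
    if len(shared) < n_types:
        raise ValueError(
            f"only {len(shared)} shared genes for {n_types} cell types"
        )
    S = signature.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(S) < n_types:
        logger.warning(
            "signature matrix is rank-deficient (cond=%.3g); "
            "proportions may be unidentifiable",
            np.linalg.cond(S),
        )
    props = {}
    residuals = {}
    for sample in bulk.obs_ids:
        x = bulk.values.loc[shared, sample].to_numpy(dtype=float)
        coef, resid = scipy.optimize.nnls(S, x)
        total = coef.sum()
        if total == 0:
            logger.warning("sample %s: all-zero NNLS fit, uniform fallback",
                           sample)
            coef = np.full(n_types, 1.0 / n_types)
        else:
            coef = coef / total
        props[sample] = coef
        residuals[sample] = resid
    proportions = pd.DataFrame(props, index=signature.columns).T
    return proportions, pd.Series(residuals, name="residual_norm")


def validate_against_truth(
    scores: ScoreMatrix,
    truth: pd.DataFrame,
    label_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of scores vs ground-truth proportions.

    ``truth`` is samples x cell types (e.g. proportions counted from an
    annotated single-cell-resolution image of the same tissue).
    ``label_map`` translates score cell-type labels to truth labels when
    the vocabularies differ. Returns a per-cell-type table of (r, p, n)
    plus a ``mean`` summary row averaging r over cell types.
    """
    label_map = label_map or {}
    shared_samples = [s for s in scores.samples if s in truth.index]
    if len(shared_samples) < 3:
        raise ValueError(
            f"need >= 3 shared samples, got {len(shared_samples)}"
        )
    rows = []
    for cell_type in scores.cell_types:
        truth_label = label_map.get(cell_type, cell_type)
        if truth_label not in truth.columns:
            continue
        x = scores.scores.loc[cell_type, shared_samples].to_numpy(dtype=float)
        y = truth.loc[shared_samples, truth_label].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning(
                "cell type %s has a zero-variance vector; r undefined",
                cell_type,
            )
            rows.append({"cell_type": cell_type, "r": np.nan, "p": np.nan,
                         "n": len(shared_samples)})
            continue
        r, p = scipy.stats.pearsonr(x, y)
        rows.append({"cell_type": cell_type, "r": r, "p": p,
                     "n": len(shared_samples)})
    if not rows:
        raise ValueError("no shared cell types between scores and truth")
    report = pd.DataFrame(rows).set_index("cell_type")
    report.loc["mean"] = [report["r"].mean(skipna=True), np.nan,
                          len(shared_samples)]
    return report
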