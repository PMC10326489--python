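"""Expression-based copy-number inference to flag neoplastic cells.

Large chromosomal dosage changes leave a coherent shift in the expression
of the genes they span. Per gene, each cell's log expression is centered
on the all-cell mean (the baseline), clipped to damp outliers, and
smoothed along genomic position with a centered moving average; a
chromosome whose mean smoothed score departs from zero indicates a gain
or loss. The canonical IDHwt-GBM neoplastic signature is chromosome 7
amplification together with chromosome 10 deletion, so cells showing
both are flagged for removal from an immune reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GenePositionTable

logger = logging.getLogger(__name__)


@dataclass
class CNVParams:
    window: int = 101          # genes per moving-average window (odd)
    clip: float = 3.0          # max |centered log expression| pre-smoothing
    arm_threshold: float = 0.15  # |chromosome mean| needed to call an event
    target_gain: str = "7"
    target_loss: str = "10"
    mode: str = "both"         # {"both", "either"}

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.clip <= 0 or self.arm_threshold <= 0:
            raise ValueError("clip and arm_threshold must be positive")
        if self.mode not in ("both", "either"):
            raise ValueError("mode must be 'both' or 'either'")


@dataclass
class CNVProfile:
    """Smoothed per-cell CNV tracks and per-chromosome summary scores."""

    smoothed: dict[str, pd.DataFrame]  # chrom -> genes(ordered) x cells
    chrom_means: pd.DataFrame          # cells x chroms
    params: CNVParams
    neoplastic: pd.Series | None = None  # set by flag_neoplastic


def order_genes_by_position(
    genes, positions: GenePositionTable, window: int = 3
) -> dict[str, list[str]]:
    """Per-chromosome gene lists sorted by start coordinate.

    Genes absent from the position table are dropped (logged);
    chromosomes carrying fewer than ``window`` placed genes are skipped
    because a moving average there is meaningless.
    """
    genes = list(genes)
    pos = positions.rows.set_index("gene")
    present = [g for g in genes if g in pos.index]
    dropped = len(genes) - len(present)
    if dropped:
        logger.info("%d genes absent from position table, dropped", dropped)
    if not present:
        raise ValueError("no overlap between matrix genes and position table")
    sub = pos.loc[present]
    ordered: dict[str, list[str]] = {}
    for chrom, grp in sub.groupby("chrom", sort=True):
        if len(grp) < window:
            logger.warning(
                "chromosome %s has %d genes < window %d; skipped",
                chrom, len(grp), window,
            )
            continue
        ordered[str(chrom)] = grp.sort_values(
            "start", kind="stable").index.tolist()
    if not ordered:
        raise ValueError("window exceeds the gene count on every chromosome")
    return ordered


def _moving_average_shrink(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average along axis 0 whose half-width shrinks
    symmetrically near the edges (position i averages indices
    [i-h_i, i+h_i] with h_i = min(h, i, n-1-i))."""
    n = values.shape[0]
    half = window // 2
    csum = np.vstack([np.zeros((1,) + values.shape[1:]),
                      np.cumsum(values, axis=0)])
    out = np.empty_like(values, dtype=float)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def compute_cnv_profile(
    norm: ExpressionMatrix,
    ordered_genes: dict[str, list[str]],
    params: CNVParams | None = None,
) -> CNVProfile:
    """Baseline-centered, clipped, position-smoothed CNV score per cell.

    The baseline is the all-cell mean per gene (no reference population
    needed), so scores are relative to the dataset average: a clonal
    gain present in every cell is invisible, while gains restricted to a
    subpopulation stand out against the rest.
    """
    params = params or CNVParams()
    if norm.scale != "log":
        raise ValueError("CNV profiling expects log-scale expression")
    if norm.n_obs < 2:
        raise ValueError("need at least 2 cells for a meaningful baseline")
    smoothed: dict[str, pd.DataFrame] = {}
    means: dict[str, np.ndarray] = {}
    for chrom, genes in ordered_genes.items():
        sub = norm.values.loc[genes].to_numpy(dtype=float)
        centered = sub - sub.mean(axis=1, keepdims=True)
        centered = np.clip(centered, -params.clip, params.clip)
        sm = _moving_average_shrink(centered, params.window)
        smoothed[chrom] = pd.DataFrame(sm, index=genes, columns=norm.obs_ids)
        means[chrom] = sm.mean(axis=0)
    chrom_means = pd.DataFrame(means, index=norm.obs_ids)
    return CNVProfile(smoothed, chrom_means, params)


def flag_neoplastic(
    profile: CNVProfile, params: CNVParams | None = None
) -> pd.Series:
    """Boolean per-cell flag for the gain/loss signature.

    ``mode="both"`` requires the gain chromosome mean above
    ``+arm_threshold`` AND the loss chromosome mean below
    ``-arm_threshold``; ``mode="either"`` accepts either event alone.
    """
    params = params or profile.params
    for chrom in (params.target_gain, params.target_loss):
        if chrom not in profile.chrom_means.columns:
            raise ValueError(f"chromosome {chrom!r} absent from CNV profile")
    gain = profile.chrom_means[params.target_gain] > params.arm_threshold
    loss = profile.chrom_means[params.target_loss] < -params.arm_threshold
    flags = (gain & loss) if params.mode == "both" else (gain | loss)
    flags = flags.rename("neoplastic")
    logger.info("flagged %.1f%% of cells as neoplastic", 100 * flags.mean())
    profile.neoplastic = flags
    return flags
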