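"""Core in-memory containers shared across the pipeline.

The same :class:`ExpressionMatrix` container holds single-cell raw counts
(genes x cells) and bulk expression (genes x samples); a ``scale`` tag
records whether values are raw counts, linear-scale expression (e.g. TPM)
or log-transformed, because downstream operations are scale-sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

VALID_SCALES = ("counts", "linear", "log")


def _find_duplicates(ids: Iterable[str]) -> list[str]:
    seen: set[str] = set()
    dups: list[str] = []
    for x in ids:
        if x in seen and x not in dups:
            dups.append(x)
        seen.add(x)
    return dups


@dataclass
class ExpressionMatrix:
    """Genes x observations expression values with a scale tag.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with observation IDs as columns.
    scale
        One of ``{"counts", "linear", "log"}``.
    obs_meta
        Optional per-observation annotation table (indexed by observation
        ID) carrying e.g. ``sample``, ``label`` or ``cluster`` columns.
    """

    values: pd.DataFrame
    scale: str
    obs_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(
                f"scale must be one of {VALID_SCALES}, got {self.scale!r}"
            )
        dup_genes = _find_duplicates(self.values.index)
        if dup_genes:
            raise ValueError(f"duplicate gene IDs: {dup_genes[:10]}")
        dup_obs = _find_duplicates(self.values.columns)
        if dup_obs:
            raise ValueError(f"duplicate observation IDs: {dup_obs[:10]}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if self.scale in ("counts", "linear") and (arr < 0).any():
            bad = self.values.columns[(arr < 0).any(axis=0)]
            raise ValueError(
                f"negative values not allowed on scale={self.scale!r} "
                f"(observations: {list(bad[:5])})"
            )
        if self.obs_meta is not None:
            missing = self.values.columns.difference(self.obs_meta.index)
            if len(missing):
                raise ValueError(
                    f"obs_meta missing observations: {list(missing[:5])}"
                )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def obs_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_obs(self) -> int:
        return self.values.shape[1]

    def subset_obs(self, obs: Iterable[str]) -> "ExpressionMatrix":
        obs = list(obs)
        meta = self.obs_meta.loc[obs] if self.obs_meta is not None else None
        return ExpressionMatrix(self.values[obs], self.scale, meta)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(genes)], self.scale, self.obs_meta
        )


@dataclass
class MarkerTable:
    """Ordered marker-gene lists per cell type.

    ``entries`` has columns ``gene``, ``cell_type`` and optionally ``rank``
    and ``effect_size``. File order (or derivation order) within a cell
    type is the marker rank.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "cell_type"}
        if not required.issubset(self.entries.columns):
            raise ValueError(f"marker table needs columns {sorted(required)}")
        if self.entries.empty:
            raise ValueError("marker table is empty")
        pairs = self.entries[["gene", "cell_type"]]
        dup = pairs[pairs.duplicated()]
        if len(dup):
            raise ValueError(
                "duplicated (gene, cell_type) pairs: "
                f"{dup.values[:5].tolist()}"
            )
        if (self.entries["cell_type"].astype(str).str.len() == 0).any():
            raise ValueError("empty cell_type label in marker table")

    @property
    def cell_types(self) -> list[str]:
        # preserve first-appearance order
        return list(dict.fromkeys(self.entries["cell_type"]))

    def genes_for(self, cell_type: str) -> list[str]:
        mask = self.entries["cell_type"] == cell_type
        return self.entries.loc[mask, "gene"].tolist()

    def as_dict(self) -> dict[str, list[str]]:
        return {ct: self.genes_for(ct) for ct in self.cell_types}


@dataclass
class GenePositionTable:
    """Genomic anchor per gene: chromosome and start coordinate (bp)."""

    rows: pd.DataFrame  # columns: gene, chrom, start

    def __post_init__(self) -> None:
        required = {"gene", "chrom", "start"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"position table needs columns {sorted(required)}")
        dup = self.rows["gene"][self.rows["gene"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate genes in position table: {list(dup[:5])}")
        if (self.rows["start"] < 0).any():
            bad = self.rows.loc[self.rows["start"] < 0, "gene"]
            raise ValueError(f"negative start coordinate for {list(bad[:5])}")


@dataclass
class ScoreMatrix:
    """Cell-type x sample prevalence scores.

    Scores are comparable across samples *within* a cell type only; the
    absolute score of cell type A in a sample carries no meaning relative
    to cell type B in the same sample.
    """

    scores: pd.DataFrame  # cell types x samples
    marker_coverage: pd.Series = field(default=None)  # per cell type

    def __post_init__(self) -> None:
        if self.scores.empty:
            raise ValueError("score matrix is empty")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValueError("scores must be finite")
        if self.marker_coverage is None:
            self.marker_coverage = pd.Series(1.0, index=self.scores.index)

    @property
    def cell_types(self) -> pd.Index:
        return self.scores.index

    @property
    def samples(self) -> pd.Index:
        return self.scores.columns
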