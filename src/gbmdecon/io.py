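"""Readers and writers for the on-disk formats the pipeline consumes.

Dense expression matrices are TSV/CSV with genes in rows and a header of
observation IDs; sparse matrices are MatrixMarket ``.mtx`` triplets with
``genes.txt`` / ``barcodes.txt`` companions alongside. Marker tables,
gene positions, ground-truth proportions and survival tables are plain
TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .types import ExpressionMatrix, GenePositionTable, MarkerTable, ScoreMatrix

logger = logging.getLogger(__name__)


def infer_scale(values: np.ndarray) -> str:
    """Heuristic scale inference for expression values.

    All-integer values are taken as raw counts; otherwise a small dynamic
    range (max < 50) indicates already-log-transformed data, and anything
    else is linear-scale expression. Override with an explicit
    ``scale_hint`` when the provenance is known.
    """
    if np.allclose(values, np.round(values)):
        return "counts"
    if values.max() < 50:
        return "log"
    return "linear"


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    scale_hint: str | None = None,
) -> ExpressionMatrix:
    """Load a genes x observations expression matrix.

    Parameters
    ----------
    path
        TSV/CSV file, or a ``.mtx`` file with ``genes.txt`` and
        ``barcodes.txt`` next to it.
    format
        ``{"tsv", "csv", "mtx"}``; inferred from the suffix when omitted.
    scale_hint
        Force the scale tag instead of inferring it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = {".tsv": "tsv", ".csv": "csv", ".mtx": "mtx", ".txt": "tsv"}.get(
            path.suffix.lower()
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path.name}")

    if format == "mtx":
        genes_file = path.parent / "genes.txt"
        obs_file = path.parent / "barcodes.txt"
        for companion in (genes_file, obs_file):
            if not companion.exists():
                raise FileNotFoundError(
                    f"mtx companion file missing: {companion}"
                )
        mat = scipy.io.mmread(path)
        genes = genes_file.read_text().split()
        obs = obs_file.read_text().split()
        dense = np.asarray(
            mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float
        )
        if dense.shape != (len(genes), len(obs)):
            raise ValueError(
                f"mtx shape {dense.shape} does not match "
                f"{len(genes)} genes x {len(obs)} barcodes"
            )
        values = pd.DataFrame(dense, index=genes, columns=obs)
    else:
        sep = "\t" if format == "tsv" else ","
        try:
            values = pd.read_csv(path, sep=sep, index_col=0)
        except (pd.errors.ParserError, ValueError) as exc:
            raise ValueError(f"malformed expression file {path}: {exc}") from exc
        non_numeric = values.columns[
            [not np.issubdtype(dt, np.number) for dt in values.dtypes]
        ]
        if len(non_numeric):
            raise ValueError(
                f"non-numeric columns in {path.name}: {list(non_numeric[:5])}"
            )
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)

    scale = scale_hint or infer_scale(values.to_numpy())
    if scale_hint is None:
        logger.info("inferred scale=%s for %s", scale, path.name)
    return ExpressionMatrix(values, scale)


def write_expression_matrix(mat: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    mat.values.to_csv(path, sep="\t", float_format="%.10g", index_label="gene")


def read_marker_table(path: str | Path) -> MarkerTable:
    """Load a marker TSV with ``gene`` and ``cell_type`` columns.

    File order is preserved and becomes the marker rank within each cell
    type.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene", "cell_type"}.issubset(df.columns):
        raise ValueError(
            f"{Path(path).name}: marker table must have 'gene' and "
            f"'cell_type' columns, found {list(df.columns)}"
        )
    if df[["gene", "cell_type"]].isna().any().any():
        bad = df[df[["gene", "cell_type"]].isna().any(axis=1)].index[:5]
        raise ValueError(f"missing gene/cell_type at rows {list(bad)}")
    if "effect_size" in df.columns:
        df["effect_size"] = df["effect_size"].astype(float)
    df["rank"] = df.groupby("cell_type").cumcount() + 1
    return MarkerTable(df.reset_index(drop=True))


def write_marker_table(markers: MarkerTable, path: str | Path) -> None:
    cols = [c for c in ("gene", "cell_type", "rank", "effect_size")
            if c in markers.entries.columns]
    markers.entries[cols].to_csv(path, sep="\t", index=False)


def read_gene_positions(path: str | Path) -> GenePositionTable:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "chrom": str})
    if not {"gene", "chrom", "start"}.issubset(df.columns):
        raise ValueError(
            "gene position table must have 'gene', 'chrom', 'start' columns"
        )
    df["start"] = df["start"].astype(int)
    return GenePositionTable(df.reset_index(drop=True))


def write_gene_positions(positions: GenePositionTable, path: str | Path) -> None:
    positions.rows.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ScoreMatrix(df)


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write a cell-type x sample score TSV at full float precision."""
    scores.scores.to_csv(path, sep="\t", float_format="%.12g",
                         index_label="cell_type")


def read_proportions(path: str | Path) -> pd.DataFrame:
    """Ground-truth proportions: samples in rows, cell types in columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if (df.to_numpy() < 0).any():
        raise ValueError("proportions must be nonnegative")
    return df


def write_proportions(props: pd.DataFrame, path: str | Path) -> None:
    props.to_csv(path, sep="\t", float_format="%.12g", index_label="sample")


def read_survival(path: str | Path) -> pd.DataFrame:
    """Survival TSV with columns ``sample``, ``os_months`` and optional
    ``event``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    if not {"sample", "os_months"}.issubset(df.columns):
        raise ValueError("survival table needs 'sample' and 'os_months' columns")
    df["os_months"] = df["os_months"].astype(float)
    return df.set_index("sample")


def read_label_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping score cell-type labels to truth labels."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] != 2:
        raise ValueError("label map must have exactly two columns")
    return dict(zip(df[0], df[1]))
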