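"""Synthetic data generation for every pipeline input.

The generator is a deliberately simple caricature of droplet scRNA-seq
and bulk RNA-seq over a glioblastoma-like cell population:

* single-cell counts are negative binomial around type-specific mean
  profiles with lognormal per-cell depth variation;
* each cell type carries a disjoint set of planted marker genes whose
  mean is raised by a known log2 fold-change in that type only;
* neoplastic cell types carry a chromosome-scale dosage signature (gain
  on one chromosome, loss on another — by default the chr7+/chr10-
  pattern of IDHwt GBM) applied to every gene on the affected arms;
* bulk samples are convex mixtures of the type mean profiles with
  Dirichlet-distributed proportions and multiplicative lognormal noise;
* ground-truth cell tables are multinomial draws from the mixing
  proportions; survival times are exponential with an optional link to a
  designated cell type's abundance.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ExpressionMatrix, GenePositionTable, MarkerTable

#: Default cell-type vocabulary: eight immune/myeloid populations plus
#: the four neoplastic GBM cell states (astrocyte-like, mesenchymal,
#: neural-progenitor-like, oligodendrocyte-progenitor-like).
DEFAULT_TYPES = (
    "AC", "B cells", "DC", "Mast cells", "MES", "Microglia",
    "Monocytes", "NK-cells", "NPC", "OPC", "T-cells", "TAM",
)
DEFAULT_NEOPLASTIC = ("AC", "MES", "NPC", "OPC")
N_CHROMS = 22


@dataclass
class SimulationConfig:
    cell_types: tuple[str, ...] = DEFAULT_TYPES
    n_genes: int = 3000
    cells_per_type: int = 50
    markers_per_type: int = 25
    marker_lfc: float = 2.0        # log2 fold-change of planted markers
    nb_dispersion: float = 2.0     # NB shape theta; var = mu + mu^2/theta
    depth_mean: float = 20000.0    # mean UMIs per cell over the simulated genes
    depth_sd_log: float = 0.3      # lognormal sd of per-cell depth
    neoplastic_types: tuple[str, ...] = DEFAULT_NEOPLASTIC
    cnv_gain_chrom: str = "7"
    cnv_gain_factor: float = 2.0
    cnv_loss_chrom: str = "10"
    cnv_loss_factor: float = 0.5
    n_bulk_samples: int = 50
    bulk_noise_sd: float = 0.1
    proportion_prior: float = 1.0  # Dirichlet concentration
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.cells_per_type < 1:
            raise ValueError("counts must be >= 1")
        if self.markers_per_type * self.n_types > self.n_genes:
            raise ValueError(
                "markers_per_type x n_types exceeds n_genes; marker sets "
                "must be disjoint"
            )
        for name in ("cnv_gain_factor", "cnv_loss_factor", "nb_dispersion",
                     "depth_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        unknown = set(self.neoplastic_types) - set(self.cell_types)
        if unknown:
            raise ValueError(f"neoplastic_types not in cell_types: {unknown}")

    @property
    def n_types(self) -> int:
        return len(self.cell_types)


@dataclass
class SyntheticTruth:
    """Everything the generator knows that the pipeline must recover."""

    cell_labels: pd.Series                 # cell -> type
    markers: MarkerTable                   # planted marker table
    neoplastic: pd.Series                  # cell -> bool
    positions: GenePositionTable
    type_profiles: pd.DataFrame            # genes x types, TPM-like means
    proportions: pd.DataFrame | None = None  # samples x types (bulk truth)


def _gene_positions(n_genes: int) -> GenePositionTable:
    """Round-robin gene placement across chromosomes 1-22."""
    chroms = [str((i % N_CHROMS) + 1) for i in range(n_genes)]
    starts = [(i // N_CHROMS + 1) * 10_000 for i in range(n_genes)]
    genes = [f"G{i:05d}" for i in range(n_genes)]
    return GenePositionTable(
        pd.DataFrame({"gene": genes, "chrom": chroms, "start": starts})
    )


def simulate_reference(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Labeled single-cell count matrix with planted markers and CNV events.

    Marker genes are drawn from chromosomes other than the CNV target
    arms so that marker identity is never confounded with the planted
    dosage signature (the same reasoning that motivates restricting
    neoplastic markers to tumor-intrinsic genes).
    """
    rng = np.random.default_rng(config.seed)
    positions = _gene_positions(config.n_genes)
    genes = positions.rows["gene"].tolist()
    chrom_of = dict(zip(positions.rows["gene"], positions.rows["chrom"]))

    base = rng.lognormal(mean=0.0, sigma=1.0, size=config.n_genes)

    eligible = [
        i for i, g in enumerate(genes)
        if chrom_of[g] not in (config.cnv_gain_chrom, config.cnv_loss_chrom)
    ]
    needed = config.markers_per_type * config.n_types
    if needed > len(eligible):
        raise ValueError("not enough off-target genes to plant markers")
    marker_idx = rng.choice(eligible, size=needed, replace=False)
    marker_rows = []
    marker_of_type: dict[str, np.ndarray] = {}
    for t, cell_type in enumerate(config.cell_types):
        idx = marker_idx[t * config.markers_per_type:
                         (t + 1) * config.markers_per_type]
        marker_of_type[cell_type] = idx
        for g in idx:
            marker_rows.append({"gene": genes[g], "cell_type": cell_type})
    markers = MarkerTable(pd.DataFrame(marker_rows))

    gain_idx = np.array(
        [i for i, g in enumerate(genes)
         if chrom_of[g] == config.cnv_gain_chrom], dtype=int)
    loss_idx = np.array(
        [i for i, g in enumerate(genes)
         if chrom_of[g] == config.cnv_loss_chrom], dtype=int)

    mean_profiles = np.empty((config.n_genes, config.n_types))
    for t, cell_type in enumerate(config.cell_types):
        mu = base.copy()
        mu[marker_of_type[cell_type]] *= 2.0 ** config.marker_lfc
        if cell_type in config.neoplastic_types:
            mu[gain_idx] *= config.cnv_gain_factor
            mu[loss_idx] *= config.cnv_loss_factor
        mean_profiles[:, t] = mu
    # TPM-like normalization: each type profile sums to 1e6
    frac = mean_profiles / mean_profiles.sum(axis=0, keepdims=True)
    type_profiles = pd.DataFrame(
        frac * 1e6, index=genes, columns=list(config.cell_types)
    )

    counts_blocks = []
    cell_ids: list[str] = []
    labels: list[str] = []
    theta = config.nb_dispersion
    for t, cell_type in enumerate(config.cell_types):
        depth = rng.lognormal(
            mean=np.log(config.depth_mean) - config.depth_sd_log ** 2 / 2,
            sigma=config.depth_sd_log,
            size=config.cells_per_type,
        )
        mu = frac[:, [t]] * depth[np.newaxis, :]
        p = theta / (theta + mu)
        counts_blocks.append(rng.negative_binomial(theta, p))
        tag = cell_type.replace(" ", "_")
        cell_ids.extend(
            f"{tag}.{i:04d}" for i in range(config.cells_per_type)
        )
        labels.extend([cell_type] * config.cells_per_type)

    values = pd.DataFrame(
        np.hstack(counts_blocks), index=genes, columns=cell_ids, dtype=float
    )
    cell_labels = pd.Series(labels, index=cell_ids, name="label")
    neoplastic = cell_labels.isin(config.neoplastic_types).rename("neoplastic")
    obs_meta = pd.DataFrame(
        {"label": cell_labels, "neoplastic": neoplastic}
    )
    counts = ExpressionMatrix(values, scale="counts", obs_meta=obs_meta)
    truth = SyntheticTruth(cell_labels, markers, neoplastic, positions,
                           type_profiles)
    return counts, truth


def simulate_bulk(
    truth: SyntheticTruth,
    config: SimulationConfig,
    seed: int | None = None,
    latent_pos_types: tuple[str, ...] = (),
    latent_neg_types: tuple[str, ...] = (),
    latent_strength: float = 0.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Pseudobulk mixtures of the type profiles with known proportions.

    Proportions are Dirichlet(``proportion_prior``). A latent per-sample
    factor can be shared across designated types to plant covariance
    structure (types in ``latent_pos_types`` rise together while
    ``latent_neg_types`` fall), mimicking the coupling of mesenchymal
    tumor cells with immune infiltrate.
    """
    rng = np.random.default_rng(config.seed + 101 if seed is None else seed)
    types = list(truth.type_profiles.columns)
    n = config.n_bulk_samples
    gammas = rng.gamma(config.proportion_prior, size=(n, len(types)))
    if latent_strength > 0:
        u = rng.normal(size=n)
        for j, t in enumerate(types):
            if t in latent_pos_types:
                gammas[:, j] *= np.exp(latent_strength * u)
            elif t in latent_neg_types:
                gammas[:, j] *= np.exp(-latent_strength * u)
    props = gammas / gammas.sum(axis=1, keepdims=True)
    samples = [f"S{i:03d}" for i in range(n)]
    proportions = pd.DataFrame(props, index=samples, columns=types)

    bulk = truth.type_profiles.to_numpy() @ props.T
    if config.bulk_noise_sd > 0:
        noise = rng.lognormal(
            mean=-config.bulk_noise_sd ** 2 / 2,
            sigma=config.bulk_noise_sd,
            size=bulk.shape,
        )
        bulk = bulk * noise
    matrix = ExpressionMatrix(
        pd.DataFrame(bulk, index=truth.type_profiles.index, columns=samples),
        scale="linear",
    )
    truth.proportions = proportions
    return matrix, proportions


def simulate_ground_truth_cells(
    proportions: pd.DataFrame, cells_per_sample: int, seed: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Multinomial annotated-cell table per sample plus observed
    proportions recomputed from it (the counting a single-cell-resolution
    image readout would provide)."""
    if cells_per_sample < 1:
        raise ValueError("cells_per_sample must be >= 1")
    rng = np.random.default_rng(seed)
    types = list(proportions.columns)
    rows = []
    for sample, p in proportions.iterrows():
        draws = rng.multinomial(cells_per_sample, p.to_numpy())
        for t, count in zip(types, draws):
            rows.extend(
                {"sample": sample, "cell_type": t} for _ in range(count)
            )
    table = pd.DataFrame(rows)
    table["cell_id"] = [f"c{i:06d}" for i in range(len(table))]
    observed = proportions_from_cells(table)
    observed = observed.reindex(index=proportions.index,
                                columns=types, fill_value=0.0)
    return table, observed


def proportions_from_cells(table: pd.DataFrame) -> pd.DataFrame:
    """Observed cell-type proportions per sample from an annotated cell
    table (columns ``sample`` and ``cell_type``)."""
    counts = pd.crosstab(table["sample"], table["cell_type"])
    return counts.div(counts.sum(axis=1), axis=0)


def simulate_survival(
    n_samples: int = 0,
    median_os: float = 14.0,
    seed: int = 1,
    scores: pd.Series | None = None,
    link_strength: float = 0.0,
) -> pd.DataFrame:
    """Exponential overall-survival times in months.

    With ``scores`` (a per-sample score vector) and a nonzero
    ``link_strength``, the log scale of each sample's survival time is
    shifted by the standardized score, planting a prognosis association.
    """
    if scores is not None:
        samples = list(scores.index)
    else:
        if n_samples < 8:
            raise ValueError("need n_samples >= 8")
        samples = [f"S{i:03d}" for i in range(n_samples)]
    rng = np.random.default_rng(seed)
    scale = median_os / np.log(2.0)
    os_months = rng.exponential(scale, size=len(samples))
    if scores is not None and link_strength != 0.0:
        z = (scores - scores.mean()) / scores.std(ddof=0)
        os_months = os_months * np.exp(link_strength * z.to_numpy())
    os_months = np.maximum(os_months, 1e-3)
    return pd.DataFrame(
        {"os_months": os_months, "event": 1}, index=pd.Index(samples, name="sample")
    )


def shuffle_marker_table(
    markers: MarkerTable, fraction: float, seed: int = 1
) -> MarkerTable:
    """Mismatched-marker control: reassign a fraction of marker entries
    to cell types chosen at random (a partially wrong marker set to
    contrast against the matched one)."""
    rng = np.random.default_rng(seed)
    ent = markers.entries.copy().reset_index(drop=True)
    types = list(dict.fromkeys(ent["cell_type"]))
    n_shuffle = int(round(fraction * len(ent)))
    idx = rng.choice(len(ent), size=n_shuffle, replace=False)
    for i in idx:
        current = ent.loc[i, "cell_type"]
        others = [t for t in types if t != current]
        ent.loc[i, "cell_type"] = others[rng.integers(len(others))]
    ent = ent.drop_duplicates(subset=["gene", "cell_type"])
    return MarkerTable(ent.reset_index(drop=True))
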