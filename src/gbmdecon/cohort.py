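"""Cohort-level score analysis: cross-correlation and survival strata.

Given per-sample cell-type prevalence scores for a cohort, this module
(a) correlates every pair of cell-type score vectors across samples,
(b) splits the cohort into worse/better prognosis tails at the first and
third quartiles of overall survival, and (c) compares score
distributions and correlation structure between the tails. Asterisks
follow the usual significance legend (* <.05, ** <.01, *** <.001,
**** <.0001) computed from raw p-values; Benjamini-Hochberg adjusted
p-values are reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .types import ScoreMatrix

logger = logging.getLogger(__name__)

WORSE, BETTER, MIDDLE = "worse", "better", "middle"


def stars_from_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


@dataclass
class CorrelationReport:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    stars: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.r.index.equals(self.r.columns):
            raise ValueError("correlation matrix must be square and aligned")


@dataclass
class SurvivalStrata:
    table: pd.DataFrame  # index sample; columns os_months, group
    q1: float
    q3: float

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])


def cross_correlate(scores: ScoreMatrix) -> CorrelationReport:
    """All-pairs Pearson correlation of cell-type scores across samples.

    p-values are the usual two-sided t-distributed ones; BH adjustment is
    applied over the strict upper triangle (each unordered pair counted
    once). Zero-variance score vectors yield undefined entries.
    """
    if scores.scores.shape[1] < 4:
        raise ValueError("need >= 4 samples for correlation analysis")
    if scores.scores.shape[0] < 2:
        raise ValueError("need >= 2 cell types")
    types = list(scores.cell_types)
    X = scores.scores.to_numpy(dtype=float)
    k = len(types)
    r = np.eye(k)
    p = np.full((k, k), np.nan)
    np.fill_diagonal(p, 0.0)
    flat = np.ptp(X, axis=1) == 0
    if flat.any():
        logger.warning(
            "zero-variance score vectors: %s",
            [types[i] for i in np.where(flat)[0]],
        )
    for i in range(k):
        for j in range(i + 1, k):
            if flat[i] or flat[j]:
                r[i, j] = r[j, i] = np.nan
                continue
            ri, pi = scipy.stats.pearsonr(X[i], X[j])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    iu = np.triu_indices(k, 1)
    praw = p[iu]
    padj_flat = np.full_like(praw, np.nan)
    ok = np.isfinite(praw)
    if ok.any():
        padj_flat[ok] = multipletests(praw[ok], method="fdr_bh")[1]
    p_adj = np.full((k, k), np.nan)
    np.fill_diagonal(p_adj, 0.0)
    p_adj[iu] = padj_flat
    p_adj[(iu[1], iu[0])] = padj_flat
    stars = pd.DataFrame(
        [[stars_from_p(p[i, j]) if i != j else "" for j in range(k)]
         for i in range(k)],
        index=types, columns=types,
    )
    to_df = lambda a: pd.DataFrame(a, index=types, columns=types)
    return CorrelationReport(to_df(r), to_df(p), to_df(p_adj), stars)


def stratify_survival(survival: pd.DataFrame) -> SurvivalStrata:
    """Split samples into prognosis tails at the OS quartiles.

    Worse prognosis: overall survival strictly below the first quartile;
    better: strictly above the third quartile; everything else is middle.
    Quartiles use linear interpolation between order statistics.
    """
    if "os_months" not in survival.columns:
        raise ValueError("survival table needs an 'os_months' column")
    os_months = survival["os_months"].astype(float)
    if len(os_months) < 8:
        raise ValueError("need >= 8 samples for quartile stratification")
    bad = os_months.index[os_months <= 0]
    if len(bad):
        raise ValueError(f"non-positive OS for samples {list(bad[:5])}")
    q1, q3 = np.quantile(os_months.to_numpy(), [0.25, 0.75])
    group = pd.Series(MIDDLE, index=os_months.index, name="group")
    group[os_months < q1] = WORSE
    group[os_months > q3] = BETTER
    if q1 == q3:
        logger.warning("degenerate OS distribution: q1 == q3 == %.3g", q1)
    logger.info(
        "OS quartiles %.2f / %.2f months: %d worse, %d better, %d middle",
        q1, q3, (group == WORSE).sum(), (group == BETTER).sum(),
        (group == MIDDLE).sum(),
    )
    table = pd.DataFrame({"os_months": os_months, "group": group})
    return SurvivalStrata(table, float(q1), float(q3))


def compare_groups(
    scores: ScoreMatrix, strata: SurvivalStrata, min_group: int = 4
) -> tuple[pd.DataFrame, dict[str, CorrelationReport]]:
    """Compare score distributions and correlations across prognosis tails.

    Per cell type a two-sided Wilcoxon rank-sum test contrasts worse-
    vs better-prognosis samples (BH-adjusted across cell types); the
    correlation analysis is rerun within each tail. Middle samples are
    excluded from both.
    """
    worse = [s for s in strata.samples_in(WORSE) if s in scores.samples]
    better = [s for s in strata.samples_in(BETTER) if s in scores.samples]
    for name, grp in ((WORSE, worse), (BETTER, better)):
        if len(grp) < min_group:
            raise ValueError(
                f"{name} group has {len(grp)} samples; need >= {min_group}"
            )
    rows = []
    for cell_type in scores.cell_types:
        x = scores.scores.loc[cell_type, worse].to_numpy(dtype=float)
        y = scores.scores.loc[cell_type, better].to_numpy(dtype=float)
        stat, p = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        )
        rows.append({"cell_type": cell_type, "statistic": stat, "p": p,
                     "median_worse": float(np.median(x)),
                     "median_better": float(np.median(y))})
    table = pd.DataFrame(rows).set_index("cell_type")
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
    table["stars"] = [stars_from_p(v) for v in table["p"]]
    reports = {
        WORSE: cross_correlate(ScoreMatrix(scores.scores[worse])),
        BETTER: cross_correlate(ScoreMatrix(scores.scores[better])),
    }
    return table, reports
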