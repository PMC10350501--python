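"""Trait statistics, Pearson correlations, and extreme-bulk construction.

The phenotype table is long-format: one row per (line, replicate) with the
seven seedling-trait columns SL, RL, SFW, RFW, SDW, RDW, CHL (lengths in cm,
weights in g, chlorophyll in SPAD units).  Replicates are averaged per line
before correlation or bulk selection.

Skewness and kurtosis use the bias-adjusted estimators (adjusted
Fisher-Pearson skewness; excess kurtosis), i.e. the conventions SPSS prints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import TRAITS


@dataclass(frozen=True)
class TraitStats:
    n: int
    mean: float
    minimum: float
    maximum: float
    sd: float
    skewness: float
    kurtosis: float


def summarize_trait(values: Iterable[float]) -> TraitStats:
    """Mean/min/max/SD plus bias-adjusted skewness and excess kurtosis.

    SD is the n-1 sample SD.  Skewness needs n >= 3 and kurtosis n >= 4;
    below those (or for a constant vector) the statistic is NaN.
    """
    x = np.asarray(list(values), dtype=float)
    n = len(x)
    if n == 0:
        raise ValueError("empty trait vector")
    sd = float(np.std(x, ddof=1)) if n >= 2 else math.nan
    skew = kurt = math.nan
    if n >= 3 and sd > 0:
        skew = float(stats.skew(x, bias=False))
    if n >= 4 and sd > 0:
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
    return TraitStats(n, float(np.mean(x)), float(np.min(x)), float(np.max(x)), sd, skew, kurt)


def line_means(table: pd.DataFrame, traits: Sequence[str] = TRAITS) -> pd.DataFrame:
    """Average replicates to one row per line (mean over available replicates)."""
    missing = [t for t in traits if t not in table.columns]
    if missing:
        raise ValueError(f"phenotype table lacks trait columns {missing}")
    return table.groupby("line")[list(traits)].mean()


def trait_stats_table(table: pd.DataFrame, traits: Sequence[str] = TRAITS) -> pd.DataFrame:
    """Per-trait descriptive statistics over line means (report layout)."""
    lm = line_means(table, traits)
    rows = []
    for t in traits:
        s = summarize_trait(lm[t])
        rows.append({"trait": t, "n": s.n, "mean": s.mean, "minimum": s.minimum,
                     "maximum": s.maximum, "sd": s.sd, "skewness": s.skewness,
                     "kurtosis": s.kurtosis})
    return pd.DataFrame(rows)


@dataclass
class CorrelationResult:
    r: pd.DataFrame        # Pearson r, unit diagonal
    p: pd.DataFrame        # one-tailed p-values (t transform, observed direction)
    stars: pd.DataFrame    # '**' p<0.01, '*' p<0.05, '' otherwise
    n: int

    def to_tsv(self, path) -> None:
        annotated = self.r.round(3).astype(str) + self.stars
        annotated.to_csv(path, sep="\t")


def correlation_matrix(table: pd.DataFrame, traits: Sequence[str] = TRAITS) -> CorrelationResult:
    """Pairwise Pearson correlations of line-mean traits with one-tailed p-values.

    p-values come from the t transform ``t = r sqrt((n-2)/(1-r^2))`` and are
    one-tailed in the observed direction (half the two-tailed p), the
    convention correlation tables in this field are starred with.  A trait
    with zero variance yields NaN correlations for its pairs.
    """
    lm = line_means(table, traits)
    n = len(lm)
    if n < 3:
        raise ValueError("need at least 3 lines for correlation")
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = lm.iloc[:, i].to_numpy(), lm.iloc[:, j].to_numpy()
            if np.std(xi) == 0 or np.std(xj) == 0:
                rij, pij = math.nan, math.nan
            else:
                res = stats.pearsonr(xi, xj)
                rij, pij = float(res.statistic), float(res.pvalue) / 2.0
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    idx = list(traits)
    r_df = pd.DataFrame(r, index=idx, columns=idx)
    p_df = pd.DataFrame(p, index=idx, columns=idx)
    stars = p_df.map(lambda v: "**" if v < 0.01 else ("*" if v < 0.05 else ""))
    np.fill_diagonal(stars.values, "")
    return CorrelationResult(r_df, p_df, stars, n)


@dataclass
class BulkSelection:
    """The two phenotypic-extreme bulks and the trait ranges they realize."""

    resistant: list[str]
    susceptible: list[str]
    traits: tuple[str, ...]
    ranges: dict  # bulk name -> trait -> (min, max) over selected lines
    scores: pd.Series  # composite z-score per line

    def range_table(self) -> pd.DataFrame:
        rows = []
        for bulk in ("resistant", "susceptible"):
            for t in self.traits:
                lo, hi = self.ranges[bulk][t]
                rows.append({"bulk": bulk, "trait": t, "min": lo, "max": hi})
        return pd.DataFrame(rows)


def select_bulks(table: pd.DataFrame, traits: Sequence[str] = ("SFW", "SDW", "RFW"),
                 n: int = 30) -> BulkSelection:
    """Pick the n highest- and n lowest-scoring lines as resistant/susceptible bulks.

    Lines are ranked by the mean of their per-trait z-scores over the selection
    traits (high composite = salt tolerant for these traits).  Ties at the cut
    are broken by line ID so the selection is deterministic.
    """
    lm = line_means(table, traits)
    if len(lm) < 2 * n:
        raise ValueError(f"need at least {2 * n} lines, have {len(lm)}")
    sds = lm.std(ddof=1)
    if (sds == 0).any():
        raise ValueError("selection trait with zero variance")
    z = (lm - lm.mean()) / sds
    score = z.mean(axis=1)
    # deterministic tie-break: among equal scores, lower line ID first
    order = score.loc[sorted(score.index)].sort_values(ascending=False, kind="mergesort")
    resistant = sorted(order.index[:n])
    susceptible = sorted(order.index[-n:])
    ranges = {}
    for bulk, ids in (("resistant", resistant), ("susceptible", susceptible)):
        sub = lm.loc[ids]
        ranges[bulk] = {t: (float(sub[t].min()), float(sub[t].max())) for t in traits}
    return BulkSelection(list(resistant), list(susceptible), tuple(traits), ranges, score)
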