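"""Expression-similarity neighbor ranking.

Sample similarity is the Spearman correlation of (transformed) gene
expression vectors.  The ranking produced here is the shared engine for
three uses: choosing the L feature samples of each trained model, choosing
the R reference models ensembled for a query, and the KNN baseline.

Ties in correlation are broken by preserving the samples' input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import ExpressionTable


@dataclass(frozen=True)
class NeighborRanking:
    """Ordered nearest neighbors of one query sample."""

    query_id: str
    neighbor_ids: tuple[str, ...]
    correlations: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.query_id in self.neighbor_ids:
            raise ValueError("query must be excluded from its own ranking")
        corr = np.asarray(self.correlations)
        if len(corr) > 1 and (np.diff(corr) > 1e-12).any():
            raise ValueError("correlations must be non-increasing")


def spearman_matrix(expr: ExpressionTable | pd.DataFrame) -> pd.DataFrame:
    """Samples x samples Spearman correlation matrix of expression.

    Tied expression values receive average ranks.  A zero-variance sample
    (all genes equal) has undefined correlations and is rejected by name.
    """
    data = expr.data if isinstance(expr, ExpressionTable) else expr
    values = data.to_numpy(dtype=np.float64)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 genes for Spearman correlation")
    flat = np.ptp(values, axis=0) == 0
    if flat.any():
        bad = [c for c, f in zip(data.columns, flat) if f]
        raise ValueError(f"zero-variance sample(s): {bad}")
    if values.shape[1] == 2:
        rho = stats.spearmanr(values[:, 0], values[:, 1]).statistic
        corr = np.array([[1.0, rho], [rho, 1.0]])
    else:
        corr = stats.spearmanr(values).statistic
    return pd.DataFrame(corr, index=data.columns, columns=data.columns)


def correlate_query(
    query: pd.Series, expr: ExpressionTable | pd.DataFrame
) -> pd.Series:
    """Spearman correlation of an external query expression vector against
    every sample in the table, aligned on gene ids."""
    data = expr.data if isinstance(expr, ExpressionTable) else expr
    aligned = query.reindex(data.index)
    if aligned.isna().any():
        raise ValueError("query expression missing values for table genes")
    qrank = stats.rankdata(aligned.to_numpy())
    ranks = stats.rankdata(data.to_numpy(), axis=0)
    qc = qrank - qrank.mean()
    rc = ranks - ranks.mean(axis=0)
    denom = np.sqrt((qc**2).sum() * (rc**2).sum(axis=0))
    if (denom == 0).any() or (qc**2).sum() == 0:
        raise ValueError("zero-variance ranks in query correlation")
    return pd.Series((qc @ rc) / denom, index=data.columns)


def rank_neighbors(
    query_id: str, corr: pd.DataFrame, k: int
) -> NeighborRanking:
    """Top-k samples most correlated with ``query_id``, self excluded.

    Ties keep the samples' input (column) order, implemented with a stable
    descending sort.
    """
    if query_id not in corr.columns:
        raise KeyError(query_id)
    others = corr.columns[corr.columns != query_id]
    if not 1 <= k <= len(others):
        raise ValueError(f"k={k} must be in [1, {len(others)}]")
    vals = corr.loc[query_id, others].to_numpy(dtype=np.float64)
    order = np.argsort(-vals, kind="mergesort")[:k]
    return NeighborRanking(
        query_id=query_id,
        neighbor_ids=tuple(others[order]),
        correlations=tuple(vals[order]),
    )


def rank_neighbors_from_series(
    query_id: str, correlations: pd.Series, k: int
) -> NeighborRanking:
    """As :func:`rank_neighbors` but from a precomputed correlation Series
    (e.g. an external query's correlations to the reference samples)."""
    others = correlations.index[correlations.index != query_id]
    if not 1 <= k <= len(others):
        raise ValueError(f"k={k} must be in [1, {len(others)}]")
    vals = correlations.loc[others].to_numpy(dtype=np.float64)
    order = np.argsort(-vals, kind="mergesort")[:k]
    return NeighborRanking(
        query_id=query_id,
        neighbor_ids=tuple(others[order]),
        correlations=tuple(vals[order]),
    )
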