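"""Expression preprocessing: gene filtering, quantile normalization, log2.

The pipeline applied to a TPM table before any similarity computation is:
restrict to protein-coding genes on the allowed chromosomes, quantile
normalize across samples so every sample's values follow the same empirical
distribution, then log2(x + 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .genome_io import ExpressionTable, GeneRecord

#: Autosomes 1-22 plus chrX, the chromosomes retained by default.
DEFAULT_ALLOWED_CHROMS: frozenset[str] = frozenset(
    [f"chr{i}" for i in range(1, 23)] + ["chrX"]
)


@dataclass(frozen=True)
class PreprocessConfig:
    allowed_chroms: frozenset[str] = DEFAULT_ALLOWED_CHROMS
    allowed_biotype: str = "protein_coding"
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")


def filter_genes(
    expr: ExpressionTable,
    genes: Iterable[GeneRecord],
    cfg: PreprocessConfig | None = None,
) -> ExpressionTable:
    """Restrict an expression table to genes passing biotype and chromosome
    filters, preserving the input row order of surviving genes."""
    cfg = cfg or PreprocessConfig()
    if expr.stage != "raw_tpm":
        raise ValueError(f"filter_genes expects raw_tpm, got {expr.stage!r}")
    keep_ids = {
        g.gene_id
        for g in genes
        if g.biotype == cfg.allowed_biotype and g.chrom in cfg.allowed_chroms
    }
    mask = expr.data.index.isin(keep_ids)
    if not mask.any():
        raise ValueError("no genes survive the biotype/chromosome filter")
    return ExpressionTable(data=expr.data.loc[mask].copy(), stage="raw_tpm")


def quantile_normalize(expr: ExpressionTable) -> ExpressionTable:
    """Quantile-normalize across samples.

    Every sample's sorted value vector becomes the across-sample mean of
    sorted value vectors; within-sample rank order is preserved.  Tied
    values within a sample receive the mean of the corresponding reference
    quantiles.
    """
    if expr.stage == "log2":
        raise ValueError("quantile_normalize expects pre-log values")
    values = expr.values
    n_genes, n_samples = values.shape
    if n_samples < 1:
        raise ValueError("need at least one sample")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty(n_genes)
        mapped[order] = reference
        # average reference quantiles over within-sample ties
        ties = pd.Series(mapped).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ties.to_numpy()
    df = pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns)
    return ExpressionTable(data=df, stage="quantile_normalized")


def log_transform(
    expr: ExpressionTable, pseudocount: float = 1.0
) -> ExpressionTable:
    """Apply v -> log2(v + pseudocount)."""
    if expr.stage != "quantile_normalized":
        raise ValueError(
            f"log_transform expects quantile_normalized, got {expr.stage!r}"
        )
    values = expr.values
    if ((values + pseudocount) <= 0).any():
        raise ValueError("value + pseudocount must be positive")
    df = pd.DataFrame(
        np.log2(values + pseudocount),
        index=expr.data.index,
        columns=expr.data.columns,
    )
    return ExpressionTable(data=df, stage="log2")


def preprocess_expression(
    expr: ExpressionTable,
    genes: Iterable[GeneRecord] | None = None,
    cfg: PreprocessConfig | None = None,
) -> ExpressionTable:
    """Full pipeline: optional gene filter, quantile normalization, log2."""
    cfg = cfg or PreprocessConfig()
    if genes is not None:
        expr = filter_genes(expr, genes, cfg)
    return log_transform(quantile_normalize(expr), cfg.pseudocount)
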