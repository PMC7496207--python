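"""Dropout-residual gene scoring and top-K feature selection.

Each gene j is scored by how far its observed log expression level sits above
two reference predictions:

* ``F(j) = log(mean_i E_ij + 1)`` — log-plus-one of the arithmetic mean.
* ``F1_hat(j) = a·D_j + b`` — an ordinary-least-squares fit of F on the
  per-gene dropout rate D_j (fraction of cells where the gene is exactly 0).
  The residual ``dF1 = F − F1_hat`` captures whether a gene is expressed more
  than its dropout rate alone predicts.
* ``F2_hat(j) = mean_i log(E_ij + 1)`` — mean of the per-cell logs. By
  Jensen's inequality ``F ≥ F2_hat``, so the residual ``dF2 = F − F2_hat`` is
  non-negative; it grows with the spread of the gene's expression across
  cells and acts as an entropy-like dispersion term.

The combined score is ``G = α·dF1 + (1−α)·dF2`` with α = 0.5 by default, and
the top-K genes by G (ties broken by gene name) are selected among the genes
shared by reference and query.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_data import ExpressionDataset

_LOG_SCALE = {"natural": 1.0, "2": 1.0 / np.log(2.0), "10": 1.0 / np.log(10.0)}


@dataclass
class FeatureSelectionConfig:
    """Settings for gene scoring and selection.

    alpha
        Mixing weight between the dropout-fit residual dF1 and the
        dispersion residual dF2, in [0, 1]. Default 0.5.
    n_features
        Number K of top-scoring genes to keep. Default 100.
    log_base
        "natural", "2" or "10". The log base rescales F, F1_hat, F2_hat and
        both residuals by a common factor; it changes G's ranking only
        through the alpha mix.
    """

    alpha: float = 0.5
    n_features: int = 100
    log_base: str = "natural"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if str(self.log_base) not in _LOG_SCALE:
            raise ValueError("log_base must be one of 'natural', '2', '10'")
        self.log_base = str(self.log_base)


@dataclass
class LinearFit:
    """OLS fit of gene expression level F on dropout rate D: F ≈ a·D + b."""

    slope: float
    intercept: float


def compute_dropout_rates(data: ExpressionDataset) -> np.ndarray:
    """Per-gene fraction of cells with exactly zero expression, in [0, 1]."""
    if data.n_cells < 1:
        raise ValueError("need at least one cell")
    return np.mean(data.values == 0, axis=0)


def compute_gene_scores(
    data: ExpressionDataset, config: FeatureSelectionConfig | None = None
) -> tuple[pd.DataFrame, LinearFit]:
    """Score every gene of ``data``.

    Returns a DataFrame indexed by gene name with columns
    ``dropout_rate, F, F1_hat, F2_hat, dF1, dF2, G`` and the fitted
    :class:`LinearFit` (slope ``a``, intercept ``b``).
    """
    config = config or FeatureSelectionConfig()
    if data.n_genes < 2:
        raise ValueError("need at least 2 genes for the dropout fit")
    scale = _LOG_SCALE[config.log_base]
    values = data.values
    dropout = np.mean(values == 0, axis=0)
    if np.all(dropout == dropout[0]):
        raise ValueError("degenerate dropout fit: all genes share one dropout rate")
    f = np.log(values.mean(axis=0) + 1.0) * scale
    f2_hat = np.log1p(values).mean(axis=0) * scale
    slope, intercept = np.polyfit(dropout, f, 1)
    f1_hat = slope * dropout + intercept
    df1 = f - f1_hat
    df2 = f - f2_hat
    g = config.alpha * df1 + (1.0 - config.alpha) * df2
    table = pd.DataFrame(
        {
            "dropout_rate": dropout,
            "F": f,
            "F1_hat": f1_hat,
            "F2_hat": f2_hat,
            "dF1": df1,
            "dF2": df2,
            "G": g,
        },
        index=pd.Index(data.gene_names, name="gene_name"),
    )
    return table, LinearFit(slope=float(slope), intercept=float(intercept))


def rank_genes(scores: pd.DataFrame) -> list[str]:
    """Gene names sorted by G descending, ties broken by name ascending."""
    order = sorted(scores.index, key=lambda gene: (-scores.at[gene, "G"], gene))
    return order


def select_features(
    reference: ExpressionDataset,
    query: ExpressionDataset,
    config: FeatureSelectionConfig | None = None,
    intersect_topk: bool = False,
) -> list[str]:
    """Select the top-K genes shared by reference and query.

    Both datasets must already be aligned to their shared genes (see
    :func:`enclasc.io_data.align_common_genes`). Scores are computed on the
    reference dataset; the query contributes only gene presence. With
    ``intersect_topk`` the reference ranking is instead intersected with the
    query's own top-K ranking, then re-ranked by reference score.
    """
    config = config or FeatureSelectionConfig()
    if set(reference.gene_names) != set(query.gene_names):
        raise ValueError("datasets must be aligned to shared genes first")
    ref_scores, _ = compute_gene_scores(reference, config)
    ranked = rank_genes(ref_scores)
    k = min(config.n_features, len(ranked))
    if not intersect_topk:
        return ranked[:k]
    query_scores, _ = compute_gene_scores(query, config)
    query_top = set(rank_genes(query_scores)[:k])
    both = [g for g in ranked if g in query_top]
    return both[:k]
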