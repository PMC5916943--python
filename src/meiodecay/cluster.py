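"""Normalization, PCA embedding, K-means clustering, rare-population markers.

Library-size normalization is median-ratio: each cell's counts are scaled
by (median cell total / cell total) before log1p, so doubling every count
of a cell leaves its normalized profile unchanged.  Rare-population marker
discovery follows the published thresholds: a gene is flagged as a marker
of the target cluster iff the two-sided rank-sum p-value is < 0.01 and the
log2 fold change of normalized means (pseudocount 0.01) exceeds 7.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError
from .io import CountMatrix

logger = logging.getLogger(__name__)

#: Published marker-flag gates.
DE_P_THRESHOLD = 0.01
DE_LOG2FC_THRESHOLD = 7.0
DE_PSEUDOCOUNT = 0.01


@dataclass
class NormalizedExpression:
    """Log1p median-ratio-normalized expression, aligned with the matrix."""

    values: np.ndarray        # kept cells x genes, dense
    kept: np.ndarray          # bool mask over the original cells
    size_factors: np.ndarray  # per kept cell: median total / cell total


@dataclass
class EmbeddingResult:
    """PCA coordinates of the normalized cells.

    ``coords`` are the raw principal-component scores (used for the
    trajectory, where the dominant axes carry the signal);
    :meth:`whitened` rescales each component to unit variance, the
    normalization under which cluster separation rather than component
    variance drives K-means — small distinct populations live in
    low-variance components and would otherwise be drowned out.
    """

    coords: np.ndarray                  # kept cells x n_components
    explained_variance: np.ndarray      # absolute variance per component
    explained_variance_ratio: np.ndarray
    kept: np.ndarray

    def whitened(self) -> np.ndarray:
        return self.coords / np.sqrt(self.explained_variance)


def normalize_log(matrix: CountMatrix) -> NormalizedExpression:
    """log(1 + count * median_total / cell_total) per cell and gene."""
    totals = matrix.cell_totals().astype(float)
    kept = totals > 0
    if not kept.any():
        raise AnalysisError("all cells have zero total counts")
    if not kept.all():
        logger.warning("dropping %d cells with zero total counts",
                       int((~kept).sum()))
    totals_kept = totals[kept]
    factors = np.median(totals_kept) / totals_kept
    scaled = sp.csr_matrix(matrix.counts[kept], dtype=float)
    scaled = sp.diags(factors) @ scaled
    values = np.log1p(np.asarray(scaled.todense()))
    return NormalizedExpression(values=values, kept=kept, size_factors=factors)


def embed_pca(normalized: NormalizedExpression, n_components: int = 10,
              seed: int = 0) -> EmbeddingResult:
    """PCA of the normalized expression, components by decreasing variance."""
    n_cells, n_genes = normalized.values.shape
    if n_components >= min(n_cells, n_genes):
        raise AnalysisError(
            f"n_components={n_components} must be < min(cells, genes)="
            f"{min(n_cells, n_genes)}")
    pca = PCA(n_components=n_components, svd_solver="randomized",
              random_state=seed)
    coords = pca.fit_transform(normalized.values)
    if not np.all(np.isfinite(coords)):
        raise AnalysisError("non-finite PCA coordinates")
    return EmbeddingResult(
        coords=coords,
        explained_variance=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        kept=normalized.kept,
    )


def kmeans_cluster(embedding: EmbeddingResult, k: int = 9, seed: int = 0,
                   n_init: int = 30, whiten: bool = True) -> np.ndarray:
    """Seeded K-means (k-means++ init, ``n_init`` restarts) on the embedding.

    By default the components are whitened first; rare populations form
    compact, well-separated but low-variance directions, and many
    restarts are needed for k-means++ to seed clusters of a few cells.
    """
    n = embedding.coords.shape[0]
    if k > n:
        raise AnalysisError(f"K={k} exceeds the number of cells {n}")
    coords = embedding.whitened() if whiten else embedding.coords
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(coords)


def rare_population_markers(matrix: CountMatrix, labels: np.ndarray,
                            target: int,
                            normalized: NormalizedExpression | None = None,
                            ) -> pd.DataFrame:
    """Differential expression of one cluster against all other cells.

    Two-sided Wilcoxon rank-sum test per gene on normalized expression;
    log2 fold change on normalized means with pseudocount 0.01.  The
    ``marker`` flag applies the published gates (p < 0.01, log2FC > 7);
    BH-adjusted p-values are reported for transparency but not gated on.
    """
    if normalized is None:
        normalized = normalize_log(matrix)
    labels = np.asarray(labels)
    if labels.size != normalized.values.shape[0]:
        raise AnalysisError("labels must align with the normalized cells")
    in_target = labels == target
    n_t = int(in_target.sum())
    if n_t < 3:
        raise AnalysisError(
            f"target cluster {target} has {n_t} < 3 cells; test undefined")
    vals_t = normalized.values[in_target]
    vals_r = normalized.values[~in_target]
    mean_t = vals_t.mean(axis=0)
    mean_r = vals_r.mean(axis=0)
    log2fc = np.log2((mean_t + DE_PSEUDOCOUNT) / (mean_r + DE_PSEUDOCOUNT))
    _stat, pvals = stats.ranksums(vals_t, vals_r, axis=0)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame({
        "gene_id": matrix.genes["gene_id"],
        "symbol": matrix.genes["symbol"],
        "log2fc": log2fc,
        "pvalue": pvals,
        "padj": padj,
        "target_mean": mean_t,
        "rest_mean": mean_r,
        "marker": (pvals < DE_P_THRESHOLD) & (log2fc > DE_LOG2FC_THRESHOLD),
    })
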