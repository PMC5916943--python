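"""Marker filtering, dot-plot statistics, and cluster cell-type assignment.

The expression filter mirrors the published rule: a marker is retained iff
its mean raw count over all cells is at least 0.1 (inclusive) and it is
detected (count > 0) in at least 3 cells.  Cell types are assigned per
cluster by scoring each stage's marker set on the dot-plot statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import NormalizedExpression, normalize_log
from .errors import AnalysisError
from .io import CountMatrix, MarkerTable, STAGE_VOCABULARY

logger = logging.getLogger(__name__)

MEAN_THRESHOLD = 0.1
MIN_CELLS_EXPRESSING = 3


@dataclass
class MarkerFilterResult:
    """Counts and symbol lists at each step of the marker funnel."""

    n_input: int
    annotated: list[str]
    retained: list[str]

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_input, len(self.annotated), len(self.retained))


@dataclass
class DotPlotStats:
    """Per (cluster, marker): fraction of expressing cells, mean expression.

    ``table`` covers exactly clusters x markers; ``mean_expression`` is the
    mean log-normalized expression over all cells of the cluster.
    """

    table: pd.DataFrame
    cluster_sizes: dict[int, int] = field(default_factory=dict)


def filter_markers(matrix: CountMatrix, markers: MarkerTable) -> MarkerFilterResult:
    """Apply the expression filter to the annotated literature markers."""
    if matrix.n_cells == 0 or matrix.n_genes == 0:
        raise AnalysisError("cannot filter markers on an empty matrix")
    symbols = pd.Index(matrix.genes["symbol"])
    requested = list(dict.fromkeys(markers.symbols()))  # order-stable unique
    annotated = [s for s in requested if s in symbols]
    dropped = len(requested) - len(annotated)
    if dropped:
        logger.warning("%d of %d markers not annotated in the matrix",
                       dropped, len(requested))
    counts = matrix.counts
    means = np.asarray(counts.mean(axis=0)).ravel()
    n_expressing = np.asarray((counts > 0).sum(axis=0)).ravel()
    retained = []
    for sym in annotated:
        j = symbols.get_loc(sym)
        if isinstance(j, (np.ndarray, slice)):  # duplicated symbol: first hit
            j = int(np.flatnonzero(symbols == sym)[0])
        if means[j] >= MEAN_THRESHOLD and n_expressing[j] >= MIN_CELLS_EXPRESSING:
            retained.append(sym)
    return MarkerFilterResult(
        n_input=len(requested), annotated=annotated, retained=retained)


def dotplot_stats(matrix: CountMatrix, labels: np.ndarray,
                  retained: list[str],
                  normalized: NormalizedExpression | None = None) -> DotPlotStats:
    """Fraction of expressing cells and mean expression per cluster/marker."""
    if normalized is None:
        normalized = normalize_log(matrix)
    labels = np.asarray(labels)
    if labels.size != normalized.values.shape[0]:
        raise AnalysisError("labels must cover every normalized cell")
    symbols = matrix.genes["symbol"].to_numpy()
    cols = []
    for sym in retained:
        hits = np.flatnonzero(symbols == sym)
        if hits.size == 0:
            raise AnalysisError(f"retained marker {sym!r} not in the matrix")
        cols.append(hits[0])
    cols = np.asarray(cols, dtype=int)
    raw = matrix.counts[normalized.kept][:, cols]
    norm = normalized.values[:, cols]

    rows = []
    sizes: dict[int, int] = {}
    for cl in np.unique(labels):
        members = labels == cl
        size = int(members.sum())
        if size == 0:
            logger.warning("cluster %s has no cells; excluded", cl)
            continue
        sizes[int(cl)] = size
        frac = np.asarray((raw[members] > 0).sum(axis=0)).ravel() / size
        mean_expr = norm[members].mean(axis=0)
        for sym, f, m in zip(retained, frac, mean_expr):
            rows.append((int(cl), sym, float(f), float(m)))
    table = pd.DataFrame(
        rows, columns=["cluster", "symbol", "fraction_expressing",
                       "mean_expression"])
    return DotPlotStats(table=table, cluster_sizes=sizes)


def assign_cell_types(stats: DotPlotStats, markers: MarkerTable) -> pd.DataFrame:
    """Label each cluster with the stage whose markers it best expresses.

    Score of (cluster, stage) = mean over the stage's retained markers of
    fraction_expressing x standardized mean expression (z-scored per gene
    across clusters).  Ties break toward the larger summed fraction, then
    stage order; exact ties are flagged low-confidence.
    """
    stage_of = markers.stage_of()
    table = stats.table.copy()
    table["stage"] = table["symbol"].map(stage_of)
    table = table.dropna(subset=["stage"])
    if table.empty:
        raise AnalysisError("no retained marker belongs to any stage")
    # z-score mean expression per gene across clusters
    z = table.groupby("symbol")["mean_expression"].transform(
        lambda x: (x - x.mean()) / x.std(ddof=0) if x.std(ddof=0) > 0 else 0.0)
    table["score_term"] = table["fraction_expressing"] * z

    records = []
    for cl, sub in table.groupby("cluster"):
        by_stage = sub.groupby("stage").agg(
            score=("score_term", "mean"),
            frac_sum=("fraction_expressing", "sum"))
        by_stage = by_stage.reindex(
            [s for s in STAGE_VOCABULARY if s in by_stage.index])
        best = by_stage.sort_values(
            ["score", "frac_sum"], ascending=False, kind="stable")
        top = best.iloc[0]
        runner = best.iloc[1] if len(best) > 1 else None
        low_conf = runner is not None and np.isclose(
            top["score"], runner["score"]) and np.isclose(
            top["frac_sum"], runner["frac_sum"])
        records.append({
            "cluster": int(cl),
            "cell_type": best.index[0],
            "score": float(top["score"]),
            "low_confidence": bool(low_conf),
        })
    return pd.DataFrame(records).set_index("cluster")
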