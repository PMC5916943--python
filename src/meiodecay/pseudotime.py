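"""Principal-curve pseudotime for the germ-cell trajectory.

Cells are ordered along a one-dimensional curve through the PCA embedding:
the ordering is initialized with the first principal component, then the
curve is iteratively re-smoothed against arc length and cells re-projected
onto it until the projections stabilise.  The arc-length position is
oriented so that spermatogonia markers peak near 0 and min-max scaled to
[0, 1], the convention under which the trajectory landmarks (meiosis,
protamine onset, decay) are expressed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .decay import _local_linear
from .errors import AnalysisError

logger = logging.getLogger(__name__)

SOMATIC_TYPES = ("Sertoli", "Leydig")

#: Spermatogonia markers usable as the early orientation anchor, in order
#: of preference.
EARLY_MARKER_CANDIDATES = ("DazlL", "Stra8L", "Crabp1L", "Hist1h1aL",
                           "Dazl", "Stra8", "Crabp1", "Hist1h1a")


@dataclass
class PrincipalCurveResult:
    """Raw arc-length scores from the principal-curve iteration."""

    scores: np.ndarray
    converged: bool
    n_iter: int


@dataclass
class PseudotimeAssignment:
    """Per-cell pseudotime in [0, 1]; somatic cells carry no value."""

    t: np.ndarray             # NaN outside the trajectory
    included: np.ndarray      # bool mask over all cells
    orientation_marker: str
    converged: bool = True

    def __post_init__(self) -> None:
        vals = self.t[self.included]
        if vals.size and (np.nanmin(vals) != 0.0 or np.nanmax(vals) != 1.0):
            raise AnalysisError("included pseudotimes must span [0, 1]")


def select_germ_cells(labels: np.ndarray, cell_types: dict | "pd.DataFrame",
                      ) -> np.ndarray:
    """Mask of cells in clusters not labelled Sertoli or Leydig."""
    labels = np.asarray(labels)
    if hasattr(cell_types, "to_dict"):  # assign_cell_types frame
        mapping = cell_types["cell_type"].to_dict()
    else:
        mapping = dict(cell_types)
    somatic_clusters = {cl for cl, ct in mapping.items()
                       if ct in SOMATIC_TYPES}
    mask = ~np.isin(labels, list(somatic_clusters))
    if not mask.any():
        raise AnalysisError("no germ cells left after excluding somatic clusters")
    return mask


def _project_to_polyline(points: np.ndarray, curve: np.ndarray):
    """Project points onto a polyline; return (arc positions, foot points)."""
    seg_start = curve[:-1]                      # (m-1, d)
    seg_vec = np.diff(curve, axis=0)            # (m-1, d)
    seg_len2 = (seg_vec ** 2).sum(axis=1)
    seg_len2 = np.where(seg_len2 == 0, 1e-300, seg_len2)
    arc = np.concatenate([[0.0], np.cumsum(np.sqrt(seg_len2))])
    # fractional position of each point on each segment, clamped to [0, 1]
    diff = points[:, None, :] - seg_start[None, :, :]
    frac = np.clip((diff * seg_vec[None, :, :]).sum(axis=2) / seg_len2, 0.0, 1.0)
    foot = seg_start[None, :, :] + frac[:, :, None] * seg_vec[None, :, :]
    d2 = ((points[:, None, :] - foot) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    rows = np.arange(points.shape[0])
    positions = arc[best] + frac[rows, best] * np.sqrt(seg_len2[best])
    return positions, foot[rows, best]


def infer_pseudotime(coords: np.ndarray, span: float = 0.1,
                     tol: float = 1e-4, max_iter: int = 50,
                     n_curve_points: int = 200) -> PrincipalCurveResult:
    """Arc-length ordering of cells along a fitted principal curve."""
    X = np.asarray(coords, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise AnalysisError("need >= 10 germ cells to infer pseudotime")
    Xc = X - X.mean(axis=0)
    # initial ordering: first principal component of the embedding
    _u, _s, vt = np.linalg.svd(Xc, full_matrices=False)
    s = Xc @ vt[0]

    k = max(5, int(np.ceil(span * X.shape[0])))
    prev_foot = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        order = np.argsort(s, kind="stable")
        s_sorted = s[order]
        # curve support: density quantiles merged with an even grid, so
        # heavy ties (cells projected onto a shared vertex) cannot collapse
        # the curve
        grid = np.union1d(
            np.quantile(s_sorted, np.linspace(0.0, 1.0, n_curve_points)),
            np.linspace(s_sorted[0], s_sorted[-1], n_curve_points // 4))
        if grid.size < 2:
            break  # all cells identical; ordering is arbitrary but stable
        curve = np.atleast_2d(
            _local_linear(s_sorted, X[order], k, grid))
        # extend the end segments so extreme cells project onto the curve
        # interior rather than piling up on the terminal vertices
        head = curve[0] - 2.0 * (curve[1] - curve[0])
        tail = curve[-1] + 2.0 * (curve[-1] - curve[-2])
        curve = np.vstack([head, curve, tail])
        s_new, foot = _project_to_polyline(X, curve)
        if prev_foot is not None:
            disp = float(np.linalg.norm(foot - prev_foot, axis=1).mean())
            if disp < tol:
                s = s_new
                converged = True
                break
        prev_foot = foot
        s = s_new
    if not converged:
        logger.warning("principal curve not converged after %d iterations", it)
    return PrincipalCurveResult(scores=s, converged=converged, n_iter=it)


def orient_and_scale(scores: np.ndarray, early_marker_expression: np.ndarray,
                     ) -> np.ndarray:
    """Flip the ordering if the early marker rises with it; scale to [0, 1]."""
    s = np.asarray(scores, dtype=float).copy()
    expr = np.asarray(early_marker_expression, dtype=float)
    if expr.size != s.size:
        raise AnalysisError("marker expression must align with the scores")
    if expr.std() == 0:
        raise AnalysisError(
            "orientation marker is flat; try one of: "
            + ", ".join(EARLY_MARKER_CANDIDATES))
    if np.corrcoef(expr, s)[0, 1] > 0:
        s = -s
    lo, hi = s.min(), s.max()
    if hi == lo:
        raise AnalysisError("degenerate scores: all cells identical")
    return (s - lo) / (hi - lo)


def assign_pseudotime(coords: np.ndarray, germ_mask: np.ndarray,
                      early_marker_expression: np.ndarray,
                      orientation_marker: str = "",
                      span: float = 0.1) -> PseudotimeAssignment:
    """Infer, orient and scale pseudotime for the germ cells of an embedding.

    ``coords`` and ``early_marker_expression`` cover all cells;
    ``germ_mask`` selects the trajectory cells.
    """
    germ_mask = np.asarray(germ_mask, dtype=bool)
    result = infer_pseudotime(coords[germ_mask], span=span)
    t_germ = orient_and_scale(
        result.scores, np.asarray(early_marker_expression)[germ_mask])
    t = np.full(germ_mask.size, np.nan)
    t[germ_mask] = t_germ
    return PseudotimeAssignment(
        t=t, included=germ_mask, orientation_marker=orientation_marker,
        converged=result.converged)
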