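"""2D alpha-shape areas and the percent-increase alpha-selection rule.

A cluster's footprint is quantified as the area of its alpha shape: the
union of Delaunay triangles whose squared circumradius is at most the
scale parameter alpha (in nm²). Small alphas carve the point cloud down to
its dense core; as alpha grows the shape fills in and converges to the
convex hull. The scale is swept over alpha = x² nm² for x = 5, 10, …, 200
and the working alpha is the first whose step-to-step increase of the
median cluster area falls below 5% — the point where the measured area has
effectively stopped growing. The quantification alpha used on the real
receptor-field data by this procedure is 9025 nm² (x = 95).

Each cluster is triangulated alone; a global triangulation masked by
cluster labels would let cross-cluster triangles contaminate areas.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .exceptions import EmptyInputError, ParameterError, SelectionError

__all__ = [
    "AlphaShape",
    "AlphaSweepResult",
    "DEFAULT_ALPHAS",
    "DEFAULT_SELECTION_PCT",
    "alpha_shape_area",
    "area_vs_alpha_sweep",
    "select_alpha",
    "AlphaShapeQuantifier",
]

NM2_PER_UM2 = 1e6

#: the alpha sweep: x² nm² for x = 5, 10, …, 200 (40 values, 25…40,000 nm²)
DEFAULT_ALPHAS: np.ndarray = (np.arange(5, 201, 5, dtype=float)) ** 2

#: median-area step increase (percent) below which the sweep stops
DEFAULT_SELECTION_PCT = 5.0


@dataclass(frozen=True)
class AlphaShape:
    """An alpha shape of one point set at a fixed alpha (nm²)."""

    alpha: float
    triangles: np.ndarray  # (k, 3) vertex indices of retained triangles
    area: float  # nm²
    boundary: np.ndarray  # (m, 2) vertex-index pairs on the boundary
    degenerate: bool = False


@dataclass(frozen=True)
class AlphaSweepResult:
    """Median/quartile cluster area (µm²) at every alpha of the sweep."""

    alphas: np.ndarray  # nm²
    median_area: np.ndarray  # µm²
    q25: np.ndarray
    q75: np.ndarray
    pct_increase: np.ndarray  # percent; NaN at the first alpha

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alpha_nm2": self.alphas,
                "median_um2": self.median_area,
                "q25": self.q25,
                "q75": self.q75,
                "pct_increase": self.pct_increase,
            }
        )


def _triangle_geometry(points: np.ndarray, simplices: np.ndarray):
    """Per-triangle area and squared circumradius.

    R² = (|AB|·|BC|·|CA|)² / (16·A²) for triangle area A; degenerate
    (zero-area) triangles get R² = inf so no finite alpha retains them.
    """
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    ab = b - a
    ac = c - a
    bc = c - b
    cross = ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0]
    area = np.abs(cross) / 2.0
    l2 = (
        np.einsum("ij,ij->i", ab, ab)
        * np.einsum("ij,ij->i", bc, bc)
        * np.einsum("ij,ij->i", ac, ac)
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(area > 0.0, l2 / (16.0 * area**2), np.inf)
    return area, r2


def alpha_shape_area(points: np.ndarray, alpha: float) -> AlphaShape:
    """Alpha shape of a 2D point set at squared-circumradius scale ``alpha``.

    A Delaunay triangle is retained iff its circumradius² ≤ ``alpha``
    (inclusive); the area is the summed area of retained triangles and the
    boundary is the set of edges belonging to exactly one retained
    triangle. Fewer than 3 points, or a collinear set, yields area 0 with
    the ``degenerate`` flag set.
    """
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ParameterError("expected an (n, 2) coordinate array")
    empty = AlphaShape(
        alpha=float(alpha),
        triangles=np.empty((0, 3), dtype=np.int64),
        area=0.0,
        boundary=np.empty((0, 2), dtype=np.int64),
        degenerate=True,
    )
    if len(pts) < 3:
        return empty
    try:
        tri = Delaunay(pts)
    except QhullError:
        return empty  # all points collinear
    area, r2 = _triangle_geometry(pts, tri.simplices)
    keep = r2 <= alpha
    kept = tri.simplices[keep]
    edges = np.sort(
        np.concatenate([kept[:, [0, 1]], kept[:, [1, 2]], kept[:, [0, 2]]]), axis=1
    )
    if len(edges):
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        boundary = uniq[counts == 1]
    else:
        boundary = np.empty((0, 2), dtype=np.int64)
    return AlphaShape(
        alpha=float(alpha),
        triangles=kept,
        area=float(area[keep].sum()),
        boundary=boundary,
        degenerate=False,
    )


def area_vs_alpha_sweep(
    clusters: Sequence[np.ndarray],
    alphas: np.ndarray = DEFAULT_ALPHAS,
) -> AlphaSweepResult:
    """Median and quartile alpha-shape area across clusters at each alpha.

    The per-step percent increase of the median area is reported alongside;
    it is NaN at the first alpha (no predecessor) and wherever the previous
    median is zero.
    """
    clusters = [np.asarray(c, float) for c in clusters]
    if not clusters:
        raise EmptyInputError("area_vs_alpha_sweep needs at least one cluster")
    usable = [c for c in clusters if len(c) >= 3]
    if not usable:
        raise EmptyInputError("all clusters are degenerate (fewer than 3 points)")
    alphas = np.asarray(alphas, dtype=float)

    # one triangulation per cluster, thresholded at every alpha
    per_cluster = np.zeros((len(clusters), len(alphas)))
    for ci, pts in enumerate(clusters):
        if len(pts) < 3:
            continue
        try:
            tri = Delaunay(pts)
        except QhullError:
            continue
        t_area, r2 = _triangle_geometry(pts, tri.simplices)
        order = np.argsort(r2)
        csum = np.concatenate([[0.0], np.cumsum(t_area[order])])
        n_kept = np.searchsorted(r2[order], alphas, side="right")
        per_cluster[ci] = csum[n_kept]

    per_cluster /= NM2_PER_UM2
    med = np.median(per_cluster, axis=0)
    q25 = np.percentile(per_cluster, 25, axis=0)
    q75 = np.percentile(per_cluster, 75, axis=0)
    pct = np.full(len(alphas), np.nan)
    prev = med[:-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct[1:] = np.where(prev > 0, 100.0 * (med[1:] - prev) / prev, np.nan)
    return AlphaSweepResult(alphas=alphas, median_area=med, q25=q25, q75=q75, pct_increase=pct)


def select_alpha(
    result: AlphaSweepResult, threshold_pct: float = DEFAULT_SELECTION_PCT
) -> float:
    """First alpha whose median-area step increase is strictly below threshold.

    The first grid alpha has no predecessor step and is never selectable.
    Raises :class:`SelectionError` when no step qualifies (the sweep should
    then be widened).
    """
    for i in range(1, len(result.alphas)):
        p = result.pct_increase[i]
        if np.isfinite(p) and p < threshold_pct:
            return float(result.alphas[i])
    raise SelectionError(
        f"no alpha step increases the median area by < {threshold_pct}%; widen the sweep"
    )


class AlphaShapeQuantifier:
    """Sweep-calibrated alpha-shape area measurement, estimator-style.

    ``fit(clusters)`` runs the alpha sweep over the given list of ``(n, 2)``
    point sets and selects the working alpha by the percent-increase rule
    (or accepts a fixed ``alpha``); ``transform(clusters)`` then returns
    each cluster's area in µm² at the fitted alpha.

    Parameters
    ----------
    alpha : float or None
        Fixed alpha in nm²; ``None`` selects one from the sweep at fit time.
    alphas : array
        The sweep grid (nm²).
    threshold_pct : float
        Stopping threshold of the percent-increase rule.

    Attributes
    ----------
    alpha_ : float
        Working alpha after ``fit``.
    sweep_ : AlphaSweepResult or None
        Sweep result (``None`` when ``alpha`` was fixed).
    """

    def __init__(
        self,
        alpha: float | None = None,
        alphas: np.ndarray = DEFAULT_ALPHAS,
        threshold_pct: float = DEFAULT_SELECTION_PCT,
    ):
        self.alpha = alpha
        self.alphas = alphas
        self.threshold_pct = threshold_pct

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alpha": self.alpha,
            "alphas": self.alphas,
            "threshold_pct": self.threshold_pct,
        }

    def set_params(self, **params) -> "AlphaShapeQuantifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ParameterError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, clusters: Sequence[np.ndarray], y=None) -> "AlphaShapeQuantifier":
        if self.alpha is not None:
            self.alpha_ = float(self.alpha)
            self.sweep_ = None
            return self
        self.sweep_ = area_vs_alpha_sweep(clusters, self.alphas)
        self.alpha_ = select_alpha(self.sweep_, self.threshold_pct)
        return self

    def transform(self, clusters: Sequence[np.ndarray]) -> np.ndarray:
        """Per-cluster alpha-shape area in µm² at the fitted alpha."""
        if not hasattr(self, "alpha_"):
            raise ParameterError("AlphaShapeQuantifier is not fitted")
        return np.array(
            [alpha_shape_area(c, self.alpha_).area / NM2_PER_UM2 for c in clusters]
        )

    def fit_transform(self, clusters: Sequence[np.ndarray], y=None) -> np.ndarray:
        return self.fit(clusters).transform(clusters)
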