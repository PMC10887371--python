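"""Density-based cluster extraction and the two-parameter stability sweep.

Receptor-field candidates are extracted from the (x, y) point cloud with
hierarchical density-based clustering (HDBSCAN), governed by two free
parameters: the minimum cluster size and the minimum number of samples in a
point's neighbourhood. Because the parameter choice is the main analyst
degree of freedom, a full grid of 140 combinations is evaluated (median
cluster count per image) and parameters are chosen from the largest stable
plateau of that grid; (40, 10) is the anchored default used for final
quantification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN

from .exceptions import EmptyInputError, ParameterError, SelectionError
from .io import validate_localizations

__all__ = [
    "ClusterParams",
    "ClusterSet",
    "SweepGrid",
    "DEFAULT_MCS_VALUES",
    "DEFAULT_MS_VALUES",
    "FieldClusterer",
    "extract_clusters",
    "run_sweep",
    "select_stable_params",
]

#: minimum-cluster-size grid: 10–100 in increments of 10
DEFAULT_MCS_VALUES: tuple[int, ...] = tuple(range(10, 101, 10))

#: minimum-samples grid: 2, 5–25 in increments of 5, 30–100 in increments of 10
DEFAULT_MS_VALUES: tuple[int, ...] = (2,) + tuple(range(5, 26, 5)) + tuple(range(30, 101, 10))


@dataclass(frozen=True)
class ClusterParams:
    """The two free density-clustering parameters."""

    min_cluster_size: int = 40
    min_samples: int = 10

    def __post_init__(self) -> None:
        if self.min_cluster_size < 2:
            raise ParameterError("min_cluster_size must be >= 2")
        if self.min_samples < 1:
            raise ParameterError("min_samples must be >= 1")


@dataclass(frozen=True)
class ClusterSet:
    """Labeled partition of ROI localizations into clusters plus noise.

    ``labels[i]`` is the cluster id of localization ``i`` (−1 = noise).
    Ids are assigned by descending cluster size, ties broken by the
    smallest member index, so output is deterministic for a fixed input.
    """

    labels: np.ndarray
    params: ClusterParams
    roi_label: str = ""

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if len(self.labels) else 0

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


@dataclass(frozen=True)
class SweepGrid:
    """Median cluster count per image over the full parameter grid."""

    mcs_values: tuple[int, ...]
    ms_values: tuple[int, ...]
    median_counts: np.ndarray  # shape (len(mcs_values), len(ms_values))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"mcs": m, "ms": s, "median_clusters": self.median_counts[i, j]}
            for i, m in enumerate(self.mcs_values)
            for j, s in enumerate(self.ms_values)
        ]
        return pd.DataFrame(rows)


def _canonicalize_labels(raw: np.ndarray, min_cluster_size: int) -> np.ndarray:
    """Relabel cluster ids by descending size; ties by smallest member index.

    Clusters smaller than ``min_cluster_size`` (HDBSCAN can emit them in
    rare boundary cases) are demoted to noise so the size contract holds.
    """
    labels = np.full(len(raw), -1, dtype=np.int64)
    uniq = [u for u in np.unique(raw) if u != -1]
    info = []
    for u in uniq:
        idx = np.flatnonzero(raw == u)
        if len(idx) >= min_cluster_size:
            info.append((-len(idx), idx[0], idx))
    info.sort(key=lambda t: (t[0], t[1]))
    for new_id, (_, _, idx) in enumerate(info):
        labels[idx] = new_id
    return labels


class FieldClusterer(ClusterMixin, BaseEstimator):
    """HDBSCAN-based receptor-field clusterer with deterministic labels.

    A thin scikit-learn-style estimator: ``fit(X)`` on an ``(n, 2)`` nm
    coordinate array sets ``labels_``; ids are ordered by descending
    cluster size. Inputs smaller than ``min_cluster_size`` yield all-noise
    labels rather than an error.

    Parameters
    ----------
    min_cluster_size : int, default 40
    min_samples : int, default 10
    """

    def __init__(self, min_cluster_size: int = 40, min_samples: int = 10):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples

    def fit(self, X, y=None):
        params = ClusterParams(self.min_cluster_size, self.min_samples)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ParameterError("expected an (n, 2) coordinate array")
        if len(X) < params.min_cluster_size or len(X) <= params.min_samples:
            self.labels_ = np.full(len(X), -1, dtype=np.int64)
            return self
        raw = HDBSCAN(
            min_cluster_size=params.min_cluster_size,
            min_samples=params.min_samples,
            copy=True,
        ).fit_predict(X)
        self.labels_ = _canonicalize_labels(raw, params.min_cluster_size)
        return self

    @property
    def n_clusters_(self) -> int:
        return int(self.labels_.max() + 1) if len(self.labels_) else 0


def extract_clusters(
    table: pd.DataFrame,
    params: ClusterParams = ClusterParams(),
    roi_label: str = "",
) -> ClusterSet:
    """Cluster a localization table at fixed parameters.

    Clustering uses (x, y) only; frame and A/D count ride along as
    metadata. Fewer localizations than ``min_cluster_size`` is not an
    error: the result is simply all-noise.
    """
    validate_localizations(table)
    if not len(table):
        raise EmptyInputError("cannot cluster an empty localization table")
    est = FieldClusterer(params.min_cluster_size, params.min_samples)
    est.fit(table[["x_nm", "y_nm"]].to_numpy(float))
    return ClusterSet(labels=est.labels_, params=params, roi_label=roi_label)


def run_sweep(
    images: Sequence[pd.DataFrame],
    mcs_values: Sequence[int] = DEFAULT_MCS_VALUES,
    ms_values: Sequence[int] = DEFAULT_MS_VALUES,
) -> SweepGrid:
    """Median detected-cluster count per image over the parameter grid.

    With the default grid this evaluates 10 × 14 = 140 parameter
    combinations on every image.
    """
    if not len(images):
        raise EmptyInputError("run_sweep needs at least one image")
    med = np.zeros((len(mcs_values), len(ms_values)))
    for i, mcs in enumerate(mcs_values):
        for j, ms in enumerate(ms_values):
            counts = [
                extract_clusters(img, ClusterParams(mcs, ms)).n_clusters
                for img in images
            ]
            med[i, j] = float(np.median(counts))
    return SweepGrid(tuple(mcs_values), tuple(ms_values), med)


def _stable_mask(grid: SweepGrid, rel_tol: float) -> np.ndarray:
    """Cells whose median count is within ``rel_tol`` of all 4-neighbours."""
    m = grid.median_counts
    nrow, ncol = m.shape
    ok = np.ones(m.shape, dtype=bool)
    for i in range(nrow):
        for j in range(ncol):
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                a, b = i + di, j + dj
                if not (0 <= a < nrow and 0 <= b < ncol):
                    continue
                diff = abs(m[i, j] - m[a, b])
                base = max(abs(m[i, j]), abs(m[a, b]))
                if diff > rel_tol * base and diff > 0:
                    ok[i, j] = False
                    break
    return ok


def _components(mask: np.ndarray) -> list[list[tuple[int, int]]]:
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for i in range(mask.shape[0]):
        for j in range(mask.shape[1]):
            if mask[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    comp.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = a + da, b + db
                        if (
                            0 <= na < mask.shape[0]
                            and 0 <= nb < mask.shape[1]
                            and mask[na, nb]
                            and not seen[na, nb]
                        ):
                            seen[na, nb] = True
                            stack.append((na, nb))
                comps.append(comp)
    return comps


def select_stable_params(
    grid: SweepGrid,
    rel_tol: float = 0.10,
    default: ClusterParams = ClusterParams(40, 10),
) -> ClusterParams:
    """Pick clustering parameters from the largest stable plateau.

    A cell is stable when its median cluster count differs by at most
    ``rel_tol`` (relative) from every existing 4-neighbour. Within the
    largest connected stable region the anchored default is returned if it
    lies inside; otherwise the cell closest to the region's centroid. If no
    cell is stable the tolerance is doubled until one is, with a warning —
    mirroring the fact that "stable range" is ultimately a judgement call.
    """
    tol = rel_tol
    mask = _stable_mask(grid, tol)
    while not mask.any():
        tol = max(tol * 2.0, 0.01)
        warnings.warn(
            f"no stable plateau at rel_tol={rel_tol:g}; widening to {tol:g}",
            stacklevel=2,
        )
        if tol > 10.0:
            raise SelectionError("sweep grid has no stable region at any tolerance")
        mask = _stable_mask(grid, tol)
    comps = _components(mask)
    comp = max(comps, key=len)
    cells = {
        (grid.mcs_values[i], grid.ms_values[j]): (i, j) for i, j in comp
    }
    if (default.min_cluster_size, default.min_samples) in cells:
        return default
    ci = np.mean([i for i, _ in comp])
    cj = np.mean([j for _, j in comp])
    i, j = min(comp, key=lambda c: (c[0] - ci) ** 2 + (c[1] - cj) ** 2)
    return ClusterParams(grid.mcs_values[i], grid.ms_values[j])
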