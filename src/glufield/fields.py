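"""Receptor-field exclusion criteria and summary statistics.

After clustering and area measurement, fields outside the plausible size
band are excluded: area ≤ 0.03 µm² (fragments, degenerate shapes) and
area ≥ 0.3 µm² (merged neighbouring fields) are both dropped, boundaries
included in the exclusion. Survivors are summarized the way the imaging
figures present them: median with 25th/75th-percentile box and
10th/90th-percentile whiskers, plus histograms normalized so the heights
sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .alphashape import alpha_shape_area
from .cluster import ClusterSet
from .exceptions import EmptyInputError, ParameterError

__all__ = [
    "ReceptorField",
    "FieldSummary",
    "AREA_EXCLUSION_LO",
    "AREA_EXCLUSION_HI",
    "fields_from_clusters",
    "apply_exclusion",
    "summarize",
]

NM2_PER_UM2 = 1e6

#: exclusion bounds, µm²: fields with area <= lo or >= hi are dropped
AREA_EXCLUSION_LO = 0.03
AREA_EXCLUSION_HI = 0.3


@dataclass(frozen=True)
class ReceptorField:
    """Geometry summary of one extracted cluster."""

    cluster_id: int
    roi_label: str
    n_locs: int
    area: float  # µm²
    centroid: tuple[float, float]  # nm
    degenerate: bool = False


@dataclass(frozen=True)
class FieldSummary:
    """Box-plot-style summary plus normalized histograms."""

    n_fields: int
    median_area: float
    q25_area: float
    q75_area: float
    p10_area: float
    p90_area: float
    median_locs: float
    q25_locs: float
    q75_locs: float
    p10_locs: float
    p90_locs: float
    area_hist_edges: np.ndarray = field(repr=False, default=None)
    area_hist_heights: np.ndarray = field(repr=False, default=None)
    locs_hist_edges: np.ndarray = field(repr=False, default=None)
    locs_hist_heights: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "n_fields": self.n_fields,
            "median_area_um2": self.median_area,
            "q25_area_um2": self.q25_area,
            "q75_area_um2": self.q75_area,
            "p10_area_um2": self.p10_area,
            "p90_area_um2": self.p90_area,
            "median_locs": self.median_locs,
            "q25_locs": self.q25_locs,
            "q75_locs": self.q75_locs,
            "p10_locs": self.p10_locs,
            "p90_locs": self.p90_locs,
        }


def fields_from_clusters(
    table: pd.DataFrame, clusters: ClusterSet, alpha: float
) -> list[ReceptorField]:
    """Measure every cluster of a labeled table at a fixed alpha (nm²)."""
    coords = table[["x_nm", "y_nm"]].to_numpy(float)
    fields = []
    for cid in range(clusters.n_clusters):
        idx = clusters.members(cid)
        pts = coords[idx]
        shape = alpha_shape_area(pts, alpha)
        fields.append(
            ReceptorField(
                cluster_id=cid,
                roi_label=clusters.roi_label,
                n_locs=len(idx),
                area=shape.area / NM2_PER_UM2,
                centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                degenerate=shape.degenerate,
            )
        )
    return fields


def apply_exclusion(
    fields: Sequence[ReceptorField],
    lo: float = AREA_EXCLUSION_LO,
    hi: float = AREA_EXCLUSION_HI,
) -> tuple[list[ReceptorField], pd.DataFrame]:
    """Drop fields with area ≤ lo or ≥ hi µm² (bounds excluded from keep).

    Returns the surviving fields in input order plus an audit table listing
    every input field with its fate, so the pre-/post-exclusion accounting
    stays reproducible.
    """
    if lo >= hi:
        raise ParameterError("exclusion bounds require lo < hi")
    kept, rows = [], []
    for f in fields:
        if f.area <= lo:
            reason = "area<=lo"
        elif f.area >= hi:
            reason = "area>=hi"
        else:
            reason = ""
            kept.append(f)
        rows.append(
            {
                "roi_label": f.roi_label,
                "cluster_id": f.cluster_id,
                "n_locs": f.n_locs,
                "area_um2": f.area,
                "excluded": bool(reason),
                "reason": reason,
            }
        )
    audit = pd.DataFrame(
        rows,
        columns=["roi_label", "cluster_id", "n_locs", "area_um2", "excluded", "reason"],
    )
    return kept, audit


def _box_stats(values: np.ndarray) -> tuple[float, float, float, float, float]:
    """median, q25, q75, p10, p90 with linear-interpolation percentiles."""
    return (
        float(np.percentile(values, 50)),
        float(np.percentile(values, 25)),
        float(np.percentile(values, 75)),
        float(np.percentile(values, 10)),
        float(np.percentile(values, 90)),
    )


def summarize(fields: Sequence[ReceptorField], n_bins: int = 20) -> FieldSummary:
    """Summary statistics and normalized histograms over receptor fields.

    Histogram heights are bin counts divided by the total number of fields,
    so they sum to 1 regardless of binning.
    """
    if not len(fields):
        raise EmptyInputError("summarize needs at least one field")
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    areas = np.array([f.area for f in fields], dtype=float)
    locs = np.array([f.n_locs for f in fields], dtype=float)
    med_a, q25_a, q75_a, p10_a, p90_a = _box_stats(areas)
    med_l, q25_l, q75_l, p10_l, p90_l = _box_stats(locs)
    a_counts, a_edges = np.histogram(areas, bins=n_bins)
    l_counts, l_edges = np.histogram(locs, bins=n_bins)
    return FieldSummary(
        n_fields=len(fields),
        median_area=med_a,
        q25_area=q25_a,
        q75_area=q75_a,
        p10_area=p10_a,
        p90_area=p90_a,
        median_locs=med_l,
        q25_locs=q25_l,
        q75_locs=q75_l,
        p10_locs=p10_l,
        p90_locs=p90_l,
        area_hist_edges=a_edges,
        area_hist_heights=a_counts / len(fields),
        locs_hist_edges=l_edges,
        locs_hist_heights=l_counts / len(fields),
    )
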