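"""End-to-end receptor-field quantification pipeline.

Chains the individual stages in the order they are applied to real data:

1. intensity filter (A/D count strictly above 12,000),
2. optional ROI clipping,
3. HDBSCAN cluster extraction at (min_cluster_size, min_samples),
4. alpha-shape area measurement, with alpha either fixed or selected from
   the x² sweep by the <5% median-area-increase rule,
5. area-band exclusion (0.03 < area < 0.3 µm²),
6. box-plot/histogram summary.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .alphashape import AlphaShapeQuantifier, DEFAULT_ALPHAS, DEFAULT_SELECTION_PCT
from .cluster import ClusterParams, extract_clusters
from .exceptions import EmptyInputError
from .fields import (
    AREA_EXCLUSION_HI,
    AREA_EXCLUSION_LO,
    apply_exclusion,
    fields_from_clusters,
    summarize,
)
from .io import AD_COUNT_THRESHOLD, RoiPolygon, clip_to_roi, filter_by_adcount

__all__ = ["ReceptorFieldPipeline", "analyze"]


class ReceptorFieldPipeline:
    """One-call quantification of receptor fields from a localization table.

    ``fit(table)`` runs the whole chain and exposes the intermediate and
    final products as fitted attributes; the estimator never mutates its
    inputs and is deterministic for a fixed table.

    Parameters
    ----------
    min_adcount : float
        Intensity filter threshold (strictly greater-than).
    min_cluster_size, min_samples : int
        Density-clustering parameters.
    alpha : float or None
        Fixed alpha-shape scale in nm²; ``None`` selects one from the
        sweep by the percent-increase rule.
    lo, hi : float
        Area exclusion band, µm² (boundaries excluded).
    n_bins : int
        Histogram bins of the summary.

    Attributes
    ----------
    table_ : pd.DataFrame
        Filtered (and clipped) localization table actually analyzed.
    clusters_ : ClusterSet
    alpha_ : float
    fields_ : list[ReceptorField]
        Pre-exclusion fields.
    kept_fields_ : list[ReceptorField]
    audit_ : pd.DataFrame
        Exclusion accounting of every field.
    summary_ : FieldSummary
    """

    def __init__(
        self,
        min_adcount: float = AD_COUNT_THRESHOLD,
        min_cluster_size: int = 40,
        min_samples: int = 10,
        alpha: float | None = None,
        alphas: np.ndarray = DEFAULT_ALPHAS,
        threshold_pct: float = DEFAULT_SELECTION_PCT,
        lo: float = AREA_EXCLUSION_LO,
        hi: float = AREA_EXCLUSION_HI,
        n_bins: int = 20,
    ):
        self.min_adcount = min_adcount
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.alpha = alpha
        self.alphas = alphas
        self.threshold_pct = threshold_pct
        self.lo = lo
        self.hi = hi
        self.n_bins = n_bins

    def get_params(self, deep: bool = True) -> dict:
        return {
            "min_adcount": self.min_adcount,
            "min_cluster_size": self.min_cluster_size,
            "min_samples": self.min_samples,
            "alpha": self.alpha,
            "alphas": self.alphas,
            "threshold_pct": self.threshold_pct,
            "lo": self.lo,
            "hi": self.hi,
            "n_bins": self.n_bins,
        }

    def set_params(self, **params) -> "ReceptorFieldPipeline":
        known = self.get_params()
        for k, v in params.items():
            if k not in known:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, table: pd.DataFrame, roi: RoiPolygon | None = None) -> "ReceptorFieldPipeline":
        t = filter_by_adcount(table, self.min_adcount)
        if roi is not None:
            t = clip_to_roi(t, roi)
        if not len(t):
            raise EmptyInputError("no localizations survive filtering/clipping")
        self.table_ = t
        self.clusters_ = extract_clusters(
            t,
            ClusterParams(self.min_cluster_size, self.min_samples),
            roi_label=roi.label if roi is not None else "",
        )
        coords = t[["x_nm", "y_nm"]].to_numpy(float)
        point_sets = [
            coords[self.clusters_.members(cid)]
            for cid in range(self.clusters_.n_clusters)
        ]
        if not point_sets:
            raise EmptyInputError("no clusters detected; nothing to quantify")
        quant = AlphaShapeQuantifier(
            alpha=self.alpha, alphas=self.alphas, threshold_pct=self.threshold_pct
        ).fit(point_sets)
        self.alpha_ = quant.alpha_
        self.sweep_ = quant.sweep_
        self.fields_ = fields_from_clusters(t, self.clusters_, self.alpha_)
        self.kept_fields_, self.audit_ = apply_exclusion(self.fields_, self.lo, self.hi)
        if self.kept_fields_:
            self.summary_ = summarize(self.kept_fields_, self.n_bins)
        else:
            self.summary_ = None
        return self


def analyze(
    table: pd.DataFrame, roi: RoiPolygon | None = None, **params
) -> ReceptorFieldPipeline:
    """Run :class:`ReceptorFieldPipeline` with the given parameters."""
    return ReceptorFieldPipeline(**params).fit(table, roi)
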