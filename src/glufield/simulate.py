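"""Ground-truth simulator for clustered dSTORM localization data.

The generator emulates the statistical structure the downstream analysis
assumes: receptor fields are compact regions (disks, ellipses or polygons)
populated by labeled fluorophores; each detected fluorophore blinks one or
more times, and every blink is localized with isotropic Gaussian error.
Unclustered background arises as a homogeneous Poisson process over the
ROI. The output is an ordinary localization table plus a ground-truth
assignment of every localization to its generating cluster (or background),
so cluster recovery and area estimates can be scored against known truth.

The model deliberately omits photophysics: there is no per-frame on/off
kinetics, photon budget or PSF rendering — only the marginal blink count
per fluorophore matters for cluster-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .exceptions import ParameterError
from .io import AD_COUNT_THRESHOLD, DEFAULT_N_FRAMES, LOC_COLUMNS, RoiPolygon

__all__ = [
    "GroundTruthCluster",
    "SyntheticScene",
    "truth_area",
    "simulate_scene",
    "paper_like_scene",
]

NM2_PER_UM2 = 1e6


@dataclass(frozen=True)
class GroundTruthCluster:
    """One simulated receptor field.

    Parameters
    ----------
    shape
        ``disk``, ``ellipse`` or ``polygon``.
    center
        (x, y) of the shape centre in nm (ignored for ``polygon``).
    true_area
        Area of the support region in µm² (derived from ``vertices`` for
        polygons).
    n_fluorophores
        Number of detected fluorophore sites placed uniformly in the shape.
    blinks_mean
        Mean of the geometric blink-count distribution on {1, 2, ...};
        total localizations per cluster ≈ n_fluorophores × blinks_mean.
    loc_precision_sigma
        Isotropic Gaussian localization error per blink, nm.
    aspect
        Major/minor axis ratio for ellipses (1 = disk).
    angle
        Ellipse rotation, radians.
    vertices
        Polygon corners in nm (``polygon`` shape only).
    """

    shape: Literal["disk", "ellipse", "polygon"] = "disk"
    center: tuple[float, float] = (0.0, 0.0)
    true_area: float = 0.15
    n_fluorophores: int = 40
    blinks_mean: float = 2.0
    loc_precision_sigma: float = 10.0
    aspect: float = 1.0
    angle: float = 0.0
    vertices: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.shape == "polygon":
            if self.vertices is None or len(np.asarray(self.vertices)) < 3:
                raise ParameterError("polygon cluster needs >= 3 vertices")
            object.__setattr__(self, "vertices", np.asarray(self.vertices, float))
            object.__setattr__(
                self, "true_area", float(Polygon(self.vertices).area) / NM2_PER_UM2
            )
        if self.true_area < 0:
            raise ParameterError("true_area must be >= 0")
        if self.n_fluorophores < 1:
            raise ParameterError("n_fluorophores must be >= 1")
        if self.blinks_mean < 1:
            raise ParameterError("blinks_mean must be >= 1")
        if self.loc_precision_sigma < 0:
            raise ParameterError("loc_precision_sigma must be >= 0")


@dataclass(frozen=True)
class SyntheticScene:
    """A full simulated field of view: clusters + background within a ROI."""

    clusters: Sequence[GroundTruthCluster]
    roi: RoiPolygon
    background_density: float = 1.0  # localizations per µm²
    seed: int = 0
    n_frames: int = DEFAULT_N_FRAMES
    #: fraction of A/D counts drawn above the 12,000 intensity threshold
    above_threshold_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.background_density < 0:
            raise ParameterError("background_density must be >= 0")
        if not 0.0 <= self.above_threshold_fraction <= 1.0:
            raise ParameterError("above_threshold_fraction must be in [0, 1]")


def truth_area(cluster: GroundTruthCluster) -> float:
    """Analytic area of a cluster's support region, µm².

    πr² for disks, πab for ellipses, the shoelace formula for polygons.
    """
    if cluster.shape == "polygon":
        return float(Polygon(cluster.vertices).area) / NM2_PER_UM2
    return float(cluster.true_area)


def _disk_radius_nm(area_um2: float) -> float:
    return float(np.sqrt(area_um2 * NM2_PER_UM2 / np.pi))


def _sample_in_shape(rng: np.random.Generator, c: GroundTruthCluster, n: int) -> np.ndarray:
    """Uniform fluorophore positions inside the cluster's support, nm."""
    if c.shape in ("disk", "ellipse"):
        # sample a unit disk, then scale to the requested area/aspect
        theta = rng.uniform(0.0, 2.0 * np.pi, n)
        rad = np.sqrt(rng.uniform(0.0, 1.0, n))
        u, v = rad * np.cos(theta), rad * np.sin(theta)
        if c.shape == "disk":
            r = _disk_radius_nm(c.true_area)
            x, y = r * u, r * v
        else:
            # area = pi*a*b with a = aspect*b
            b = np.sqrt(c.true_area * NM2_PER_UM2 / (np.pi * c.aspect))
            a = c.aspect * b
            x0, y0 = a * u, b * v
            ca, sa = np.cos(c.angle), np.sin(c.angle)
            x, y = ca * x0 - sa * y0, sa * x0 + ca * y0
        return np.column_stack([x + c.center[0], y + c.center[1]])
    poly = Polygon(c.vertices)
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(4 * (n - len(out)), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        import shapely

        keep = shapely.intersects(poly, shapely.points(cand[:, 0], cand[:, 1]))
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _draw_adcounts(rng: np.random.Generator, n: int, frac_above: float) -> np.ndarray:
    above = rng.uniform(0.0, 1.0, n) < frac_above
    counts = np.where(
        above,
        rng.uniform(AD_COUNT_THRESHOLD + 1.0, 2.5 * AD_COUNT_THRESHOLD, n),
        rng.uniform(0.0, AD_COUNT_THRESHOLD, n),
    )
    return counts


def simulate_scene(scene: SyntheticScene) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one field of view.

    Returns
    -------
    table
        Localization table (``x_nm, y_nm, frame, adcount``).
    truth
        Assignment table with columns ``loc_index`` and ``cluster_id``
        (``-1`` = background), aligned with ``table`` rows.

    Identical scene parameters and seed give bit-identical output.
    """
    rng = np.random.default_rng(scene.seed)
    xs, ys, ids = [], [], []

    for cid, c in enumerate(scene.clusters):
        sites = _sample_in_shape(rng, c, c.n_fluorophores)
        if c.blinks_mean == 1.0:
            k = np.ones(c.n_fluorophores, dtype=np.int64)
        else:
            k = rng.geometric(1.0 / c.blinks_mean, c.n_fluorophores)
        pos = np.repeat(sites, k, axis=0)
        noise = rng.normal(0.0, c.loc_precision_sigma, pos.shape) if c.loc_precision_sigma else 0.0
        pos = pos + noise
        xs.append(pos[:, 0])
        ys.append(pos[:, 1])
        ids.append(np.full(len(pos), cid, dtype=np.int64))

    roi_area_um2 = scene.roi.area_nm2 / NM2_PER_UM2
    n_bg = int(rng.poisson(scene.background_density * roi_area_um2))
    if n_bg:
        minx, miny, maxx, maxy = scene.roi.polygon.bounds
        bg = np.empty((0, 2))
        while len(bg) < n_bg:
            m = max(4 * (n_bg - len(bg)), 16)
            cand = np.column_stack(
                [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
            )
            import shapely

            keep = shapely.intersects(
                scene.roi.polygon, shapely.points(cand[:, 0], cand[:, 1])
            )
            bg = np.vstack([bg, cand[keep]])
        bg = bg[:n_bg]
        xs.append(bg[:, 0])
        ys.append(bg[:, 1])
        ids.append(np.full(n_bg, -1, dtype=np.int64))

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    cid_arr = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    n = len(x)
    table = pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": y,
            "frame": rng.integers(0, scene.n_frames, n),
            "adcount": _draw_adcounts(rng, n, scene.above_threshold_fraction),
        },
        columns=list(LOC_COLUMNS),
    )
    truth = pd.DataFrame({"loc_index": np.arange(n, dtype=np.int64), "cluster_id": cid_arr})
    return table, truth


def paper_like_scene(
    n_clusters: int = 30,
    seed: int = 0,
    median_area: float = 0.15,
    area_sigma_log: float = 0.35,
    area_bounds: tuple[float, float] = (0.03, 0.3),
    n_fluorophores: int = 40,
    blinks_mean: float = 2.0,
    loc_precision_sigma: float = 10.0,
    background_density: float = 1.0,
    pitch_nm: float = 3000.0,
) -> SyntheticScene:
    """Default scene preset mirroring the analyzed receptor-field statistics.

    Cluster areas are log-normal with the given median, truncated to
    ``area_bounds``; each cluster carries ~``n_fluorophores × blinks_mean``
    localizations (~80 by default). Cluster centres sit on a jittered square
    grid with ``pitch_nm`` spacing so fields are well separated, inside a
    rectangular ROI with a half-pitch margin.
    """
    rng = np.random.default_rng(seed)
    areas = []
    while len(areas) < n_clusters:
        a = float(np.exp(rng.normal(np.log(median_area), area_sigma_log)))
        if area_bounds[0] < a < area_bounds[1]:
            areas.append(a)
    ncol = int(np.ceil(np.sqrt(n_clusters)))
    nrow = int(np.ceil(n_clusters / ncol))
    clusters = []
    for k, a in enumerate(areas):
        i, j = divmod(k, ncol)
        cx = (j + 0.5) * pitch_nm + rng.uniform(-0.1, 0.1) * pitch_nm
        cy = (i + 0.5) * pitch_nm + rng.uniform(-0.1, 0.1) * pitch_nm
        clusters.append(
            GroundTruthCluster(
                shape="disk",
                center=(cx, cy),
                true_area=a,
                n_fluorophores=n_fluorophores,
                blinks_mean=blinks_mean,
                loc_precision_sigma=loc_precision_sigma,
            )
        )
    w, h = ncol * pitch_nm, nrow * pitch_nm
    roi = RoiPolygon(
        np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]]), label="paper_like"
    )
    return SyntheticScene(
        clusters=clusters,
        roi=roi,
        background_density=background_density,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
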