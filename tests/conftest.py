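import numpy as np
import pandas as pd
import pytest

from glufield import GroundTruthCluster, RoiPolygon, SyntheticScene, simulate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_roi():
    """10x10 µm square ROI starting at the origin, nm coordinates."""
    return RoiPolygon(
        np.array([[0.0, 0.0], [10_000.0, 0.0], [10_000.0, 10_000.0], [0.0, 10_000.0]]),
        label="sq",
    )


def make_table(x, y, frame=None, adcount=None):
    x = np.asarray(x, float)
    n = len(x)
    return pd.DataFrame(
        {
            "x_nm": x,
            "y_nm": np.asarray(y, float),
            "frame": np.zeros(n, dtype=np.int64) if frame is None else np.asarray(frame),
            "adcount": np.full(n, 20_000.0) if adcount is None else np.asarray(adcount, float),
        }
    )


@pytest.fixture
def two_disk_table():
    """Two dense disjoint 100-point disks 2 µm apart, no background.

    Radius 150 nm, so typical nearest-neighbour spacing is well under
    50 nm while the gap between disks is >10x the disk diameter.
    """
    rng = np.random.default_rng(7)
    pts = []
    for cx in (0.0, 2000.0):
        theta = rng.uniform(0, 2 * np.pi, 100)
        rad = 150.0 * np.sqrt(rng.uniform(0, 1, 100))
        pts.append(np.c_[cx + rad * np.cos(theta), rad * np.sin(theta)])
    pts = np.vstack(pts)
    return make_table(pts[:, 0], pts[:, 1])


def disk_scene(n_clusters, seed, **kw):
    """Well-separated equal disks inside a matching rectangular ROI."""
    defaults = dict(
        true_area=0.15, n_fluorophores=40, blinks_mean=2.0, loc_precision_sigma=10.0
    )
    defaults.update(kw.pop("cluster_kw", {}))
    pitch = 3000.0
    ncol = int(np.ceil(np.sqrt(n_clusters)))
    nrow = int(np.ceil(n_clusters / ncol))
    clusters = [
        GroundTruthCluster(
            shape="disk",
            center=((k % ncol + 0.5) * pitch, (k // ncol + 0.5) * pitch),
            **defaults,
        )
        for k in range(n_clusters)
    ]
    w, h = ncol * pitch, nrow * pitch
    roi = RoiPolygon(np.array([[0.0, 0.0], [w, 0.0], [w, h], [0.0, h]]))
    return SyntheticScene(clusters=clusters, roi=roi, seed=seed, **kw)


@pytest.fixture
def fifty_cluster_point_sets():
    """Point sets of the 50 ground-truth clusters of a fixed synthetic scene."""
    table, truth = simulate_scene(disk_scene(50, seed=42, background_density=0.0))
    coords = table[["x_nm", "y_nm"]].to_numpy()
    return [coords[(truth.cluster_id == k).to_numpy()] for k in range(50)]
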