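"""Cluster extraction, the 140-cell parameter sweep, and plateau selection."""

import numpy as np
import pytest

from glufield import (
    ClusterParams,
    DEFAULT_MCS_VALUES,
    DEFAULT_MS_VALUES,
    FieldClusterer,
    ParameterError,
    SweepGrid,
    extract_clusters,
    run_sweep,
    select_stable_params,
    simulate_scene,
)

from conftest import disk_scene, make_table


def _epsilon_components(coords, eps):
    """Single-linkage connected components at distance eps (oracle)."""
    n = len(coords)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    for i in range(n):
        for j in range(i + 1, n):
            if d2[i, j] <= eps**2:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


class TestExtractClusters:
    def test_two_disjoint_disks(self, two_disk_table):
        cs = extract_clusters(two_disk_table, ClusterParams(40, 10))
        assert cs.n_clusters == 2
        assert (cs.labels >= 0).all()  # no noise in this construction

    def test_clusters_match_epsilon_components(self, two_disk_table):
        # every eps-connected component of size >= 40 maps into one cluster
        coords = two_disk_table[["x_nm", "y_nm"]].to_numpy()
        cs = extract_clusters(two_disk_table, ClusterParams(40, 10))
        for comp in _epsilon_components(coords, eps=50.0):
            if len(comp) >= 40:
                labels = {cs.labels[i] for i in comp} - {-1}
                assert len(labels) == 1

    def test_too_few_points_all_noise(self, rng):
        t = make_table(rng.uniform(0, 100, 30), rng.uniform(0, 100, 30))
        cs = extract_clusters(t, ClusterParams(40, 10))
        assert cs.n_clusters == 0 and (cs.labels == -1).all()

    def test_sparse_background_rarely_clusters(self):
        # 1 µm^-2 uniform noise over 100 µm²: ~100 points, far too sparse
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = make_table(rng.uniform(0, 10_000, 100), rng.uniform(0, 10_000, 100))
            if extract_clusters(t, ClusterParams(40, 10)).n_clusters > 0:
                hits += 1
        assert hits <= 5

    def test_labels_partition_points(self, two_disk_table):
        cs = extract_clusters(two_disk_table)
        assert len(cs.labels) == len(two_disk_table)
        for cid in range(cs.n_clusters):
            assert len(cs.members(cid)) >= cs.params.min_cluster_size

    def test_ids_ordered_by_descending_size(self):
        rng = np.random.default_rng(0)
        small = np.c_[rng.normal(0, 40, 60), rng.normal(0, 40, 60)]
        big = np.c_[rng.normal(5000, 40, 150), rng.normal(0, 40, 150)]
        t = make_table(*np.vstack([small, big]).T)
        cs = extract_clusters(t, ClusterParams(40, 10))
        assert cs.n_clusters == 2
        assert len(cs.members(0)) > len(cs.members(1))

    def test_deterministic_for_fixed_input(self, two_disk_table):
        a = extract_clusters(two_disk_table).labels
        b = extract_clusters(two_disk_table).labels
        assert (a == b).all()

    def test_parameter_validation(self):
        with pytest.raises(ParameterError):
            ClusterParams(1, 10)
        with pytest.raises(ParameterError):
            ClusterParams(40, 0)


class TestFieldClustererEstimator:
    def test_sklearn_surface(self, two_disk_table):
        est = FieldClusterer(min_cluster_size=40, min_samples=10)
        assert est.get_params() == {"min_cluster_size": 40, "min_samples": 10}
        est.set_params(min_samples=5)
        labels = est.fit_predict(two_disk_table[["x_nm", "y_nm"]].to_numpy())
        assert est.n_clusters_ == 2 and len(labels) == 200


class TestSweep:
    def test_grid_enumerates_140_combinations(self):
        assert len(DEFAULT_MCS_VALUES) == 10
        assert len(DEFAULT_MS_VALUES) == 14
        assert DEFAULT_MS_VALUES == (2, 5, 10, 15, 20, 25, 30, 40, 50, 60, 70, 80, 90, 100)
        grid = run_sweep([make_table(np.arange(5.0), np.arange(5.0))])
        assert grid.median_counts.size == 140

    def test_constructed_two_cluster_image(self, two_disk_table):
        grid = run_sweep([two_disk_table])
        assert set(np.unique(grid.median_counts)) <= {0.0, 1.0, 2.0}
        i = DEFAULT_MCS_VALUES.index(40)
        j = DEFAULT_MS_VALUES.index(10)
        assert grid.median_counts[i, j] == 2.0

    def test_duplicated_images_leave_median_unchanged(self, two_disk_table):
        g1 = run_sweep([two_disk_table], mcs_values=[40, 50], ms_values=[5, 10])
        g5 = run_sweep([two_disk_table] * 5, mcs_values=[40, 50], ms_values=[5, 10])
        assert np.array_equal(g1.median_counts, g5.median_counts)

    def test_monotone_in_min_cluster_size(self, two_disk_table):
        grid = run_sweep([two_disk_table], ms_values=[10])
        counts = grid.median_counts[:, 0]
        assert (np.diff(counts) <= 0).all()


class TestStableParams:
    def test_constant_grid_returns_default(self):
        grid = SweepGrid(DEFAULT_MCS_VALUES, DEFAULT_MS_VALUES, np.full((10, 14), 7.0))
        assert select_stable_params(grid) == ClusterParams(40, 10)

    def test_single_constant_block_in_chaos(self):
        rng = np.random.default_rng(0)
        m = rng.uniform(10, 1000, (10, 14))
        m[4:7, 6:9] = 5.0  # 3x3 constant block
        grid = SweepGrid(DEFAULT_MCS_VALUES, DEFAULT_MS_VALUES, m)
        p = select_stable_params(grid)
        i = DEFAULT_MCS_VALUES.index(p.min_cluster_size)
        j = DEFAULT_MS_VALUES.index(p.min_samples)
        assert 4 <= i < 7 and 6 <= j < 9

    def test_no_plateau_falls_back_with_warning(self):
        # strictly geometric growth: no two neighbours within rel_tol=0
        m = np.arange(1.0, 141.0).reshape(10, 14) ** 2
        grid = SweepGrid(DEFAULT_MCS_VALUES, DEFAULT_MS_VALUES, m)
        with pytest.warns(UserWarning, match="widening"):
            select_stable_params(grid, rel_tol=0.0)

    def test_recovery_on_synthetic_scene(self):
        # K well-separated clusters: (40,10) reports exactly K
        table, _ = simulate_scene(disk_scene(6, seed=21, background_density=1.0))
        cs = extract_clusters(table, ClusterParams(40, 10))
        assert cs.n_clusters == 6
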