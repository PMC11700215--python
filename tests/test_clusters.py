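"""Distance map, boundary-rule cluster extraction, composition accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ramansom import synthesis as syn
from ramansom.clusters import (ClusterDefinition, DistanceMap,
                               cluster_purity, cluster_score_distributions,
                               cluster_spectral_summary, composition_table,
                               distance_map, extract_clusters,
                               select_threshold)
from ramansom.som import SOMConfig, SOMGrid, init_grid
from ramansom.spectra import SpectrumSet


def _dmap(scores):
    scores = np.asarray(scores, float)
    return DistanceMap(scores=scores, x_dim=scores.shape[1],
                       y_dim=scores.shape[0])


def _cluster(cid, obs):
    return ClusterDefinition(cluster_id=cid, member_nodes=[(1, 1)],
                             member_observations=list(obs))


class TestDistanceMap:
    def test_identical_weights_give_zero_scores(self):
        grid = SOMGrid(np.ones((12, 5)), 4, 3)
        assert np.all(distance_map(grid).scores == 0.0)

    def test_outlier_node_scores_one(self):
        w = np.zeros((6, 3))
        w[4] = 10.0  # node (1, 1) on a 3x2 lattice
        dmap = distance_map(SOMGrid(w, 3, 2))
        assert dmap.score(1, 1) == 1.0
        assert dmap.scores.max() == 1.0

    def test_matches_brute_force_neighbour_mean(self):
        grid = init_grid(SOMConfig(x_dim=5, y_dim=4, seed=2), 7)
        dmap = distance_map(grid)
        raw = np.zeros((4, 5))
        for y in range(4):
            for x in range(5):
                ds = []
                for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    if 0 <= x + dx < 5 and 0 <= y + dy < 4:
                        ds.append(np.linalg.norm(
                            grid.node_weights(x, y)
                            - grid.node_weights(x + dx, y + dy)))
                raw[y, x] = np.mean(ds)
        np.testing.assert_allclose(dmap.scores, raw / raw.max())


class TestExtractClusters:
    def test_uniform_populated_interior_is_one_cluster(self):
        scores = np.full((5, 6), 0.1)
        hits = {(x, y): [y * 6 + x] for x in range(6) for y in range(5)}
        cls, audit = extract_clusters(_dmap(scores), hits, 0.72)
        assert len(cls) == 1
        assert len(cls[0].member_nodes) == 4 * 3  # the full interior

    def test_high_distance_column_separates_two_clusters(self):
        scores = np.full((5, 7), 0.1)
        scores[:, 3] = 1.0
        hits = {(x, y): [y * 7 + x] for x in range(7) for y in range(5)}
        cls, _ = extract_clusters(_dmap(scores), hits, 0.72)
        assert len(cls) == 2

    def test_corner_observations_always_excluded(self):
        scores = np.full((4, 5), 0.1)
        hits = {(0, 0): [0, 1, 2], (2, 2): [3]}
        cls, audit = extract_clusters(_dmap(scores), hits, 0.72)
        corner = audit[(audit.col == 0) & (audit.row == 0)].iloc[0]
        assert corner.status == "excluded_corner"
        assert all(0 not in c.member_observations for c in cls)

    def test_populated_edge_attaches_to_adjacent_cluster(self):
        scores = np.full((4, 5), 0.1)
        hits = {(1, 1): [0], (1, 0): [1, 2]}  # edge node below an interior one
        cls, audit = extract_clusters(_dmap(scores), hits, 0.72)
        assert len(cls) == 1
        assert (1, 0) in cls[0].edge_nodes
        assert sorted(cls[0].member_observations) == [0, 1, 2]

    def test_boundary_island_anchors_edge_observations(self):
        # observations pushed onto edge/corner nodes above an empty,
        # isolated low-distance interior pocket still define a cluster
        scores = np.full((5, 7), 0.9)
        scores[1, 5] = 0.1          # empty interior pocket at (5, 1)
        scores[0, 5] = 0.1          # populated edge below it
        hits = {(5, 0): [0, 1, 2, 3]}
        cls, _ = extract_clusters(_dmap(scores), hits, 0.5)
        assert len(cls) == 1
        assert cls[0].member_observations == [0, 1, 2, 3]

    def test_empty_chains_do_not_bridge_populated_regions(self):
        # two populated pockets joined only by a 2-node empty corridor
        scores = np.full((5, 8), 0.2)
        hits = {(1, 2): [0, 1], (2, 2): [2], (5, 2): [3, 4], (6, 2): [5]}
        cls, _ = extract_clusters(_dmap(scores), hits, 0.72)
        assert len(cls) == 2

    def test_threshold_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            extract_clusters(_dmap(np.zeros((4, 5))), {}, 1.5)

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_audit_partitions_lattice_and_members_monotone(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random((5, 7))
        scores /= scores.max()
        hits = {}
        for i in range(30):
            hits.setdefault((int(rng.integers(7)), int(rng.integers(5))),
                            []).append(i)
        lo_cls, lo_audit = extract_clusters(_dmap(scores), hits, 0.4)
        hi_cls, hi_audit = extract_clusters(_dmap(scores), hits, 0.8)
        for audit in (lo_audit, hi_audit):
            assert len(audit) == 35  # every node exactly once
        # clusters are observation-disjoint
        for cls in (lo_cls, hi_cls):
            seen = [i for c in cls for i in c.member_observations]
            assert len(seen) == len(set(seen))
        # populated member interior nodes survive a threshold raise
        def members(cls):
            return {n for c in cls for n in c.member_nodes
                    if hits.get(n)}
        assert members(lo_cls) <= members(hi_cls)


class TestSelectThreshold:
    def test_reads_the_cleft_of_a_two_region_map(self):
        scores = np.full((5, 7), 0.15)
        scores[:, 3] = 0.9
        hits = {(x, y): list(range(10)) for x in range(7) for y in range(5)
                if x != 3}
        thr = select_threshold(_dmap(scores), hits, min_size=5)
        cls, _ = extract_clusters(_dmap(scores), hits, thr)
        assert len(cls) == 2
        assert thr < 0.9


class TestCompositionTable:
    def test_printed_table_arithmetic(self):
        labels = np.array(["normal"] * 154 + ["cancer"] * 130)
        cls = [
            _cluster("A", range(0, 121)),
            _cluster("B", range(154, 172)),
            _cluster("C", range(172, 245)),
        ]
        table = composition_table(cls, labels).set_index("cluster")
        assert table.loc["A", "subset_pct_normal"] == 79
        assert table.loc["B", "subset_pct_cancer"] == 14
        assert table.loc["C", "subset_pct_cancer"] == 56
        assert table.loc["A", "total_pct"] == 43
        combined = 100.0 * (table.loc["B", "count_cancer"]
                            + table.loc["C", "count_cancer"]) / 130
        assert combined == 70.0

    def test_empty_cluster_list_gives_empty_table(self):
        table = composition_table([], np.array(["normal", "cancer"]))
        assert table.empty


class TestSpectralSummary:
    def _set(self, rows):
        rows = np.asarray(rows, float)
        return SpectrumSet(np.arange(rows.shape[1], dtype=float) + 2700.0,
                           rows)

    def test_identical_members_have_zero_se(self):
        sset = self._set(np.tile(np.linspace(0, 1, 8), (4, 1)))
        out = cluster_spectral_summary([_cluster("A", [0, 1, 2])], sset)
        np.testing.assert_allclose(out["A"]["se"].intensity, 0.0, atol=1e-12)

    def test_grand_average_is_weighted_cluster_mean_plus_remainder(self, rng):
        rows = rng.random((10, 6))
        sset = self._set(rows)
        cls = [_cluster("A", [0, 1, 2]), _cluster("B", [3, 4])]
        out = cluster_spectral_summary(cls, sset)
        weighted = (3 * out["A"]["mean"].intensity
                    + 2 * out["B"]["mean"].intensity
                    + rows[5:].sum(axis=0)) / 10
        np.testing.assert_allclose(out["all"]["mean"].intensity, weighted)

    def test_overlapping_clusters_rejected(self, rng):
        sset = self._set(rng.random((5, 4)))
        with pytest.raises(ValueError):
            cluster_spectral_summary([_cluster("A", [0, 1]),
                                      _cluster("B", [1, 2])], sset)

    def test_cluster_means_reflect_generating_band_pattern(self, small_preprocessed):
        pp, truth = small_preprocessed
        sub = truth.sub_profile.to_numpy()
        cls = [ClusterDefinition(cluster_id=name, member_nodes=[(1, 1)],
                                 member_observations=list(np.flatnonzero(sub == name)))
               for name in ("normal_A", "cancer_C")]
        out = cluster_spectral_summary(cls, pp)
        j2852 = np.argmin(np.abs(pp.axis - 2852.0))
        j2933 = np.argmin(np.abs(pp.axis - 2933.0))
        delta = out["cancer_C"]["mean"].intensity - out["normal_A"]["mean"].intensity
        assert delta[j2852] > 0 and delta[j2933] < 0


class TestScoreDistributions:
    def test_identical_clusters_have_identical_distributions(self, rng):
        proj = rng.random(10)
        cls = [_cluster("A", [0, 1, 2]), _cluster("B", [0, 1, 2])]
        out = cluster_score_distributions(cls, proj)
        np.testing.assert_array_equal(out["samples"]["A"], out["samples"]["B"])
        assert out["effect_sizes"]["A|B"] == 0.0

    def test_effect_size_matches_brute_force_pooled_sd(self, rng):
        proj = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 2, 30)])
        cls = [_cluster("A", range(20)), _cluster("B", range(20, 50))]
        out = cluster_score_distributions(cls, proj)
        a, b = proj[:20], proj[20:]
        pooled = np.sqrt(((19 * a.var(ddof=1) + 29 * b.var(ddof=1)) / 48))
        expected = abs(a.mean() - b.mean()) / pooled
        assert out["effect_sizes"]["A|B"] == pytest.approx(expected)

    def test_separated_profiles_have_disjoint_pc_supports(self, small_preprocessed):
        from ramansom.chemometrics import fit_pca

        pp, truth = small_preprocessed
        sub = truth.sub_profile.to_numpy()
        keep = np.isin(sub, ["normal_A", "cancer_C"])
        model = fit_pca(pp.intensities[keep])
        proj = model.scores[:, 0]
        ids = np.flatnonzero(keep)
        relabel = {obs: i for i, obs in enumerate(ids)}
        cls = [ClusterDefinition(cluster_id=n, member_nodes=[(1, 1)],
                                 member_observations=[relabel[o] for o in ids
                                                      if sub[o] == n])
               for n in ("normal_A", "cancer_C")]
        out = cluster_score_distributions(cls, proj)
        a, b = out["samples"]["normal_A"], out["samples"]["cancer_C"]
        assert a.max() < b.min() or b.max() < a.min()


class TestPurity:
    def test_majority_and_purity_accounting(self):
        truth = np.array(["x"] * 5 + ["y"] * 5)
        cls = [_cluster("A", [0, 1, 2, 3, 5])]
        out = cluster_purity(cls, truth)
        assert out.loc[0, "majority_label"] == "x"
        assert out.loc[0, "purity"] == pytest.approx(0.8)
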