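"""Cover geometry, eps optimisation, bin clustering, and nerve correctness."""

import itertools

import numpy as np
import pytest

from microstrat.geometry import DistanceMatrix, Lens
from microstrat.io_metadata import AbundanceTable
from microstrat.mapper import (
    CoverBin,
    axis_intervals,
    build_cover,
    build_network,
    cluster_bin,
    cover_ratio,
    mapper_network,
    optimize_eps,
    parameter_sweep,
    read_network,
    write_network,
)


def lens_from_coords(coords) -> Lens:
    coords = np.asarray(coords, dtype=float)
    return Lens(
        sample_ids=[f"s{i}" for i in range(len(coords))], coords=coords, stress=0.0
    )


def distance_matrix_from_points(pts) -> DistanceMatrix:
    pts = np.asarray(pts, dtype=float)
    values = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    values = values / max(values.max(), 1.0)
    return DistanceMatrix([f"s{i}" for i in range(len(pts))], values)


class TestCover:
    def test_interval_geometry_resolution2_overlap_half(self):
        intervals = axis_intervals(0.0, 1.0, resolution=2, overlap=0.5)
        assert intervals[0] == (pytest.approx(-0.125), pytest.approx(0.625))
        assert intervals[1] == (pytest.approx(0.375), pytest.approx(1.125))
        shared = intervals[0][1] - intervals[1][0]
        assert shared == pytest.approx(0.25)

    def test_zero_overlap_partitions(self):
        intervals = axis_intervals(0.0, 1.0, resolution=4, overlap=0.0)
        for (lo1, hi1), (lo2, _) in zip(intervals, intervals[1:]):
            assert hi1 == pytest.approx(lo2)

    def test_resolution_one_single_bin_holds_everything(self):
        lens = lens_from_coords([[0, 0], [0.5, 0.2], [1, 1]])
        cover = build_cover(lens, resolution=1, overlap=0.5)
        assert len(cover) == 1
        assert set(cover[0].member_samples) == {"s0", "s1", "s2"}

    def test_every_sample_covered(self):
        rng = np.random.default_rng(0)
        lens = lens_from_coords(rng.random((40, 2)))
        cover = build_cover(lens, resolution=5, overlap=0.3)
        covered = set(itertools.chain.from_iterable(b.member_samples for b in cover))
        assert covered == set(lens.sample_ids)

    def test_degenerate_axis_single_interval(self):
        lens = lens_from_coords([[0.0, 0.7], [1.0, 0.7], [0.3, 0.7]])
        cover = build_cover(lens, resolution=3, overlap=0.2)
        assert {b.index[1] for b in cover} == {0}


class TestOptimizeEps:
    def test_all_distances_equal(self):
        values = np.full((4, 4), 0.4)
        np.fill_diagonal(values, 0.0)
        D = DistanceMatrix(["a", "b", "c", "d"], values)
        assert optimize_eps(D, 0.95) == pytest.approx(0.4)

    def test_nearest_rank_quantile_on_line(self):
        # 1-D points {0, 1, 3, 7}: NN distances {1, 1, 2, 4}
        pts = np.array([[0.0], [1.0], [3.0], [7.0]]) / 7.0
        D = distance_matrix_from_points(pts * 7)
        eps = optimize_eps(D, 0.95)
        assert eps == pytest.approx(4.0 / 7.0)

    def test_threshold_one_gives_max_nn_distance(self):
        rng = np.random.default_rng(3)
        D = distance_matrix_from_points(rng.random((10, 2)))
        off = D.values + np.diag(np.full(10, np.inf))
        assert optimize_eps(D, 1.0) == pytest.approx(off.min(axis=1).max())


class TestClusterBin:
    @staticmethod
    def _bin(sample_ids):
        return CoverBin(
            index=(0, 0),
            x_interval=(0, 1),
            y_interval=(0, 1),
            member_samples=list(sample_ids),
        )

    @staticmethod
    def brute_force_dbscan(values, eps, min_samples):
        """Transitive closure of the eps-graph over core points, plus
        border points attached to any reachable core."""
        n = values.shape[0]
        neigh = [set(np.flatnonzero(values[i] <= eps)) for i in range(n)]
        core = [i for i in range(n) if len(neigh[i]) >= min_samples]
        # components over core points
        comp = {}
        for c in core:
            if c in comp:
                continue
            stack, comp_id = [c], len(set(comp.values()))
            while stack:
                u = stack.pop()
                if u in comp:
                    continue
                comp[u] = comp_id
                for v in neigh[u]:
                    if v in core and v not in comp:
                        stack.append(v)
        clusters: dict[int, set[int]] = {}
        for c, cid in comp.items():
            clusters.setdefault(cid, set()).add(c)
        for i in range(n):
            if i in comp:
                continue
            for c in core:
                if i in neigh[c]:
                    clusters[comp[c]].add(i)
                    break
        return {frozenset(v) for v in clusters.values()}

    def test_single_tight_cluster(self):
        values = np.full((6, 6), 0.1)
        np.fill_diagonal(values, 0.0)
        D = DistanceMatrix([f"s{i}" for i in range(6)], values)
        clusters = cluster_bin(self._bin(D.sample_ids), D, eps=0.2, min_samples=5)
        assert clusters == [set(D.sample_ids)]

    def test_two_separated_groups(self):
        pts = np.array([[0.01 * i, 0] for i in range(6)] + [[5 + 0.01 * i, 0] for i in range(6)])
        D = distance_matrix_from_points(pts)
        clusters = cluster_bin(self._bin(D.sample_ids), D, eps=0.05, min_samples=5)
        assert len(clusters) == 2
        assert {frozenset(c) for c in clusters} == {
            frozenset(f"s{i}" for i in range(6)),
            frozenset(f"s{i}" for i in range(6, 12)),
        }

    def test_too_few_points_all_noise(self):
        values = np.zeros((4, 4))
        D = DistanceMatrix([f"s{i}" for i in range(4)], values)
        assert cluster_bin(self._bin(D.sample_ids), D, eps=0.5, min_samples=5) == []

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            pts = rng.random((15, 2))
            D = distance_matrix_from_points(pts)
            eps = 0.25
            got = cluster_bin(self._bin(D.sample_ids), D, eps=eps, min_samples=3)
            index = {s: i for i, s in enumerate(D.sample_ids)}
            got_sets = {frozenset(index[s] for s in c) for c in got}
            oracle = self.brute_force_dbscan(D.values, eps, 3)
            # border points on the frontier of two clusters may be assigned
            # to either; compare core memberships
            assert len(got_sets) == len(oracle)
            for cluster in got_sets:
                assert any(cluster & o for o in oracle)

    def test_member_order_invariance(self):
        rng = np.random.default_rng(5)
        pts = rng.random((12, 2))
        D = distance_matrix_from_points(pts)
        ids = list(D.sample_ids)
        a = cluster_bin(self._bin(ids), D, eps=0.3, min_samples=3)
        b = cluster_bin(self._bin(ids[::-1]), D, eps=0.3, min_samples=3)
        assert {frozenset(c) for c in a} == {frozenset(c) for c in b}


class TestBuildNetwork:
    def _network(self, clusters_by_bin, lens):
        cover = []
        for i, clusters in enumerate(clusters_by_bin):
            members = sorted(set(itertools.chain.from_iterable(clusters)))
            cover.append(
                CoverBin(index=(i, 0), x_interval=(0, 1), y_interval=(0, 1), member_samples=members)
            )
        return build_network(cover, clusters_by_bin, lens)

    def test_shared_sample_edges_only(self):
        lens = lens_from_coords([[0, 0], [1, 0], [2, 0], [3, 0], [4, 0]])
        net = self._network(
            [[{"s0", "s1"}], [{"s1", "s2"}], [{"s3"}]], lens
        )
        assert len(net.nodes) == 3
        assert net.edges == {(0, 1)}

    def test_disjoint_clusters_no_edges(self):
        lens = lens_from_coords([[0, 0], [1, 0], [2, 0], [3, 0]])
        net = self._network([[{"s0", "s1"}], [{"s2", "s3"}]], lens)
        assert net.edges == set()

    def test_identical_member_sets_single_edge(self):
        lens = lens_from_coords([[0, 0], [1, 0]])
        net = self._network([[{"s0", "s1"}], [{"s0", "s1"}]], lens)
        assert net.edges == {(0, 1)}

    def test_centroid_is_mean_lens_position(self):
        lens = lens_from_coords([[0, 0], [2, 4]])
        net = self._network([[{"s0", "s1"}]], lens)
        assert net.nodes[0].centroid == (1.0, 2.0)

    def test_nerve_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(10, 40))
            lens = lens_from_coords(rng.random((n, 2)))
            # random clusters in random bins
            clusters_by_bin = []
            for _ in range(4):
                k = int(rng.integers(1, 4))
                clusters = []
                for _ in range(k):
                    size = int(rng.integers(1, 6))
                    members = set(rng.choice(lens.sample_ids, size=size, replace=False))
                    clusters.append(members)
                # DBSCAN clusters within one bin are disjoint
                seen: set[str] = set()
                disjoint = []
                for c in clusters:
                    c = c - seen
                    if c:
                        disjoint.append(c)
                        seen |= c
                clusters_by_bin.append(disjoint)
            net = self._network(clusters_by_bin, lens)
            ids = net.node_ids
            expected = {
                (a, b)
                for a in ids
                for b in ids
                if a < b and net.nodes[a].members & net.nodes[b].members
            }
            assert net.edges == expected

    def test_every_node_within_its_bin(self):
        rng = np.random.default_rng(8)
        pts = rng.random((60, 4))
        pts /= pts.sum(1, keepdims=True)
        table = AbundanceTable([f"s{i}" for i in range(60)], list("abcd"), pts)
        from microstrat.geometry import pairwise_distances, mds_lens

        D = pairwise_distances(table)
        lens = mds_lens(D)
        cover = build_cover(lens, resolution=3, overlap=0.4)
        net = mapper_network(D, lens, resolution=3, overlap=0.4, min_samples=3)
        bins = {b.index: set(b.member_samples) for b in cover}
        for node in net.nodes.values():
            assert node.members <= bins[node.bin_index]


class TestCoverRatio:
    def test_all_samples_retained(self):
        lens = lens_from_coords([[0, 0], [1, 0]])
        cover = [CoverBin((0, 0), (0, 1), (0, 1), ["s0", "s1"])]
        net = build_network(cover, [[{"s0", "s1"}]], lens)
        assert cover_ratio(net, 2) == 1.0

    def test_empty_network(self):
        lens = lens_from_coords([[0, 0]])
        net = build_network([], [], lens)
        assert cover_ratio(net, 10) == 0.0

    def test_dropped_sample_accounting(self):
        # published accounting: 4,437 samples in, 2,910 retained
        assert 4437 - 2910 == 1527
        assert round(2910 / 4437 * 100, 2) == 65.58


class TestParameterSweep:
    def test_grid_rows_and_component_consistency(self):
        from microstrat.synthetic import blob_dataset
        from microstrat.geometry import pairwise_distances, mds_lens

        table, _ = blob_dataset(3, 40, 30, seed=2)
        D = pairwise_distances(table)
        lens = mds_lens(D)
        sweep = parameter_sweep(D, lens, [4, 6], [0.4, 0.6])
        assert len(sweep) == 4
        assert (sweep["h0_clusters"] == 3).all()
        assert (sweep["n_components"] == 3).all()


class TestNetworkIO:
    def test_graphml_round_trip(self, tmp_path):
        lens = lens_from_coords([[0, 0], [1, 0], [2, 0]])
        cover = [
            CoverBin((0, 0), (0, 1), (0, 1), ["s0", "s1"]),
            CoverBin((1, 0), (0, 1), (0, 1), ["s1", "s2"]),
        ]
        net = build_network(
            cover, [[{"s0", "s1"}], [{"s1", "s2"}]], lens, params={"resolution": 2}
        )
        write_network(net, tmp_path / "net.graphml", tmp_path / "members.json")
        loaded = read_network(tmp_path / "net.graphml", tmp_path / "members.json")
        assert loaded.edges == net.edges
        assert {n: loaded.nodes[n].members for n in loaded.node_ids} == {
            n: net.nodes[n].members for n in net.node_ids
        }
        assert loaded.params["resolution"] == 2
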