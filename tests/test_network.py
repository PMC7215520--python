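"""Contact graphs, per-residue L and BC, averaging and the outlier screen."""

import numpy as np
import pytest

from resdyn import (
    ContactNetwork,
    GeneratorConfig,
    ResidueProfile,
    TrajectoryError,
    average_profiles,
    betweenness_profile,
    contact_network,
    generate,
    global_average_path_length,
    network_timeseries,
    select_outliers,
    shortest_path_profile,
    stride_for_interval,
)
from resdyn.network import NetworkTimeSeries
from resdyn.trajectory import ResidueLabel

from .oracles import betweenness_by_enumeration, per_node_average_path, random_graph


def _net(adj):
    return ContactNetwork(adjacency=np.asarray(adj, bool))


PATH_ABC = [[0, 1, 0], [1, 0, 1], [0, 1, 0]]


class TestContactNetwork:
    @pytest.mark.parametrize(
        "distance,edge", [(6.0, True), (7.0, False), (6.70, True)]
    )
    def test_cutoff_boundary_inclusive(self, distance, edge):
        coords = np.array([[0.0, 0.0, 0.0], [distance, 0.0, 0.0]])
        net = contact_network(coords)
        assert bool(net.adjacency[0, 1]) is edge

    def test_exclusive_flag(self):
        coords = np.array([[0.0, 0.0, 0.0], [6.7, 0.0, 0.0]])
        assert not contact_network(coords, inclusive=False).adjacency[0, 1]

    def test_nonfinite_coordinates_rejected(self):
        coords = np.array([[0.0, 0.0, 0.0], [np.nan, 0.0, 0.0]])
        with pytest.raises(TrajectoryError):
            contact_network(coords)

    def test_no_self_edges(self, jitter_trajectory):
        from resdyn import coordinates_for

        net = contact_network(coordinates_for(jitter_trajectory, "CB_GLY_CA")[0])
        assert not np.any(np.diag(net.adjacency))


class TestShortestPath:
    def test_path_graph_hand_enumeration(self):
        L = shortest_path_profile(_net(PATH_ABC))
        np.testing.assert_allclose(L, [1.5, 1.0, 1.5])

    def test_complete_graph_all_one(self):
        adj = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(shortest_path_profile(_net(adj)), 1.0)

    def test_isolated_node_missing_with_warning(self):
        adj = np.zeros((3, 3), bool)
        adj[0, 1] = adj[1, 0] = True
        with pytest.warns(RuntimeWarning, match="no reachable"):
            L = shortest_path_profile(_net(adj))
        assert np.isnan(L[2]) and L[0] == 1.0

    def test_matches_floyd_warshall_on_random_graphs(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            adj = random_graph(n, float(rng.uniform(0.2, 0.7)), rng)
            got = shortest_path_profile(_net(adj)) if adj.any() else None
            expected = per_node_average_path(adj)
            if got is None:
                continue
            np.testing.assert_allclose(got, expected, atol=1e-12, equal_nan=True)

    def test_global_average_matches_definition(self):
        adj = np.asarray(PATH_ABC, bool)
        # ordered pairs: d sums to 2*(1+1+2) = 8; n(n-1) = 6
        assert global_average_path_length(_net(adj)) == pytest.approx(8 / 6)

    def test_edge_addition_never_increases_distances(self):
        from .oracles import floyd_warshall

        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 11))
            adj = random_graph(n, 0.5, rng)
            empty = np.argwhere(~adj & ~np.eye(n, dtype=bool))
            if empty.size == 0:
                continue
            i, j = empty[rng.integers(len(empty))]
            denser = adj.copy()
            denser[i, j] = denser[j, i] = True
            # pairwise distances can only shrink
            assert np.all(floyd_warshall(denser) <= floyd_warshall(adj))
            # on an already-connected graph the per-node average L follows suit
            # (with new nodes entering the reachable set the average may rise)
            if np.all(np.isfinite(floyd_warshall(adj) )):
                before = shortest_path_profile(_net(adj))
                after = shortest_path_profile(_net(denser))
                assert np.all(after <= before + 1e-12)


class TestBetweenness:
    def test_path_graph(self):
        bc = betweenness_profile(_net(PATH_ABC))
        np.testing.assert_allclose(bc, [0.0, 1.0, 0.0])

    def test_star_centre_closed_form(self):
        n = 6
        adj = np.zeros((n, n), bool)
        adj[0, 1:] = adj[1:, 0] = True
        bc = betweenness_profile(_net(adj))
        assert bc[0] == pytest.approx((n - 1) * (n - 2) / 2)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_matches_path_enumeration_on_random_graphs(self):
        rng = np.random.default_rng(1234)
        for _ in range(30):
            n = int(rng.integers(4, 11))
            adj = random_graph(n, float(rng.uniform(0.25, 0.7)), rng)
            got = betweenness_profile(_net(adj))
            expected = betweenness_by_enumeration(adj)
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_bounded_by_interior_pair_count(self):
        rng = np.random.default_rng(5)
        adj = random_graph(12, 0.4, rng)
        bc = betweenness_profile(_net(adj))
        n = 12
        assert np.all(bc <= (n - 1) * (n - 2) / 2 + 1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(77)
        adj = random_graph(9, 0.4, rng)
        perm = rng.permutation(9)
        shuffled = adj[np.ix_(perm, perm)]
        bc = betweenness_profile(_net(adj))
        bc_shuffled = betweenness_profile(_net(shuffled))
        np.testing.assert_allclose(bc_shuffled, bc[perm], atol=1e-12)
        L = shortest_path_profile(_net(adj))
        L_shuffled = shortest_path_profile(_net(shuffled))
        np.testing.assert_allclose(L_shuffled, L[perm], atol=1e-12, equal_nan=True)


class TestTimeSeries:
    def test_static_trajectory_identical_profiles(self):
        cfg = GeneratorConfig(n_residues=20, n_frames=5, seed=3, fluctuation_sigma=0.0)
        ts = network_timeseries(generate(cfg))
        assert np.allclose(ts.L, ts.L[0])
        assert np.allclose(ts.BC_raw, ts.BC_raw[0])

    def test_stride_equal_to_length_keeps_one_frame(self, jitter_trajectory):
        ts = network_timeseries(jitter_trajectory, stride=jitter_trajectory.n_frames)
        assert ts.frames_used.tolist() == [0]

    def test_interval_derives_stride(self):
        assert stride_for_interval(100.0, 10.0) == 10
        assert stride_for_interval(100.0, 100.0) == 1
        assert stride_for_interval(100.0, 400.0) == 1  # never below 1

    def test_contact_loss_shows_in_per_frame_L(self):
        # residue pushed out of contact range in half the frames
        coords = np.zeros((4, 3, 3))
        coords[:, 1, 0] = 5.0
        coords[:, 2, 0] = 10.0
        coords[2:, 2, 0] = 30.0  # breaks the 1-2 contact in frames 2,3
        sites = [("CA", "GLY", 23 + i, "A") for i in range(3)]
        from resdyn.trajectory import Trajectory

        traj = Trajectory(sites, coords)
        ts = network_timeseries(traj, cutoff=6.7, stride=1)
        assert ts.L[0, 2] == pytest.approx(1.5)
        assert np.isnan(ts.L[2, 2])


def _ts(L, BC):
    L = np.asarray(L, float)
    labels = [ResidueLabel("ALA", 23 + i) for i in range(L.shape[1])]
    return NetworkTimeSeries(
        labels=labels, L=L, BC_raw=np.asarray(BC, float),
        frames_used=np.arange(L.shape[0]),
    )


class TestAveraging:
    def test_single_frame_minmax(self):
        avg = average_profiles(_ts([[1.0, 2.0, 3.0]], [[0.0, 1.0, 2.0]]))
        np.testing.assert_allclose(avg.avg_L_normalized, [0.0, 0.5, 1.0])

    def test_two_identical_frames_equal_single(self):
        one = average_profiles(_ts([[1.0, 2.0, 4.0]], [[0.0, 3.0, 1.0]]))
        two = average_profiles(
            _ts([[1.0, 2.0, 4.0]] * 2, [[0.0, 3.0, 1.0]] * 2)
        )
        np.testing.assert_allclose(two.avg_L_normalized, one.avg_L_normalized)
        np.testing.assert_allclose(two.avg_BC_normalized, one.avg_BC_normalized)

    def test_known_profiles_hand_average(self):
        L = [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]
        BC = [[0.0, 2.0, 4.0], [4.0, 0.0, 2.0]]
        avg = average_profiles(_ts(L, BC))
        np.testing.assert_allclose(avg.avg_L_normalized, [0.5, 0.5, 0.5])
        np.testing.assert_allclose(avg.avg_BC_normalized, [0.5, 0.25, 0.75])
        np.testing.assert_allclose(avg.avg_BC_raw, [2.0, 1.0, 3.0])

    def test_constant_frame_normalises_to_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant profile"):
            avg = average_profiles(_ts([[2.0, 2.0, 2.0]], [[1.0, 1.0, 1.0]]))
        np.testing.assert_allclose(avg.avg_L_normalized, 0.0)

    def test_missing_values_counted(self):
        avg = average_profiles(_ts([[1.0, np.nan], [1.0, 2.0]], [[0.0, 0.0]] * 2))
        assert avg.missing_counts.tolist() == [0, 1]


def _delta(values, metric="deltaL"):
    labels = [ResidueLabel("ALA", 23 + i) for i in range(len(values))]
    return ResidueProfile(labels=labels, values=np.asarray(values, float), metric=metric)


class TestOutliers:
    def test_all_equal_yields_empty_report_with_note(self):
        rep = select_outliers(_delta([0.3] * 10))
        assert rep.increase_residues == [] and rep.decrease_residues == []
        assert "SD = 0" in rep.note

    def test_single_spike_flagged_as_increase(self):
        values = [0.0] * 50 + [10.0]
        rep = select_outliers(_delta(values))
        assert [r.residue_number for r in rep.increase_residues] == [73]
        assert rep.decrease_residues == []
        # against direct mean/SD computation
        arr = np.array(values)
        assert rep.mean == pytest.approx(arr.mean())
        assert rep.sd == pytest.approx(arr.std())

    def test_negation_swaps_lists(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=80)
        values[3], values[40] = 9.0, -9.0
        rep = select_outliers(_delta(values))
        neg = select_outliers(_delta(-values))
        assert rep.increase_residues == neg.decrease_residues
        assert rep.decrease_residues == neg.increase_residues

    def test_flagged_residues_beyond_k_sd(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=200)
        rep = select_outliers(_delta(values), k=1.5)
        for lab, v in zip(_delta(values).labels, values):
            flagged = lab in rep.increase_residues or lab in rep.decrease_residues
            assert flagged == (abs(v - rep.mean) > 1.5 * rep.sd)

    def test_semantics_by_metric(self):
        repL = select_outliers(_delta([0.0] * 30 + [5.0], metric="deltaL"))
        assert repL.semantics[0] == "residue accessibility increase"
        repBC = select_outliers(_delta([0.0] * 30 + [5.0], metric="deltaBC"))
        assert repBC.semantics[0] == "residue communication reduction"
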