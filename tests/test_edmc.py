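"""Hourly state sequences, transition counts, centrality and exports."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg as sla
from hypothesis import given, settings
from hypothesis import strategies as st

from atollnet import (
    ABSENT,
    count_transitions,
    discretize_hourly_states,
    eigenvector_centrality_power,
    export_network,
    group_chain,
    merge_receiver_nodes,
    node_degree,
    normalize_transitions,
)
from atollnet.edmc import read_edge_list
from atollnet.io import NodeMap
from atollnet.simulate import SimulationConfig, simulate_cohort

from conftest import make_detection_set


def _merged(rows):
    ds = make_detection_set(rows)
    return merge_receiver_nodes(ds, NodeMap.identity(ds.stations["receiver_id"]))


def stationary_by_eig(P: np.ndarray) -> np.ndarray:
    w, vl = sla.eig(P, left=True, right=False)
    k = int(np.argmax(w.real))
    pi = np.abs(vl[:, k].real)
    return pi / pi.sum()


class TestDiscretize:
    def test_gap_hour_labelled_absent(self):
        ds = _merged(
            [
                ("2008-01-01T09:10:00Z", "A", "X"),
                ("2008-01-01T09:50:00Z", "A", "X"),
                ("2008-01-01T11:05:00Z", "B", "X"),
            ]
        )
        seq = discretize_hourly_states(ds, "X")
        assert seq.tolist() == ["A", ABSENT, "B"]

    def test_single_hour_sequence(self):
        ds = _merged(
            [("2008-01-01T09:10:00Z", "A", "X"), ("2008-01-01T09:50:00Z", "A", "X")]
        )
        assert discretize_hourly_states(ds, "X").tolist() == ["A"]

    def test_majority_with_latest_tiebreak(self):
        ds = _merged(
            [
                ("2008-01-01T09:01:00Z", "A", "X"),
                ("2008-01-01T09:02:00Z", "B", "X"),
                ("2008-01-01T09:03:00Z", "A", "X"),
                ("2008-01-01T09:04:00Z", "B", "X"),
            ]
        )
        assert discretize_hourly_states(ds, "X").tolist() == ["B"]

    def test_absent_shark_gives_empty_sequence(self):
        ds = _merged([("2008-01-01T09:10:00Z", "A", "X")])
        assert len(discretize_hourly_states(ds, "nobody")) == 0

    def test_lossless_simulation_recovers_true_states(self, cleaned_sim):
        ds, truth, _ = cleaned_sim
        labels = np.array(truth.state_labels, dtype=object)
        for sid in truth.sharks["shark_id"]:
            seq = discretize_hourly_states(ds, sid)
            start, arr = truth.states[sid]
            true_labels = pd.Series(
                labels[arr], index=pd.date_range(start, periods=len(arr), freq="h")
            )
            overlap = true_labels.reindex(seq.index)
            assert (seq == overlap).all()


class TestTransitionCounts:
    def test_hand_enumerated_counts(self):
        seq = ["A", "A", ABSENT, "B", "B", "B", ABSENT]
        m = count_transitions(seq)
        assert m.loc["A", "A"] == 1
        assert m.loc["A", ABSENT] == 1
        assert m.loc[ABSENT, "B"] == 1
        assert m.loc["B", "B"] == 2
        assert m.loc["B", ABSENT] == 1
        assert m.to_numpy().sum() == len(seq) - 1

    def test_constant_sequence_single_diagonal_entry(self):
        m = count_transitions(["A"] * 7)
        assert m.loc["A", "A"] == 6
        assert m.to_numpy().sum() == 6

    def test_counts_are_additive_over_sequences(self):
        rng = np.random.default_rng(0)
        states = ["A", "B", ABSENT]
        s1 = list(rng.choice(states, 40))
        s2 = list(rng.choice(states, 25))
        m = count_transitions(s1, states) + count_transitions(s2, states)
        assert m.to_numpy().sum() == (len(s1) - 1) + (len(s2) - 1)

    @settings(derandomize=True, max_examples=100)
    @given(
        seq=st.lists(st.sampled_from(["A", "B", "C", ABSENT]), min_size=2, max_size=60)
    )
    def test_counts_conserve_sequence_length(self, seq):
        m = count_transitions(seq, ["A", "B", "C", ABSENT])
        assert m.to_numpy().sum() == len(seq) - 1
        assert (m.to_numpy() >= 0).all()

    def test_short_sequence_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            m = count_transitions(["A"])
        assert m.to_numpy().sum() == 0


class TestNormalize:
    def test_rows_normalised(self):
        counts = pd.DataFrame(
            [[3, 1], [0, 0]], index=["A", "B"], columns=["A", "B"]
        )
        P, dropped = normalize_transitions(counts)
        assert P.loc["A"].tolist() == [0.75, 0.25]
        # B was entered but never left: kept as an absorbing artifact
        assert P.loc["B"].tolist() == [0.0, 1.0]
        assert dropped == []

    def test_truly_unvisited_state_is_dropped(self):
        counts = pd.DataFrame(
            [[3, 1, 0], [2, 1, 0], [0, 0, 0]],
            index=["A", "B", "C"], columns=["A", "B", "C"],
        )
        P, dropped = normalize_transitions(counts)
        assert dropped == ["C"]
        assert list(P.index) == ["A", "B"]

    def test_every_row_sums_to_one(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(0, 20, (5, 5)), index=list("ABCDE"), columns=list("ABCDE")
        )
        P, _ = normalize_transitions(counts)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_pooling_then_normalising_equals_normalising_sum(self):
        rng = np.random.default_rng(2)
        idx = list("ABC")
        c1 = pd.DataFrame(rng.integers(0, 10, (3, 3)), index=idx, columns=idx)
        c2 = pd.DataFrame(rng.integers(0, 10, (3, 3)), index=idx, columns=idx)
        P_sum, _ = normalize_transitions(c1 + c2)
        P_again, _ = normalize_transitions((c1 + c2).copy())
        pd.testing.assert_frame_equal(P_sum, P_again)

    def test_all_zero_matrix_raises(self):
        counts = pd.DataFrame(0, index=["A"], columns=["A"])
        with pytest.raises(ValueError):
            normalize_transitions(counts)


class TestPowerMethod:
    def test_two_state_chain_closed_form(self):
        P = np.array([[0.9, 0.1], [0.5, 0.5]])
        pi = eigenvector_centrality_power(P)
        np.testing.assert_allclose(pi, [5 / 6, 1 / 6], atol=1e-9)

    def test_doubly_stochastic_gives_uniform(self):
        P = np.array([[0.2, 0.5, 0.3], [0.5, 0.3, 0.2], [0.3, 0.2, 0.5]])
        pi = eigenvector_centrality_power(P)
        np.testing.assert_allclose(pi, np.full(3, 1 / 3), atol=1e-9)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_dense_eigensolver_up_to_17_states(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 18))
        P = rng.random((n, n)) ** 3
        P /= P.sum(axis=1, keepdims=True)
        pi = eigenvector_centrality_power(P, tol=1e-13)
        np.testing.assert_allclose(pi, stationary_by_eig(P), atol=1e-8)

    def test_periodic_chain_converges_via_damping(self):
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        pi = eigenvector_centrality_power(P)
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-6)

    def test_non_stochastic_matrix_raises(self):
        with pytest.raises(ValueError):
            eigenvector_centrality_power(np.array([[0.5, 0.2], [0.5, 0.5]]))


class TestDegrees:
    def test_star_topology(self):
        idx = ["A", "B", "C", "D", ABSENT]
        counts = pd.DataFrame(0, index=idx, columns=idx)
        for x in "BCD":
            counts.loc["A", x] = 2
            counts.loc[x, "A"] = 1
        counts.loc["A", ABSENT] = 5
        deg = node_degree(counts)
        assert deg["A"] == 3
        assert deg["B"] == deg["C"] == deg["D"] == 1
        assert ABSENT not in deg.index

    def test_no_off_diagonal_counts_gives_zero_degrees(self):
        idx = ["A", "B"]
        counts = pd.DataFrame(np.diag([4, 2]), index=idx, columns=idx)
        assert (node_degree(counts) == 0).all()

    def test_planted_corridor_node_has_highest_degree(self):
        # movement routed through node 0: every hop leaves from or
        # arrives at the corridor
        nodes = 16
        K = np.zeros((nodes + 1, nodes + 1))
        K[0, 0] = 0.2
        K[0, 1:nodes] = 0.6 / (nodes - 1)
        K[0, nodes] = 0.2
        for i in range(1, nodes):
            K[i, i] = 0.55
            K[i, 0] = 0.35
            K[i, nodes] = 0.10
        K[nodes, nodes] = 0.7
        K[nodes, 0] = 0.3
        cfg = SimulationConfig(
            seed=13,
            group_sizes={("M", "B"): 2},
            kernels={("M", "B"): K},
            max_duration_days=45,
            detection_prob=1.0,
        )
        ds, truth = simulate_cohort(cfg)
        ds = merge_receiver_nodes(ds)
        res = group_chain(ds, truth.sharks["shark_id"].tolist(), "corridor")
        corridor = truth.state_labels[0]
        deg = res.degrees
        assert deg.idxmax() == corridor


class TestGroupChain:
    def test_group_of_one_equals_individual_chain(self, cleaned_sim):
        ds, truth, _ = cleaned_sim
        sid = truth.sharks["shark_id"].iloc[0]
        solo = group_chain(ds, [sid], "solo")
        seq = discretize_hourly_states(ds, sid)
        direct = count_transitions(seq.to_numpy(), solo.states)
        pd.testing.assert_frame_equal(solo.counts, direct)

    def test_conservation_and_stochasticity(self, cleaned_sim):
        ds, truth, _ = cleaned_sim
        ids = truth.sharks["shark_id"].tolist()
        total_len = 0
        for sid in ids:
            total_len += len(discretize_hourly_states(ds, sid)) - 1
        res = group_chain(ds, ids, "all")
        assert res.counts.to_numpy().sum() == total_len
        np.testing.assert_allclose(
            res.transition_matrix.sum(axis=1), 1.0, atol=1e-9
        )
        assert res.fixed_point_residual() < 1e-8
        assert res.centrality.sum() == pytest.approx(1.0)
        assert (res.centrality >= 0).all()

    def test_absent_dominates_for_sparse_occupancy(self, cleaned_sim):
        ds, truth, _ = cleaned_sim
        ids = truth.sharks["shark_id"].tolist()
        res = group_chain(ds, ids, "all")
        occ_absent = np.mean(
            [truth.occupancy(sid)[ABSENT] for sid in ids]
        )
        assert occ_absent > 0.5
        assert res.centrality.idxmax() == ABSENT

    def test_estimated_matrix_within_monte_carlo_error(self):
        from atollnet.simulate import GroupParams, empirical_group_matrix
        from atollnet import apply_minimum_days_filter, remove_false_detections

        gp = {("F", "C"): GroupParams(0.2, 0.05, 0.10, home_bias=0.0)}
        cfg = SimulationConfig(
            seed=21, group_sizes={("F", "C"): 10}, group_params=gp,
            max_duration_days=120, detection_prob=1.0,
        )
        ds, truth = simulate_cohort(cfg)
        ds = remove_false_detections(ds)
        ds, _ = apply_minimum_days_filter(ds)
        ds = merge_receiver_nodes(ds)
        P = empirical_group_matrix(ds, truth, ("F", "C"))
        K = truth.kernels[("F", "C")]
        counts = group_chain(
            ds, truth.sharks["shark_id"].tolist(), "g", states=truth.state_labels
        ).counts
        for s in P.index:
            n = counts.loc[s].sum()
            for t in P.columns:
                p = K.loc[s, t]
                se = np.sqrt(max(p * (1 - p), 1e-12) / n)
                assert abs(P.loc[s, t] - p) <= 3 * se + 3 / n

    def test_empty_group_raises(self, cleaned_sim):
        ds, _, _ = cleaned_sim
        with pytest.raises(ValueError):
            group_chain(ds, [], "none")


class TestExport:
    def test_edge_list_roundtrip_and_edge_count(self, cleaned_sim, tmp_path):
        import networkx as nx

        ds, truth, _ = cleaned_sim
        res = group_chain(ds, truth.sharks["shark_id"].tolist(), "all")
        paths = export_network(res, tmp_path)
        edges = read_edge_list(paths["edges"])
        # re-imported counts identical
        for _, row in edges.iterrows():
            assert res.counts.loc[row["from"], row["to"]] == row["count"]
        # non-self edges equal the positive off-diagonal count cells
        arr = res.counts.to_numpy().copy()
        np.fill_diagonal(arr, 0)
        n_offdiag = int((arr > 0).sum())
        assert (edges["from"] != edges["to"]).sum() == n_offdiag
        G = nx.read_graphml(paths["graphml"])
        assert set(G.nodes) == set(res.states)
        some = res.centrality.idxmax()
        assert G.nodes[some]["centrality"] == pytest.approx(res.centrality[some])
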