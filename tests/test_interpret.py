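"""Dependency-network interpretation: centrality, compositions, statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pairturn import (
    CHANNELS,
    TurnEvent,
    betweenness_scores,
    mrf_adjacency,
    normalize_turn_curves,
    per_state_stats,
    rank_parameters,
    state_composition,
)

# A published channel-level betweenness row for a wall-avoidance state
# (leader wall distance dominant); used as input data for ranking.
REFERENCE_BCS_ROW = {
    "Fdis": 0.435444, "Wldis": 1.000000, "Wfdis": 0.060832,
    "DlHeading": 0.2545, "DfHeading": 0.202669, "Lspeed": 0.0,
    "Fspeed": 0.0, "Lald": 0.141837, "Fald": 0.275916, "Rpa": 0.006207,
}


def betweenness_matrix_power_oracle(graph):
    """Brute-force betweenness via path counting with adjacency powers.

    Shortest-path counts sigma_st equal (A^d)_st for d = dist(s, t)
    because minimal-length walks are simple; the count of shortest s-t
    paths through v is (A^{d(s,v)})_sv * (A^{d(v,t)})_vt when the
    distances add up.
    """
    nodes = list(graph.nodes)
    n = len(nodes)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    powers = [np.eye(n)]
    for _ in range(n):
        powers.append(powers[-1] @ a)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    for dd in range(1, n + 1):
        newly = (powers[dd] > 0) & np.isinf(dist)
        dist[newly] = dd
    scores = dict.fromkeys(nodes, 0.0)
    for si in range(n):
        for ti in range(si + 1, n):
            d = dist[si, ti]
            if not np.isfinite(d):
                continue
            sigma = powers[int(d)][si, ti]
            for vi in range(n):
                if vi in (si, ti):
                    continue
                d1, d2 = dist[si, vi], dist[vi, ti]
                if d1 + d2 == d:
                    through = powers[int(d1)][si, vi] * powers[int(d2)][vi, ti]
                    scores[nodes[vi]] += through / sigma
    return scores


class TestMrfAdjacency:
    def test_diagonal_theta_empty_graph(self):
        g = mrf_adjacency(np.eye(6), d=3, w=2)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_single_offdiagonal_block_entry(self):
        theta = np.eye(3)
        theta[0, 1] = theta[1, 0] = 0.4
        g = mrf_adjacency(theta, d=3, w=1)
        assert set(g.edges) == {(CHANNELS[0], CHANNELS[1])}

    def test_cross_lag_coupling_detected(self):
        d, w = 2, 3
        theta = np.eye(d * w)
        theta[0, 3] = theta[3, 0] = 0.2  # channel 0 frame 0 <-> channel 1 frame 1
        g = mrf_adjacency(theta, d=d, w=w)
        assert set(g.edges) == {(CHANNELS[0], CHANNELS[1])}

    def test_edge_set_matches_threshold_scan(self, rng):
        d, w = 4, 3
        theta = np.eye(d * w)
        # sprinkle sparse couplings, replicated along block diagonals
        base = rng.normal(size=(d, d)) * (rng.random((d, d)) < 0.4)
        lag1 = rng.normal(size=(d, d)) * (rng.random((d, d)) < 0.3)
        for m in range(w):
            theta[m * d:(m + 1) * d, m * d:(m + 1) * d] += base + base.T
        for m in range(w - 1):
            theta[m * d:(m + 1) * d, (m + 1) * d:(m + 2) * d] += lag1
            theta[(m + 1) * d:(m + 2) * d, m * d:(m + 1) * d] += lag1.T
        g = mrf_adjacency(theta, d=d, w=w, edge_eps=1e-3)
        # oracle: direct scan over all index pairs of the big matrix
        weight = np.zeros((d, d))
        for i in range(d * w):
            for j in range(d * w):
                u, v = i % d, j % d
                if u != v:
                    weight[u, v] = max(weight[u, v], abs(theta[i, j]))
        wmax = weight.max()
        expect = {frozenset((CHANNELS[u], CHANNELS[v]))
                  for u in range(d) for v in range(d)
                  if u != v and weight[u, v] > 1e-3 * wmax}
        assert {frozenset(e) for e in g.edges} == expect


class TestBetweenness:
    def test_path_graph_closed_form(self):
        g = nx.path_graph(["A", "B", "C"])
        scores = betweenness_scores(g)
        assert scores == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_star_centre_scores_one(self):
        g = nx.star_graph(4)
        scores = betweenness_scores(g)
        assert scores[0] == 1.0
        assert all(scores[i] == 0.0 for i in range(1, 5))

    def test_matches_matrix_power_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for trial in range(20):
            n = int(rng.integers(4, 11))
            g = nx.gnp_random_graph(n, 0.4, seed=int(rng.integers(1 << 30)))
            raw = nx.betweenness_centrality(g, normalized=False)
            oracle = betweenness_matrix_power_oracle(g)
            for node in g.nodes:
                assert raw[node] == pytest.approx(oracle[node], abs=1e-9)
            top = max(oracle.values())
            scores = betweenness_scores(g)
            if top > 0:
                for node in g.nodes:
                    assert scores[node] == pytest.approx(oracle[node] / top, abs=1e-9)
            else:
                assert all(v == 0.0 for v in scores.values())

    def test_edgeless_graph_all_zero(self):
        g = nx.empty_graph(5)
        assert set(betweenness_scores(g).values()) == {0.0}


class TestRanking:
    def test_distinct_scores_strict_order(self):
        scores = {"Fdis": 0.3, "Wldis": 0.9, "Rpa": 0.1}
        assert rank_parameters(scores) == ["Wldis", "Fdis", "Rpa"]

    def test_ties_keep_frozen_channel_order(self):
        scores = {ch: 0.5 for ch in CHANNELS}
        assert rank_parameters(scores) == list(CHANNELS)

    def test_reference_row_puts_leader_wall_distance_first(self):
        ranked = rank_parameters(REFERENCE_BCS_ROW)
        assert ranked[0] == "Wldis"
        assert REFERENCE_BCS_ROW[ranked[0]] == 1.0


class TestStateComposition:
    def _event(self, pe):
        return TurnEvent(epoints={"A": pe - 10, "B": pe + 10}, pair_epoint=pe,
                         window=(pe - 150, pe + 150))

    def test_rle_basic(self):
        frames = np.arange(995, 1005)
        labels = np.array([5, 5, 5, 5, 5, 5, 2, 2, 5, 5])
        comp = state_composition(labels, frames, self._event(1004), q=9)
        assert comp.composition == "5-2-5"
        assert comp.tokens == (5, 2, 5)

    def test_constant_labels_single_token(self):
        frames = np.arange(900, 1101)
        labels = np.full(201, 3)
        comp = state_composition(labels, frames, self._event(1050), q=100)
        assert comp.composition == "3"

    def test_early_phase_excludes_post_epoint_labels(self):
        frames = np.arange(800, 1301)
        labels = np.where(frames <= 1000, 1, 4)
        comp = state_composition(labels, frames, self._event(1000), q=150,
                                 phase="early")
        assert comp.composition == "1"
        full = state_composition(labels, frames, self._event(1000), q=150,
                                 phase="full")
        assert full.composition == "1-4"

    def test_expand_inverts_rle(self):
        frames = np.arange(0, 400)
        rng = np.random.default_rng(8)
        labels = np.repeat(rng.integers(1, 6, size=20), 20)
        ev = self._event(200)
        comp = state_composition(labels, frames, ev, q=150, phase="full")
        mask = (frames >= 50) & (frames <= 350)
        assert np.array_equal(comp.expand(), labels[mask])

    def test_gap_in_coverage_rejected(self):
        frames = np.concatenate([np.arange(900, 950), np.arange(1000, 1100)])
        labels = np.ones(len(frames), dtype=int)
        with pytest.raises(ValueError, match="gap"):
            state_composition(labels, frames, self._event(1000), q=100)


class TestPerStateStats:
    def _series_df(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(100, 10)), columns=list(CHANNELS))
        return df

    def test_single_segment_mean(self):
        df = self._series_df()
        labels = np.ones(100, dtype=int)
        stats, segs = per_state_stats(df, labels)
        assert len(segs) == 1
        assert segs["mean_fdis"].iloc[0] == pytest.approx(df["Fdis"].mean())

    def test_segment_means_averaged_per_state(self):
        df = self._series_df()
        df["Fdis"] = np.concatenate([np.full(30, 1.0), np.full(40, 9.9),
                                     np.full(30, 3.0)])
        labels = np.concatenate([np.full(30, 1), np.full(40, 2), np.full(30, 1)])
        _, segs = per_state_stats(df, labels)
        state1 = segs[segs["cluster"] == 1]["mean_fdis"]
        assert len(state1) == 2
        assert state1.mean() == pytest.approx(2.0)

    def test_quartiles_and_median_per_cluster(self):
        df = self._series_df()
        labels = np.repeat([1, 2], 50)
        stats, _ = per_state_stats(df, labels)
        sub = df["Rpa"].iloc[:50]
        assert stats.loc[(1, "Rpa"), "median"] == pytest.approx(sub.median())
        assert stats.loc[(1, "Rpa"), "q1"] == pytest.approx(sub.quantile(0.25))


class TestNormalizeTurnCurves:
    def test_single_event_rescaled_copy(self, clean_series):
        _, series, gt = clean_series
        ev = TurnEvent(epoints={"A": 990, "B": 1010}, pair_epoint=1000,
                       window=(850, 1150), turn_type="dominated")
        out = normalize_turn_curves(series, [ev], q=150)
        assert out["curves"][0].shape == (101, 10)
        assert np.allclose(out["means"]["dominated"], out["curves"][0])

    def test_mean_of_identical_events_equals_either(self, clean_series):
        _, series, _ = clean_series
        ev = TurnEvent(epoints={"A": 990, "B": 1010}, pair_epoint=1000,
                       window=(850, 1150), turn_type="dominated")
        twin = TurnEvent(epoints={"A": 990, "B": 1010}, pair_epoint=1000,
                         window=(850, 1150), turn_type="dominated")
        out = normalize_turn_curves(series, [ev, twin], q=150)
        assert np.allclose(out["means"]["dominated"], out["curves"][0])

    def test_linear_ramp_stays_linear(self, arena):
        # affine time rescaling preserves linearity of a channel
        from pairturn.kinematics import PairStateSeries

        n = 301
        frames = np.arange(850, 850 + n)
        data = pd.DataFrame(
            np.tile(np.linspace(0, 1, n)[:, None], (1, 10)), columns=list(CHANNELS))
        series = PairStateSeries(
            frames=frames, data=data, leader=np.full(n, "A"),
            direction=np.ones(n), los=np.zeros(n),
            ald={"A": np.zeros(n), "B": np.zeros(n)},
            roa={"A": np.zeros(n), "B": np.zeros(n)},
            arena=arena, fish_ids=("A", "B"))
        ev = TurnEvent(epoints={"A": 995, "B": 1005}, pair_epoint=1000,
                       window=(850, 1150), turn_type="dominated")
        out = normalize_turn_curves(series, [ev], q=150)
        curve = out["curves"][0][:, 0]
        assert np.allclose(np.diff(curve, 2), 0.0, atol=1e-12)
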