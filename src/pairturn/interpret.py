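"""Interpretation of fitted clusters: dependency networks, centrality,
state compositions and per-state statistics.

A cluster's block-Toeplitz precision matrix is an MRF over d channels x
w frames.  For channel-level interpretation the MRF is collapsed to a
d-node graph: the weight of edge (u, v) is the largest absolute
precision entry coupling the two channels at any frame lag, and an edge
is kept when its weight exceeds a small fraction of the maximum.  Node
importance is shortest-path betweenness, normalised so the top channel
of each cluster scores exactly 1.

Turn windows are summarised as run-length-encoded label strings
("state compositions", e.g. ``"5-2-5"``); the early stage of a turn is
the half-window before the pairwise turning moment (the first half of
the manoeuvre, where the decision is made).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .events import TurnEvent
from .kinematics import CHANNELS, PairStateSeries

__all__ = [
    "mrf_adjacency",
    "betweenness_scores",
    "rank_parameters",
    "StateComposition",
    "state_composition",
    "per_state_stats",
    "normalize_turn_curves",
]


def mrf_adjacency(
    theta: np.ndarray,
    d: int,
    w: int,
    edge_eps: float = 1e-3,
    names: tuple = CHANNELS,
) -> nx.Graph:
    """Collapse a (d*w, d*w) block-Toeplitz precision to a d-node graph.

    weight(u, v) = max over block lags of |theta_block(lag)[u, v]|;
    an edge is present when its weight exceeds ``edge_eps`` times the
    largest weight.  All d nodes are always present (possibly isolated).
    """
    theta = np.asarray(theta, dtype=np.float64)
    blocks = theta.reshape(w, d, w, d).transpose(0, 2, 1, 3)
    weight = np.zeros((d, d))
    for lag in range(w):
        i = np.arange(0, w - lag)
        blk = np.abs(blocks[i, i + lag]).max(axis=0) if len(i) else 0
        weight = np.maximum(weight, np.maximum(blk, blk.T))
    np.fill_diagonal(weight, 0.0)
    g = nx.Graph()
    g.add_nodes_from(names[:d] if len(names) >= d else range(d))
    nodes = list(g.nodes)
    wmax = weight.max()
    if wmax <= 0:
        g.graph["empty"] = True
        return g
    thr = edge_eps * wmax
    for u in range(d):
        for v in range(u + 1, d):
            if weight[u, v] > thr:
                g.add_edge(nodes[u], nodes[v], weight=float(weight[u, v]))
    return g


def betweenness_scores(graph: nx.Graph) -> dict:
    """Unweighted shortest-path betweenness, normalised to max 1 per graph.

    Every node of an edgeless graph scores 0.
    """
    raw = nx.betweenness_centrality(graph, normalized=False, weight=None)
    top = max(raw.values(), default=0.0)
    if top <= 0:
        return {node: 0.0 for node in graph.nodes}
    return {node: score / top for node, score in raw.items()}


def rank_parameters(scores: dict, order: tuple = CHANNELS) -> list:
    """Channels sorted by descending score; ties keep the frozen channel order."""
    idx = {name: i for i, name in enumerate(order)}
    return sorted(scores, key=lambda name: (-scores[name], idx.get(name, len(idx))))


@dataclass
class StateComposition:
    """Run-length-encoded cluster-label sequence of one turn window."""

    pair_epoint: int
    composition: str       # e.g. "5-2-5"
    tokens: tuple          # (5, 2, 5)
    run_lengths: tuple     # frames per token
    phase: str             # "early" or "full"

    def expand(self) -> np.ndarray:
        """Reconstruct the label slice from tokens and run lengths."""
        return np.repeat(self.tokens, self.run_lengths)


def _rle(labels: np.ndarray) -> tuple[tuple, tuple]:
    labels = np.asarray(labels)
    if len(labels) == 0:
        return (), ()
    change = np.where(labels[1:] != labels[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return tuple(int(labels[s]) for s in starts), tuple(int(e - s) for s, e in zip(starts, ends))


def state_composition(
    labels: np.ndarray,
    frames: np.ndarray,
    event: TurnEvent,
    q: int = 150,
    phase: str = "early",
) -> StateComposition:
    """Run-length-encode the cluster labels across a turn window.

    ``phase="early"`` uses [pair_epoint - q, pair_epoint] (the first
    half of the manoeuvre); ``"full"`` uses the whole +-q window.
    """
    pe = event.pair_epoint
    lo, hi = (pe - q, pe) if phase == "early" else (pe - q, pe + q)
    mask = (frames >= lo) & (frames <= hi)
    if not mask.any():
        raise ValueError(f"labels do not cover the window [{lo}, {hi}]")
    covered = frames[mask]
    if covered.min() > max(lo, frames.min()) or len(covered) != covered.max() - covered.min() + 1:
        raise ValueError("label coverage of the turn window has gaps")
    tokens, runs = _rle(labels[mask])
    return StateComposition(
        pair_epoint=pe, composition="-".join(str(t) for t in tokens),
        tokens=tokens, run_lengths=runs, phase=phase)


def per_state_stats(
    series: PairStateSeries | pd.DataFrame,
    labels: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster channel statistics and segment-averaged Fdis.

    Returns
    -------
    channel_stats : DataFrame
        Rows indexed by (cluster, channel) with mean, median and
        quartiles over all frames of the cluster.
    fdis_segments : DataFrame
        One row per maximal single-label run: its cluster, length and
        mean Fdis; the per-state average Fdis is the mean of these
        per-segment means.
    """
    data = series.data if isinstance(series, PairStateSeries) else series
    labels = np.asarray(labels)
    if len(labels) != len(data):
        raise ValueError("labels and series length mismatch")
    rows = []
    for c in np.unique(labels):
        sub = data[labels == c]
        for ch in data.columns:
            col = sub[ch]
            rows.append({
                "cluster": int(c), "channel": ch, "mean": col.mean(),
                "median": col.median(), "q1": col.quantile(0.25),
                "q3": col.quantile(0.75), "n_frames": len(col)})
    channel_stats = pd.DataFrame(rows).set_index(["cluster", "channel"])

    tokens, runs = _rle(labels)
    seg_rows = []
    start = 0
    for tok, run in zip(tokens, runs):
        seg = data.iloc[start: start + run]
        seg_rows.append({
            "cluster": int(tok), "start": start, "length": int(run),
            "mean_fdis": float(seg["Fdis"].mean()) if "Fdis" in data.columns else np.nan})
        start += run
    fdis_segments = pd.DataFrame(seg_rows)
    return channel_stats, fdis_segments


def normalize_turn_curves(
    series: PairStateSeries,
    events: list[TurnEvent],
    q: int = 150,
    grid_points: int = 101,
) -> dict:
    """Rescale each event's channel curves to a common [0, 1] time grid.

    Each +-q window is linearly mapped onto ``grid_points`` samples;
    group means are reported per turn type.  Returns a dict with keys
    ``grid``, ``curves`` (event index -> (grid_points, d) array),
    ``types`` and ``means`` (turn type -> (grid_points, d) array).
    """
    grid = np.linspace(0.0, 1.0, grid_points)
    curves = {}
    types = {}
    for i, ev in enumerate(events):
        lo, hi = ev.pair_epoint - q, ev.pair_epoint + q
        mask = (series.frames >= lo) & (series.frames <= hi)
        if not mask.any():
            continue
        sub = series.values[mask]
        x = np.linspace(0.0, 1.0, len(sub))
        curves[i] = np.column_stack(
            [np.interp(grid, x, sub[:, j]) for j in range(sub.shape[1])])
        types[i] = ev.turn_type
    means = {}
    for ty in set(types.values()):
        stack = np.stack([curves[i] for i in curves if types[i] == ty])
        means[ty] = stack.mean(axis=0)
    return {"grid": grid, "curves": curves, "types": types, "means": means}
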