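"""Empirically derived Markov chain (EDMC) movement networks.

Detections are discretised into hourly presence states over the node
network (16 merged receiver nodes by default) plus an explicit ABSENT
state for hours with no detection.  Consecutive hourly states are
tallied into a square transition-count matrix whose diagonal holds
residency periods and whose ABSENT row/column holds departures and
returns; row-normalising gives the empirical transition matrix P.

The dominant left eigenvector of P (its stationary distribution),
computed by the power method, serves as an eigenvector-centrality proxy
for the long-run probability of finding an animal at each node; node
degree (distinct neighbours with any observed transition) describes the
connectivity of the movement network.  Chains are built per animal or
pooled by sex x life-history-stage group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import DetectionSet

__all__ = [
    "ABSENT",
    "MarkovChainResult",
    "discretize_hourly_states",
    "count_transitions",
    "normalize_transitions",
    "eigenvector_centrality_power",
    "node_degree",
    "group_chain",
    "export_network",
    "read_edge_list",
]

ABSENT = "ABSENT"


def discretize_hourly_states(ds: DetectionSet, shark_id: str) -> pd.Series:
    """Hourly state labels from first to last detection hour of one animal.

    Hours holding at least one detection are labelled with the node with
    the most detections that hour (ties broken toward the node of the
    hour's latest detection); all other hours are ABSENT.  Returns an
    empty series for an animal with no detections.
    """
    ev = ds.events_for(shark_id)
    return _discretize_events(ev)


def _discretize_events(ev: pd.DataFrame) -> pd.Series:
    if not len(ev):
        return pd.Series(dtype=object, name="state")
    if "node_id" not in ev.columns:
        raise ValueError("detections must be node-merged first (merge_receiver_nodes)")
    hours = ev["timestamp"].dt.floor("h")
    agg = (
        ev.assign(_hour=hours)
        .groupby(["_hour", "node_id"], observed=True)["timestamp"]
        .agg(n="size", last="max")
        .reset_index()
        .sort_values(["_hour", "n", "last"], kind="mergesort")
    )
    winners = (
        agg.groupby("_hour", observed=True).tail(1).set_index("_hour")["node_id"].astype(object)
    )
    full = pd.date_range(hours.min(), hours.max(), freq="h")
    out = winners.reindex(full).fillna(ABSENT)
    out.name = "state"
    return out


def count_transitions(
    sequence, states: list[str] | None = None
) -> pd.DataFrame:
    """Square matrix of consecutive-pair counts over a state sequence.

    ``states`` fixes the matrix's state space (order preserved); by
    default the distinct labels observed, with ABSENT last.  Counts sum
    to ``len(sequence) - 1``; a shorter sequence yields a zero matrix
    with a warning.
    """
    labels = np.asarray(list(sequence), dtype=object)
    if states is None:
        seen = [s for s in dict.fromkeys(labels) if s != ABSENT]
        states = seen + ([ABSENT] if ABSENT in labels else [])
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=np.int64)
    if len(labels) < 2:
        import warnings

        warnings.warn("sequence shorter than 2; zero transition matrix", stacklevel=2)
    else:
        a = np.fromiter((index[s] for s in labels[:-1]), dtype=np.int64)
        b = np.fromiter((index[s] for s in labels[1:]), dtype=np.int64)
        np.add.at(counts, (a, b), 1)
    return pd.DataFrame(counts, index=states, columns=states)


def normalize_transitions(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-normalise a count matrix, dropping unvisited states.

    States with no incident counts at all (zero row and zero column)
    were never visited; they are removed from both axes and returned as
    the second element.  A state that was entered but never left (an
    end-of-sequence artifact) is kept with an absorbing self-loop so the
    matrix stays row-stochastic; the centrality solver later excludes it
    from the communicating class.  Raises on an all-zero matrix.
    """
    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    visited = [s for s in counts.index if row_sums[s] > 0 or col_sums[s] > 0]
    dropped = [s for s in counts.index if s not in visited]
    if not visited:
        raise ValueError("all-zero transition count matrix")
    sub = counts.loc[visited, visited].astype(float)
    rs = sub.sum(axis=1)
    for s in rs.index[rs == 0]:
        sub.loc[s, s] = 1.0
    P = sub.div(sub.sum(axis=1), axis=0)
    return P, dropped


def _communicating_class(P: pd.DataFrame) -> list[str]:
    """States of the main communicating class of P.

    Builds the directed graph of positive transitions and returns the
    largest strongly connected component containing ABSENT (or simply
    the largest, for chains without an absent state).  A finite sample
    can make rarely visited states look absorbing or unreachable; those
    fall outside the class and receive zero centrality.
    """
    G = nx.DiGraph()
    G.add_nodes_from(P.index)
    arr = P.to_numpy()
    for i, s in enumerate(P.index):
        for j, t in enumerate(P.columns):
            if arr[i, j] > 0:
                G.add_edge(s, t)
    comps = list(nx.strongly_connected_components(G))
    with_absent = [c for c in comps if ABSENT in c]
    chosen = with_absent[0] if with_absent else max(comps, key=len)
    return [s for s in P.index if s in chosen]


def eigenvector_centrality_power(
    P, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray | pd.Series:
    """Stationary distribution of a row-stochastic P by power iteration.

    Iterates x <- xP from the uniform vector until successive iterates
    differ by less than ``tol`` in the infinity norm.  A reducible chain
    is restricted to its largest communicating class containing the
    absent state, rows renormalised (zeros elsewhere in the output);
    if plain iteration stalls on a periodic chain, a lazy damping
    P' = 0.999 P + 0.001 I -- which leaves the fixed point unchanged --
    is applied.  Raises if still unconverged at ``max_iter``.
    """
    is_frame = isinstance(P, pd.DataFrame)
    if is_frame:
        states = list(P.index)
        A = P.to_numpy(float)
    else:
        A = np.asarray(P, float)
        states = list(range(A.shape[0]))
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("P must be square")
    if not np.allclose(A.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("P must be row-stochastic")

    frame = pd.DataFrame(A, index=states, columns=states)
    cls = _communicating_class(frame)
    idx = [states.index(s) for s in cls]
    B = A[np.ix_(idx, idx)]
    B = B / B.sum(axis=1, keepdims=True)

    def iterate(M: np.ndarray) -> tuple[np.ndarray, int] | None:
        x = np.full(M.shape[0], 1.0 / M.shape[0])
        for it in range(1, max_iter + 1):
            x_new = x @ M
            x_new /= x_new.sum()
            resid = np.abs(x_new - x).max()
            x = x_new
            if resid < tol:
                return x, it
        return None

    budget = max(1000, max_iter // 10)
    probe = iterate_limited(B, tol, budget)
    if probe is not None:
        x = probe
    else:
        # periodic or slowly mixing: lazy damping preserves the fixed point
        damped = 0.999 * B + 0.001 * np.eye(B.shape[0])
        res = iterate(damped)
        if res is None:
            x_try = iterate(B)
            if x_try is None:
                raise RuntimeError(
                    f"power iteration failed to converge within {max_iter} iterations"
                )
            x = x_try[0]
        else:
            x = res[0]

    full = np.zeros(len(states))
    for k, i in enumerate(idx):
        full[i] = x[k]
    full /= full.sum()
    if is_frame:
        return pd.Series(full, index=states, name="centrality")
    return full


def iterate_limited(M: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Plain power iteration with an iteration budget; None if unconverged."""
    x = np.full(M.shape[0], 1.0 / M.shape[0])
    for _ in range(max_iter):
        x_new = x @ M
        x_new /= x_new.sum()
        if np.abs(x_new - x).max() < tol:
            return x_new
        x = x_new
    return None


def node_degree(counts: pd.DataFrame, exclude_absent: bool = True) -> pd.Series:
    """Distinct-neighbour degree of each node in the movement network.

    A neighbour is any *other* node with a positive transition count in
    either direction; self-transitions never contribute.  With
    ``exclude_absent`` (default) the ABSENT state is dropped both as a
    node and as a potential neighbour.
    """
    nodes = [s for s in counts.index if not (exclude_absent and s == ABSENT)]
    sub = counts.loc[nodes, nodes]
    arr = sub.to_numpy()
    adj = (arr + arr.T) > 0
    np.fill_diagonal(adj, False)
    return pd.Series(adj.sum(axis=1), index=nodes, name="degree")


@dataclass
class MarkovChainResult:
    """A fitted movement chain for one animal or a pooled group."""

    label: str
    states: list[str]
    counts: pd.DataFrame
    transition_matrix: pd.DataFrame  # row-stochastic over visited states
    centrality: pd.Series  # stationary distribution, sums to 1
    degrees: pd.Series
    dropped_states: list[str] = field(default_factory=list)
    n_sharks: int = 1

    def fixed_point_residual(self) -> float:
        """Max |pi P - pi| on the communicating class the chain was solved on.

        States outside that class carry zero centrality; the restriction
        of P to the class is row-renormalised (as during solving) before
        the residual is evaluated.
        """
        pi = self.centrality.reindex(self.transition_matrix.index).fillna(0.0)
        support = pi[pi > 0].index
        sub = self.transition_matrix.loc[support, support].to_numpy(float)
        sub = sub / sub.sum(axis=1, keepdims=True)
        p = pi[support].to_numpy()
        return float(np.abs(p @ sub - p).max())


def group_chain(
    ds: DetectionSet,
    shark_ids,
    label: str = "group",
    states: list[str] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MarkovChainResult:
    """Pooled movement chain over a group of animals.

    Per-animal hourly sequences are counted independently and the count
    matrices summed before normalising, so each animal's first-to-last
    detection window contributes without creating artificial transitions
    between animals.  ABSENT is part of the state space.
    """
    shark_ids = list(shark_ids)
    if not shark_ids:
        raise ValueError("empty group")
    if states is None:
        if ds.node_map is not None:
            states = ds.node_map.node_ids + [ABSENT]
        else:
            states = sorted(ds.events["node_id"].unique()) + [ABSENT]
    total = pd.DataFrame(0, index=states, columns=states, dtype=np.int64)
    wanted = set(str(s) for s in shark_ids)
    ev = ds.events[ds.events["transmitter_id"].isin(wanted)]
    for sid, sub in ev.groupby("transmitter_id", observed=True):
        seq = _discretize_events(sub)
        if len(seq) >= 2:
            total += count_transitions(seq.to_numpy(), states)
    P, dropped = normalize_transitions(total)
    pi = eigenvector_centrality_power(P, tol=tol, max_iter=max_iter)
    centrality = pi.reindex(states).fillna(0.0)
    return MarkovChainResult(
        label=label,
        states=states,
        counts=total,
        transition_matrix=P,
        centrality=centrality,
        degrees=node_degree(total),
        dropped_states=dropped,
        n_sharks=len(shark_ids),
    )


def export_network(result: MarkovChainResult, outdir) -> dict:
    """Write the movement network as an edge list CSV and GraphML.

    The edge list holds every positive transition count with its
    empirical probability; GraphML nodes carry centrality and degree.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    P = result.transition_matrix
    for s in result.counts.index:
        for t in result.counts.columns:
            c = int(result.counts.loc[s, t])
            if c > 0:
                prob = float(P.loc[s, t]) if s in P.index and t in P.columns else np.nan
                rows.append({"from": s, "to": t, "count": c, "probability": prob})
    edges = pd.DataFrame(rows, columns=["from", "to", "count", "probability"])
    edge_path = outdir / f"edges_{result.label}.csv"
    try:
        edges.to_csv(edge_path, index=False, float_format="%.10g")
    except OSError as exc:
        raise OSError(f"failed writing edge list to {edge_path}: {exc}") from exc

    G = nx.DiGraph()
    for s in result.states:
        G.add_node(
            s,
            centrality=float(result.centrality.get(s, 0.0)),
            degree=int(result.degrees.get(s, 0)),
        )
    for row in rows:
        G.add_edge(
            row["from"], row["to"], count=row["count"],
            probability=0.0 if pd.isna(row["probability"]) else row["probability"],
        )
    gml_path = outdir / f"network_{result.label}.graphml"
    nx.write_graphml(G, gml_path)
    return {"edges": edge_path, "graphml": gml_path}


def read_edge_list(path) -> pd.DataFrame:
    """Re-import an exported edge list (round-trips counts exactly)."""
    return pd.read_csv(path, dtype={"from": str, "to": str})
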