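"""Connectivity-pattern analysis of converged plastic networks.

After STDP has driven every synapse to one of its bounds, the weight
matrix defines a directed graph (edge j -> i where the j-to-i synapse
saturated at 1).  In heterogeneous networks of class I neurons these
graphs organize into synchronized clusters, each enslaved by a single
pacemaker: the neuron whose natural period equals the cluster's common
period and which receives no input from within its cluster.  Because a
slow driver can lock a faster neuron at winding ``n/1``, the pacemaker
of a cluster is often one of the *slow* neurons, and the fast members
then fire ``n`` spikes per common cycle — their raw interspike mean is
a fraction of the cluster period, and the cycle-aligned period (mean
interval times the locked ``n``) is the quantity that matches the
pacemaker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .engine import EventLog, _analysis_start

__all__ = [
    "ConnectivityGraph",
    "ClusterInfo",
    "PatternReport",
    "threshold_graph",
    "actual_periods",
    "find_clusters",
]


@dataclass
class ConnectivityGraph:
    """Thresholded weight matrix as a directed graph.

    ``graph`` has one node per neuron and an edge ``j -> i`` wherever
    ``W[i][j] > 1 - eps_w``.  ``unconverged`` lists ``(i, j)`` entries
    caught between the bounds; any such entry marks the matrix as
    transient and the caller decides whether to proceed.
    """

    graph: nx.DiGraph
    unconverged: list[tuple[int, int]]

    @property
    def is_converged(self) -> bool:
        return not self.unconverged


def threshold_graph(W: np.ndarray, eps_w: float = 0.05) -> ConnectivityGraph:
    """Binarize a weight matrix at ``1 - eps_w`` into a directed graph."""
    if not 0.0 < eps_w < 0.5:
        raise ValueError(f"eps_w must lie in (0, 0.5), got {eps_w}")
    W = np.asarray(W)
    N = W.shape[0]
    g = nx.DiGraph()
    g.add_nodes_from(range(N))
    unconverged = []
    for i in range(N):
        for j in range(N):
            if i == j:
                continue
            w = W[i, j]
            if w > 1 - eps_w:
                g.add_edge(j, i, weight=float(w))
            elif w > eps_w:
                unconverged.append((i, j))
    return ConnectivityGraph(graph=g, unconverged=unconverged)


def actual_periods(
    log: EventLog, t_start: float | None = None, max_intervals: int = 30
) -> pd.DataFrame:
    """Mean asymptotic interspike interval per neuron.

    Uses at most the last ``max_intervals`` intervals after ``t_start``
    (default: the log's post-transient cut), so an early weight
    saturation does not drag the initial phase transient into the
    average.  Returns a DataFrame with columns ``neuron,
    natural_period, mean_isi, n_spikes``; silent neurons get ``NaN``.
    """
    t0 = _analysis_start(log) if t_start is None else t_start
    rows = []
    for i in range(len(log.periods)):
        times = log.spikes_of(i)
        times = times[times >= t0][-(max_intervals + 1):]
        mean_isi = float(np.diff(times).mean()) if times.size >= 3 else np.nan
        rows.append(
            dict(
                neuron=i,
                natural_period=float(log.periods[i]),
                mean_isi=mean_isi,
                n_spikes=int(times.size),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class ClusterInfo:
    members: list[int]
    pacemaker: int | None  # None when no period-consistent pacemaker exists
    period: float | None
    windings: dict[int, int] = field(default_factory=dict)  # spikes per common cycle


@dataclass
class PatternReport:
    """Cluster decomposition of a converged network."""

    clusters: list[ClusterInfo]
    isolated: list[int]
    periods: pd.DataFrame  # actual_periods output + cycle_aligned column
    transient: bool
    inconsistent: list[list[int]]  # member lists of clusters without a pacemaker

    def to_dict(self) -> dict:
        return dict(
            clusters=[asdict(c) for c in self.clusters],
            isolated=self.isolated,
            periods=self.periods.to_dict(orient="records"),
            transient=self.transient,
            inconsistent=self.inconsistent,
        )


def find_clusters(
    cg: ConnectivityGraph,
    periods: pd.DataFrame,
    *,
    period_tol: float = 1e-3,
) -> PatternReport:
    """Partition a thresholded network into pacemaker-led clusters.

    Clusters are the weakly connected components with at least one
    edge; degree-0 nodes are isolated.  Within a cluster the pacemaker
    is the neuron with no incoming intra-cluster edges whose natural
    period matches every member's cycle-aligned period to
    ``period_tol`` relative; ties are broken toward the smallest
    natural period.  A cluster with no consistent pacemaker is flagged
    rather than guessed at.
    """
    g = cg.graph
    by_neuron = periods.set_index("neuron")
    clusters: list[ClusterInfo] = []
    isolated: list[int] = []
    inconsistent: list[list[int]] = []
    aligned = {int(i): np.nan for i in g.nodes}
    windings_all: dict[int, int] = {}

    for comp in nx.weakly_connected_components(g):
        members = sorted(int(i) for i in comp)
        if len(members) == 1:
            isolated.append(members[0])
            m = members[0]
            aligned[m] = by_neuron.loc[m, "mean_isi"]
            continue
        sub = g.subgraph(members)
        candidates = sorted(
            (m for m in members if sub.in_degree(m) == 0),
            key=lambda m: by_neuron.loc[m, "natural_period"],
        )
        chosen = None
        for cand in candidates:
            T_ref = by_neuron.loc[cand, "natural_period"]
            windings: dict[int, int] = {}
            ok = True
            for m in members:
                isi = by_neuron.loc[m, "mean_isi"]
                if not np.isfinite(isi) or isi <= 0:
                    ok = False
                    break
                n = max(1, round(T_ref / isi))
                if abs(n * isi - T_ref) > period_tol * T_ref:
                    ok = False
                    break
                windings[m] = int(n)
            if ok:
                chosen = (cand, float(T_ref), windings)
                break
        if chosen is None:
            inconsistent.append(members)
            clusters.append(ClusterInfo(members=members, pacemaker=None, period=None))
        else:
            cand, T_ref, windings = chosen
            clusters.append(
                ClusterInfo(members=members, pacemaker=cand, period=T_ref, windings=windings)
            )
            windings_all.update(windings)
            for m in members:
                aligned[m] = windings[m] * by_neuron.loc[m, "mean_isi"]

    out = periods.copy()
    out["cycle_aligned"] = [aligned.get(int(i), np.nan) for i in out["neuron"]]
    out["winding"] = [windings_all.get(int(i), 1) for i in out["neuron"]]
    return PatternReport(
        clusters=clusters,
        isolated=sorted(isolated),
        periods=out,
        transient=not cg.is_converged,
        inconsistent=inconsistent,
    )
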