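"""Mutation co-occurrence networks: construction, curation, centrality.

Phase I records each cycle's elite mutation set as a *complete network*
(a clique over the mutation labels).  The m cliques are merged by
summation into one weighted mutation network: node weight = number of
cycles a mutation appeared in, edge weight = number of cycles a pair
co-occurred in.

Phase II curates that network toward a scale-free topology, monitored
by the exponent g of a discrete power law fitted to the (unweighted)
degree distribution by maximum likelihood.  Scale-free networks are
expected to show g between 2 and 3; curation either prunes
low-centrality nodes upward (*ascending*) or grows from the
high-centrality nodes downward (*descending*) until g lands in that
band.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import zeta


class NetworkError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Network containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompleteNetwork:
    """The clique over one cycle's elite mutation labels."""

    nodes: frozenset[str]

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        return frozenset(tuple(sorted(p)) for p in combinations(self.nodes, 2))

    def __len__(self) -> int:
        return len(self.nodes)


@dataclass
class MutationNetwork:
    """Weighted co-occurrence network over mutation labels."""

    node_count: dict[str, int]
    edge_count: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        for (u, v), c in self.edge_count.items():
            if u not in self.node_count or v not in self.node_count:
                raise NetworkError(f"edge ({u},{v}) references an absent node")
            if c > min(self.node_count[u], self.node_count[v]):
                raise NetworkError(
                    f"edge ({u},{v}) count {c} exceeds an endpoint node count"
                )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for label, c in self.node_count.items():
            g.add_node(label, count=c)
        for (u, v), c in self.edge_count.items():
            g.add_edge(u, v, weight=c)
        return g

    def subgraph(self, labels: Iterable[str]) -> "MutationNetwork":
        keep = set(labels)
        return MutationNetwork(
            {n: c for n, c in self.node_count.items() if n in keep},
            {e: c for e, c in self.edge_count.items() if e[0] in keep and e[1] in keep},
        )

    def degrees(self) -> dict[str, int]:
        d = {n: 0 for n in self.node_count}
        for u, v in self.edge_count:
            d[u] += 1
            d[v] += 1
        return d

    @property
    def n_nodes(self) -> int:
        return len(self.node_count)


def complete_network(mutations) -> CompleteNetwork:
    """Clique over a mutation set (labels or Mutation objects)."""
    labels = frozenset(getattr(m, "label", m) for m in mutations)
    return CompleteNetwork(labels)


def merge_networks(cliques: Sequence[CompleteNetwork]) -> MutationNetwork:
    """Summation merge: count appearances and co-appearances over cycles."""
    if not cliques:
        raise NetworkError("nothing to merge")
    node_count: dict[str, int] = {}
    edge_count: dict[tuple[str, str], int] = {}
    for clique in cliques:
        for n in clique.nodes:
            node_count[n] = node_count.get(n, 0) + 1
        for e in clique.edges:
            edge_count[e] = edge_count.get(e, 0) + 1
    return MutationNetwork(node_count, edge_count)


# ---------------------------------------------------------------------------
# Count files (canonical JSON forms)
# ---------------------------------------------------------------------------

def write_counts(
    network: MutationNetwork, node_path: str | Path, edge_path: str | Path
) -> None:
    """Write the node-count and edge-count files in canonical sorted form."""
    nodes = dict(
        sorted(network.node_count.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    edges = sorted(
        ([u, v, c] for (u, v), c in network.edge_count.items()),
        key=lambda row: (-row[2], row[0], row[1]),
    )
    Path(node_path).write_text(json.dumps(nodes, indent=1) + "\n")
    Path(edge_path).write_text(json.dumps(edges, indent=1) + "\n")


def read_counts(node_path: str | Path, edge_path: str | Path) -> MutationNetwork:
    nodes = json.loads(Path(node_path).read_text())
    rows = json.loads(Path(edge_path).read_text())
    edge_count = {}
    for u, v, c in rows:
        if u not in nodes or v not in nodes:
            raise NetworkError(f"edge ({u},{v}) references a node missing from the node file")
        edge_count[tuple(sorted((u, v)))] = int(c)
    return MutationNetwork({k: int(v) for k, v in nodes.items()}, edge_count)


# ---------------------------------------------------------------------------
# Discrete power-law exponent (maximum likelihood)
# ---------------------------------------------------------------------------

def powerlaw_mle(samples: Sequence[int], x_min: int = 1) -> float:
    """Discrete power-law exponent by maximum likelihood.

    Fits P(x) ∝ x^(-g) for integer x >= x_min by maximizing the exact
    discrete log-likelihood n·[-g·mean(ln x) - ln ζ(g, x_min)] using the
    Hurwitz zeta function (the Clauset–Shalizi–Newman estimator).
    """
    xs = np.asarray([x for x in samples if x >= x_min], dtype=float)
    if len(xs) == 0:
        raise NetworkError(f"no samples at or above x_min={x_min}")
    if len(np.unique(xs)) < 2:
        return math.nan  # degenerate: all observations equal
    mean_log = float(np.mean(np.log(xs)))

    def nll(g: float) -> float:
        return g * mean_log + math.log(zeta(g, x_min))

    res = minimize_scalar(nll, bounds=(1.0001, 12.0), method="bounded",
                          options={"xatol": 1e-6})
    return float(res.x)


def estimate_g(network: MutationNetwork, x_min: int = 1) -> float:
    """Power-law exponent of the network's unweighted degree distribution.

    Returns NaN when the degree distribution is degenerate (fewer than
    two distinct degree values at or above x_min); callers must handle
    the flag.
    """
    degs = [d for d in network.degrees().values() if d >= x_min]
    if not degs:
        return math.nan
    return powerlaw_mle(degs, x_min)


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------

_MEASURES = ("degree", "weighted_degree", "betweenness", "eigenvector")


def centrality(
    network: MutationNetwork, measure: str = "weighted_degree"
) -> list[tuple[str, float]]:
    """Rank nodes by a centrality measure, descending.

    Ties break by (node occurrence count descending, label ascending) so
    rankings — and everything selected from them — are deterministic.
    ``weighted_degree`` sums incident co-occurrence counts, using the
    edge weights the method records; ``degree``/``betweenness``/
    ``eigenvector`` operate on the unweighted topology.
    """
    if measure not in _MEASURES:
        raise NetworkError(f"unknown centrality measure {measure!r}")
    if not network.node_count:
        raise NetworkError("empty network")
    g = network.to_networkx()
    if measure == "degree":
        values = {n: float(d) for n, d in g.degree()}
    elif measure == "weighted_degree":
        values = {n: float(d) for n, d in g.degree(weight="weight")}
    elif measure == "betweenness":
        values = nx.betweenness_centrality(g, normalized=True)
    else:
        values = nx.eigenvector_centrality_numpy(g) if g.number_of_edges() else {
            n: 0.0 for n in g
        }
    ranked = sorted(
        values.items(),
        key=lambda kv: (-kv[1], -network.node_count[kv[0]], kv[0]),
    )
    return [(n, float(v)) for n, v in ranked]


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

@dataclass
class CurationResult:
    network: MutationNetwork
    g_value: float
    trajectory: list[tuple[int, float]]
    approach: str
    changed_nodes: list[str]  # removed (ascending) or added (descending), in order
    reached_target: bool
    measure: str


def _g_distance(g: float, target: tuple[float, float]) -> float:
    if math.isnan(g):
        return math.inf
    lo, hi = target
    if lo <= g <= hi:
        return 0.0
    return min(abs(g - lo), abs(g - hi))


def curate_ascending(
    network: MutationNetwork,
    measure: str = "weighted_degree",
    target: tuple[float, float] = (2.0, 3.0),
    batch: int = 1,
    min_nodes: int = 10,
    x_min: int = 1,
) -> CurationResult:
    """Prune lowest-centrality nodes until the degree exponent enters target.

    Centrality is recomputed after every removal step; nodes isolated by
    edge loss are dropped along with their edges.  If g never enters the
    target band before the node floor, the best-g state seen is returned
    with ``reached_target=False``.
    """
    current = network.subgraph(network.node_count)
    trajectory: list[tuple[int, float]] = []
    removed: list[str] = []
    best = None  # (distance, step, network, g)
    step = 0
    while True:
        g = estimate_g(current, x_min)
        trajectory.append((step, g))
        dist = _g_distance(g, target)
        if best is None or dist < best[0]:
            best = (dist, step, current, g)
        lo, hi = target
        if not math.isnan(g) and lo <= g <= hi:
            return CurationResult(current, g, trajectory, "ascending", removed, True, measure)
        if current.n_nodes - batch < min_nodes:
            _, _, net, gb = best
            return CurationResult(net, gb, trajectory, "ascending", removed, False, measure)
        ranked = centrality(current, measure)
        to_drop = [n for n, _ in ranked[-batch:]]
        keep = set(current.node_count) - set(to_drop)
        removed.extend(to_drop)
        current = current.subgraph(keep)
        # drop nodes isolated by the edge removals
        degs = current.degrees()
        isolated = [n for n, d in degs.items() if d == 0]
        if isolated and current.n_nodes - len(isolated) >= min_nodes:
            removed.extend(sorted(isolated))
            current = current.subgraph(set(current.node_count) - set(isolated))
        step += 1


def curate_descending(
    network: MutationNetwork,
    measure: str = "weighted_degree",
    target: tuple[float, float] = (2.0, 3.0),
    batch: int = 1,
    x_min: int = 1,
) -> CurationResult:
    """Grow from the top-centrality nodes until the exponent enters target.

    The ranking is computed once on the full network; the retained set
    is always a prefix of it, with edges induced from the edge counts.
    """
    ranked = [n for n, _ in centrality(network, measure)]
    trajectory: list[tuple[int, float]] = []
    added: list[str] = []
    best = None
    step = 0
    size = 1
    while True:
        prefix = ranked[:size]
        added = list(prefix)
        current = network.subgraph(prefix)
        g = estimate_g(current, x_min)
        trajectory.append((step, g))
        dist = _g_distance(g, target)
        if best is None or dist < best[0]:
            best = (dist, step, current, g)
        lo, hi = target
        if not math.isnan(g) and lo <= g <= hi:
            return CurationResult(current, g, trajectory, "descending", added, True, measure)
        if size >= len(ranked):
            _, _, net, gb = best
            kept = [n for n in ranked if n in net.node_count]
            return CurationResult(net, gb, trajectory, "descending", kept, False, measure)
        size = min(size + batch, len(ranked))
        step += 1
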