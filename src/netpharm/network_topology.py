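"""Compound–target and protein–protein network topology.

The compound–target network is an undirected bipartite graph between the
remedy's compounds and the candidate disease genes they are predicted to
bind. Compounds are screened on two centralities computed over the whole
graph: degree and Brandes betweenness (normalized by (N−1)(N−2)/2, N being
the total node count), with a compound declared "active" when both values
strictly exceed the compound-node means. The candidate genes' PPI subgraph
is summarized after removing zero-degree ("free") members, and hub genes
are ranked by degree with alphabetical tie-breaking and tie expansion at
the cut.

Betweenness is implemented directly by Brandes' dependency-accumulation
algorithm (unweighted BFS variant) so its normalization and
disconnected-graph conventions are explicit; pair dependencies are only
accumulated over reachable pairs, with no per-component renormalization.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .io_formats import EdgeList
from .target_sets import CompoundTargetMap, OverlapResult

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Bipartite compound–target network
# ---------------------------------------------------------------------------

@dataclass
class BipartiteNetwork:
    """Compound nodes + target nodes + undirected compound–target edges."""

    compound_nodes: set[str]
    target_nodes: set[str]
    edges: set[frozenset[str]]
    dropped_compounds: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.compound_nodes & self.target_nodes:
            raise ValueError("compound and target node sets must be disjoint")
        for edge in self.edges:
            a, b = tuple(edge)
            if not (
                (a in self.compound_nodes and b in self.target_nodes)
                or (b in self.compound_nodes and a in self.target_nodes)
            ):
                raise ValueError(f"edge {set(edge)} does not join a compound to a target")

    @property
    def n_nodes(self) -> int:
        return len(self.compound_nodes) + len(self.target_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.compound_nodes, side="compound")
        g.add_nodes_from(self.target_nodes, side="target")
        g.add_edges_from(tuple(e) for e in self.edges)
        return g


def build_bipartite(overlap: OverlapResult, compound_map: CompoundTargetMap) -> BipartiteNetwork:
    """Restrict compound–target edges to the overlap gene set.

    Compounds left with no edge into the overlap are dropped (and recorded),
    matching the convention that the drawn network shows only connected
    compounds.
    """
    if overlap.is_empty:
        raise ValueError("empty overlap: no shared targets to build a network on")
    members = overlap.intersection
    edges: set[frozenset[str]] = set()
    compounds: set[str] = set()
    dropped: set[str] = set()
    for compound, genes in compound_map.entries.items():
        hit = genes & members
        if hit:
            compounds.add(compound)
            for gene in hit:
                edges.add(frozenset((compound, gene)))
        else:
            dropped.add(compound)
    if dropped:
        logger.info("dropped %d compounds with no overlap targets: %s",
                    len(dropped), sorted(dropped))
    targets = {g for e in edges for g in e if g in members}
    return BipartiteNetwork(compounds, targets, edges, dropped)


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------

def degree(graph: nx.Graph | BipartiteNetwork) -> dict[str, int]:
    """Exact incident-edge count per node."""
    if isinstance(graph, BipartiteNetwork):
        graph = graph.to_networkx()
    return {node: int(d) for node, d in graph.degree()}


def betweenness(graph: nx.Graph | BipartiteNetwork, normalized: bool = True) -> dict[str, float]:
    """Brandes betweenness centrality for an undirected, unweighted graph.

    For each source s, a BFS records shortest-path counts sigma and
    predecessor lists; dependencies delta are accumulated in reverse BFS
    order. Each unordered pair {s, t} is counted once (the undirected
    convention halves the accumulated totals). With ``normalized`` the raw
    value is divided by (N−1)(N−2)/2 where N is the node count of the whole
    graph; unreachable pairs contribute nothing. Graphs with fewer than
    three nodes have all-zero betweenness.
    """
    if isinstance(graph, BipartiteNetwork):
        graph = graph.to_networkx()
    nodes = list(graph.nodes)
    bc = {v: 0.0 for v in nodes}
    n = len(nodes)
    if n < 3:
        return bc
    for s in nodes:
        # single-source shortest paths (BFS)
        stack: list = []
        pred: dict = {v: [] for v in nodes}
        sigma = {v: 0.0 for v in nodes}
        dist = {v: -1 for v in nodes}
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in graph[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation
        delta = {v: 0.0 for v in nodes}
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += (sigma[v] / sigma[w]) * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    for v in bc:
        bc[v] /= 2.0  # each unordered pair counted from both endpoints
        if normalized:
            bc[v] /= (n - 1) * (n - 2) / 2.0
    return bc


# ---------------------------------------------------------------------------
# Topology records & screening
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TopologyRecord:
    node: str
    degree: int
    betweenness: float


def topology_records(network: BipartiteNetwork, side: str = "compound") -> list[TopologyRecord]:
    """Per-node degree and normalized betweenness for one side of the network."""
    g = network.to_networkx()
    deg = degree(g)
    bc = betweenness(g, normalized=True)
    nodes = network.compound_nodes if side == "compound" else network.target_nodes
    return [TopologyRecord(n, deg[n], bc[n]) for n in sorted(nodes)]


def read_topology_table(path: str | Path) -> list[TopologyRecord]:
    """Read a per-compound topology table: TSV with compound/betweenness/degree."""
    frame = pd.read_csv(path, sep="\t")
    frame.columns = [c.strip().lower() for c in frame.columns]
    name_col = next(c for c in frame.columns if "compound" in c or "node" in c)
    return [
        TopologyRecord(str(r[name_col]).strip(), int(r["degree"]), float(r["betweenness"]))
        for _, r in frame.iterrows()
    ]


@dataclass
class ScreeningResult:
    mean_degree: float
    mean_betweenness: float
    selected: list[str]  # sorted by degree descending, ties by name
    comparator: str = "gt"

    def __contains__(self, compound: str) -> bool:
        return compound in self.selected


def screen_compounds(records: list[TopologyRecord], comparator: str = "gt") -> ScreeningResult:
    """Select compounds whose degree AND betweenness exceed the means.

    Means are computed over the supplied (compound) records only. The
    default comparator is strict ``>``; duplicate records are ignored so
    the result is invariant to row order and duplication.
    """
    if comparator not in ("gt", "ge"):
        raise ValueError("comparator must be 'gt' or 'ge'")
    if not records:
        raise ValueError("need at least one compound record")
    unique = {r.node: r for r in records}
    recs = list(unique.values())
    mean_deg = sum(r.degree for r in recs) / len(recs)
    mean_bc = sum(r.betweenness for r in recs) / len(recs)
    if comparator == "gt":
        hits = [r for r in recs if r.degree > mean_deg and r.betweenness > mean_bc]
    else:
        hits = [r for r in recs if r.degree >= mean_deg and r.betweenness >= mean_bc]
    hits.sort(key=lambda r: (-r.degree, r.node))
    return ScreeningResult(mean_deg, mean_bc, [r.node for r in hits], comparator)


# ---------------------------------------------------------------------------
# PPI network & hub ranking
# ---------------------------------------------------------------------------

@dataclass
class PPINetwork:
    nodes: set[str]
    edges: set[frozenset[str]]
    excluded_free_nodes: set[str]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2 * self.n_edges / self.n_nodes if self.nodes else 0.0

    def degrees(self) -> dict[str, int]:
        out = {n: 0 for n in self.nodes}
        for e in self.edges:
            for v in e:
                out[v] += 1
        return out


def build_ppi(edge_list: EdgeList, member_set: set[str]) -> PPINetwork:
    """Restrict a PPI edge list to the candidate gene set.

    Members that end up with no edge inside the set are "free genes": they
    are excluded from the network but recorded, so node counts before and
    after exclusion stay auditable.
    """
    members = set(member_set)
    edges = {pair for pair in edge_list.pairs() if pair <= members}
    connected = {v for e in edges for v in e}
    free = members - connected
    if free:
        logger.info("excluded %d free genes: %s", len(free), sorted(free))
    net = PPINetwork(connected, edges, free)
    logger.info("PPI: %d nodes, %d edges, mean degree %.3f",
                net.n_nodes, net.n_edges, net.mean_degree)
    return net


def rank_hubs(ppi: PPINetwork, k: int = 6) -> list[tuple[str, int]]:
    """Top-k genes by PPI degree, alphabetical within ties.

    If the k-th degree is tied beyond position k, every tied gene is
    included (and the expansion logged), because a degree cut inside a tie
    would be arbitrary.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(ppi.degrees().items(), key=lambda kv: (-kv[1], kv[0]))
    if k >= len(ranked):
        if k > len(ranked):
            logger.warning("k=%d exceeds node count %d; returning all", k, len(ranked))
        return ranked
    cut_degree = ranked[k - 1][1]
    out = [kv for kv in ranked if kv[1] > cut_degree]
    ties = [kv for kv in ranked if kv[1] == cut_degree]
    out.extend(ties)
    if len(out) > k:
        logger.info("hub cut expanded from %d to %d by ties at degree %d",
                    k, len(out), cut_degree)
    return out


def realize_bipartite_degree_sequence(
    compound_degrees: dict[str, int], n_targets: int, target_prefix: str = "T"
) -> BipartiteNetwork:
    """Construct a bipartite graph realizing a compound-side degree sequence.

    Targets are given near-uniform capacities summing to the same edge
    total, and compounds (largest degree first) greedily connect to the
    targets with the most remaining capacity — the standard Gale–Ryser
    style realization. Raises if the sequence is not realizable on
    ``n_targets`` targets.
    """
    total = sum(compound_degrees.values())
    if max(compound_degrees.values(), default=0) > n_targets:
        raise ValueError("a compound degree exceeds the number of targets")
    if total < n_targets:
        raise ValueError("fewer edges than targets: some targets would be isolated")
    base, extra = divmod(total, n_targets)
    targets = [f"{target_prefix}{i + 1:02d}" for i in range(n_targets)]
    capacity = {t: base + (1 if i < extra else 0) for i, t in enumerate(targets)}
    edges: set[frozenset[str]] = set()
    for compound in sorted(compound_degrees, key=lambda c: -compound_degrees[c]):
        chosen = sorted(targets, key=lambda t: (-capacity[t], t))[: compound_degrees[compound]]
        if capacity[chosen[-1]] <= 0:
            raise ValueError("degree sequence not realizable with these capacities")
        for t in chosen:
            capacity[t] -= 1
            edges.add(frozenset((compound, t)))
    return BipartiteNetwork(set(compound_degrees), set(targets), edges)


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def export_network(network: BipartiteNetwork, sif_path: str | Path, attr_path: str | Path) -> None:
    """Write a SIF edge file plus a TSV node-attribute table."""
    g = network.to_networkx()
    deg = degree(g)
    bc = betweenness(g, normalized=True)
    with open(sif_path, "w", encoding="utf-8", newline="\n") as fh:
        for edge in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{edge[0]} ct {edge[1]}\n")
    rows = [
        {
            "node": n,
            "side": "compound" if n in network.compound_nodes else "target",
            "degree": deg[n],
            "betweenness": round(bc[n], 6),
        }
        for n in sorted(g.nodes)
    ]
    pd.DataFrame(rows).to_csv(attr_path, sep="\t", index=False)
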