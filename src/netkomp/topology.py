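"""Single-network topology: modules, global attributes, node/edge tables.

Module detection is greedy modularity maximization (Clauset–Newman–Moore)
on the unweighted, unsigned simple graph. Node roles follow the classic
within-module connectivity (Zi) / among-module connectivity (Pi) scheme:
``Zi`` is the z-score of a node's within-module degree relative to its
module, ``Pi = 1 - sum_m (k_im / k_i)^2`` is the participation coefficient,
and nodes are classified with the standard thresholds Zi = 2.5 and
Pi = 0.62 into module hubs, connectors, network hubs and peripherals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import CooccurrenceNetwork, NetworkCollection, ValidationError

logger = logging.getLogger(__name__)

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62

ROLES = ("module hub", "connector", "network hub", "peripheral")


@dataclass
class Partition:
    """Node → module assignment with its (unweighted) modularity Q."""

    assignment: dict[str, int]
    modularity_q: float = float("nan")

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, m in self.assignment.items():
            out.setdefault(m, []).append(node)
        return out

    def __len__(self) -> int:
        return len(self.assignment)


@dataclass
class NodeRoleRecord:
    node: str
    module: int
    zi: float
    pi: float
    role: str | None = None


def _unsigned_graph(net: CooccurrenceNetwork, positive_only: bool = False) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    for u, v, d in net.graph.edges(data=True):
        if positive_only and d.get("sign") == "negative":
            continue
        a, b = (u, v) if u < v else (v, u)
        g.add_edge(a, b)
    return g


def detect_modules(net: CooccurrenceNetwork, method: str = "greedy_modularity",
                   seed: int = 0, positive_only: bool = False) -> Partition:
    """Partition a network into modules by greedy modularity maximization.

    Runs on the unweighted, unsigned simple graph (negative edges count as
    present unless ``positive_only``); isolated nodes become singleton
    modules. Module IDs are consecutive integers ordered by decreasing
    module size, ties broken by the lexicographically smallest member, so
    the result is deterministic for a given graph. The ``module`` node
    attribute is set on the network and Q is stored on the partition.
    """
    if method != "greedy_modularity":
        raise ValidationError(f"unknown module detection method {method!r}")
    g = _unsigned_graph(net, positive_only=positive_only)
    if g.number_of_nodes() == 0:
        return Partition({}, float("nan"))
    isolates = sorted(nx.isolates(g))
    core = g.subgraph([n for n in g.nodes if n not in set(isolates)])
    if core.number_of_edges() > 0:
        comms = [set(c) for c in
                 nx.algorithms.community.greedy_modularity_communities(core)]
    else:
        comms = []
    comms.extend({n} for n in isolates)
    comms.sort(key=lambda c: (-len(c), min(c)))
    assignment = {node: m for m, comm in enumerate(comms) for node in sorted(comm)}
    part = Partition(assignment)
    part.modularity_q = modularity(net, part)
    for node, m in assignment.items():
        net.graph.nodes[node]["module"] = int(m)
    return part


def modularity(net: CooccurrenceNetwork, partition: Partition) -> float:
    """Unweighted Newman modularity Q of a partition.

    ``Q = sum_m (e_mm - a_m^2)`` with e_mm the fraction of edges inside
    module m and a_m the fraction of edge endpoints in m. An edgeless
    network has Q = 0 by convention (logged).
    """
    missing = set(net.graph.nodes) - set(partition.assignment)
    if missing:
        raise ValidationError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    g = _unsigned_graph(net)
    if g.number_of_edges() == 0:
        logger.info("modularity: edgeless network, Q = 0 by convention")
        return 0.0
    comms = [set(nodes) for nodes in partition.modules().values()]
    return float(nx.algorithms.community.modularity(g, comms, weight=None))


def global_attributes(net: CooccurrenceNetwork) -> dict[str, float]:
    """Global topological attributes of one network.

    Path length and diameter are unweighted and computed on the largest
    connected component; they (and the clustering means) are NaN when
    undefined (fewer than 2 nodes / no edges).
    """
    g = _unsigned_graph(net)
    v = g.number_of_nodes()
    e = g.number_of_edges()
    pos = sum(1 for _, _, d in net.graph.edges(data=True) if d.get("sign") == "positive")
    neg = e - pos
    nan = float("nan")
    out = {
        "node_count": float(v),
        "edge_count": float(e),
        "positive_edge_count": float(pos),
        "negative_edge_count": float(neg),
        "density": 2.0 * e / (v * (v - 1)) if v > 1 else nan,
        "average_degree": 2.0 * e / v if v > 0 else nan,
        "global_clustering": float(nx.transitivity(g)) if v > 0 else nan,
        "average_local_clustering": float(nx.average_clustering(g)) if v > 0 else nan,
    }
    if v <= 1 or e == 0:
        if v <= 1:
            logger.info("global_attributes: V <= 1, path metrics undefined")
        out["average_path_length"] = nan
        out["diameter"] = nan
    else:
        lcc = g.subgraph(max(nx.connected_components(g), key=lambda c: (len(c), sorted(c))))
        if lcc.number_of_nodes() > 1:
            out["average_path_length"] = float(nx.average_shortest_path_length(lcc))
            out["diameter"] = float(nx.diameter(lcc))
        else:
            out["average_path_length"] = nan
            out["diameter"] = nan
    out["connected_component_count"] = float(nx.number_connected_components(g)) if v else 0.0
    modules = nx.get_node_attributes(net.graph, "module")
    if len(modules) == len(net.graph.nodes) and v > 0:
        part = Partition({n: int(m) for n, m in modules.items()})
        out["modularity_Q"] = modularity(net, part)
    return out


def collect_attributes(collection: NetworkCollection) -> pd.DataFrame:
    """Merge :func:`global_attributes` of every network: property × network."""
    if not collection:
        raise ValidationError("collection is empty")
    cols = {label: global_attributes(net) for label, net in collection.items()}
    return pd.DataFrame(cols, columns=list(collection.labels))


def zi_pi(net: CooccurrenceNetwork, partition: Partition) -> list[NodeRoleRecord]:
    """Within-module connectivity Zi and participation coefficient Pi.

    For node i in module s with within-module degree k_is:
    ``Zi = (k_is - mean_s) / sd_s`` using the population sd of within-module
    degrees over module s (modules of size 1 or zero spread give Zi = 0);
    ``Pi = 1 - sum_m (k_im / k_i)^2`` with k_i the total degree (isolated
    nodes get Pi = 0). Degrees count all edges regardless of sign. The
    Zi/Pi node attributes are set on the network.
    """
    missing = set(net.graph.nodes) - set(partition.assignment)
    if missing:
        raise ValidationError(f"partition does not cover nodes: {sorted(missing)[:5]}")
    g = _unsigned_graph(net)
    assign = partition.assignment
    # within-module degree per node, and per-node degree split by target module
    within = {n: 0 for n in g.nodes}
    split: dict[str, dict[int, int]] = {n: {} for n in g.nodes}
    for u, v in g.edges:
        mu, mv = assign[u], assign[v]
        split[u][mv] = split[u].get(mv, 0) + 1
        split[v][mu] = split[v].get(mu, 0) + 1
        if mu == mv:
            within[u] += 1
            within[v] += 1
    stats: dict[int, tuple[float, float]] = {}
    for m, members in partition.modules().items():
        ks = np.array([within[n] for n in members], dtype=float)
        stats[m] = (float(ks.mean()), float(ks.std()))  # population sd
    records = []
    for n in sorted(g.nodes):
        m = assign[n]
        mean, sd = stats[m]
        zi = (within[n] - mean) / sd if sd > 0 else 0.0
        k = g.degree[n]
        pi = 1.0 - sum((c / k) ** 2 for c in split[n].values()) if k > 0 else 0.0
        records.append(NodeRoleRecord(node=n, module=m, zi=zi, pi=pi))
        net.graph.nodes[n]["Zi"] = zi
        net.graph.nodes[n]["Pi"] = pi
    return records


def classify_role(zi: float, pi: float) -> str:
    """Role of one node from its (Zi, Pi) pair.

    Module hub: Zi > 2.5 and Pi <= 0.62; connector: Zi <= 2.5 and
    Pi > 0.62; network hub: Zi > 2.5 and Pi > 0.62; peripheral: Zi <= 2.5
    and Pi < 0.62. The undefined boundary Zi <= 2.5, Pi == 0.62 is
    assigned peripheral.
    """
    if zi > ZI_THRESHOLD:
        return "module hub" if pi <= PI_THRESHOLD else "network hub"
    return "connector" if pi > PI_THRESHOLD else "peripheral"


def classify_roles(records: list[NodeRoleRecord],
                   net: CooccurrenceNetwork | None = None) -> list[NodeRoleRecord]:
    """Fill the ``role`` field of Zi/Pi records (and node attributes)."""
    for rec in records:
        rec.role = classify_role(rec.zi, rec.pi)
        if rec.pi == PI_THRESHOLD and rec.zi <= ZI_THRESHOLD:
            logger.info("node %s sits on the Pi = %.2f boundary; classified peripheral",
                        rec.node, PI_THRESHOLD)
        if net is not None and rec.node in net.graph.nodes:
            net.graph.nodes[rec.node]["role"] = rec.role
    return records


def node_table(net: CooccurrenceNetwork, normalized_betweenness: bool = False
               ) -> pd.DataFrame:
    """Per-node property table: taxonomy, module, degree, betweenness, Zi/Pi/role.

    Betweenness is unweighted shortest-path betweenness, unnormalized by
    default. Zi/Pi/role columns are filled from node attributes when module
    detection and role classification have run; otherwise left NaN/empty.
    """
    g = _unsigned_graph(net)
    btw = nx.betweenness_centrality(g, normalized=normalized_betweenness)
    rows = []
    for n in sorted(net.graph.nodes):
        d = net.graph.nodes[n]
        row = {"node": n}
        for rank in ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species"):
            if rank in d:
                row[rank] = d[rank]
        row.update({
            "module": d.get("module", pd.NA),
            "degree": g.degree[n],
            "betweenness": btw[n],
            "Zi": d.get("Zi", float("nan")),
            "Pi": d.get("Pi", float("nan")),
            "role": d.get("role", ""),
        })
        rows.append(row)
    return pd.DataFrame(rows).set_index("node")


def edge_table(net: CooccurrenceNetwork) -> pd.DataFrame:
    """Per-edge property table with canonical endpoint order (node1 < node2)."""
    from .core_io import network_edge_table
    return network_edge_table(net)
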