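"""Cross-network comparisons.

Everything here consumes a :class:`~netkomp.core_io.NetworkCollection`:
node/edge presence matrices and their Venn region counts, extraction of
intersection (or any region's) edges into a new network, per-edge
phylogenetic distances with an ANOVA + Duncan letters test, and the
taxon-source composition of edges (which rank-label pairs the endpoints of
positive/negative edges come from).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core_io import (CooccurrenceNetwork, NetworkCollection, ValidationError,
                      edge_key)
from .stats import PosthocResult, anova_duncan

logger = logging.getLogger(__name__)

EDGE_SEP = " -- "


@dataclass
class PresenceMatrix:
    """Binary item × network incidence.

    Items are feature IDs (node comparison) or canonical edge keys rendered
    as ``"node1 -- node2"`` (edge comparison; with sign matching,
    ``"node1 -- node2 -- sign"``). No all-zero rows occur by construction.
    """

    matrix: pd.DataFrame  # items × networks, values {0, 1}

    @property
    def items(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def networks(self) -> list[str]:
        return list(self.matrix.columns)


def node_comp(collection: NetworkCollection) -> PresenceMatrix:
    """Presence/absence of every node across the collection's networks."""
    if len(collection) < 2:
        raise ValidationError("node_comp needs at least 2 networks")
    union = sorted(set().union(*(set(net.graph.nodes) for net in collection.values())))
    data = {label: [1 if n in net.graph.nodes else 0 for n in union]
            for label, net in collection.items()}
    return PresenceMatrix(pd.DataFrame(data, index=union, columns=collection.labels))


def edge_comp(collection: NetworkCollection, match_sign: bool = False) -> PresenceMatrix:
    """Presence/absence of every canonical edge across networks.

    By default edges match on their endpoint pair only; ``match_sign=True``
    additionally requires equal sign.
    """
    if len(collection) < 2:
        raise ValidationError("edge_comp needs at least 2 networks")
    def keys(net: CooccurrenceNetwork) -> set[str]:
        out = set()
        for (a, b), d in net.edges(data=True):
            k = f"{a}{EDGE_SEP}{b}"
            if match_sign:
                k += f"{EDGE_SEP}{d.get('sign')}"
            out.add(k)
        return out
    sets = {label: keys(net) for label, net in collection.items()}
    union = sorted(set().union(*sets.values()))
    data = {label: [1 if k in s else 0 for k in union] for label, s in sets.items()}
    return PresenceMatrix(pd.DataFrame(data, index=union, columns=collection.labels))


def venn_counts(pm: PresenceMatrix) -> dict[frozenset, int]:
    """Count items in every non-empty membership region.

    Keys are frozensets of the network labels an item belongs to; counts
    over all regions sum to the number of items. With more than 5 networks
    the counts are still exact, only a Venn diagram would be unreadable.
    """
    if len(pm.networks) < 2:
        raise ValidationError("venn_counts needs at least 2 networks")
    if len(pm.networks) > 5:
        logger.info("venn_counts: %d networks; counts only, no diagram layout",
                    len(pm.networks))
    counts: dict[frozenset, int] = {}
    labels = pm.networks
    for _, row in pm.matrix.iterrows():
        sig = frozenset(l for l in labels if row[l] == 1)
        if sig:
            counts[sig] = counts.get(sig, 0) + 1
    return counts


def venn_counts_table(pm: PresenceMatrix) -> pd.DataFrame:
    """Venn regions as a table: one row per region, labels joined by '&'."""
    counts = venn_counts(pm)
    labels = pm.networks
    rows = []
    for r in range(1, len(labels) + 1):
        for combo in combinations(labels, r):
            sig = frozenset(combo)
            rows.append({"region": "&".join(combo), "count": counts.get(sig, 0)})
    return pd.DataFrame(rows)


def subset_network(collection: NetworkCollection,
                   region: str | frozenset = "intersection") -> CooccurrenceNetwork:
    """Extract the edges of one Venn region into a new network.

    ``region="intersection"`` keeps edges present in every network; a
    frozenset (or set) of labels keeps edges present in exactly those
    networks and absent from the rest. Edge attributes are copied from the
    first collection member containing the edge; nodes are the endpoints of
    the kept edges.
    """
    if not collection:
        raise ValidationError("collection is empty")
    labels = collection.labels
    edge_sets = {label: net.edge_keys() for label, net in collection.items()}
    if region == "intersection":
        wanted = set.intersection(*edge_sets.values())
        region_desc = "intersection"
    else:
        sig = frozenset(region)
        unknown = sig - set(labels)
        if unknown:
            raise ValidationError(f"unknown network labels in region: {sorted(unknown)}")
        if not sig:
            raise ValidationError("region signature is empty")
        wanted = {e for e in set().union(*edge_sets.values())
                  if frozenset(l for l in labels if e in edge_sets[l]) == sig}
        region_desc = "&".join(sorted(sig))
    net = CooccurrenceNetwork(provenance={"operation": "subset_network",
                                          "region": region_desc,
                                          "source_networks": ",".join(labels)})
    if not wanted:
        logger.warning("subset_network: region %s is empty", region_desc)
        return net
    for a, b in sorted(wanted):
        donor_label = next(l for l in labels if (a, b) in edge_sets[l])
        donor = collection[donor_label]
        for n in (a, b):
            net.add_node(n, **dict(donor.graph.nodes[n]))
        d = dict(donor.edge_data(a, b))
        w = d.pop("weight")
        d.pop("sign", None)
        net.add_edge(a, b, weight=w, **d)
    return net


def edge_node_distance(collection: NetworkCollection, dis_matrix: pd.DataFrame,
                       group_by_sign: bool = False) -> pd.DataFrame:
    """Distance between the two endpoints of every edge, per network.

    ``dis_matrix`` is any symmetric feature × feature matrix (patristic
    distances, niche overlap, ...). Edges whose endpoints are missing from
    the matrix are dropped and logged. Returns one row per (network, edge)
    with columns network, sign, node1, node2, distance.
    """
    if list(dis_matrix.index) != list(dis_matrix.columns) or \
            not np.allclose(dis_matrix.values, dis_matrix.values.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric with matching names")
    names = set(dis_matrix.index)
    rows = []
    dropped = 0
    for label, net in collection.items():
        for (a, b), d in sorted(net.edges(data=True)):
            if a not in names or b not in names:
                dropped += 1
                continue
            rows.append({"network": label,
                         "sign": d.get("sign") if group_by_sign else "",
                         "node1": a, "node2": b,
                         "distance": float(dis_matrix.at[a, b])})
    if dropped:
        logger.warning("edge_node_distance: dropped %d edges with endpoints "
                       "missing from the distance matrix", dropped)
    return pd.DataFrame(rows, columns=["network", "sign", "node1", "node2", "distance"])


def edge_distance_test(table: pd.DataFrame, alpha: float = 0.05,
                       posthoc: str = "duncan") -> PosthocResult:
    """ANOVA + Duncan letters over the network (× sign) distance groups."""
    if table.empty:
        raise ValidationError("edge distance table is empty")
    has_sign = "sign" in table.columns and (table["sign"] != "").any()
    groups = (table["network"] + " " + table["sign"]).str.strip() if has_sign \
        else table["network"]
    return anova_duncan(table["distance"], groups, alpha=alpha, posthoc=posthoc)


def edge_tax_comp(collection: NetworkCollection, rank: str = "Phylum",
                  sign: str = "positive") -> pd.DataFrame:
    """Taxon-source composition of edges: rank-label pair × network ratios.

    For each network, edges of the requested sign are tallied by the
    unordered pair of taxonomy labels their endpoints carry at ``rank``
    (missing labels grouped as "unclassified"); each count is divided by
    the total number of edges of that sign in that network. A network with
    no such edges gets NaN ratios (with a warning).
    """
    if sign not in ("positive", "negative"):
        raise ValidationError("sign must be 'positive' or 'negative'")
    per_net: dict[str, dict[tuple[str, str], int]] = {}
    totals: dict[str, int] = {}
    for label, net in collection.items():
        tally: dict[tuple[str, str], int] = {}
        total = 0
        for (a, b), d in net.edges(data=True):
            if d.get("sign") != sign:
                continue
            total += 1
            ta = str(net.graph.nodes[a].get(rank, "") or "unclassified")
            tb = str(net.graph.nodes[b].get(rank, "") or "unclassified")
            ta = ta if ta else "unclassified"
            tb = tb if tb else "unclassified"
            pair = (ta, tb) if ta <= tb else (tb, ta)
            tally[pair] = tally.get(pair, 0) + 1
        if total == 0:
            logger.warning("edge_tax_comp: network %r has no %s edges; ratios NaN",
                           label, sign)
        per_net[label] = tally
        totals[label] = total
    pairs = sorted(set().union(*(set(t) for t in per_net.values())) or set())
    index = [f"{a}{EDGE_SEP}{b}" for a, b in pairs]
    data = {}
    for label in collection.labels:
        t = totals[label]
        col = [per_net[label].get(p, 0) / t if t > 0 else float("nan") for p in pairs]
        data[label] = col
    return pd.DataFrame(data, index=index, columns=collection.labels)
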