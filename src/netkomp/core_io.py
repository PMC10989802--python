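"""Core data model and file plumbing for co-occurrence network analysis.

The toolkit revolves around three containers:

* :class:`FeatureTable` — a feature (OTU/ASV/species) × sample abundance
  matrix together with per-feature taxonomy, per-sample metadata and an
  optional symmetric feature–feature distance matrix (e.g. patristic
  distances from a phylogenetic tree), all kept name-consistent.
* :class:`CooccurrenceNetwork` — a signed, weighted, undirected graph whose
  nodes are features and whose edges are inferred associations.
* :class:`NetworkCollection` — an ordered label → network mapping, the unit
  every cross-network comparison operates on.

All tabular IO is plain TSV (tab-separated, UTF-8, ``.`` decimal); trees are
newick; networks export to GraphML/GEXF (Gephi-compatible) or a flat
edge-TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical taxonomy ranks, kingdom down to species
TAXONOMY_RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus", "Species")

EXPORT_FORMATS = ("graphml", "gexf", "edge-tsv")


class ValidationError(ValueError):
    """Input violates a documented contract (duplicate IDs, bad shape...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending cell."""


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical edge key: the two endpoint IDs in lexicographic order."""
    if u == v:
        raise ValidationError(f"self-loop not allowed: {u!r}")
    return (u, v) if u < v else (v, u)


class CooccurrenceNetwork:
    """Signed weighted undirected graph of feature associations.

    Thin wrapper around :class:`networkx.Graph` that enforces canonical
    edge keys (lexicographic endpoint order, no self-loops) and keeps the
    ``sign`` edge attribute consistent with the sign of ``weight``.
    ``provenance`` records how the network was built (method, parameters,
    source group label).
    """

    def __init__(self, provenance: Mapping | None = None):
        self.graph = nx.Graph()
        self.provenance: dict = dict(provenance or {})

    # -- construction -------------------------------------------------
    def add_node(self, node: str, **attrs) -> None:
        self.graph.add_node(node, **attrs)

    def add_edge(self, u: str, v: str, weight: float, p: float | None = None,
                 p_adj: float | None = None, **attrs) -> None:
        a, b = edge_key(u, v)
        data = {"weight": float(weight),
                "sign": "positive" if weight > 0 else "negative"}
        if p is not None:
            data["p"] = float(p)
        if p_adj is not None:
            data["p_adj"] = float(p_adj)
        data.update(attrs)
        self.graph.add_edge(a, b, **data)

    # -- access --------------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    def edge_keys(self) -> set[tuple[str, str]]:
        return {edge_key(u, v) for u, v in self.graph.edges}

    def edges(self, data: bool = False) -> Iterator:
        for u, v, d in self.graph.edges(data=True):
            k = edge_key(u, v)
            yield (k, d) if data else k

    def edge_data(self, u: str, v: str) -> dict:
        return self.graph.edges[u, v]

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    @property
    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def edge_count(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "CooccurrenceNetwork":
        out = CooccurrenceNetwork(self.provenance)
        out.graph = self.graph.copy()
        return out

    def validate(self) -> None:
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValidationError(f"self-loop on {u!r}")
            if "weight" not in d or "sign" not in d:
                raise ValidationError(f"edge {(u, v)} missing weight/sign")
            want = "positive" if d["weight"] > 0 else "negative"
            if d["sign"] != want:
                raise ValidationError(f"edge {(u, v)}: sign inconsistent with weight")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<CooccurrenceNetwork {self.node_count} nodes, "
                f"{self.edge_count} edges, provenance={self.provenance}>")


class NetworkCollection(dict):
    """Ordered ``label -> CooccurrenceNetwork`` map (insertion order kept)."""

    def __setitem__(self, label: str, net: CooccurrenceNetwork) -> None:
        if not isinstance(label, str) or not label:
            raise ValidationError("network labels must be non-empty strings")
        super().__setitem__(label, net)

    @property
    def labels(self) -> list[str]:
        return list(self.keys())


@dataclass
class FeatureTable:
    """Abundance matrix plus aligned taxonomy, metadata and distances.

    ``abundance`` is feature × sample with non-negative entries;
    ``taxonomy`` is feature × rank (missing ranks stored as empty strings);
    ``metadata`` is sample × variable (numeric abiotic factors and/or a
    categorical group column); ``feature_distance`` is a symmetric
    feature × feature matrix with zero diagonal.
    """

    abundance: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None
    feature_distance: pd.DataFrame | None = None

    @property
    def features(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def subset_features(self, features: Iterable[str]) -> "FeatureTable":
        keep = [f for f in self.abundance.index if f in set(features)]
        return FeatureTable(
            abundance=self.abundance.loc[keep],
            taxonomy=self.taxonomy.loc[keep] if self.taxonomy is not None else None,
            metadata=self.metadata,
            feature_distance=(self.feature_distance.loc[keep, keep]
                              if self.feature_distance is not None else None),
        )

    def subset_samples(self, samples: Iterable[str]) -> "FeatureTable":
        keep = [s for s in self.abundance.columns if s in set(samples)]
        return FeatureTable(
            abundance=self.abundance[keep],
            taxonomy=self.taxonomy,
            metadata=self.metadata.loc[keep] if self.metadata is not None else None,
            feature_distance=self.feature_distance,
        )

    def validate(self) -> None:
        ab = self.abundance
        if ab.index.duplicated().any():
            raise ValidationError("duplicate feature IDs in abundance")
        if ab.columns.duplicated().any():
            raise ValidationError("duplicate sample IDs in abundance")
        if (ab.values < 0).any():
            raise ValidationError("abundance contains negative values")
        if self.feature_distance is not None:
            _check_symmetric_distance(self.feature_distance)


def _check_symmetric_distance(d: pd.DataFrame) -> None:
    if list(d.index) != list(d.columns):
        raise ValidationError("distance matrix rows/columns disagree")
    vals = d.values.astype(float)
    if not np.allclose(vals, vals.T, atol=1e-9):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(vals), 0.0, atol=1e-9):
        raise ValidationError("distance matrix diagonal is not zero")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv_matrix(path, what: str, numeric: bool = True) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    cols = header[1:]
    if len(set(cols)) != len(cols):
        dup = sorted({c for c in cols if cols.count(c) > 1})
        raise ValidationError(f"duplicate column IDs in {what}: {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dup = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"duplicate row IDs in {what}: {dup}")
    if not numeric:
        return df
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.strip() != "")
        if bad.any():
            row = df.index[bad.argmax()]
            raise ParseError(f"non-numeric cell in {what} at row {row!r}, "
                             f"column {col!r}: {df.loc[row, col]!r}")
        if converted.isna().any():
            row = df.index[converted.isna().argmax()]
            raise ParseError(f"empty cell in {what} at row {row!r}, column {col!r}")
        out[col] = converted.astype(float)
    return out


def read_abundance(path) -> pd.DataFrame:
    """Read a feature × sample abundance TSV (first column = feature IDs)."""
    df = _read_tsv_matrix(path, "abundance table")
    if (df.values < 0).any():
        i, j = np.argwhere(df.values < 0)[0]
        raise ValidationError(f"negative abundance at row {df.index[i]!r}, "
                              f"column {df.columns[j]!r}")
    return df


def write_abundance(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a feature × rank taxonomy TSV; missing ranks become ''."""
    df = _read_tsv_matrix(path, "taxonomy table", numeric=False)
    return df.fillna("")


def read_metadata(path) -> pd.DataFrame:
    """Read a sample × variable metadata TSV; numeric columns are coerced."""
    df = _read_tsv_matrix(path, "metadata table", numeric=False)
    out = {}
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        out[col] = df[col] if converted.isna().any() else converted
    return pd.DataFrame(out, index=df.index)


def read_distance_matrix(path) -> pd.DataFrame:
    """Read any symmetric feature × feature distance TSV."""
    df = _read_tsv_matrix(path, "distance matrix")
    _check_symmetric_distance(df)
    return df


def read_tree_distances(path) -> pd.DataFrame:
    """Patristic (branch-length path) distances between all tips of a newick tree.

    Every non-root edge must carry an explicit branch length; no default is
    substituted. Duplicate tip labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.utility.error.DataParseError as exc:
        if "Multiple occurrences" in str(exc) or "duplicate" in str(exc).lower():
            raise ValidationError(f"duplicate tip labels in tree: {exc}") from exc
        raise ParseError(f"could not parse newick tree: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lab is None for lab in labels):
        raise ParseError("tree has unlabeled tips")
    if len(set(labels)) != len(labels):
        dup = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate tip labels: {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:  # root edge; a length here is meaningless
            continue
        if edge.length is None:
            raise ParseError("tree contains an edge without a branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    order = sorted(labels)
    mat = np.zeros((len(order), len(order)))
    for i, a in enumerate(order):
        for j in range(i + 1, len(order)):
            d = pdm.patristic_distance(taxa[a], taxa[order[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=order, columns=order)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def assemble_feature_table(abundance: pd.DataFrame,
                           taxonomy: pd.DataFrame | None = None,
                           metadata: pd.DataFrame | None = None,
                           feature_distance: pd.DataFrame | None = None,
                           ) -> FeatureTable:
    """Trim all parts to the shared feature and sample ID sets.

    Features must appear in every supplied feature-indexed part (abundance,
    taxonomy, distance); samples in abundance and metadata. Dropped counts
    are logged; an empty intersection is an error.
    """
    features = set(abundance.index)
    if taxonomy is not None:
        features &= set(taxonomy.index)
    if feature_distance is not None:
        features &= set(feature_distance.index)
    samples = set(abundance.columns)
    if metadata is not None:
        samples &= set(metadata.index)
    if not features:
        raise ValidationError("no feature IDs shared across inputs")
    if not samples:
        raise ValidationError("no sample IDs shared across inputs")

    feat_order = [f for f in abundance.index if f in features]
    samp_order = [s for s in abundance.columns if s in samples]
    for name, part, n_all in (("abundance features", abundance.index, feat_order),
                              ("abundance samples", abundance.columns, samp_order)):
        dropped = len(part) - len(n_all)
        if dropped:
            logger.info("assemble: dropped %d %s", dropped, name)
    if taxonomy is not None and len(taxonomy) != len(feat_order):
        logger.info("assemble: dropped %d taxonomy features",
                    len(taxonomy) - len(feat_order))
    if metadata is not None and len(metadata) != len(samp_order):
        logger.info("assemble: dropped %d metadata samples",
                    len(metadata) - len(samp_order))

    table = FeatureTable(
        abundance=abundance.loc[feat_order, samp_order].astype(float),
        taxonomy=taxonomy.loc[feat_order].fillna("") if taxonomy is not None else None,
        metadata=metadata.loc[samp_order] if metadata is not None else None,
        feature_distance=(feature_distance.loc[feat_order, feat_order]
                          if feature_distance is not None else None),
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

def _clean_attrs(d: Mapping) -> dict:
    """Keep only scalar, non-missing attributes (GraphML/GEXF-serializable)."""
    out = {}
    for k, v in d.items():
        if v is None:
            continue
        if isinstance(v, float) and math.isnan(v):
            continue
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        if isinstance(v, (str, int, float, bool)):
            out[k] = v
    return out


def _to_plain_graph(net: CooccurrenceNetwork) -> nx.Graph:
    g = nx.Graph()
    for n, d in net.graph.nodes(data=True):
        g.add_node(n, **_clean_attrs(d))
    for u, v, d in net.graph.edges(data=True):
        a, b = edge_key(u, v)
        g.add_edge(a, b, **_clean_attrs(d))
    return g


def network_edge_table(net: CooccurrenceNetwork) -> pd.DataFrame:
    """One canonical edge per row with its attributes (node1 < node2)."""
    rows = []
    for (a, b), d in sorted(net.edges(data=True)):
        rows.append({"node1": a, "node2": b, "weight": d.get("weight"),
                     "sign": d.get("sign"), "p": d.get("p", float("nan")),
                     "p_adj": d.get("p_adj", float("nan"))})
    return pd.DataFrame(rows, columns=["node1", "node2", "weight", "sign", "p", "p_adj"])


def export_network(net: CooccurrenceNetwork, path, format: str = "graphml") -> None:
    """Write a network as GraphML, GEXF (both Gephi-readable) or edge-TSV."""
    if format not in EXPORT_FORMATS:
        raise ValueError(f"unknown format {format!r}; choose one of {EXPORT_FORMATS}")
    if format in ("graphml", "gexf") and net.node_count == 0:
        raise ValidationError(f"refusing to write an empty network as {format}")
    if format == "graphml":
        nx.write_graphml(_to_plain_graph(net), str(path))
    elif format == "gexf":
        nx.write_gexf(_to_plain_graph(net), str(path))
    else:
        network_edge_table(net).to_csv(path, sep="\t", index=False)


def read_network(path, format: str | None = None) -> CooccurrenceNetwork:
    """Read a network previously written by :func:`export_network`."""
    p = str(path)
    if format is None:
        if p.endswith(".graphml"):
            format = "graphml"
        elif p.endswith(".gexf"):
            format = "gexf"
        else:
            format = "edge-tsv"
    net = CooccurrenceNetwork()
    if format in ("graphml", "gexf"):
        g = nx.read_graphml(p) if format == "graphml" else nx.read_gexf(p)
        for n, d in g.nodes(data=True):
            d = {k: v for k, v in d.items() if k != "label"}
            net.add_node(str(n), **d)
        for u, v, d in g.edges(data=True):
            d = dict(d)
            d.pop("id", None)
            w = float(d.pop("weight"))
            d.pop("sign", None)
            net.add_edge(str(u), str(v), weight=w, **d)
    elif format == "edge-tsv":
        df = pd.read_csv(p, sep="\t", dtype={"node1": str, "node2": str})
        for _, row in df.iterrows():
            kw = {}
            if "p" in df.columns and not pd.isna(row["p"]):
                kw["p"] = float(row["p"])
            if "p_adj" in df.columns and not pd.isna(row["p_adj"]):
                kw["p_adj"] = float(row["p_adj"])
            net.add_edge(row["node1"], row["node2"], weight=float(row["weight"]), **kw)
    else:
        raise ValueError(f"unknown format {format!r}; choose one of {EXPORT_FORMATS}")
    return net
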