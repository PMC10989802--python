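"""Per-sample subnetworks and their topological properties.

Each sample induces a subnetwork of its group's network on the features it
actually contains (abundance > 0). The global attributes of all these
subnetworks form a sample × property table that can be correlated with
sample-level metadata (abiotic factors, diversity) exactly like module
eigengenes.
"""

from __future__ import annotations

import logging

import pandas as pd

from .core_io import CooccurrenceNetwork, FeatureTable, NetworkCollection, ValidationError
from .module_analysis import CorrelationGrid, env_correlation
from .topology import global_attributes

logger = logging.getLogger(__name__)


def sample_subnetwork(net: CooccurrenceNetwork, table: FeatureTable, sample: str,
                      min_abund: float = 0.0) -> CooccurrenceNetwork:
    """Induced subgraph on the features present in one sample.

    Presence means abundance strictly greater than ``min_abund`` (default
    0, i.e. any non-zero count). Node and edge attributes are inherited;
    provenance records the parent network and the sample.
    """
    if sample not in table.abundance.columns:
        raise ValidationError(f"unknown sample {sample!r}")
    col = table.abundance[sample]
    present = set(col.index[col > min_abund])
    keep = [n for n in net.graph.nodes if n in present]
    sub = CooccurrenceNetwork(provenance={**net.provenance,
                                          "operation": "sample_subnetwork",
                                          "sample": sample})
    sub.graph = net.graph.subgraph(keep).copy()
    return sub


def subnet_properties(collection: NetworkCollection, table: FeatureTable,
                      group_column: str, min_abund: float = 0.0) -> pd.DataFrame:
    """Global attributes of every sample's subnetwork (sample × property).

    Each sample is matched to the network labelled with its group; samples
    whose group has no network in the collection are skipped with a
    warning. With a single-network collection and no usable group column,
    all samples are induced from that network.
    """
    if table.metadata is not None and group_column in table.metadata.columns:
        groups = table.metadata[group_column].astype(str)
    elif len(collection) == 1:
        only = collection.labels[0]
        groups = pd.Series(only, index=table.samples)
    else:
        raise ValidationError(f"metadata has no column {group_column!r}")
    rows = {}
    for sample in table.samples:
        label = groups.get(sample)
        if label not in collection:
            logger.warning("subnet_properties: sample %r group %r has no network; skipped",
                           sample, label)
            continue
        sub = sample_subnetwork(collection[label], table, sample, min_abund=min_abund)
        rows[sample] = global_attributes(sub)
    return pd.DataFrame(rows).T


def subnet_env_correlation(props: pd.DataFrame, metadata: pd.DataFrame,
                           variables: list[str] | None = None) -> CorrelationGrid:
    """Correlate subnetwork properties with numeric metadata variables."""
    return env_correlation(props.T, metadata, variables=variables)
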