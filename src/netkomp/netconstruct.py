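"""Co-occurrence network construction.

Networks are built either per sample-group (one network per level of a
categorical metadata column) or per construction method (Pearson / Spearman
correlation at chosen thresholds, or Bray-Curtis similarity). Correlation
edges are kept when ``|r| >= r_threshold`` and the (optionally BH-adjusted)
two-sided p-value falls below ``p_threshold``; Bray-Curtis edges when the
similarity ``1 - dissimilarity`` reaches the threshold. Edge weight is the
coefficient itself and the edge sign follows its sign, so similarity
networks contain only positive edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import CooccurrenceNetwork, FeatureTable, NetworkCollection, ValidationError

logger = logging.getLogger(__name__)

METHODS = ("pearson", "spearman", "braycurtis")


@dataclass
class ConstructionSpec:
    """Parameters of one network construction.

    ``min_prevalence`` is the fraction of samples in which a feature must be
    non-zero; ``min_mean_relabund`` the minimum mean relative abundance.
    ``p_threshold`` and ``p_adjust`` are ignored for the Bray-Curtis method.
    """

    method: str = "pearson"
    r_threshold: float = 0.6
    p_threshold: float = 0.05
    p_adjust: str = "BH"
    min_prevalence: float = 0.1
    min_mean_relabund: float = 0.0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        if not 0.0 <= self.r_threshold <= 1.0:
            raise ValidationError("r_threshold must be in [0, 1]")
        if not 0.0 < self.p_threshold <= 1.0:
            raise ValidationError("p_threshold must be in (0, 1]")
        if self.p_adjust not in ("BH", "none"):
            raise ValidationError("p_adjust must be 'BH' or 'none'")
        if not 0.0 <= self.min_prevalence <= 1.0:
            raise ValidationError("min_prevalence must be in [0, 1]")
        if self.min_mean_relabund < 0:
            raise ValidationError("min_mean_relabund must be >= 0")


def filter_features(table: FeatureTable, spec: ConstructionSpec) -> FeatureTable:
    """Drop sparse / rare features before network construction.

    Retains features with prevalence >= ``min_prevalence`` and mean relative
    abundance (per-sample proportions averaged over samples) >=
    ``min_mean_relabund``.
    """
    ab = table.abundance
    prevalence = (ab.values > 0).mean(axis=1)
    totals = ab.values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, ab.values / totals, 0.0)
    mean_rel = rel.mean(axis=1)
    keep = (prevalence >= spec.min_prevalence) & (mean_rel >= spec.min_mean_relabund)
    kept = [f for f, k in zip(ab.index, keep) if k]
    if not kept:
        raise ValidationError(
            "no features pass the prevalence/abundance filter; "
            "loosen min_prevalence or min_mean_relabund")
    logger.info("filter_features: retained %d / %d features", len(kept), len(ab))
    return table.subset_features(kept)


def correlate(abundance: pd.DataFrame, method: str = "pearson"
              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs correlation coefficients and two-sided p-values.

    ``abundance`` is feature × sample. Pearson is computed directly;
    Spearman is Pearson on within-feature ranks (ties get average ranks).
    p-values come from the t statistic ``t = r * sqrt((n-2) / (1-r^2))``
    with ``n - 2`` degrees of freedom. Features with zero variance get
    r = 0, p = 1 against everything (their diagonal stays r = 1).
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"correlation method must be pearson/spearman, got {method!r}")
    X = abundance.values.astype(float)
    n = X.shape[1]
    if n < 4:
        raise ValidationError(f"need at least 4 samples for correlation, got {n}")
    if method == "spearman":
        X = np.apply_along_axis(sps.rankdata, 1, X)
    sd = X.std(axis=1)
    zero_var = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.sqrt((Xc * Xc).sum(axis=1))
    denom[zero_var] = 1.0  # avoid 0/0; rows zeroed below
    R = (Xc / denom[:, None]) @ (Xc / denom[:, None]).T
    np.clip(R, -1.0, 1.0, out=R)
    # snap numerically perfect correlations so boundary thresholds behave
    R[np.abs(R) >= 1.0 - 1e-12] = np.sign(R[np.abs(R) >= 1.0 - 1e-12])
    R[zero_var, :] = 0.0
    R[:, zero_var] = 0.0
    np.fill_diagonal(R, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = R * np.sqrt((n - 2) / (1.0 - R * R))
    P = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    P[np.isnan(P)] = 0.0  # |r| == 1 -> t infinite -> p = 0
    P[zero_var, :] = 1.0
    P[:, zero_var] = 1.0
    np.fill_diagonal(P, 0.0)
    idx = abundance.index
    return (pd.DataFrame(R, index=idx, columns=idx),
            pd.DataFrame(P, index=idx, columns=idx))


def _adjust_upper_triangle(p: pd.DataFrame, how: str) -> pd.DataFrame:
    """BH-adjust the upper-triangle p-values as one family; mirror back."""
    if how == "none":
        return p.copy()
    vals = p.values
    iu = np.triu_indices(len(p), k=1)
    flat = vals[iu]
    if flat.size:
        adj = multipletests(flat, method="fdr_bh")[1]
    else:
        adj = flat
    out = np.zeros_like(vals)
    out[iu] = adj
    out = out + out.T
    return pd.DataFrame(out, index=p.index, columns=p.columns)


def correlation_network(table: FeatureTable, spec: ConstructionSpec
                        ) -> CooccurrenceNetwork:
    """Build a correlation-thresholded network from a feature table.

    Applies :func:`filter_features`, correlates all pairs, BH-adjusts the
    pooled upper-triangle p-values (unless ``p_adjust='none'``), and keeps
    an edge when ``|r| >= r_threshold`` and ``p_adj < p_threshold``.
    Features that end up without edges are retained as isolated nodes.
    """
    if spec.method not in ("pearson", "spearman"):
        raise ValidationError("correlation_network requires method pearson/spearman")
    table = filter_features(table, spec)
    r, p = correlate(table.abundance, spec.method)
    p_adj = _adjust_upper_triangle(p, spec.p_adjust)
    net = CooccurrenceNetwork(provenance={
        "method": spec.method, "r_threshold": spec.r_threshold,
        "p_threshold": spec.p_threshold, "p_adjust": spec.p_adjust,
        "min_prevalence": spec.min_prevalence,
        "min_mean_relabund": spec.min_mean_relabund,
    })
    _add_nodes_with_taxonomy(net, table)
    feats = list(table.features)
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            rv = r.at[a, b]
            if abs(rv) >= spec.r_threshold and p_adj.at[a, b] < spec.p_threshold:
                net.add_edge(a, b, weight=rv, p=p.at[a, b], p_adj=p_adj.at[a, b])
    return net


def braycurtis_network(table: FeatureTable, spec: ConstructionSpec
                       ) -> CooccurrenceNetwork:
    """Build a similarity network from pairwise Bray-Curtis indices.

    For features i, j the similarity is ``1 - sum|x_i - x_j| / sum(x_i + x_j)``
    over samples, on raw abundances; an edge is kept when the similarity
    reaches ``r_threshold``. All edges are positive. A pair whose profiles
    are both all-zero has undefined dissimilarity; its similarity is set to
    0 and logged.
    """
    if spec.method != "braycurtis":
        raise ValidationError("braycurtis_network requires method 'braycurtis'")
    table = filter_features(table, spec)
    X = table.abundance.values.astype(float)
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    zero_den = den == 0
    if zero_den[np.triu_indices(len(X), k=1)].any():
        logger.warning("braycurtis: %d pairs with all-zero profiles; similarity set to 0",
                       int(zero_den[np.triu_indices(len(X), k=1)].sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(zero_den, 0.0, 1.0 - num / np.where(zero_den, 1.0, den))
    net = CooccurrenceNetwork(provenance={
        "method": "braycurtis", "r_threshold": spec.r_threshold,
        "min_prevalence": spec.min_prevalence,
        "min_mean_relabund": spec.min_mean_relabund,
    })
    _add_nodes_with_taxonomy(net, table)
    feats = list(table.features)
    for i, a in enumerate(feats):
        for j in range(i + 1, len(feats)):
            if sim[i, j] >= spec.r_threshold:
                net.add_edge(a, feats[j], weight=sim[i, j])
    return net


def build_network(table: FeatureTable, spec: ConstructionSpec) -> CooccurrenceNetwork:
    """Dispatch to the correlation or Bray-Curtis constructor."""
    if spec.method == "braycurtis":
        return braycurtis_network(table, spec)
    return correlation_network(table, spec)


def build_group_networks(table: FeatureTable, group_column: str,
                         spec: ConstructionSpec) -> NetworkCollection:
    """One network per level of a categorical metadata column.

    Each group's samples are subset first, then filtered and constructed
    independently; collection order follows first appearance of the labels
    in the metadata. Correlation methods require >= 4 samples per group.
    """
    if table.metadata is None or group_column not in table.metadata.columns:
        raise ValidationError(f"metadata has no column {group_column!r}")
    groups = table.metadata[group_column]
    order = list(dict.fromkeys(groups))
    coll = NetworkCollection()
    for label in order:
        samples = list(groups.index[groups == label])
        if spec.method in ("pearson", "spearman") and len(samples) < 4:
            raise ValidationError(
                f"group {label!r} has only {len(samples)} samples; "
                "correlation needs at least 4")
        sub = table.subset_samples(samples)
        net = build_network(sub, spec)
        net.provenance["group"] = str(label)
        coll[str(label)] = net
    return coll


def _add_nodes_with_taxonomy(net: CooccurrenceNetwork, table: FeatureTable) -> None:
    tax = table.taxonomy
    for f in table.features:
        attrs = {}
        if tax is not None:
            attrs = {rank: str(tax.at[f, rank]) for rank in tax.columns}
        net.add_node(f, **attrs)
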