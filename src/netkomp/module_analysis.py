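"""Module eigengenes, eigengene–environment correlation, module communities.

The eigengene of a module is the first principal component of its member
features' abundance profiles, computed after z-scoring each feature across
samples (optionally on per-sample relative abundances first), and rescaled
to unit variance across samples.
Its sign is fixed so that it correlates positively with the module's mean
(standardized) profile. Correlating eigengenes (or any entity × sample
matrix) with numeric metadata yields an r/p/p_adj/stars grid in the style
of the usual eigengene–trait heatmaps (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .core_io import CooccurrenceNetwork, FeatureTable, ValidationError
from .topology import Partition

logger = logging.getLogger(__name__)

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class EigengeneResult:
    eigengene: pd.DataFrame            # module × sample, unit variance rows
    variance_explained: dict[int, float]


@dataclass
class CorrelationGrid:
    r: pd.DataFrame
    p: pd.DataFrame
    p_adj: pd.DataFrame
    stars: pd.DataFrame


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """z-score each row (population sd); zero-variance rows become zeros."""
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe


def module_eigengene(table: FeatureTable, partition: Partition,
                     transform: str = "raw_z") -> EigengeneResult:
    """First-PC summary profile of each module across samples.

    ``transform`` controls the preprocessing of member abundances:
    ``raw_z`` (default) z-scores each feature across samples; ``relabund_z``
    converts to per-sample relative abundance first. The relative-abundance
    option suits depth-varying count data, but closure couples modules
    whose totals co-vary, which biases the module summary when absolute
    abundances are meaningful. A singleton module's eigengene is its
    member's standardized profile with variance_explained = 1 (logged).
    """
    missing = set(partition.assignment) - set(table.features)
    if missing:
        raise ValidationError(f"partition nodes missing from table: {sorted(missing)[:5]}")
    if transform not in ("relabund_z", "raw_z"):
        raise ValidationError(f"unknown transform {transform!r}")
    ab = table.abundance
    X_all = ab.values.astype(float)
    if transform == "relabund_z":
        totals = X_all.sum(axis=0)
        X_all = X_all / np.where(totals > 0, totals, 1.0)
    samples = list(ab.columns)
    n = len(samples)
    eig_rows = {}
    var_exp = {}
    for m, members in sorted(partition.modules().items()):
        idx = [ab.index.get_loc(f) for f in members]
        Z = _standardize_rows(X_all[idx, :])        # feature × sample
        if len(members) == 1:
            logger.info("module %d has a single member; eigengene = its profile", m)
            e = Z[0]
            var_exp[m] = 1.0
        else:
            # PCA of the sample × feature matrix; PC1 sample scores
            U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
            e = U[:, 0] * S[0]
            tot = float((S ** 2).sum())
            var_exp[m] = float(S[0] ** 2 / tot) if tot > 0 else 0.0
        sd = e.std()
        e = e / sd if sd > 0 else e
        mean_profile = Z.mean(axis=0)
        if mean_profile.std() > 0 and e.std() > 0:
            if np.corrcoef(e, mean_profile)[0, 1] < 0:
                e = -e
        eig_rows[m] = e
    eig = pd.DataFrame(eig_rows, index=samples).T
    eig.index.name = "module"
    return EigengeneResult(eigengene=eig, variance_explained=var_exp)


def env_correlation(rows: pd.DataFrame, metadata: pd.DataFrame,
                    variables: list[str] | None = None,
                    stars_on: str = "raw") -> CorrelationGrid:
    """Pearson r/p grid between row entities and numeric metadata variables.

    ``rows`` is entity × sample; ``metadata`` is sample × variable. p-values
    are BH-adjusted per variable (one family per metadata column). Stars
    mark raw p by default (``stars_on="adjusted"`` switches to p_adj) at
    0.05 / 0.01 / 0.001. Zero-variance variables give NaN with a warning.
    """
    shared = [s for s in rows.columns if s in metadata.index]
    if len(shared) < 4:
        raise ValidationError(f"need >= 4 shared samples, got {len(shared)}")
    if variables is None:
        variables = [c for c in metadata.columns
                     if pd.api.types.is_numeric_dtype(metadata[c])]
    if not variables:
        raise ValidationError("no numeric metadata variables to correlate")
    R = pd.DataFrame(index=rows.index, columns=variables, dtype=float)
    P = pd.DataFrame(index=rows.index, columns=variables, dtype=float)
    for var in variables:
        y = metadata.loc[shared, var].astype(float).values
        if np.std(y) == 0:
            logger.warning("env_correlation: variable %r has zero variance", var)
            R[var] = np.nan
            P[var] = np.nan
            continue
        for ent in rows.index:
            x = rows.loc[ent, shared].astype(float).values
            if np.std(x) == 0:
                R.at[ent, var] = np.nan
                P.at[ent, var] = np.nan
                continue
            r, p = sps.pearsonr(x, y)
            R.at[ent, var] = r
            P.at[ent, var] = p
    P_adj = P.copy()
    for var in variables:
        mask = P[var].notna()
        if mask.any():
            P_adj.loc[mask, var] = multipletests(P.loc[mask, var].values,
                                                 method="fdr_bh")[1]
    basis = P if stars_on == "raw" else P_adj
    stars = basis.map(_stars)
    return CorrelationGrid(r=R, p=P, p_adj=P_adj, stars=stars)


def _stars(p: float) -> str:
    if pd.isna(p):
        return ""
    for thr, s in STAR_THRESHOLDS:
        if p < thr:
            return s
    return ""


def modules_to_communities(net: CooccurrenceNetwork, table: FeatureTable
                           ) -> dict[int, FeatureTable]:
    """Split the feature table by module into community-like tables.

    Each module's table is the input restricted to its member features
    (all samples kept), ready for composition summaries at any rank.
    """
    modules = {n: d.get("module") for n, d in net.graph.nodes(data=True)}
    if any(m is None for m in modules.values()):
        raise ValidationError("network nodes lack module assignments; "
                              "run detect_modules first")
    out: dict[int, FeatureTable] = {}
    for m in sorted(set(modules.values())):
        members = [n for n, mm in modules.items() if mm == m and n in set(table.features)]
        out[int(m)] = table.subset_features(members)
    return out


def module_composition(module_tables: dict[int, FeatureTable],
                       rank: str = "Phylum") -> pd.DataFrame:
    """Total abundance per rank label per module (label × module)."""
    cols = {}
    for m, t in sorted(module_tables.items()):
        if t.taxonomy is None:
            raise ValidationError("taxonomy required for composition")
        labels = t.taxonomy[rank].replace("", "unclassified")
        totals = t.abundance.sum(axis=1)
        cols[m] = totals.groupby(labels).sum()
    return pd.DataFrame(cols).fillna(0.0)


def read_function_mapping(path) -> pd.DataFrame:
    """Read a (rank, label, function) mapping TSV; malformed rows are errors."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3 or not all(p.strip() for p in parts):
                raise ValidationError(
                    f"malformed mapping row at line {lineno}: {line!r} "
                    "(expected rank<TAB>label<TAB>function)")
            rows.append(dict(zip(("rank", "label", "function"), parts)))
    return pd.DataFrame(rows, columns=["rank", "label", "function"])


def functional_annotation(module_tables: dict[int, FeatureTable],
                          mapping: pd.DataFrame) -> pd.DataFrame:
    """Count member features matching each taxon → function rule, per module.

    A feature matches a rule when its taxonomy label at the rule's rank
    equals the rule's label. Returns a function × module count table
    (empty mapping → empty table).
    """
    if mapping.empty:
        return pd.DataFrame()
    functions = list(dict.fromkeys(mapping["function"]))
    out = pd.DataFrame(0, index=functions, columns=sorted(module_tables), dtype=int)
    for m, t in sorted(module_tables.items()):
        if t.taxonomy is None:
            raise ValidationError("taxonomy required for functional annotation")
        for _, rule in mapping.iterrows():
            rank, label, fn = rule["rank"], rule["label"], rule["function"]
            if rank not in t.taxonomy.columns:
                continue
            out.at[fn, m] += int((t.taxonomy[rank] == label).sum())
    return out
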