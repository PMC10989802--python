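"""Seeded synthetic community generator.

Emulates the structure of grouped amplicon/metagenomic survey data: block-
correlated features (planted modules driven by latent factors that are
partially coupled to stored environmental variables), taxonomy in which
modules map predominantly to distinct phyla, a random bifurcating tree
placing module members close together, and sample metadata with numeric
abiotic variables plus a categorical group column. Ground truth (module
assignment, latent factors, planted edges) is returned alongside so
recovery can be tested without re-deriving it.

Abundances follow ``softplus(loading * latent + noise)``: the softplus link
keeps them non-negative while approximately preserving the Gaussian-scale
correlation structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (CooccurrenceNetwork, FeatureTable, ValidationError,
                      edge_key)

RANKS = ("Kingdom", "Phylum", "Class", "Order", "Family", "Genus")


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic data set; fully reproducible from seed.

    ``within_module_correlation`` is the target Pearson correlation between
    same-module features on the latent (Gaussian) scale; ``noise_sd``
    scales the idiosyncratic noise (0 gives perfectly correlated members).
    ``env_coupling`` is the correlation between each module's latent factor
    and its stored environmental variable. A fraction
    ``negative_loading_fraction`` of each module's features can be loaded
    negatively to plant negative associations.
    """

    n_features: int = 60
    n_samples: int = 40
    n_groups: int = 3
    n_modules: int = 3
    within_module_correlation: float = 0.8
    noise_sd: float = 1.0
    env_coupling: float = 0.8
    negative_loading_fraction: float = 0.0
    phylum_mixing: float = 0.1
    branch_length_scale: float = 0.1
    module_stem_length: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_features", "n_samples", "n_groups", "n_modules"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.n_modules > self.n_features:
            raise ValidationError("more modules than features is infeasible")
        if not 0.0 < self.within_module_correlation < 1.0:
            raise ValidationError("within_module_correlation must be in (0, 1)")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not 0.0 <= self.negative_loading_fraction < 1.0:
            raise ValidationError("negative_loading_fraction must be in [0, 1)")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _random_bifurcating(labels: list[str], rng: np.random.Generator,
                        scale: float) -> str:
    """Random bifurcating newick subtree with exponential branch lengths."""
    if len(labels) == 1:
        return labels[0]
    labels = list(labels)
    rng.shuffle(labels)
    split = rng.integers(1, len(labels))
    left = _random_bifurcating(labels[:split], rng, scale)
    right = _random_bifurcating(labels[split:], rng, scale)
    bl, br = rng.exponential(scale, size=2)
    return f"({left}:{bl:.6f},{right}:{br:.6f})"


def generate(spec: SyntheticSpec) -> tuple[FeatureTable, dict]:
    """Generate a FeatureTable plus its ground truth.

    Returns ``(table, truth)`` where ``truth`` holds the planted module
    assignment (Series feature → module), the latent factors (module ×
    sample DataFrame), the per-feature loadings, the planted within-module
    edge list (canonical pairs) and the newick string of the tree.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_features))
    features = [f"F{i + 1:0{width}d}" for i in range(spec.n_features)]
    samples = [f"S{j + 1:03d}" for j in range(spec.n_samples)]

    # contiguous blocks of features per module
    bounds = np.linspace(0, spec.n_features, spec.n_modules + 1).astype(int)
    module_of = {}
    for m in range(spec.n_modules):
        for i in range(bounds[m], bounds[m + 1]):
            module_of[features[i]] = m

    env = rng.standard_normal((spec.n_modules, spec.n_samples))
    rho = spec.env_coupling
    latent = rho * env + np.sqrt(1.0 - rho ** 2) * \
        rng.standard_normal((spec.n_modules, spec.n_samples))

    w = spec.within_module_correlation
    abundance = np.empty((spec.n_features, spec.n_samples))
    loadings = {}
    for i, f in enumerate(features):
        m = module_of[f]
        sign = -1.0 if rng.random() < spec.negative_loading_fraction else 1.0
        loadings[f] = sign
        g = sign * np.sqrt(w) * latent[m] + \
            np.sqrt(1.0 - w) * spec.noise_sd * rng.standard_normal(spec.n_samples)
        abundance[i] = _softplus(1.5 * g + 2.0)

    # taxonomy: module -> predominant phylum, with controlled mixing
    phyla = [f"Phylum_{m + 1}" for m in range(spec.n_modules)]
    tax_rows = {}
    for f in features:
        m = module_of[f]
        if spec.n_modules > 1 and rng.random() < spec.phylum_mixing:
            other = [p for i_, p in enumerate(phyla) if i_ != m]
            phylum = other[rng.integers(len(other))]
        else:
            phylum = phyla[m]
        tax_rows[f] = {"Kingdom": "Bacteria", "Phylum": phylum,
                       "Class": f"Class_{phylum}", "Order": f"Order_{phylum}",
                       "Family": f"Family_{f}", "Genus": f"Genus_{f}"}
    taxonomy = pd.DataFrame.from_dict(tax_rows, orient="index")[list(RANKS)]

    # tree: per-module subtrees joined by long stems
    subtrees = []
    for m in range(spec.n_modules):
        members = [f for f in features if module_of[f] == m]
        sub = _random_bifurcating(members, rng, spec.branch_length_scale)
        subtrees.append(f"{sub}:{spec.module_stem_length:.6f}")
    newick = "(" + ",".join(subtrees) + ");" if spec.n_modules > 1 \
        else subtrees[0].rsplit(":", 1)[0] + ";"

    group_labels = [f"G{(j % spec.n_groups) + 1}" for j in range(spec.n_samples)]
    metadata = pd.DataFrame(
        {**{f"env_{m + 1}": env[m] for m in range(spec.n_modules)},
         "Group": group_labels}, index=samples)

    table = FeatureTable(
        abundance=pd.DataFrame(abundance, index=features, columns=samples),
        taxonomy=taxonomy, metadata=metadata)
    table.validate()

    planted_edges = []
    for m in range(spec.n_modules):
        members = [f for f in features if module_of[f] == m]
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                planted_edges.append(edge_key(a, b))

    truth = {
        "modules": pd.Series(module_of, name="module"),
        "latent": pd.DataFrame(latent, index=range(spec.n_modules), columns=samples),
        "env": pd.DataFrame(env, index=range(spec.n_modules), columns=samples),
        "loadings": pd.Series(loadings, name="loading"),
        "planted_edges": planted_edges,
        "newick": newick,
    }
    return table, truth


def generate_toy_graphs() -> dict[str, CooccurrenceNetwork]:
    """The small named oracle graphs used across the test-suite.

    triangle, P4 path, S4 star, K5, two triangles joined by a bridge edge,
    and two disconnected edges — all with unit positive weights.
    """
    def build(nodes, edges) -> CooccurrenceNetwork:
        net = CooccurrenceNetwork(provenance={"method": "toy"})
        for n in nodes:
            net.add_node(n)
        for u, v in edges:
            net.add_edge(u, v, weight=1.0)
        return net

    graphs = {
        "triangle": build("abc", [("a", "b"), ("b", "c"), ("a", "c")]),
        "path4": build("abcd", [("a", "b"), ("b", "c"), ("c", "d")]),
        "star4": build(["hub", "l1", "l2", "l3"],
                       [("hub", "l1"), ("hub", "l2"), ("hub", "l3")]),
        "k5": build("abcde", [(u, v) for i, u in enumerate("abcde")
                              for v in "abcde"[i + 1:]]),
        "bridge": build(["t1", "t2", "t3", "t4", "t5", "t6"],
                        [("t1", "t2"), ("t2", "t3"), ("t1", "t3"),
                         ("t4", "t5"), ("t5", "t6"), ("t4", "t6"),
                         ("t3", "t4")]),
        "two_edges": build("abcd", [("a", "b"), ("c", "d")]),
    }
    for g in graphs.values():
        g.validate()
    return graphs
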