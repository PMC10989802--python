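# netkomp

Construction and **comparison of microbial co-occurrence networks** from
feature (OTU/ASV/species) × sample abundance tables.

Ecologists routinely infer association networks from amplicon or
metagenomic surveys and then need to compare several of them at once —
networks built from different sample groups (habitats, treatments) or from
different construction methods (Pearson/Spearman at various thresholds,
Bray-Curtis similarity). `netkomp` is a toolkit for exactly that workflow:
build a collection of networks, characterise each one (modules, global
topology, node roles), and compare them — shared nodes and edges, Venn
regions, intersection networks, phylogenetic distances of linked taxa,
taxon sources of edges, module eigengenes against abiotic factors, and
per-sample subnetwork properties.

## The model

A co-occurrence network is an edge-weighted undirected graph *G = (V, E)*:
nodes are features, an edge means an inferred association, its weight is
the correlation (or similarity) coefficient and its sign the direction of
the association. Correlation networks keep the pair (i, j) when
|r<sub>ij</sub>| ≥ r<sub>thr</sub> and the BH-adjusted two-sided p-value
(from t = r√((n−2)/(1−r²)), df = n−2) is below p<sub>thr</sub>;
Bray-Curtis networks keep pairs whose similarity 1 − BC<sub>ij</sub>
reaches the threshold.

Per network, modules come from greedy modularity maximization
(Clauset–Newman–Moore, unweighted), and each node gets its
within-module connectivity Z<sub>i</sub> (z-score of within-module degree)
and participation coefficient P<sub>i</sub> = 1 − Σ<sub>m</sub>
(k<sub>im</sub>/k<sub>i</sub>)², classified with the classic thresholds
into **module hubs** (Z > 2.5, P ≤ 0.62), **connectors** (Z ≤ 2.5,
P > 0.62), **network hubs** (Z > 2.5, P > 0.62) and **peripherals**.
Module eigengenes (first principal component of the members' standardized
profiles) and per-sample subnetwork properties are correlated with numeric
metadata; grouped edge distances are tested with one-way ANOVA followed by
Duncan's new multiple range test with a compact letter display.

## Worked example

Everything below runs on synthetic data from the built-in seeded
generator, which plants block-correlated modules driven by latent factors
coupled to stored environmental variables:

```python
import netkomp as nk

table, truth = nk.generate(nk.SyntheticSpec(seed=7))   # 60 features, 40 samples
spec = nk.ConstructionSpec(min_prevalence=0.0)          # pearson, |r|>=0.6, BH p<0.05
coll = nk.build_group_networks(table, "Group", spec)
for label, net in coll.items():
    part = nk.detect_modules(net)
    print(f"{label}: {net.node_count} nodes, {net.edge_count} edges, "
          f"{len(part.modules())} modules, Q = {part.modularity_q:.3f}")

pm = nk.edge_comp(coll)
counts = nk.venn_counts(pm)
print("edges shared by all three networks:",
      counts[frozenset(coll.labels)], "of", len(pm.items))
```

prints

```
G1: 60 nodes, 520 edges, 3 modules, Q = 0.664
G2: 60 nodes, 431 edges, 4 modules, Q = 0.626
G3: 60 nodes, 495 edges, 3 modules, Q = 0.579
edges shared by all three networks: 305 of 612
```

Each group's network is strongly modular (Q ≈ 0.6, recovering the three
planted feature blocks) and half of all distinct edges replicate across
all three sample groups. Correlating module eigengenes of the first
network with the environmental variables recovers the planted
module–environment coupling — each module tracks exactly one factor:

```python
part = nk.detect_modules(coll["G1"])
eig = nk.module_eigengene(table.subset_features(list(part.assignment)), part)
grid = nk.env_correlation(eig.eigengene, table.metadata,
                          variables=["env_1", "env_2", "env_3"])
print(grid.r.round(2)); print(grid.stars)
```

```
        env_1  env_2  env_3
module
0        0.72  -0.12   0.16
1       -0.15   0.82  -0.08
2        0.23  -0.13   0.73

       env_1 env_2 env_3
module
0        ***
1              ***
2                    ***
```

The same analyses are available from the shell (`netkomp synth`, `netkomp
build`, `netkomp modules`, `netkomp venn`, `netkomp edgedist`, `netkomp
eigengene`, `netkomp subnet`, …, or `netkomp run --config run.yaml` for a
whole pipeline); networks are written as GraphML/GEXF for Gephi and all
tables as TSV.

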