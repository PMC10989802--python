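import numpy as np
import pandas as pd
import pytest

from netkomp import (ConstructionSpec, FeatureTable, SyntheticSpec,
                     correlation_network, detect_modules, generate,
                     generate_toy_graphs)


@pytest.fixture(scope="session")
def toy_graphs():
    return generate_toy_graphs()


@pytest.fixture(scope="session")
def synth():
    """Default synthetic data set (seed 7) with its ground truth."""
    table, truth = generate(SyntheticSpec(seed=7))
    return table, truth


@pytest.fixture(scope="session")
def synth_network(synth):
    """Network built from the default synthetic table, with modules."""
    table, _ = synth
    net = correlation_network(table, ConstructionSpec())
    partition = detect_modules(net)
    return net, partition


@pytest.fixture()
def tiny_table():
    """A hand-sized 6-feature x 8-sample table with taxonomy and metadata."""
    rng = np.random.default_rng(42)
    features = [f"F{i}" for i in range(1, 7)]
    samples = [f"S{j}" for j in range(1, 9)]
    base = rng.uniform(0.5, 5.0, size=(6, 8))
    abundance = pd.DataFrame(base, index=features, columns=samples)
    taxonomy = pd.DataFrame(
        {"Kingdom": ["Bacteria"] * 6,
         "Phylum": ["P1", "P1", "P1", "P2", "P2", "P3"]},
        index=features)
    metadata = pd.DataFrame(
        {"pH": rng.uniform(4, 9, 8), "TOC": rng.uniform(1, 30, 8),
         "Group": ["A", "A", "A", "A", "B", "B", "B", "B"]},
        index=samples)
    return FeatureTable(abundance=abundance, taxonomy=taxonomy, metadata=metadata)
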