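import numpy as np
import pandas as pd
import pytest

from chromonet import (
    CountMatrix,
    SimulationConfig,
    make_annotation,
    simulate_counts,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        n_genes=120,
        n_chromosomes=4,
        n_healthy=40,
        n_cancer=40,
        block_size=10,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    ann = make_annotation(small_cfg)
    counts, samples, truth = simulate_counts(small_cfg, ann)
    return ann, counts, samples, truth


@pytest.fixture(scope="session")
def small_cm(small_dataset):
    ann, counts, samples, truth = small_dataset
    return CountMatrix(values=counts, conditions=samples.set_index("sample")["condition"])


@pytest.fixture
def toy_annotation():
    """Hand-built annotation: 10 genes on 2 chromosomes, 2 defective records."""
    rows = []
    for i in range(10):
        rows.append(
            {
                "gene_id": f"g{i}",
                "symbol": f"S{i}",
                "alt_symbol": f"A{i}",
                "chromosome": "1" if i < 5 else "2",
                "start": 1000 * (i + 1),
                "end": 1000 * (i + 1) + 500,
                "gc": 0.4 + 0.01 * i,
                "biotype": "protein_coding",
            }
        )
    rows[3]["chromosome"] = "MT"  # non-conventional -> dropped
    rows[7]["symbol"] = ""  # missing symbol -> dropped
    return pd.DataFrame(rows)


@pytest.fixture
def toy_counts(toy_annotation):
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.integers(5, 500, size=(10, 6)),
        index=pd.Index(toy_annotation["gene_id"], name="gene_id"),
        columns=[f"s{j}" for j in range(6)],
    )
    conditions = pd.Series(
        ["healthy"] * 3 + ["cancer"] * 3, index=values.columns, name="condition"
    )
    return CountMatrix(values=values, conditions=conditions)
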