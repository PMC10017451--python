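import numpy as np
import pytest

from genesieve import ExpressionDataset, SynthSpec, generate_dataset


@pytest.fixture(scope="session")
def small_planted():
    """Small 3-class dataset with 5 planted genes among 60."""
    spec = SynthSpec(
        class_sizes=[50, 100, 80],
        n_genes=60,
        n_informative=5,
        effect_size=2.0,
        dropout_rate=0.5,
        seed=1,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def tiny_ds():
    """Deterministic 6-cell x 3-gene dataset for exact-value tests."""
    values = np.array(
        [
            [0.0, 1.0, 2.0],
            [0.5, 1.5, 2.5],
            [1.0, 2.0, 3.0],
            [1.5, 2.5, 3.5],
            [2.0, 3.0, 4.0],
            [2.5, 3.5, 4.5],
        ]
    )
    return ExpressionDataset(
        values=values,
        gene_ids=["g1", "g2", "g3"],
        cell_ids=[f"c{i}" for i in range(6)],
        labels=np.array(["A", "A", "A", "B", "B", "B"], dtype=object),
    )
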