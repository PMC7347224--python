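import numpy as np
import pytest

from layervis.core import ExpressionMatrix, MetricsTable, TreatmentPair
from layervis.simulate import SimulationConfig, simulate_counts, worked_fixture


@pytest.fixture(scope="session")
def worked():
    """The hand-checkable 8-gene x (2x2) fixture and its metrics."""
    return worked_fixture()


@pytest.fixture()
def small_sim():
    """A 150-gene, 2-treatment x 3-replicate simulated dataset (seeded)."""
    return simulate_counts(SimulationConfig(n_genes=150, seed=42))


@pytest.fixture()
def random_metrics():
    """500-gene random metrics table for threshold/ordering oracles."""
    rng = np.random.default_rng(7)
    n = 500
    import pandas as pd

    frame = pd.DataFrame(
        {
            "logFC": rng.normal(0, 1.5, n),
            "PValue": rng.uniform(0, 1, n),
        },
        index=[f"g{i:03d}" for i in range(n)],
    )
    frame["FDR"] = np.minimum(frame["PValue"] * 1.3, 1.0)
    return MetricsTable(TreatmentPair("A", "B"), frame)


@pytest.fixture()
def matrix_3treat():
    """Tiny 3-treatment matrix for pair enumeration and litre geometry."""
    rng = np.random.default_rng(11)
    labels = ["N.1", "N.2", "P.1", "P.2", "P.3", "S.1"]
    counts = rng.integers(0, 200, size=(20, len(labels))).astype(float)
    return ExpressionMatrix.from_arrays(
        [f"gene{i}" for i in range(20)], counts, labels
    )
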