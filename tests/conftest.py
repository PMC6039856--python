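import numpy as np
import pandas as pd
import pytest

from mlmescan import (
    CallRule,
    ExpressionMatrix,
    MarkerPanel,
    SimulationConfig,
    call_positive,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 cells with easily hand-checked values."""
    values = np.array(
        [
            [0.0, 1.0, 2.0, 3.0],
            [5.0, 5.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 10.0],
        ]
    )
    meta = pd.DataFrame(
        {
            "embryo_id": ["e1", "e1", "e2", "e2"],
            "stage": ["E5", "E5", "E6", "E6"],
            "lineage": ["EPI", "TE", "PE", "pre-lineage"],
            "dataset_id": ["toy"] * 4,
        },
        index=pd.Index(["c1", "c2", "c3", "c4"], name="cell_id"),
    )
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3"],
        cell_ids=["c1", "c2", "c3", "c4"],
        values=values,
        cell_meta=meta,
    )


@pytest.fixture(scope="session")
def toy_panel() -> MarkerPanel:
    return MarkerPanel(
        lineage_markers={
            "EPI": ["NANOG", "POU5F1", "SOX2", "E1", "E2", "E3g"],
            "TE": ["T1", "T2", "T3", "T4", "T5", "T6"],
            "PE": ["P1", "P2", "P3", "P4", "P5", "P6"],
        }
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """1,000-cell simulated dataset without dropout: the parameter-recovery
    regime (well-separated on/off states)."""
    return simulate_dataset(SimulationConfig(seed=42, dropout_prob=0.0))


@pytest.fixture(scope="session")
def clean_calls(clean_dataset):
    return call_positive(clean_dataset.matrix, CallRule(kind="population_median"))
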