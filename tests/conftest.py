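import numpy as np
import pandas as pd
import pytest

from mixnorm import AbundanceMatrix, SampleAnnotation, SimConfig


@pytest.fixture
def two_batch_dataset():
    """Hand-built 3-metabolite, two-batch dataset with one undetected cell."""
    values = np.array(
        [
            [14.2, 13.7, 15.0, 16.1, 16.4, 15.9],
            [10.0, 12.0, 11.0, 20.0, 22.0, 21.0],
            [13.0, 13.5, 0.0, 14.0, 14.5, 14.2],
        ]
    )
    detected = np.ones_like(values, dtype=bool)
    detected[2, 2] = False
    sample_ids = [f"S{i}" for i in range(1, 7)]
    matrix = AbundanceMatrix(values, detected, ["M1", "M2", "M3"], sample_ids)
    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "batch": ["b1", "b1", "b1", "b2", "b2", "b2"],
                "run_order": [1, 2, 3, 1, 2, 3],
                "sample_class": ["qc_pool", "analytical", "analytical"] * 2,
            }
        )
    )
    return matrix, annotation


@pytest.fixture
def small_sim_config():
    """Scaled-down simulated experiment for fast unit/property checks."""
    return SimConfig(
        n_metabolites=40,
        n_batches=8,
        analytical_per_batch=10,
        qc_per_batch=3,
        n_rounds=50,
        seed_constants=11,
        seed_rounds=12,
    )


def make_qc_only_dataset(values_by_batch, qc_per_batch=None):
    """Build a QC-only dataset from {batch: list of metabolite-row arrays}."""
    cols, batches, orders = [], [], []
    blocks = []
    for batch, block in values_by_batch.items():
        block = np.atleast_2d(np.asarray(block, dtype=float))
        blocks.append(block)
        for j in range(block.shape[1]):
            cols.append(f"{batch}_q{j + 1}")
            batches.append(batch)
            orders.append(j + 1)
    values = np.hstack(blocks)
    matrix = AbundanceMatrix(
        values,
        np.isfinite(values),
        [f"M{i + 1}" for i in range(values.shape[0])],
        cols,
    )
    annotation = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": cols,
                "batch": batches,
                "run_order": orders,
                "sample_class": "qc_pool",
            }
        )
    )
    return matrix, annotation
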