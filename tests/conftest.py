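import numpy as np
import pytest

import ncanet as nn


@pytest.fixture(scope="session")
def small_truth():
    """Noiseless 40-gene, 4-TF ground truth on the default stage panel."""
    return nn.generate_truth(n_genes=40, n_tfs=4, edges_per_gene=2,
                             noise_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noisy_truth():
    """Moderately noisy 60-gene, 5-TF ground truth."""
    return nn.generate_truth(n_genes=60, n_tfs=5, edges_per_gene=2,
                             noise_sd=0.1, seed=11)


@pytest.fixture
def toy_expression():
    """Hand-built 4-gene, 4-stage log2-ratio matrix, control = S1."""
    vals = np.array([
        [0.0, 1.0, 2.0, 1.0],
        [0.0, -1.0, -2.0, -1.0],
        [0.0, 0.5, 1.1, 0.4],
        [0.0, 0.0, 0.0, 0.0],
    ])
    return nn.ExpressionMatrix(
        gene_ids=["g1", "g2", "g3", "g4"],
        stage_labels=["S1", "S2", "S3", "S4"],
        values=vals,
        control_stage="S1",
    )


def align_activities(fitted: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Least-squares diagonal gauge alignment of fitted activity rows."""
    out = fitted.copy()
    for j in range(fitted.shape[0]):
        denom = float(fitted[j] @ fitted[j])
        if denom > 0:
            out[j] *= float(fitted[j] @ truth[j]) / denom
    return out
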