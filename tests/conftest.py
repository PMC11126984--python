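import numpy as np
import pytest

import burstline as bl


@pytest.fixture(scope="session")
def small_study():
    """Two-sample study with planted damaged cells and tag genes.

    200 genes keep per-cell QC metrics well separated from the planted
    thresholds so the damaged flags are exactly recoverable.
    """
    cfg = bl.StudyConfig(
        n_samples=2,
        cells_per_sample=100,
        n_genes=200,
        frac_mito_genes=0.05,
        mito_count_fraction=0.05,
        frac_damaged_cells=0.1,
        tag_detection_rate=0.08,
        qc_min_genes=60,
        seed=11,
    )
    matrix, truth = bl.generate_study(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def tiny_matrix():
    """2 genes x 2 cells matrix for round-trip and arithmetic checks."""
    counts = np.array([[3, 0], [1, 5]])
    return bl.CountMatrix(
        counts,
        gene_ids=["GENEA", "MT-1"],
        barcodes=["c1", "c2"],
        sample_labels=["s", "s"],
    )
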