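import logging

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from neuralplate.config import PipelineConfig
from neuralplate.io import compute_cell_metrics
from neuralplate.simulate import SimConfig, simulate_tissue

logging.getLogger("neuralplate").setLevel(logging.ERROR)


def make_adata(counts, cell_ids=None, gene_ids=None) -> AnnData:
    """Build a minimal dataset from a dense cells × genes count array."""
    counts = np.asarray(counts)
    n, g = counts.shape
    adata = AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=cell_ids or [f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=gene_ids or [f"g{j}" for j in range(g)]),
    )
    adata.layers["counts"] = adata.X
    compute_cell_metrics(adata)
    return adata


@pytest.fixture(scope="session")
def small_tissue():
    """A 400-cell tissue with all gene categories, no low-quality cells."""
    cfg = SimConfig(
        seed=3, n_cells=400, n_genes=300, n_ap=30, n_ml=20, n_both=10, n_time=15
    )
    return simulate_tissue(cfg)


@pytest.fixture(scope="session")
def reference_summary():
    """The full reference pipeline run used by the acceptance tests."""
    from neuralplate.run_reference import run_reference_pipeline

    return run_reference_pipeline(PipelineConfig(seed=1))
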