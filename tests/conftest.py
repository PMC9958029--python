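import numpy as np
import pandas as pd
import pytest

from hnscc_stepwise.config import PipelineConfig
from hnscc_stepwise.core_io import CellMatrix


def tiny_matrix(values, chroms=None, tissue_types=None, cell_types=None,
                scale="counts", go_terms=None):
    """Hand-rolled CellMatrix for unit tests."""
    values = np.asarray(values, dtype=float)
    n_genes, n_cells = values.shape
    gene_ids = [f"G{i:03d}" for i in range(n_genes)]
    cell_ids = [f"c{i:03d}" for i in range(n_cells)]
    chroms = chroms or ["1"] * n_genes
    gene_meta = pd.DataFrame(
        {
            "chrom": chroms,
            "start_bp": [1 + 1000 * i for i in range(n_genes)],
            "end_bp": [500 + 1000 * i for i in range(n_genes)],
            "biotype": ["protein_coding"] * n_genes,
            "go_terms": go_terms or [frozenset()] * n_genes,
        },
        index=gene_ids,
    )
    cell_meta = pd.DataFrame(
        {
            "patient_id": [f"P{i % 3}" for i in range(n_cells)],
            "tissue_type": tissue_types or ["NL"] * n_cells,
            "hpv_status": ["neg"] * n_cells,
            "cell_type": cell_types or ["epithelial"] * n_cells,
        },
        index=cell_ids,
    )
    return CellMatrix(values, gene_ids, cell_ids, gene_meta, cell_meta, scale=scale)


@pytest.fixture
def default_config():
    return PipelineConfig()


@pytest.fixture
def synthetic_config():
    """Config tuned to the synthetic cohort scale (tracks are left unsmoothed
    and the CBS permutation budget is reduced; thresholds keep their printed
    defaults)."""
    return PipelineConfig(
        smoothing_window=1, cbs_n_perm=500, cbs_alpha=0.002, n_permutations=1000
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
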