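import anndata as ad
import numpy as np
import pandas as pd
import pytest

from gliaxis import SimConfig


@pytest.fixture
def small_sc_config():
    """Two-condition, two-donor single-cell config small enough for fast DE."""
    return SimConfig(
        seed=13,
        n_genes=150,
        n_donors=2,
        cells_per_condition=40,
        conditions=("control", "lps_ifng_24"),
        n_de_genes=20,
    )


@pytest.fixture
def small_meta_config():
    return SimConfig(seed=13, n_genes=400, n_datasets=3, samples_per_dataset=8)


def make_adata(values: np.ndarray, obs: pd.DataFrame | None = None) -> ad.AnnData:
    """Dense cells x genes matrix as AnnData with generated identifiers."""
    n_cells, n_genes = values.shape
    if obs is None:
        obs = pd.DataFrame(index=[f"c{i}" for i in range(n_cells)])
    var = pd.DataFrame(index=[f"g{j}" for j in range(n_genes)])
    import scipy.sparse as sp

    return ad.AnnData(X=sp.csr_matrix(np.asarray(values, dtype=float)), obs=obs, var=var)
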