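import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tecsuite as ts

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_atlas():
    """10 cell types x 100 cells, 400 genes, 10% breadth-1 genes."""
    spec = ts.AtlasSpec(n_cell_types=10, n_cells_per_type=100, n_genes=400,
                        on_mean=5.0, off_mean=0.1, dispersion=2.0, seed=11)
    adata, truth = ts.simulate_atlas(spec)
    return spec, adata, truth


@pytest.fixture(scope="session")
def small_experiment():
    """Two genotypes x two replicates, 3 cell types, planted programs."""
    spec = ts.ExperimentSpec(
        cell_types=("A", "B", "C"),
        composition={"WT": [0.2, 0.4, 0.4], "KO": [0.5, 0.25, 0.25]},
        n_cells_per_sample=600, n_genes=300,
        n_induced=20, n_repressed=20, regulated_lfc=2.0,
        n_batch_genes=10, batch_lfc=1.5, seed=21,
    )
    adata, truth = ts.simulate_tec_experiment(spec)
    return spec, adata, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
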