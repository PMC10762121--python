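import warnings

import pytest

from regulonkit import RegulonNetworkModel, SimulationConfig, generate_dataset
from regulonkit.io_qc import normalize

SMALL = SimulationConfig(n_cells=300, n_genes=200, n_clusters=3, n_tfs=6,
                         targets_per_tf=8, stage_marker_count=15,
                         background_per_cluster=10, seed=11)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SMALL)


@pytest.fixture(scope="session")
def small_normalized(small_dataset):
    adata = small_dataset.adata
    if "lognorm" not in adata.layers:
        normalize(adata)
    return adata


@pytest.fixture(scope="session")
def small_results(small_dataset, small_normalized):
    model = RegulonNetworkModel.from_synthetic(small_dataset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return model.fit(seed=11)
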