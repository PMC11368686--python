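import numpy as np
import pytest

import contrastmap as cm


@pytest.fixture(scope="session")
def small_reference():
    """A small synthetic spatial reference (raw counts), fast to train on."""
    config = cm.SimConfig(n_cells=200, n_genes=40, n_zones=4, seed=11)
    return cm.generate_spatial_dataset(config)


@pytest.fixture(scope="session")
def small_lognorm_reference(small_reference):
    profile = cm.log_normalize(small_reference.profile)
    ds = cm.SpatialDataset(profile=profile, coords=small_reference.coords)
    ds.sim_config = small_reference.sim_config
    return ds


@pytest.fixture(scope="session")
def tiny_trained_state(small_lognorm_reference):
    """A briefly trained encoder for plumbing tests (not for quality)."""
    config = cm.ModelConfig(epochs=5, batch_size=16, positive_knn=10, seed=11)
    return cm.train(small_lognorm_reference, config)


def make_profile(values, lognorm=False, cell_types=None):
    values = np.asarray(values, float)
    n, g = values.shape
    return cm.ExpressionProfile(
        values=values,
        gene_ids=[f"g{j}" for j in range(g)],
        cell_ids=[f"c{i}" for i in range(n)],
        cell_types=cell_types,
        is_lognorm=lognorm,
    )
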