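import numpy as np
import pytest

from alenet import FociGenConfig, gen_foci_corpus, ma_map, mni_like_grid


@pytest.fixture(scope="session")
def small_grid():
    return mni_like_grid(shape=(20, 24, 20), voxel_mm=2.0)


@pytest.fixture(scope="session")
def toy_corpus(small_grid):
    cfg = FociGenConfig(
        mask=small_grid, n_experiments=6, cluster_centers=((0.0, 0.0, 0.0),),
        foci_per_cluster_per_experiment=2, noise_foci_per_experiment=2, seed=7,
    )
    return gen_foci_corpus(cfg)


@pytest.fixture(scope="session")
def toy_ma_maps(toy_corpus, small_grid):
    return [ma_map(e, small_grid) for e in toy_corpus]
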