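import numpy as np
import pytest

from yampop.synth import AccessionTruth, DepthModel, PopConfig, sample_reads


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_cfg():
    return PopConfig(n_pops=2, split_times=(200,), pop_sizes=(500, 500),
                     migration_rate=0.0, n_sites=500, n_chroms=4, seed=7)


@pytest.fixture()
def toy_panel():
    """Six diploids with hand-set dosages over 10 sites plus read data."""
    rng = np.random.default_rng(3)
    dosages = rng.integers(0, 3, size=(6, 10)).astype(np.int8)
    accs = [
        AccessionTruth(f"S{i}", "pop1", 2, None, dosages[i])
        for i in range(6)
    ]
    dm = DepthModel(mean_depth=40, depth_distribution="fixed", error_rate=0.0,
                    missing_rate=0.0)
    table = sample_reads(accs, dm, seed=11)
    return accs, table
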