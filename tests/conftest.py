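import numpy as np
import pytest

import coldjet
from coldjet.arrays import ma_transform
from coldjet.normalize import normalize_array


NOISE_FREE = dict(noise_sd_log2=0.0, dye_bias_coeffs=(0.0,),
                  probe_affinity_sd_log2=0.0, channel_gain_sd_log2=0.0)


@pytest.fixture(scope="session")
def default_experiment():
    """One full simulated experiment at the default study conditions."""
    return coldjet.simulate_experiment(seed=11)


@pytest.fixture(scope="session")
def normalized_default(default_experiment):
    """Normalized MA sets and trend fits for the default experiment."""
    norm, fits = [], {}
    for scan in default_experiment.scans:
        n, f = normalize_array(ma_transform(scan))
        norm.append(n)
        fits[scan.array_id] = f
    return norm, fits


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """An on-disk 1000-gene experiment for I/O, pipeline and GO tests."""
    out = tmp_path_factory.mktemp("experiment")
    config = coldjet.SimulationConfig(n_genes=1000, seed=5)
    paths = coldjet.write_experiment(out, config=config)
    return out, config, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
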