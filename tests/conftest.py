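import numpy as np
import pytest

import langmap
from langmap.config import validate_config
from langmap.pipeline import run_experiment


@pytest.fixture(scope="session")
def small_atlas():
    """16^3 grid, 4 networks x 3 parcels: cheap enough for unit tests."""
    return langmap.make_phantom_atlas(grid_shape=(16, 16, 16), n_networks=4,
                                      rois_per_network=3, seed=7,
                                      parcel_radius=1.5)


@pytest.fixture(scope="session")
def small_protocol():
    return langmap.AcquisitionProtocol(tr=2.2, n_frames_per_run=120, n_runs=1,
                                       grid_shape=(16, 16, 16))


@pytest.fixture(scope="session")
def noiseless_subject(small_atlas, small_protocol):
    """Noise-free, drift-free rest run: every parcel voxel equals its latent."""
    return langmap.simulate_rest_run(small_atlas, small_protocol,
                                     snr=np.inf, drift_amplitude=0.0, seed=3)


@pytest.fixture(scope="session")
def noisy_subject(small_atlas, small_protocol):
    return langmap.simulate_rest_run(small_atlas, small_protocol, snr=5.0,
                                     drift_amplitude=0.3, seed=4)


@pytest.fixture(scope="session")
def e2e_bundle(tmp_path_factory):
    """The full phantom experiment at the package's default study conditions
    (12 subjects, 24^3 grid, 6 networks), with the reduced test-suite
    bootstrap (1,000 replicates)."""
    out = tmp_path_factory.mktemp("e2e")
    cfg = validate_config({"seed": 1, "out_dir": str(out),
                           "evaluate": {"n_boot": 1000}})
    return run_experiment(cfg)
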