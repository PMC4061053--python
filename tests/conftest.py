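import numpy as np
import pytest
from hypothesis import settings

import dsfm_attention as da

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25, database=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    return da.stimulus.StimulusParams()


@pytest.fixture(scope="session")
def tiny_design():
    """Two scans of the full block design (alternating unattended direction)."""
    return da.design.build_design(seed=0, n_scans=2)


@pytest.fixture(scope="session")
def tiny_events(tiny_design):
    return da.design.design_to_events(tiny_design)


@pytest.fixture(scope="session")
def tiny_rois():
    """Two visual areas x two hemispheres on a small grid (80 voxels each)."""
    return da.bold.make_rois((10, 8, 4), ("V1", "hMT+"))


@pytest.fixture(scope="session")
def tiny_dataset(tiny_design, tiny_rois):
    """Default-gain noisy dataset used across analysis tests."""
    return da.bold.simulate_dataset(tiny_design, tiny_rois,
                                    da.bold.SimulationParams(), seed=11)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """One clean scan: no noise, drift, dispersion or direction weights."""
    design = da.design.build_design(seed=3, n_scans=1)
    rois = da.bold.make_rois((10, 8, 4), ("V1", "hMT+"))
    params = da.bold.SimulationParams(noise_sd=0.0, drift_pct=0.0,
                                      gain_dispersion=0.0, w_dir_sd=0.0,
                                      ar1=0.0)
    return da.bold.simulate_dataset(design, rois, params, seed=4)
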