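import numpy as np
import pytest

from chromodyn import (
    AcquisitionSchedule,
    KineticsTruth,
    edge_roi,
    synth_nucleus,
    synth_timelapse,
)


@pytest.fixture(scope="session")
def small_nucleus():
    """A 128x128 nucleus with heterochromatin texture, shared across tests."""
    return synth_nucleus(shape=(128, 128), n_blobs=40, seed=1)


@pytest.fixture(scope="session")
def small_roi(small_nucleus):
    return edge_roi(small_nucleus)


@pytest.fixture(scope="session")
def control_sim(small_nucleus, small_roi):
    """One control-condition simulated stack with full ground truth."""
    kin = KineticsTruth(
        t_on=6.0,
        t_off_intensity=30.0,
        t_off_cv=30.0,
        relax_amplitude=0.4,
        decay_start_s=60.0,
    )
    return synth_timelapse(
        small_nucleus, kin, small_roi, schedule=AcquisitionSchedule(), seed=11
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
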