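import numpy as np
import pytest

from swigpc.protocol import ProtocolParams, RRSeries
from swigpc.simulator import (
    PhantomSpec,
    Region,
    VelocityWaveform,
    default_phantom,
    make_coil_model,
    sample_spokes,
    simulate_rr,
)
from swigpc.trajectory import swig_angles


@pytest.fixture(scope="session")
def tissue_protocol():
    return ProtocolParams()  # TR 6.8, VENC 30, 13 beats, matrix 64, FOV 320


@pytest.fixture(scope="session")
def constant_rr():
    """13 beats at exactly 67 bpm (no variability)."""
    return RRSeries(np.full(13, 60000.0 / 67.0))


@pytest.fixture(scope="session")
def small_protocol():
    """Tiny protocol for fast unit tests."""
    return ProtocolParams(matrix=32, fov=320.0, n_heartbeats=5)


@pytest.fixture(scope="session")
def disk_phantom():
    """Single static disk centered in the FOV (radius 60 mm = 12 px)."""
    return PhantomSpec(
        regions=(Region("disk", "disk", (0.0, 0.0), (60.0,), 1.0),)
    )


@pytest.fixture(scope="session")
def swig_raw(tissue_protocol):
    """One noiseless SWIG acquisition of the default phantom, 4 coils.

    Session-scoped: simulation is the expensive common setup for the recon
    and velocimetry tests.
    """
    rr = simulate_rr(13, 67.0, 17.0, seed=5)
    coil = make_coil_model(4, tissue_protocol.matrix, 0.0, seed=6)
    sched = swig_angles(13, rr, tissue_protocol.tr)
    return sample_spokes(default_phantom(), sched, rr, tissue_protocol, coil)
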