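"""Shared fixtures: small geometries, noiseless simulations, tiny models."""
import os

# pin linear-algebra thread pools before numpy spins them up: float32 training
# trajectories are chaotic enough that reduction order must not vary by host
for _v in ("OPENBLAS_NUM_THREADS", "OMP_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_v, "1")

import numpy as np
import pytest

from oce4d import (
    ExcitationSpec,
    ScanGeometry,
    SimConfig,
    desk_preset,
    make_phantom,
    synth_wave_field,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_geometry():
    """A miniature scan: 8 x 8 lateral, 48 depth voxels, 40 volumes."""
    return ScanGeometry(
        fov_mm=(3.0, 3.0, 2.0), raw_shape_px=(8, 8, 48), volume_rate_hz=831.0,
        n_volumes=40,
    )


@pytest.fixture
def excitation():
    return ExcitationSpec(frequency_hz=100.0, needle_position_mm=(0.0, 0.0),
                          amplitude_nm=100.0)


@pytest.fixture
def noiseless_sim():
    return SimConfig(phase_noise_sd_rad=0.0, surface_depth_px_range=(6, 12))


@pytest.fixture
def noiseless_sequence(small_geometry, excitation, noiseless_sim):
    """One noiseless 10% gelatin acquisition at a 1.5 mm lateral offset."""
    phantom = make_phantom(10.0, "p0")
    return synth_wave_field(
        phantom, excitation, small_geometry, noiseless_sim,
        position_mm=(1.0, 1.0), rng=np.random.default_rng(7),
    )


@pytest.fixture(scope="session")
def desk_conditions():
    return desk_preset(phantoms_per_conc=2)
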