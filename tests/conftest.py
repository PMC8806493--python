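"""Shared fixtures: probe layout, small grids, and cached phantom-analog frames.

All synthetic data is generated at test time; grids are chosen coarse enough
to keep the full suite fast while the generator/reconstructor closure keeps
recovery exact on any self-consistent grid.
"""

import numpy as np
import pytest

from sbdot import (
    DiffusionForward,
    EllipsoidZone,
    Grid,
    MeasurementFrame,
    OpticalProperties,
    ProbeLayout,
    SceneModel,
)
from sbdot.synth import make_phantom_scene

AGAR_750 = OpticalProperties(0.006, 1.07)
COAG_PROPS = OpticalProperties(0.03, 3.0)


@pytest.fixture(scope="session")
def layout():
    return ProbeLayout()


@pytest.fixture(scope="session")
def fast_grid():
    """Coarse grid for unit tests (2240 voxels)."""
    return Grid((42.0, 48.0, 30.0), 3.0)


@pytest.fixture(scope="session")
def coarse_grid():
    """Grid used for the acceptance-style reconstructions."""
    return Grid((42.0, 48.0, 30.0), 3.0)


@pytest.fixture(scope="session")
def phantom_scene(coarse_grid):
    """Phantom-analog truth: agar background, 10 mm inclusion 2.7 mm from probe."""
    return make_phantom_scene(zone_props=COAG_PROPS, grid=coarse_grid)


@pytest.fixture(scope="session")
def phantom_prediction(phantom_scene, layout):
    return DiffusionForward(phantom_scene, layout).predict()


@pytest.fixture(scope="session")
def phantom_frame(phantom_prediction):
    """Noiseless calibrated phantom-analog frame."""
    return MeasurementFrame(0.0, 750.0, phantom_prediction, calibrated=True)


def noisy_frame(prediction, sigma, seed, time_s=0.0):
    rng = np.random.default_rng(seed)
    gains = 1.0 + sigma * rng.standard_normal((8, 8))
    return MeasurementFrame(time_s, 750.0, prediction * np.clip(gains, 0.05, None),
                            calibrated=True)


@pytest.fixture(scope="session")
def small_zone_scene(fast_grid):
    """A zone fully representable within the fit bounds (for closure tests)."""
    return SceneModel(
        background=AGAR_750,
        zone=EllipsoidZone((0.0, 0.0, 12.0), a=8.0, b=8.0),
        zone_props=COAG_PROPS,
        grid=fast_grid,
    )


@pytest.fixture(scope="session")
def small_zone_frame(small_zone_scene, layout):
    pred = DiffusionForward(small_zone_scene, layout).predict()
    return MeasurementFrame(0.0, 750.0, pred, calibrated=True)
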