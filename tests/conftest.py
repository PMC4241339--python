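"""Shared fixtures: compact phantom geometries and calibrated series."""

from __future__ import annotations

import pytest
from hypothesis import settings

from osteotrack import (
    AcquisitionModel,
    HealingTrajectory,
    PhantomSpec,
    apply_hu_map,
    estimate_hu_map,
    extract_phantom_region,
    generate_series,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: compact geometry for fast unit tests (full-size defaults are exercised
#: by the acceptance suite)
SMALL_PHANTOM = dict(
    grid_shape=(80, 64, 64),
    shaft_length=5.0,
    tube_offset=2.4,
    tube_radius=0.55,
    tube_wall_thickness=0.15,
)

#: larger field of view used by registration tests so that pose jitter
#: cannot push metric samples near the (static) calibration tubes
REG_PHANTOM = dict(
    grid_shape=(112, 96, 96),
    shaft_length=6.0,
    tube_offset=3.9,
    tube_radius=0.8,
    tube_wall_thickness=0.2,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return PhantomSpec(**SMALL_PHANTOM)


@pytest.fixture(scope="session")
def reg_spec() -> PhantomSpec:
    return PhantomSpec(**REG_PHANTOM)


def calibrate_volume(vol, spec):
    """Raw-to-HU conversion using the analytic tube regions."""
    water = extract_phantom_region(vol, spec.water_tube())
    air = extract_phantom_region(vol, spec.air_tube())
    return apply_hu_map(vol, estimate_hu_map(water, air))


@pytest.fixture(scope="session")
def clean_series(small_spec):
    """Noise-free, jitter-free 4-timepoint series with its ground truth."""
    traj = HealingTrajectory.unreamed()
    acq = AcquisitionModel(seed=5)
    volumes, truth = generate_series(small_spec, traj, acq, (0, 7, 14, 30))
    return volumes, truth


@pytest.fixture(scope="session")
def clean_series_hu(clean_series, small_spec):
    volumes, truth = clean_series
    return [calibrate_volume(v, small_spec) for v in volumes], truth
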