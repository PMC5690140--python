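"""Shared fixtures: a small fast torso phantom and test geometries."""

from __future__ import annotations

import numpy as np
import pytest

from tiletrack import PhantomSpec, ProjectionGeometry, TissueDensities, build_torso_volume


def small_phantom_spec(**overrides) -> PhantomSpec:
    """A scaled-down torso (half-size structures) that rasterizes fast."""
    defaults = dict(
        body_semiaxes=(70.0, 55.0, 60.0),
        lung_centers=((-28.0, -3.0, 6.0), (28.0, -3.0, 6.0)),
        lung_semiaxes=(22.0, 27.0, 35.0),
        rib_count=4,
        rib_ring_semiaxes=(62.0, 45.0),
        rib_spacing_mm=14.0,
        rib_center_z_mm=6.0,
        rib_half_height_mm=2.5,
        heart_center=(5.0, 12.0, 0.0),
        heart_radius_mm=18.0,
        tumor_center=(28.0, -3.0, 2.0),
        tumor_diameter_mm=18.0,
        tumor_height_mm=18.0,
        marker_offsets=((12.0, 0.0, 4.0), (-10.0, 7.0, -4.0), (0.0, -10.0, 7.0)),
        spacing=(2.5, 2.5, 3.0),
        margin_mm=5.0,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return small_phantom_spec()


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_torso_volume(small_spec)


@pytest.fixture(scope="session")
def small_spec_nomarkers() -> PhantomSpec:
    return small_phantom_spec(marker_offsets=())


@pytest.fixture(scope="session")
def small_phantom_nomarkers(small_spec_nomarkers):
    return build_torso_volume(small_spec_nomarkers)


@pytest.fixture
def test_geometry() -> ProjectionGeometry:
    """Desk-scale detector: 128 px at 1.6 mm pitch, Vero SAD/SDD."""
    return ProjectionGeometry(pixel_pitch_mm=1.6, detector_shape=(128, 128))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
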