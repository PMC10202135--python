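"""Shared fixtures: small canopies and rendered frames built per test run.

All pixel data is generated programmatically — no stored image fixtures.
Sizes are kept small (128-768 px sensors, <= 10 plants) so the whole suite
runs on one CPU in minutes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from tipsim import (
    CanopyScene,
    FieldConfig,
    LightConfig,
    PlantParams,
    TextureSet,
    build_canopy,
    build_plant,
    camera_for_gsd,
    render_scene,
)

# deprecation chatter from skimage morphology shims is irrelevant here
warnings.filterwarnings("ignore", category=FutureWarning)


FLAT_TEXTURES = TextureSet(leaf_texture="leaf_flat", soil_texture="soil_flat")
DIFFUSE_LIGHT = LightConfig(diffuse_fraction=1.0, cast_shadows=False)


@pytest.fixture(scope="session")
def default_params() -> PlantParams:
    return PlantParams()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_single_plant_scene(seed: int, tt_range=(50.0, 250.0), jitter_mm=30.0):
    """One plant near the origin on a 320 mm soil square; H <= 2.5 so no
    leaf can arch over another leaf's tip (tips stay unoccluded at nadir)."""
    gen = np.random.default_rng(seed)
    tt = float(gen.uniform(*tt_range))
    base = np.array([gen.uniform(-jitter_mm, jitter_mm),
                     gen.uniform(-jitter_mm, jitter_mm), 0.0])
    plant = build_plant(tt, PlantParams(), gen, base)
    return CanopyScene(plants=[plant], soil_extent=(-160.0, -160.0, 160.0, 160.0))


def make_random_canopy(seed: int, n_plants_max: int = 10):
    gen = np.random.default_rng(seed)
    n = int(gen.integers(3, n_plants_max + 1))
    fc = FieldConfig(
        sowing_density=float(n / 0.04),  # plot is 0.2 m x 0.2 m
        plot_width=200.0,
        plot_depth=200.0,
        row_spacing=100.0,
        thermal_time=float(gen.uniform(120.0, 380.0)),
        seed=seed,
    )
    return build_canopy(fc, PlantParams())


@pytest.fixture(scope="session")
def small_canopy() -> CanopyScene:
    fc = FieldConfig(
        sowing_density=150.0, plot_width=200.0, plot_depth=200.0,
        row_spacing=100.0, thermal_time=220.0, seed=5,
    )
    return build_canopy(fc, PlantParams())


@pytest.fixture(scope="session")
def rendered_small_canopy(small_canopy):
    cam = camera_for_gsd(1.0, view_zenith=30.0, sensor_width_px=160,
                         look_at=(100.0, 100.0, 0.0))
    light = LightConfig(diffuse_fraction=0.3, cast_shadows=True)
    frame = render_scene(small_canopy, cam, light, aa_factor=2)
    return small_canopy, cam, light, frame
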