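"""Shared fixtures: cached synthetic scenes and small geometric rasters."""

from __future__ import annotations

import functools

import numpy as np
import pytest

from hma.synthetic import SceneParams, generate_scene


@functools.lru_cache(maxsize=32)
def _cached_scene(seed: int, small: bool):
    if small:
        params = SceneParams(
            height=320, width=320, n_cells=6, cell_radius=(20.0, 28.0)
        )
    else:
        params = SceneParams()
    return generate_scene(params, seed=seed)


@pytest.fixture(scope="session")
def scene_factory():
    """scene_factory(seed, small=True) -> cached SyntheticScene."""

    def factory(seed: int, small: bool = True):
        return _cached_scene(seed, small)

    return factory


@pytest.fixture(scope="session")
def default_scene(scene_factory):
    """One scene at the full default study conditions."""
    return scene_factory(1, small=False)


@pytest.fixture()
def disk_image():
    """A bright disk (radius 20) on a dark 96x96 field, plus its mask."""
    yy, xx = np.mgrid[:96, :96]
    mask = (yy - 48) ** 2 + (xx - 48) ** 2 <= 20**2
    img = np.where(mask, 0.8, 0.2)
    return img, mask


@pytest.fixture()
def dumbbell_mask():
    """Two radius-12 disks with centers 20 px apart (overlapping)."""
    yy, xx = np.mgrid[:64, :96]
    d1 = (yy - 32) ** 2 + (xx - 38) ** 2 <= 12**2
    d2 = (yy - 32) ** 2 + (xx - 58) ** 2 <= 12**2
    return d1 | d2
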