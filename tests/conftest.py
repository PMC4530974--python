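"""Shared fixtures: phantoms and cached segmentation runs.

Session-scoped segmentations are reused across test modules so the suite
does not re-segment the same volume repeatedly.
"""

from dataclasses import replace

import numpy as np
import pytest

from octseg.metrics import compare_surfaces
from octseg.phantom import default_specs, generate_phantom
from octseg.pipeline import PipelineConfig, segment_volume


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def small_clean_spec(specs):
    """A 3-frame noise-free phantom with a frame-uniform pit (fast, exact)."""
    return replace(specs["fovea_clean"], n_frames=3)


@pytest.fixture(scope="session")
def small_clean_phantom(small_clean_spec):
    return generate_phantom(small_clean_spec)


@pytest.fixture(scope="session")
def speckle_phantom(specs):
    """The default 10-frame speckled fovea fixture, seed 1."""
    return generate_phantom(replace(specs["fovea_speckle"], seed=1))


@pytest.fixture(scope="session")
def vessels_phantom(specs):
    """The default 10-frame speckled + vessels fixture, seed 1."""
    return generate_phantom(replace(specs["vessels_speckle"], seed=1))


@pytest.fixture(scope="session")
def vessels_segmentation(vessels_phantom):
    """Full pipeline output on the vessels fixture at default config."""
    vol, truth, vessel_mask = vessels_phantom
    surfaces, enface = segment_volume(vol, PipelineConfig())
    return surfaces, enface, truth, vessel_mask


@pytest.fixture(scope="session")
def speckle_segmentation(speckle_phantom):
    vol, truth, _ = speckle_phantom
    surfaces, enface = segment_volume(vol, PipelineConfig())
    return surfaces, enface, truth


def crop_like(full_grid: np.ndarray, surfaces) -> np.ndarray:
    """Slice a full-volume (frame, column) grid to a SurfaceSet's window."""
    return full_grid[
        surfaces.frame_offset:surfaces.frame_offset + surfaces.n_frames,
        surfaces.column_offset:surfaces.column_offset + surfaces.n_cols,
    ]


@pytest.fixture(scope="session")
def stats_vs_truth():
    def _stats(surfaces, truth):
        return compare_surfaces(surfaces, truth)
    return _stats
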