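import warnings

import numpy as np
import pytest

from piezoecho import materials as mat
from piezoecho import mesh
from piezoecho.phantom import synthetic_scene


@pytest.fixture(autouse=True)
def _quiet_star_convexity():
    # shell tissues legitimately trigger the non-star-convex fallback
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*non-star-convex.*")
        yield


@pytest.fixture(scope="session")
def uniform_grid_5():
    """5x5x5 uniform grid, h = 1 cm."""
    return mesh.build_grid([0.05, 0.05, 0.05], 0.01)


@pytest.fixture(scope="session")
def water():
    return mat.get_material("Water")


@pytest.fixture(scope="session")
def small_tank():
    """Small homogeneous water box (4x4x4 cm, h = 5 mm, 512 cells)."""
    _, scene = synthetic_scene("homogeneous",
                               {"extent": (0.04, 0.04, 0.04), "base_h": 0.005})
    scene.meta["source_center"] = np.array([0.02, 0.02, 0.04])
    scene.meta["source_normal"] = np.array([0.0, 0.0, -1.0])
    return scene
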