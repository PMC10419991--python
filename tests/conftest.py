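import numpy as np
import pytest

from periograft import PhantomSpec, SurfaceMesh, generate_phantom
from periograft.meshing import extract_surface

# Explicit unit-cube triangulation (outward CCW winding) used by the
# hand-derived geometry oracles; keep it frozen.
CUBE_VERTS = np.array(
    [
        [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
        [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
    ],
    dtype=float,
)
CUBE_FACES = np.array(
    [
        [0, 2, 1], [0, 3, 2],  # bottom (-z)
        [4, 5, 6], [4, 6, 7],  # top (+z)
        [0, 1, 5], [0, 5, 4],  # front (-y)
        [2, 3, 7], [2, 7, 6],  # back (+y)
        [0, 4, 7], [0, 7, 3],  # left (-x)
        [1, 2, 6], [1, 6, 5],  # right (+x)
    ],
    dtype=np.int64,
)


@pytest.fixture
def unit_cube() -> SurfaceMesh:
    return SurfaceMesh(CUBE_VERTS.copy(), CUBE_FACES.copy(), name="cube")


def coarse_spec(**overrides) -> PhantomSpec:
    """Down-scaled study phantom for fast unit tests: same anatomy in mm,
    0.3 mm voxels on a 64^3 grid."""
    overrides.setdefault("grid_shape", (64, 64, 64))
    overrides.setdefault("spacing_mm", 0.3)
    return PhantomSpec(**overrides)


@pytest.fixture(scope="session")
def coarse_phantom():
    """Noiseless coarse phantom with ground truth and default seeds."""
    return generate_phantom(coarse_spec(noise_sd=0.0, blur_sigma_mm=0.0), rng_seed=0)


@pytest.fixture(scope="session")
def coarse_tissue(coarse_phantom) -> SurfaceMesh:
    """Hard-tissue (teeth + bone) surface of the coarse phantom truth."""
    return extract_surface(coarse_phantom.truth, [1, 2])
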