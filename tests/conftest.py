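import numpy as np
import pytest

from petqa.volumes import Grid, ImageVolume


@pytest.fixture(scope="session")
def disk_volume():
    """Uniform disk of radius 60 mm, activity 3.0, on a 96x96x4 grid with
    2 mm in-plane voxels (analytic oracle geometry used across recon tests)."""
    n = 96
    grid = Grid((n, n, 4), (2.0, 2.0, 2.0))
    x = (np.arange(n) - n // 2) * 2.0
    X, Y = np.meshgrid(x, x, indexing="ij")
    disk = ((X**2 + Y**2) <= 60.0**2).astype(float) * 3.0
    vol = ImageVolume(np.repeat(disk[:, :, None], 4, axis=2), grid.voxel_size)
    interior = (X**2 + Y**2) <= 40.0**2
    return {"grid": grid, "volume": vol, "interior_2d": interior, "activity": 3.0,
            "radius_mm": 60.0}


@pytest.fixture(scope="session")
def small_hoffman():
    from petqa.phantoms import HoffmanSurrogateSpec, generate_hoffman_surrogate

    grid = Grid((96, 96, 32), (2.0, 2.0, 2.78))
    spec = HoffmanSurrogateSpec(seed=1)
    vol, labels = generate_hoffman_surrogate(spec, grid)
    return {"grid": grid, "spec": spec, "volume": vol, "labels": labels}
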