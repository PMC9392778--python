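import numpy as np
import pytest

from hybridseg import PhantomSpec, Volume, generate_phantom
from hybridseg.variational import MarkerSet


@pytest.fixture(scope="session")
def sphere():
    """Binary sphere (radius 10 vox) in a 32³ grid with its analytic mask."""
    n = 32
    z, y, x = np.mgrid[:n, :n, :n]
    mask = (z - 16) ** 2 + (y - 16) ** 2 + (x - 16) ** 2 <= 100
    return mask


@pytest.fixture
def sphere_volume(sphere):
    return Volume(np.where(sphere, 0.8, 0.2).astype(float))


@pytest.fixture
def center_marker():
    return MarkerSet(inside=[(16, 16, 16)])


@pytest.fixture(scope="session")
def clean_aneurysm():
    """Noise-free, artifact-free straight-tube aneurysm phantom."""
    spec = PhantomSpec(
        grid_shape=(40, 40, 40),
        centerline_amplitude_mm=0.0,
        lumen_radius_mm=5.0,
        thrombus_outer_radius_mm=12.0,
        noise_sigma=0.0,
        dropout_fraction=0.0,
        texture_amplitude=0.0,
        rng_seed=1,
    )
    return generate_phantom(spec)


def dice_of(pred: np.ndarray, ref: np.ndarray) -> float:
    """Brute-force Dice used as an oracle against the package's pipeline."""
    pred = pred.astype(bool)
    ref = ref.astype(bool)
    den = pred.sum() + ref.sum()
    return 1.0 if den == 0 else 2.0 * np.logical_and(pred, ref).sum() / den
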