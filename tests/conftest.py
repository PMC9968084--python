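import numpy as np
import pytest

from octfundus.core import BORDER_NAMES, LayerSurfaces, OCTVolume
from octfundus.synthetic import PhantomConfig, render_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Speckled small-preset phantom shared across read-only tests."""
    return render_phantom(PhantomConfig.small(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free small phantom for exact construction checks."""
    return render_phantom(PhantomConfig.small(seed=7, speckle_shape=None))


@pytest.fixture()
def flat_volume_surfaces():
    """A tiny volume with flat, hand-placed borders for projection tests."""
    X, Y, Z = 5, 4, 24
    vol = OCTVolume(np.full((X, Y, Z), 0.5, dtype=np.float32), (1.0, 1.0, 0.5))
    depths = [2, 4, 6, 8, 10, 12, 14, 16, 20]
    surfaces = LayerSurfaces({
        name: np.full((X, Y), d, dtype=np.int32)
        for name, d in zip(BORDER_NAMES, depths)
    })
    return vol, surfaces


def naive_projection(volume, surfaces, top, bottom):
    """Independent brute-force per-pixel projection oracle (triple loop)."""
    X, Y, Z = volume.dims
    out = np.zeros((X, Y))
    t, b = surfaces[top], surfaces[bottom]
    for x in range(X):
        for y in range(Y):
            lo, hi = sorted((t[x, y], b[x, y]))
            acc = 0.0
            for z in range(lo, hi + 1):
                acc += float(volume.intensities[x, y, z])
            out[x, y] = acc / (hi - lo + 1)
    return out
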