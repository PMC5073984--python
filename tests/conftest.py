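import numpy as np
import pytest

from gelquant import GelImage
from gelquant.simulate import default_fixture, render_gel


def make_image(pixels, **kwargs) -> GelImage:
    """Build a GelImage from an array, padding to the 16x16 minimum."""
    px = np.asarray(pixels, dtype=float)
    if px.shape[0] < 16 or px.shape[1] < 16:
        padded = np.zeros((max(px.shape[0], 16), max(px.shape[1], 16)))
        padded[: px.shape[0], : px.shape[1]] = px
        px = padded
    return GelImage(pixels=px, **kwargs)


@pytest.fixture(scope="session")
def clean_gel():
    """One rendered 'clean' preset gel with its spec and truth table."""
    spec = default_fixture("clean", seed=7)
    image, truth = render_gel(spec)
    return spec, image, truth


def random_profiles(rng: np.random.Generator, n: int, max_len: int = 512):
    """Random test profiles: pure noise, and noise plus Gaussian bumps."""
    for _ in range(n):
        length = int(rng.integers(16, max_len + 1))
        values = rng.uniform(0.0, 10.0, length)
        if rng.random() < 0.5:
            rows = np.arange(length, dtype=float)
            for _ in range(int(rng.integers(1, 6))):
                pos = rng.uniform(2, length - 3)
                amp = rng.uniform(20, 200)
                sig = rng.uniform(1.0, 4.0)
                values += amp * np.exp(-((rows - pos) ** 2) / (2 * sig**2))
        yield values
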