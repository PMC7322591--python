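import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A seeded random 24x24 color image."""
    return rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)


@pytest.fixture
def random_plane(rng):
    """A seeded random 20x20 gray plane."""
    return rng.integers(0, 256, (20, 20), dtype=np.uint8)


def naive_local_entropy(plane: np.ndarray, n: int, bins: int = 256) -> np.ndarray:
    """Brute-force per-pixel window-histogram entropy (independent oracle)."""
    pad = n // 2
    padded = np.pad(plane, pad, mode="reflect").astype(np.int64)
    if bins != 256:
        padded = padded * bins // 256
    h, w = plane.shape
    out = np.zeros((h, w), dtype=np.float64)
    for i in range(h):
        for j in range(w):
            window = padded[i : i + n, j : j + n].ravel()
            counts = np.bincount(window, minlength=bins)
            p = counts[counts > 0] / (n * n)
            out[i, j] = -(p * np.log2(p)).sum()
    return out
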