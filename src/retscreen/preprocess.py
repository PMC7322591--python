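"""Unsharp masking and local Shannon-entropy images.

The screening pipeline turns each fundus photograph into two texture maps:
the luminance (gray level) and the green component are sharpened by unsharp
masking (UM) and then converted into *entropy images* — per-pixel Shannon
entropy of the intensity histogram in a centered ``n x n`` window::

    E(x, y) = - sum_i P(i) * log2 P(i)

where ``P(i)`` is the relative frequency of the i-th intensity level inside
the window.  High local entropy marks heterogeneous regions (vessels,
hemorrhages, exudates); severer retinopathy produces more of them.  The
entropy maps are rescaled to [0, 1] by the fixed theoretical maximum
``log2(min(n^2, bins))`` — not per-image min-max, which would destroy
comparability across images — and become the CNN inputs.

``local_entropy`` computes every window histogram exactly with per-level
summed-area tables, so a brute-force per-pixel histogram gives identical
values; borders are handled by reflective padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from . import image_io
from .errors import ConfigError, DataError
from .image_io import round_half_up, validate_plane, validate_rgb

__all__ = [
    "UMParams",
    "EntropyParams",
    "unsharp_mask",
    "local_entropy",
    "rescale_unit",
    "make_channel_input",
    "entropy_to_png",
    "CHANNELS",
]

CHANNELS = ("gray", "green")


@dataclass(frozen=True)
class UMParams:
    """Unsharp-mask parameters.

    sigma : Gaussian blur standard deviation in pixels (> 0).
    amount : scale of the high-frequency mask added back (>= 0);
        0 leaves the image unchanged.

    Defaults (sigma=2 px, amount=1) are tuned for the 100x100 working
    resolution and are fully configurable.
    """

    sigma: float = 2.0
    amount: float = 1.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ConfigError(f"sigma must be > 0, got {self.sigma}")
        if self.amount < 0:
            raise ConfigError(f"amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class EntropyParams:
    """Local-entropy parameters: odd window side ``block_size`` (default 9,
    the block size that maximized screening accuracy) and the number of
    intensity levels ``bins`` the 8-bit range is divided into (default 256,
    i.e. raw intensities)."""

    block_size: int = 9
    bins: int = 256

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ConfigError(f"block_size must be odd and >= 3, got {self.block_size}")
        if not 2 <= self.bins <= 256:
            raise ConfigError(f"bins must be in [2, 256], got {self.bins}")

    @property
    def max_entropy_bits(self) -> float:
        """Largest achievable window entropy: log2(min(n^2, bins))."""
        return float(np.log2(min(self.block_size**2, self.bins)))


def unsharp_mask(plane: np.ndarray, params: UMParams = UMParams()) -> np.ndarray:
    """Sharpen by adding back the high-frequency residual.

    ``out = clip(round(plane + amount * (plane - blur(plane, sigma))), 0, 255)``
    with reflective boundary handling in the Gaussian blur.
    """
    arr = validate_plane(plane).astype(np.float64)
    # "mirror" = reflect about the edge pixel, matching the np.pad
    # reflective padding used by local_entropy
    blurred = gaussian_filter(arr, sigma=params.sigma, mode="mirror")
    sharpened = arr + params.amount * (arr - blurred)
    return np.clip(round_half_up(sharpened), 0, 255).astype(np.uint8)


def _bin_indices(plane: np.ndarray, bins: int) -> np.ndarray:
    # uniform quantization of [0, 255] into `bins` levels
    idx = plane.astype(np.int64)
    if bins != 256:
        idx = idx * bins // 256
    return idx


def local_entropy(plane: np.ndarray, params: EntropyParams = EntropyParams()) -> np.ndarray:
    """Per-pixel Shannon entropy (bits) of the centered n x n window histogram.

    Output has the same height x width as the input (reflective padding at
    the borders); ``0 * log2(0)`` is taken as 0.  Exact: window counts are
    integer histograms accumulated by per-level summed-area tables.
    """
    arr = validate_plane(plane)
    n = params.block_size
    h, w = arr.shape
    if h < n or w < n:
        raise DataError(f"plane {arr.shape} smaller than {n}x{n} window")

    pad = n // 2
    padded = np.pad(arr, pad, mode="reflect")
    idx = _bin_indices(padded, params.bins)

    # one summed-area table per intensity level -> exact window counts
    # int16 suffices while the padded pixel count fits; counts stay exact
    dtype = np.int16 if idx.size < 2**15 else np.int64
    sat = np.zeros((params.bins, idx.shape[0] + 1, idx.shape[1] + 1), dtype=dtype)
    rows, cols = np.indices(idx.shape)
    sat[idx, rows + 1, cols + 1] = 1
    np.cumsum(sat, axis=1, out=sat)
    np.cumsum(sat, axis=2, out=sat)
    counts = sat[:, n:, n:] - sat[:, :-n, n:] - sat[:, n:, :-n] + sat[:, :-n, :-n]
    assert counts.shape[1:] == (h, w)

    # -sum_i p_i log2 p_i  ==  log2 N - (1/N) sum_i c_i log2 c_i,  N = n^2
    n_sq = n * n
    levels = np.arange(1, n_sq + 1, dtype=np.float64)
    table = np.concatenate(([0.0], levels * np.log2(levels)))
    return np.log2(n_sq) - table[counts].sum(axis=0) / n_sq


def rescale_unit(entropy: np.ndarray, params: EntropyParams = EntropyParams()) -> np.ndarray:
    """Divide by the fixed theoretical maximum log2(min(n^2, bins)).

    Fixed (not per-image) scaling keeps entropy images comparable across the
    corpus; output lies in [0, 1].
    """
    arr = np.asarray(entropy, dtype=np.float64)
    if arr.size and arr.min() < 0:
        raise DataError("entropy values must be >= 0")
    return arr / params.max_entropy_bits


def make_channel_input(
    image: np.ndarray,
    um: UMParams = UMParams(),
    ep: EntropyParams = EntropyParams(),
    channel: str = "gray",
) -> np.ndarray:
    """Full preprocessing for one CNN input channel.

    Composition: channel extraction (luminance or green plane) ->
    unsharp_mask -> local_entropy -> rescale_unit.
    """
    rgb = validate_rgb(image)
    if channel == "gray":
        plane = image_io.to_luminance(rgb)
    elif channel == "green":
        plane = image_io.extract_green(rgb)
    else:
        raise ConfigError(f"channel must be one of {CHANNELS}, got {channel!r}")
    sharpened = unsharp_mask(plane, um)
    return rescale_unit(local_entropy(sharpened, ep), ep)


def entropy_to_png(entropy: np.ndarray, path) -> None:
    """Export a unit-scaled entropy image as 8-bit PNG for visual inspection."""
    arr = np.asarray(entropy, dtype=np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise DataError("expected unit-scaled entropy in [0, 1]")
    image_io.save_image(np.clip(round_half_up(arr * 255), 0, 255).astype(np.uint8), path)
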