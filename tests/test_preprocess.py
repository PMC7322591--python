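import numpy as np
import pytest

from retscreen import image_io, preprocess
from retscreen.errors import ConfigError, DataError
from retscreen.preprocess import EntropyParams, UMParams

from conftest import naive_local_entropy


def dense_unsharp_oracle(plane: np.ndarray, sigma: float, amount: float) -> np.ndarray:
    """Direct dense separable Gaussian convolution with the same truncated
    kernel and reflective padding, then the same round/clip step."""
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    arr = plane.astype(np.float64)
    padded = np.pad(arr, radius, mode="reflect")
    h, w = arr.shape
    rows = np.zeros((h, w + 2 * radius))
    for i in range(h):
        for j in range(w + 2 * radius):
            rows[i, j] = (padded[i : i + 2 * radius + 1, j] * kernel).sum()
    blurred = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            blurred[i, j] = (rows[i, j : j + 2 * radius + 1] * kernel).sum()
    sharp = arr + amount * (arr - blurred)
    return np.clip(np.floor(sharp + 0.5), 0, 255).astype(np.uint8)


class TestUnsharpMask:
    def test_constant_plane_unchanged(self):
        plane = np.full((12, 12), 42, dtype=np.uint8)
        assert np.array_equal(preprocess.unsharp_mask(plane, UMParams(1.5, 2.0)), plane)

    def test_zero_amount_is_identity(self, random_plane):
        out = preprocess.unsharp_mask(random_plane, UMParams(2.0, 0.0))
        assert np.array_equal(out, random_plane)

    def test_step_edge_overshoots(self):
        plane = np.zeros((9, 16), dtype=np.uint8)
        plane[:, 8:] = 200
        out = preprocess.unsharp_mask(plane, UMParams(1.0, 1.0)).astype(int)
        # high-boost sharpening overshoots above the step and clips to zero below it
        assert (out[:, 8] > 200).all()
        assert (out[:, 7] == 0).all()
        assert np.array_equal(out, dense_unsharp_oracle(plane, 1.0, 1.0))

    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    def test_matches_dense_convolution_oracle(self, rng, sigma):
        plane = rng.integers(0, 256, (16, 16), dtype=np.uint8)
        out = preprocess.unsharp_mask(plane, UMParams(sigma, 1.0))
        oracle = dense_unsharp_oracle(plane, sigma, 1.0)
        assert np.array_equal(out, oracle)

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ConfigError):
            UMParams(sigma=0.0)
        with pytest.raises(ConfigError):
            UMParams(sigma=1.0, amount=-0.5)


class TestLocalEntropy:
    def test_constant_plane_gives_zero(self):
        plane = np.full((15, 15), 93, dtype=np.uint8)
        assert not preprocess.local_entropy(plane, EntropyParams(9)).any()

    def test_all_distinct_window_reaches_log2_81(self):
        # 9x9 block of 81 distinct intensities: uniform histogram
        plane = np.arange(81, dtype=np.uint8).reshape(9, 9)
        ent = preprocess.local_entropy(plane, EntropyParams(9))
        assert ent[4, 4] == pytest.approx(np.log2(81), abs=1e-12)

    def test_two_level_window_closed_form(self):
        # 40 pixels of one intensity, 41 of another
        plane = np.full((9, 9), 10, dtype=np.uint8)
        plane.ravel()[:40] = 200
        ent = preprocess.local_entropy(plane, EntropyParams(9))
        expected = -(40 / 81) * np.log2(40 / 81) - (41 / 81) * np.log2(41 / 81)
        assert ent[4, 4] == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_matches_bruteforce_histogram_oracle(self, rng, n):
        plane = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        fast = preprocess.local_entropy(plane, EntropyParams(n))
        assert np.abs(fast - naive_local_entropy(plane, n)).max() <= 1e-9

    @pytest.mark.parametrize("bins", [8, 64])
    def test_reduced_bins_match_oracle(self, rng, bins):
        plane = rng.integers(0, 256, (15, 15), dtype=np.uint8)
        fast = preprocess.local_entropy(plane, EntropyParams(5, bins=bins))
        assert np.abs(fast - naive_local_entropy(plane, 5, bins=bins)).max() <= 1e-9

    def test_permutation_invariance(self, rng, random_plane):
        # entropy depends only on the histogram, not the intensity labels
        perm = rng.permutation(256).astype(np.uint8)
        base = preprocess.local_entropy(random_plane, EntropyParams(5))
        remapped = preprocess.local_entropy(perm[random_plane], EntropyParams(5))
        assert np.abs(base - remapped).max() <= 1e-12

    def test_bounds_and_zero_iff_constant(self, rng):
        plane = rng.integers(0, 256, (20, 20), dtype=np.uint8)
        for n in (3, 9):
            ent = preprocess.local_entropy(plane, EntropyParams(n))
            assert ent.min() >= 0
            assert ent.max() <= np.log2(min(n * n, 256)) + 1e-12
            # a dense random plane has no constant window
            assert (ent > 0).all()

    def test_plane_smaller_than_window_rejected(self):
        with pytest.raises(DataError):
            preprocess.local_entropy(np.zeros((5, 5), dtype=np.uint8), EntropyParams(9))

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigError):
            EntropyParams(block_size=4)
        with pytest.raises(ConfigError):
            EntropyParams(block_size=1)
        with pytest.raises(ConfigError):
            EntropyParams(block_size=9, bins=257)

    def test_contrast_stretch_does_not_reduce_entropy(self, rng):
        # widening intensity spacing (injective integer map) preserves the
        # window histograms, so mean local entropy cannot drop
        plane = rng.integers(80, 176, (20, 20), dtype=np.uint8)
        stretched = np.clip(
            np.floor((plane.astype(np.float64) - 128) * 1.5 + 128 + 0.5), 0, 255
        ).astype(np.uint8)
        before = preprocess.local_entropy(plane, EntropyParams(9)).mean()
        after = preprocess.local_entropy(stretched, EntropyParams(9)).mean()
        assert after >= before - 1e-12


class TestRescaleUnit:
    def test_zero_maps_to_zero(self):
        out = preprocess.rescale_unit(np.zeros((4, 4)), EntropyParams(9))
        assert not out.any()

    def test_theoretical_max_maps_to_one(self):
        out = preprocess.rescale_unit(np.array([[np.log2(81)]]), EntropyParams(9))
        assert out[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_value(self):
        half = np.log2(81) / 2
        out = preprocess.rescale_unit(np.array([[half]]), EntropyParams(9))
        assert out[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_bins_limit_the_maximum(self):
        # with fewer intensity levels than window pixels, bins cap the entropy
        out = preprocess.rescale_unit(np.array([[3.0]]), EntropyParams(9, bins=8))
        assert out[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_negative_entropy_rejected(self):
        with pytest.raises(DataError):
            preprocess.rescale_unit(np.array([[-0.1]]), EntropyParams(9))


class TestMakeChannelInput:
    def test_constant_image_gives_zero_inputs(self):
        img = np.full((20, 20, 3), 120, dtype=np.uint8)
        for channel in preprocess.CHANNELS:
            assert not preprocess.make_channel_input(img, channel=channel).any()

    def test_pure_green_image_zero_entropy_both_paths(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        img[:, :, 1] = 255
        # gray path sees a constant 150 plane, green path a constant 255 plane
        assert image_io.to_luminance(img)[0, 0] == 150
        for channel in preprocess.CHANNELS:
            assert not preprocess.make_channel_input(img, channel=channel).any()

    def test_composition_equals_manual_chain(self, random_rgb):
        um, ep = UMParams(1.5, 0.8), EntropyParams(5)
        combined = preprocess.make_channel_input(random_rgb, um, ep, "green")
        manual = preprocess.rescale_unit(
            preprocess.local_entropy(
                preprocess.unsharp_mask(image_io.extract_green(random_rgb), um), ep
            ),
            ep,
        )
        assert np.array_equal(combined, manual)

    def test_unknown_channel_rejected(self, random_rgb):
        with pytest.raises(ConfigError):
            preprocess.make_channel_input(random_rgb, channel="blue")

    def test_entropy_png_export(self, tmp_path, random_rgb):
        ent = preprocess.make_channel_input(random_rgb)
        path = tmp_path / "entropy.png"
        preprocess.entropy_to_png(ent, path)
        from PIL import Image

        arr = np.asarray(Image.open(path))
        assert arr.shape == ent.shape
        assert np.array_equal(arr, np.floor(ent * 255 + 0.5).astype(np.uint8))
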