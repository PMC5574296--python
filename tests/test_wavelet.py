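"""Color-wavelet features: DWT, subband selection, GLCM, Haralick stats."""

import numpy as np
import pytest
import pywt

import polypscan as ps
from polypscan import wavelet
from polypscan.exceptions import ConfigError, DataError, ShapeError
from polypscan.wavelet import (
    ChannelDecomposition,
    compute_glcm,
    dwt3,
    haralick_stats,
    quantize,
    select_middle_subbands,
    split_channels,
)


def brute_force_glcm(img, direction, distance, levels):
    """Independent oracle: enumerate every pixel pair with nested loops."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = (o * distance for o in offsets[direction])
    counts = np.zeros((levels, levels))
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[img[r, c], img[r2, c2]] += 1
    counts += counts.T
    return counts / counts.sum()


def direct_haralick(p):
    """Independent oracle: literal summation over all (i, j)."""
    g = p.shape[0]
    mu_i = sum(i * p[i, j] for i in range(g) for j in range(g))
    mu_j = sum(j * p[i, j] for i in range(g) for j in range(g))
    var_i = sum((i - mu_i) ** 2 * p[i, j] for i in range(g) for j in range(g))
    var_j = sum((j - mu_j) ** 2 * p[i, j] for i in range(g) for j in range(g))
    energy = sum(p[i, j] ** 2 for i in range(g) for j in range(g))
    entropy = -sum(p[i, j] * np.log2(p[i, j]) for i in range(g) for j in range(g) if p[i, j] > 0)
    homogeneity = sum(p[i, j] / (1 + abs(i - j)) for i in range(g) for j in range(g))
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        corr = 1.0
    else:
        corr = sum((i - mu_i) * (j - mu_j) * p[i, j] for i in range(g) for j in range(g)) / denom
    return corr, energy, homogeneity, entropy


class TestSplitChannels:
    def test_pure_red_window(self):
        px = np.zeros((227, 227, 3), dtype=np.uint8)
        px[:, :, 0] = 255
        ch = split_channels(ps.Window(px, (0, 0)))
        assert (ch["r"] == 255).all() and (ch["g"] == 0).all() and (ch["b"] == 0).all()

    def test_gray_window_gives_identical_channels(self):
        px = np.full((227, 227, 3), 77, dtype=np.uint8)
        ch = split_channels(ps.Window(px, (0, 0)))
        np.testing.assert_array_equal(ch["r"], ch["g"])
        np.testing.assert_array_equal(ch["g"], ch["b"])

    def test_channels_recombine_to_window(self, random_window):
        ch = split_channels(random_window)
        recombined = np.stack([ch["r"], ch["g"], ch["b"]], axis=-1)
        np.testing.assert_array_equal(recombined, random_window.pixels)

    def test_grayscale_input_raises(self):
        with pytest.raises(ShapeError):
            split_channels(np.zeros((227, 227)))


class TestDwt3:
    def test_constant_image_has_zero_details(self):
        decomp = dwt3(np.full((227, 227), 42.0))
        assert len(decomp.details) == 9
        for cl in range(1, 10):
            assert np.abs(decomp.detail(cl)).max() < 1e-10

    def test_perfect_reconstruction(self, rng):
        img = rng.standard_normal((227, 227)) * 50 + 100
        decomp = dwt3(img, wavelet="db6", mode="symmetric")
        coeffs = [
            decomp.approx,
            tuple(decomp.details[6:9]),
            tuple(decomp.details[3:6]),
            tuple(decomp.details[0:3]),
        ]
        rec = pywt.waverec2(coeffs, "db6", mode="symmetric")
        assert np.abs(rec[: img.shape[0], : img.shape[1]] - img).max() < 1e-8

    def test_unknown_wavelet_raises(self):
        with pytest.raises(ConfigError):
            dwt3(np.zeros((32, 32)), wavelet="not_a_wavelet")

    def test_level_ordering_matches_band_frequencies(self, rng):
        # level-1 details of a fine checkerboard carry more energy than level-3
        img = np.indices((128, 128)).sum(axis=0) % 2 * 100.0
        decomp = dwt3(img, wavelet="haar", mode="periodization")
        e1 = sum(np.sum(decomp.detail(cl) ** 2) for cl in (1, 2, 3))
        e3 = sum(np.sum(decomp.detail(cl) ** 2) for cl in (7, 8, 9))
        assert e1 > 100 * e3


class TestSubbandSelection:
    def test_selects_nine_middle_detail_images(self, random_window):
        ch = split_channels(random_window)
        decomps = {c: dwt3(ch[c], name=c) for c in "rgb"}
        selected = select_middle_subbands(decomps)
        assert len(selected) == 9
        k = 0
        for c in "rgb":
            for cl in (4, 5, 6):
                np.testing.assert_array_equal(selected[k], decomps[c].detail(cl))
                k += 1

    def test_selection_ignores_other_subbands(self, random_window):
        ch = split_channels(random_window)
        decomps = {c: dwt3(ch[c], name=c) for c in "rgb"}
        baseline = select_middle_subbands(decomps)
        perturbed = {
            c: ChannelDecomposition(
                channel=c,
                approx=d.approx + 99.0,
                details=tuple(band + 99.0 if cl not in (4, 5, 6) else band for cl, band in enumerate(d.details, start=1)),
            )
            for c, d in decomps.items()
        }
        for a, b in zip(baseline, select_middle_subbands(perturbed)):
            np.testing.assert_array_equal(a, b)


class TestQuantize:
    def test_constant_maps_to_zero(self):
        assert (quantize(np.full((10, 10), 3.7), 32) == 0).all()

    def test_three_values_three_levels(self):
        q = quantize(np.array([[-1.0, 0.0, 1.0]]), 3)
        np.testing.assert_array_equal(q, [[0, 1, 2]])

    def test_ramp_occupies_every_level(self):
        q = quantize(np.linspace(0, 1, 1024).reshape(32, 32), 32)
        assert set(np.unique(q)) == set(range(32))

    def test_non_finite_raises(self):
        with pytest.raises(DataError):
            quantize(np.array([[np.nan, 1.0]]), 8)


class TestGlcm:
    def test_two_horizontal_pairs_by_hand(self):
        glcm = compute_glcm(np.array([[0, 0], [1, 1]]), 0, 1, 2)
        np.testing.assert_allclose(glcm.matrix, [[0.5, 0.0], [0.0, 0.5]])

    def test_two_vertical_pairs_by_hand(self):
        glcm = compute_glcm(np.array([[0, 1], [0, 1]]), 90, 1, 2)
        np.testing.assert_allclose(glcm.matrix, [[0.5, 0.0], [0.0, 0.5]])

    @pytest.mark.parametrize("direction", [0, 45, 90, 135])
    def test_matches_brute_force_oracle(self, direction, rng):
        for _ in range(25):
            levels = int(rng.integers(2, 9))
            img = rng.integers(0, levels, (int(rng.integers(3, 17)), int(rng.integers(3, 17))))
            ours = compute_glcm(img, direction, 1, levels).matrix
            np.testing.assert_array_equal(ours, brute_force_glcm(img, direction, 1, levels))

    @pytest.mark.parametrize("direction,skimage_angle", [(0, 0.0), (45, 3 * np.pi / 4), (90, np.pi / 2), (135, np.pi / 4)])
    def test_matches_skimage_graycomatrix(self, direction, skimage_angle, rng):
        from skimage.feature import graycomatrix

        img = rng.integers(0, 8, (14, 14)).astype(np.uint8)
        ours = compute_glcm(img, direction, 1, 8).matrix
        ref = graycomatrix(img, [1], [skimage_angle], levels=8, symmetric=True, normed=True)[:, :, 0, 0]
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_normalized_and_symmetric(self, rng):
        img = rng.integers(0, 16, (20, 20))
        m = compute_glcm(img, 45, 1, 16).matrix
        assert abs(m.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(m, m.T)

    def test_image_smaller_than_offset_raises(self):
        with pytest.raises(DataError):
            compute_glcm(np.array([[0]]), 0, 1, 2)


class TestHaralick:
    def test_constant_image_degenerate_conventions(self):
        p = np.zeros((4, 4))
        p[0, 0] = 1.0
        corr, energy, homog, entropy = haralick_stats(p)
        assert (corr, energy, homog) == (1.0, 1.0, 1.0)
        assert entropy == 0.0

    def test_two_level_diagonal_closed_form(self):
        corr, energy, homog, entropy = haralick_stats(np.diag([0.5, 0.5]))
        assert corr == 1.0 and energy == 0.5 and homog == 1.0
        assert abs(entropy - 1.0) < 1e-15  # one bit

    def test_uniform_matrix_closed_form(self):
        g = 8
        corr, energy, homog, entropy = haralick_stats(np.full((g, g), 1.0 / g**2))
        assert abs(energy - 1.0 / g**2) < 1e-15
        assert abs(entropy - 2 * np.log2(g)) < 1e-12
        assert abs(corr) < 1e-12

    def test_matches_direct_summation_oracle(self, rng):
        for _ in range(20):
            g = int(rng.integers(2, 10))
            m = rng.random((g, g))
            m = m + m.T
            m /= m.sum()
            np.testing.assert_allclose(haralick_stats(m), direct_haralick(m), atol=1e-12)


class TestExtractColorWavelet:
    def test_vector_has_documented_length_and_is_finite(self, random_window):
        v = ps.extract_color_wavelet(random_window)
        assert v.shape == (144,)
        assert np.isfinite(v).all()

    def test_deterministic(self, random_window):
        np.testing.assert_array_equal(
            ps.extract_color_wavelet(random_window), ps.extract_color_wavelet(random_window)
        )

    def test_independent_of_frame_index(self, random_window):
        moved = ps.Window(random_window.pixels, origin=(10, 20), frame_index=5)
        np.testing.assert_array_equal(ps.extract_color_wavelet(random_window), ps.extract_color_wavelet(moved))

    def test_statistic_range_invariants(self, small_dataset):
        extractor = ps.ColorWaveletExtractor()
        feats = extractor.transform(small_dataset.windows[:6])
        layout = feats.reshape(len(feats), 9, 4, 4)  # (win, channel×subband, direction, stat)
        energy, homog, entropy = layout[..., 1], layout[..., 2], layout[..., 3]
        assert ((energy > 0) & (energy <= 1)).all()
        assert ((homog > 0) & (homog <= 1)).all()
        assert (entropy >= 0).all()

    def test_swapping_r_and_b_swaps_feature_blocks(self, random_window):
        v = ps.extract_color_wavelet(random_window)
        swapped = ps.Window(random_window.pixels[:, :, ::-1], origin=(0, 0))
        w = ps.extract_color_wavelet(swapped)
        np.testing.assert_array_equal(w[0:48], v[96:144])
        np.testing.assert_array_equal(w[96:144], v[0:48])
        np.testing.assert_array_equal(w[48:96], v[48:96])

    def test_transformer_matches_function(self, random_window):
        ours = ps.ColorWaveletExtractor().transform([random_window])[0]
        np.testing.assert_array_equal(ours, ps.extract_color_wavelet(random_window))
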