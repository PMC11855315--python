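import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from poremorph import apply_clahe, apply_threshold, denoise_nlm, preprocess
from poremorph.errors import ContractError, DegenerateTileError
from poremorph.preprocessing import BLACK, WHITE
from poremorph.scale import AnalysisSettings


def classic_histeq_oracle(img):
    """Closed-form histogram equalization: v -> (cdf(v)-cdf_min)/(1-cdf_min)*255."""
    hist = np.bincount(img.ravel(), minlength=256)
    cdf = np.cumsum(hist) / img.size
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    lut = np.rint((cdf - cdf_min) / (1 - cdf_min) * 255).astype(np.uint8) if cdf_min < 1 else None
    return lut[img]


def clipped_tile_histeq_oracle(img, n_tiles, clip_limit):
    """Independent brute-force CLAHE: per-tile clipped histeq, no interpolation."""
    h, w = img.shape
    out = np.zeros_like(img)
    th, tw = h // n_tiles, w // n_tiles
    for i in range(n_tiles):
        for j in range(n_tiles):
            tile = img[i * th : (i + 1) * th, j * tw : (j + 1) * tw]
            hist = np.bincount(tile.ravel(), minlength=256).astype(float)
            clip = clip_limit * tile.size / 256.0
            excess = np.maximum(hist - clip, 0).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            cdf = np.cumsum(hist) / hist.sum()
            lut = np.rint(cdf * 255).astype(np.uint8)
            out[i * th : (i + 1) * th, j * tw : (j + 1) * tw] = lut[tile]
    return out


def histogram_flatness(img):
    """Variance of the 256-bin histogram counts; flatter = smaller."""
    return float(np.var(np.bincount(img.ravel(), minlength=256)))


class TestClahe:
    def test_constant_image_stays_constant(self):
        img = np.full((32, 32), 128, np.uint8)
        out = apply_clahe(img, clahe_size=4)
        assert (out == out.flat[0]).all()
        assert out.shape == img.shape

    def test_single_tile_huge_clip_is_classic_histeq(self):
        img = np.full((8, 8), 50, np.uint8)
        img[:, 4:] = 200
        out = apply_clahe(img, clahe_size=1, clip_limit=1e9)
        expected = classic_histeq_oracle(img)  # 50 -> 0, 200 -> 255
        assert (out == expected).all()

    def test_bimodal_halves_flatten(self):
        rng = np.random.default_rng(7)
        img = np.empty((64, 64))
        img[:, :32] = rng.normal(60, 5, (64, 32))
        img[:, 32:] = rng.normal(180, 5, (64, 32))
        img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
        out = apply_clahe(img, clahe_size=2, clip_limit=10.0)
        oracle = clipped_tile_histeq_oracle(img, 2, 10.0)
        # both the implementation and the independent oracle widen the
        # per-half spans and flatten the global histogram
        for result in (out, oracle):
            assert np.ptp(result[:, :32]) > np.ptp(img[:, :32])
            assert np.ptp(result[:, 32:]) > np.ptp(img[:, 32:])
            assert histogram_flatness(result) < histogram_flatness(img)
        assert out.shape == img.shape and out.dtype == np.uint8

    def test_tile_larger_than_image_errors(self):
        with pytest.raises(DegenerateTileError):
            apply_clahe(np.zeros((16, 16), np.uint8), clahe_size=32)

    def test_pixels_mode_tile_side(self):
        img = np.random.default_rng(0).integers(0, 255, (64, 64)).astype(np.uint8)
        out = apply_clahe(img, clahe_size=16, mode="pixels")
        assert out.shape == img.shape


class TestDenoise:
    def test_constant_image_unchanged(self):
        img = np.full((24, 24), 77, np.uint8)
        assert (denoise_nlm(img, strength=50, kernel_size=5) == 77).all()

    def test_outlier_pulled_toward_background(self):
        img = np.full((21, 21), 100, np.uint8)
        img[10, 10] = 255
        out = denoise_nlm(img, strength=40, kernel_size=7)
        assert out[10, 10] < 255
        assert out[10, 10] >= 100

    def test_outlier_direction_matches_nlm_weight_oracle(self):
        # direct evaluation of the plain NLM weighted mean at the outlier
        img = np.full((15, 15), 100.0)
        img[7, 7] = 255.0
        h, half, p = 40.0, 2, 5  # 5x5 patches
        patches = {}
        for r in range(half, 15 - half):
            for c in range(half, 15 - half):
                patches[(r, c)] = img[r - half : r + half + 1, c - half : c + half + 1]
        ref = patches[(7, 7)]
        wsum = vsum = 0.0
        for (r, c), patch in patches.items():
            d2 = ((patch - ref) ** 2).mean()
            wgt = np.exp(-d2 / h**2)
            wsum += wgt
            vsum += wgt * img[r, c]
        oracle_value = vsum / wsum
        assert oracle_value < 255.0  # oracle agrees: the outlier must move toward 100
        out = denoise_nlm(img.astype(np.uint8), strength=40, kernel_size=5)
        assert out[7, 7] < 255

    def test_gaussian_noise_variance_reduced(self):
        rng = np.random.default_rng(42)
        clean = np.full((64, 64), 120.0)
        noisy = np.clip(clean + rng.normal(0, 15, clean.shape), 0, 255).astype(np.uint8)
        den = denoise_nlm(noisy, strength=30, kernel_size=5)
        assert ((den - clean) ** 2).mean() < ((noisy - clean) ** 2).mean()

    def test_even_kernel_rejected(self):
        with pytest.raises(ContractError):
            denoise_nlm(np.zeros((8, 8), np.uint8), strength=10, kernel_size=4)


class TestThreshold:
    def test_strictly_under_goes_black(self):
        img = np.array([[84, 85, 86]], np.uint8)
        out = apply_threshold(img, 85)
        assert out.tolist() == [[BLACK, WHITE, WHITE]]

    def test_uniform_above_cutoff_all_white(self):
        out = apply_threshold(np.full((10, 10), 200, np.uint8), 120)
        assert (out == WHITE).all()

    @given(
        hnp.arrays(np.uint8, (12, 12), elements=st.integers(0, 255)),
        st.integers(0, 255),
        st.integers(0, 255),
    )
    @settings(max_examples=50, deadline=None)
    def test_black_set_monotone_in_cutoff(self, img, c1, c2):
        lo, hi = sorted((c1, c2))
        black_lo = apply_threshold(img, lo) == BLACK
        black_hi = apply_threshold(img, hi) == BLACK
        assert (black_lo <= black_hi).all()  # raising the cutoff never shrinks the black set

    @given(hnp.arrays(np.uint8, (8, 8), elements=st.integers(0, 255)), st.integers(1, 255))
    @settings(max_examples=30, deadline=None)
    def test_idempotent_on_own_output(self, img, cutoff):
        once = apply_threshold(img, cutoff)
        assert (apply_threshold(once, cutoff) == once).all()


def test_pipeline_order_and_stages():
    img = np.random.default_rng(5).integers(0, 255, (64, 64)).astype(np.uint8)
    s = AnalysisSettings(denoise_strength=10, denoise_size=5, clahe_size=4)
    stages = preprocess(img, s)
    assert list(stages) == ["original", "clahe", "denoised", "threshold"]
    manual = apply_threshold(
        denoise_nlm(apply_clahe(img, 4, s.clahe_clip_limit), 10, 5), s.grayscale_threshold
    )
    assert (stages["threshold"] == manual).all()
    assert set(np.unique(stages["threshold"])) <= {BLACK, WHITE}
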