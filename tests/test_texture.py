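import numpy as np
import pytest

from burnscope import (compute_glcm, feature_vector, glcm_contrast,
                       glcm_correlation, quantize_levels, rgb_to_luv)
from burnscope.errors import ValidationError
from burnscope.texture import OFFSETS


def brute_force_glcm(indices, distance, angle, symmetric, levels):
    """Independent double-loop pair enumeration."""
    dr, dc = (o * distance for o in OFFSETS[angle])
    H, W = indices.shape
    counts = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                counts[indices[r, c], indices[r2, c2]] += 1
                if symmetric:
                    counts[indices[r2, c2], indices[r, c]] += 1
    return counts / counts.sum()


def brute_force_contrast(p):
    G = p.shape[0]
    return sum((i - j) ** 2 * p[i, j] for i in range(G) for j in range(G))


def brute_force_correlation(p):
    G = p.shape[0]
    pi, pj = p.sum(axis=1), p.sum(axis=0)
    mi = sum(i * pi[i] for i in range(G))
    mj = sum(j * pj[j] for j in range(G))
    si = np.sqrt(sum((i - mi) ** 2 * pi[i] for i in range(G)))
    sj = np.sqrt(sum((j - mj) ** 2 * pj[j] for j in range(G)))
    if si == 0 or sj == 0:
        return 0.0
    return sum((i - mi) * (j - mj) * p[i, j] for i in range(G)
               for j in range(G)) / (si * sj)


class TestQuantizeLevels:
    def test_two_levels(self):
        out = quantize_levels(np.array([[0.0, 255.0]] * 4), 2)
        assert sorted(np.unique(out)) == [0, 1]

    def test_constant_plane_all_zero(self):
        assert not quantize_levels(np.full((6, 6), 9.0), 8).any()

    def test_uniform_ramp_equal_bins(self):
        out = quantize_levels(np.arange(256.0).reshape(16, 16), 8)
        counts = np.bincount(out.ravel(), minlength=8)
        assert np.abs(counts - 32).max() <= 1


class TestComputeGlcm:
    def test_constant_image_single_entry(self):
        g = compute_glcm(np.zeros((4, 4), dtype=int), 1, 0, True, levels=1)
        assert g.p.shape == (1, 1) and g.p[0, 0] == 1.0

    def test_2x2_hand_enumeration(self):
        g = compute_glcm(np.array([[0, 1], [2, 3]]), 1, 0, symmetric=False)
        assert g.p[0, 1] == 0.5 and g.p[2, 3] == 0.5
        assert g.p.sum() == 1.0

    @pytest.mark.parametrize("angle", [0, 45, 90, 135])
    @pytest.mark.parametrize("distance", [1, 2])
    @pytest.mark.parametrize("symmetric", [True, False])
    def test_matches_brute_force_oracle(self, angle, distance, symmetric, rng):
        for _ in range(5):
            idx = rng.integers(0, 8, (16, 16))
            ours = compute_glcm(idx, distance, angle, symmetric, levels=8)
            ref = brute_force_glcm(idx, distance, angle, symmetric, 8)
            assert np.abs(ours.p - ref).max() <= 1e-12

    def test_symmetric_matrix_is_symmetric(self, rng):
        idx = rng.integers(0, 4, (10, 10))
        g = compute_glcm(idx, 1, 45, symmetric=True)
        assert np.allclose(g.p, g.p.T)

    def test_sums_to_one(self, rng):
        idx = rng.integers(0, 6, (12, 12))
        for angle in OFFSETS:
            assert abs(compute_glcm(idx, 1, angle, True).p.sum() - 1.0) < 1e-12

    def test_offset_too_large_rejected(self):
        with pytest.raises(ValidationError):
            compute_glcm(np.zeros((4, 4), dtype=int), 5, 0, True)


class TestContrastCorrelation:
    def test_checkerboard_contrast_one_correlation_minus_one(self):
        cb = np.indices((8, 8)).sum(axis=0) % 2
        g = compute_glcm(cb, 1, 0, symmetric=True, levels=2)
        assert glcm_contrast(g) == 1.0
        assert glcm_correlation(g) == -1.0

    def test_banded_image_correlation_plus_one(self):
        banded = np.repeat(np.arange(4), 4).reshape(4, 4).T  # constant columns
        g = compute_glcm(banded, 1, 90, symmetric=True, levels=4)
        assert abs(glcm_correlation(g) - 1.0) < 1e-12

    def test_constant_image_degenerate_zero(self):
        g = compute_glcm(np.zeros((5, 5), dtype=int), 1, 0, True, levels=1)
        assert glcm_contrast(g) == 0.0
        assert glcm_correlation(g) == 0.0

    def test_contrast_invariant_to_transpose_of_matrix(self, rng):
        idx = rng.integers(0, 5, (10, 10))
        g = compute_glcm(idx, 1, 0, symmetric=True)
        gt = compute_glcm(idx, 1, 0, symmetric=True)
        gt.p = gt.p.T
        assert abs(glcm_contrast(g) - glcm_contrast(gt)) < 1e-12

    def test_features_match_brute_force(self, rng):
        idx = rng.integers(0, 8, (16, 16))
        g = compute_glcm(idx, 1, 135, symmetric=True, levels=8)
        assert abs(glcm_contrast(g) - brute_force_contrast(g.p)) < 1e-12
        assert abs(glcm_correlation(g) - brute_force_correlation(g.p)) < 1e-10

    def test_correlation_bounded(self, rng):
        for _ in range(20):
            idx = rng.integers(0, 6, (8, 8))
            g = compute_glcm(idx, 1, 0, symmetric=True)
            assert -1.0 - 1e-12 <= glcm_correlation(g) <= 1.0 + 1e-12


class TestFeatureVector:
    def test_length_and_names(self, small_phantom):
        img, _ = small_phantom
        tf = feature_vector(rgb_to_luv(img))
        assert tf.values.shape == (10,)
        d = tf.as_dict()
        assert set(k.split("_")[0] for k in d) == {"L", "C"}

    def test_constant_image_degenerate(self):
        from burnscope import RgbImage
        img = RgbImage(pixels=np.full((16, 16, 3), 120, np.uint8))
        tf = feature_vector(rgb_to_luv(img))
        d = tf.as_dict()
        assert d["L_contrast"] == 0.0 and d["L_correlation"] == 0.0
        assert d["L_mean"] > 0

    def test_invariant_to_90_degree_rotation(self, small_phantom):
        from burnscope import RgbImage
        img, _ = small_phantom
        rot = RgbImage(pixels=np.ascontiguousarray(np.rot90(img.pixels)))
        a = feature_vector(rgb_to_luv(img)).values
        b = feature_vector(rgb_to_luv(rot)).values
        assert np.allclose(a, b, atol=1e-9)

    def test_invariant_to_transposition(self, small_phantom):
        from burnscope import RgbImage
        img, _ = small_phantom
        tr = RgbImage(pixels=np.ascontiguousarray(img.pixels.transpose(1, 0, 2)))
        a = feature_vector(rgb_to_luv(img)).values
        b = feature_vector(rgb_to_luv(tr)).values
        assert np.allclose(a, b, atol=1e-9)

    def test_texture_scale_separates_burn_depths(self):
        # superficial vs deep phantoms differ in L-contrast by > 3 pooled sd
        from burnscope import generate_dataset
        ds = generate_dataset(n=18, seed=42, size=(64, 64))
        feats = np.stack([feature_vector(rgb_to_luv(im)).values for im in ds.images])
        sup = feats[ds.labels == 1, 0]
        deep = feats[ds.labels == 3, 0]
        pooled = np.sqrt((sup.std() ** 2 + deep.std() ** 2) / 2)
        assert abs(deep.mean() - sup.mean()) > 3 * pooled
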