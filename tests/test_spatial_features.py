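"""Texture/roughness features against brute-force oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hsinuclei import (TextureConfig, build_feature_table, cooccurrence,
                       quantize_masked, roughness_features, texture_features)
from hsinuclei.spatial_features import (OFFSETS, ROUGHNESS_NAMES,
                                        TEXTURE_NAMES, _texture_from_matrix)

from conftest import make_subimage


def brute_force_glcm(q, mask, angle_deg, levels, distance=1):
    """Independent oracle: enumerate every ordered in-mask pixel pair."""
    dr, dc = OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    P = np.zeros((levels, levels))
    rows, cols = q.shape
    for r in range(rows):
        for c in range(cols):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < rows and 0 <= c2 < cols and mask[r, c] and mask[r2, c2]:
                P[q[r, c], q[r2, c2]] += 1
    return P / P.sum()


def brute_force_texture(sub, cfg):
    q = quantize_masked(sub, cfg.levels)
    mask = sub.mask.values.astype(bool)
    per_dir = [_texture_from_matrix(
        brute_force_glcm(q, mask, a, cfg.levels, cfg.distance))
        for a in cfg.angles_deg]
    return {name: np.mean([d[name] for d in per_dir])
            for name in TEXTURE_NAMES}


class TestQuantize:
    def test_range_endpoints(self):
        sub = make_subimage([[0.0, 1.0]])
        q = quantize_masked(sub, levels=32)
        assert q[0, 0] == 0 and q[0, 1] == 31

    def test_constant_maps_to_zero(self):
        q = quantize_masked(make_subimage(np.full((3, 3), 4.2)), levels=32)
        assert (q == 0).all()

    def test_linear_ramp_identity_binning(self):
        sub = make_subimage(np.arange(32, dtype=float).reshape(1, 32))
        q = quantize_masked(sub, levels=32)
        np.testing.assert_array_equal(q[0], np.arange(32))

    def test_quantization_uses_in_mask_range_only(self):
        values = np.array([[0.0, 10.0], [1000.0, 5.0]])
        mask = np.array([[1, 1], [0, 1]])
        q = quantize_masked(make_subimage(values, mask), levels=2)
        # in-mask range is [0, 10]: 0 -> 0, 10 -> 1, 5 -> 1; the masked-out
        # 1000 never widens the range
        assert q[0, 0] == 0 and q[0, 1] == 1 and q[1, 1] == 1


class TestCooccurrence:
    def test_single_pair(self):
        q = np.array([[3, 5]])
        P = cooccurrence(q, np.ones((1, 2)), 0, levels=8)
        assert P[3, 5] == 1.0 and P.sum() == 1.0

    def test_180_is_transpose_of_0(self, rng):
        q = rng.integers(0, 8, (6, 6))
        mask = rng.random((6, 6)) > 0.3
        mask[0, :] = True  # guarantee at least one pair
        P0 = cooccurrence(q, mask, 0, levels=8)
        P180 = cooccurrence(q, mask, 180, levels=8)
        np.testing.assert_allclose(P180, P0.T)

    def test_45_degrees_matches_hand_enumeration(self):
        q = np.array([[0, 1, 2],
                      [2, 0, 1],
                      [1, 2, 0]])
        mask = np.array([[1, 1, 0],
                         [1, 1, 1],
                         [1, 1, 1]])
        # 45 deg offset (-1, +1): in-mask pairs (1,0)->(0,1): (2,1);
        # (2,0)->(1,1): (1,0); (2,1)->(1,2): (2,1).  ((1,1)->(0,2) excluded.)
        P = cooccurrence(q, mask, 45, levels=3)
        expected = np.zeros((3, 3))
        expected[2, 1] = 2 / 3
        expected[1, 0] = 1 / 3
        np.testing.assert_allclose(P, expected)

    def test_no_valid_pair_raises(self):
        q = np.zeros((2, 2), dtype=int)
        mask = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="45"):
            cooccurrence(q, mask, 45, levels=2)


class TestTextureFeatures:
    def test_constant_image_degenerate_values(self):
        fv = texture_features(make_subimage(np.full((5, 5), 3.0)))
        vals = fv.as_dict()
        assert vals["contrast"] == 0.0
        assert vals["dissimilarity"] == 0.0
        assert vals["homogeneity"] == pytest.approx(1.0)
        assert vals["energy"] == pytest.approx(1.0)
        assert vals["entropy"] == pytest.approx(0.0)
        assert vals["correlation"] == 1.0

    def test_checkerboard_contrast_hand_value(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        fv = texture_features(make_subimage(board.astype(float)),
                              TextureConfig(angles_deg=(0,)))
        # adjacent horizontal pairs always differ: levels 0 and 31,
        # so contrast = 31^2 from the two-cell co-occurrence table
        assert fv.as_dict()["contrast"] == pytest.approx(31.0 ** 2)

    def test_matches_brute_force_oracle_on_random_masked_images(self):
        cfg = TextureConfig()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            values = rng.uniform(0, 10, (6, 6))
            mask = rng.random((6, 6)) > 0.3
            mask[2:4, 2:4] = True
            sub = make_subimage(values, mask)
            got = texture_features(sub, cfg).as_dict()
            want = brute_force_texture(sub, cfg)
            for name in TEXTURE_NAMES:
                assert got[name] == pytest.approx(want[name], abs=1e-10), name

    def test_agrees_with_skimage_on_full_rectangle(self, rng):
        skimage_feature = pytest.importorskip("skimage.feature")
        values = rng.uniform(0, 1, (8, 8))
        sub = make_subimage(values)
        q = quantize_masked(sub, 8).astype(np.uint8)
        G = skimage_feature.graycomatrix(q, [1], [0], levels=8,
                                         symmetric=False, normed=True)
        P = cooccurrence(q, np.ones((8, 8)), 0, levels=8)
        np.testing.assert_allclose(P, G[:, :, 0, 0], atol=1e-12)
        for prop, name in [("contrast", "contrast"),
                           ("dissimilarity", "dissimilarity"),
                           ("homogeneity", "homogeneity"),
                           ("ASM", "energy"),
                           ("correlation", "correlation")]:
            want = skimage_feature.graycoprops(G, prop)[0, 0]
            assert _texture_from_matrix(P)[name] == pytest.approx(want)

    @given(st.integers(0, 200))
    def test_translation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 5, (5, 5))
        mask = rng.random((5, 5)) > 0.3
        mask[1:4, 1:4] = True
        big_v = np.zeros((9, 9))
        big_m = np.zeros((9, 9), dtype=bool)
        dr, dc = rng.integers(0, 4, 2)
        big_v[dr:dr + 5, dc:dc + 5] = values
        big_m[dr:dr + 5, dc:dc + 5] = mask
        a = texture_features(make_subimage(values, mask)).values
        b = texture_features(make_subimage(big_v, big_m)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    @given(st.integers(0, 200), st.floats(0.1, 10.0), st.floats(0.0, 5.0))
    def test_affine_rescaling_leaves_texture_unchanged(self, seed, a, b):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 5, (6, 6))
        base = texture_features(make_subimage(values)).values
        scaled = texture_features(make_subimage(a * values + b)).values
        np.testing.assert_allclose(base, scaled, atol=1e-9)


class TestRoughnessFeatures:
    def test_constant_field(self):
        fv = roughness_features(make_subimage(np.full((4, 4), 2.5)))
        vals = fv.as_dict()
        assert vals["mean"] == 2.5
        assert vals["rms"] == pytest.approx(2.5)
        assert vals["min"] == vals["max"] == 2.5
        assert vals["skewness"] == 0.0 and vals["kurtosis"] == 0.0
        assert vals["extrema5"] == pytest.approx(5.0)  # 2c fallback

    def test_strip_hand_arithmetic(self):
        fv = roughness_features(make_subimage([[1.0, 2.0, 3.0]]))
        vals = fv.as_dict()
        assert vals["mean"] == pytest.approx(2.0)
        assert vals["rms"] == pytest.approx(np.sqrt(14.0 / 3.0))
        assert vals["min"] == 1.0 and vals["max"] == 3.0

    def test_symmetric_distribution_has_zero_skew(self, rng):
        half = rng.uniform(0, 1, 50)
        values = np.concatenate([1.0 + half, 1.0 - half]).reshape(10, 10)
        assert roughness_features(
            make_subimage(values)).as_dict()["skewness"] == pytest.approx(
                0.0, abs=1e-12)

    def test_extrema5_single_peak_and_pit(self):
        values = np.full((5, 5), 1.0)
        values[1, 1] = 9.0   # the only strict local max
        values[3, 3] = 0.1   # the only strict local min
        vals = roughness_features(make_subimage(values)).as_dict()
        assert vals["extrema5"] == pytest.approx(9.0 + 0.1)

    @given(st.integers(0, 100), st.floats(0.5, 3.0))
    def test_pure_scaling_maps_mean_rms_min_max(self, seed, a):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0.1, 5, (5, 5))
        base = roughness_features(make_subimage(values)).as_dict()
        scaled = roughness_features(make_subimage(a * values)).as_dict()
        for name in ("mean", "rms", "min", "max"):
            assert scaled[name] == pytest.approx(a * base[name])


class TestBuildFeatureTable:
    def _subs(self, rng, n=4):
        return {(f"n{k}", "b"): make_subimage(rng.uniform(0, 5, (5, 5)),
                                              nucleus_id=f"n{k}")
                for k in range(n)}

    def test_row_cardinality(self, rng):
        df = build_feature_table(self._subs(rng, 4))
        assert len(df) == 8  # 4 nuclei x 1 band x 2 groups
        assert set(df["group"]) == {"texture", "roughness"}

    def test_order_invariance(self, rng):
        subs = self._subs(rng, 4)
        df1 = build_feature_table(subs)
        shuffled = dict(reversed(list(subs.items())))
        df2 = build_feature_table(shuffled)
        assert df1.equals(df2)

    def test_group_columns_complete(self, rng):
        df = build_feature_table(self._subs(rng, 2))
        tex = df[df.group == "texture"]
        ruf = df[df.group == "roughness"]
        assert not tex[list(TEXTURE_NAMES)].isna().any().any()
        assert not ruf[list(ROUGHNESS_NAMES)].isna().any().any()
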