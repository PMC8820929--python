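import math

import numpy as np
import pytest

from cfcanopy.texture import (FEATURE_NAMES, GLCMConfig, extract_table,
                              features, glcm, marginals, quantize)

EPS = float(np.finfo(np.float64).eps)


# ---------------------------------------------------------------- oracles

def naive_glcm(q, offset=(0, 1), symmetric=True, ng=9):
    """Double-loop pair counting, independent of the vectorized path."""
    h, w = q.shape
    dr, dc = offset
    counts = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w and q[r, c] > 0 and q[r2, c2] > 0:
                counts[q[r, c] - 1, q[r2, c2] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def naive_features(g):
    """All 23 traits by naive double loops over (i, j) and k."""
    ng = g.shape[0]
    px = [sum(g[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(g[i, j] for i in range(ng)) for j in range(ng)]
    mu_x = sum((i + 1) * px[i] for i in range(ng))
    mu_y = sum((j + 1) * py[j] for j in range(ng))
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))
    pxy_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    pxy_diff = {k: 0.0 for k in range(ng)}
    for i in range(ng):
        for j in range(ng):
            pxy_sum[i + j + 2] += g[i, j]
            pxy_diff[abs(i - j)] += g[i, j]
    mu_plus = sum(k * v for k, v in pxy_sum.items())
    mu_minus = sum(k * v for k, v in pxy_diff.items())
    hx = -sum(p * math.log2(p + EPS) for p in px)
    hy = -sum(p * math.log2(p + EPS) for p in py)
    hxy = -sum(g[i, j] * math.log2(g[i, j] + EPS)
               for i in range(ng) for j in range(ng))
    hxy1 = -sum(g[i, j] * math.log2(px[i] * py[j] + EPS)
                for i in range(ng) for j in range(ng))
    hxy2 = -sum(px[i] * py[j] * math.log2(px[i] * py[j] + EPS)
                for i in range(ng) for j in range(ng))
    f = {}
    f["autoc"] = sum((i + 1) * (j + 1) * g[i, j]
                     for i in range(ng) for j in range(ng))
    f["contr"] = sum((i - j) ** 2 * g[i, j]
                     for i in range(ng) for j in range(ng))
    sigma = math.sqrt(var_x * var_y)
    f["corrm"] = sum((i + 1 - mu_x) * (j + 1 - mu_y) * g[i, j]
                     for i in range(ng) for j in range(ng)) / sigma
    f["corrp"] = (f["autoc"] - mu_x * mu_y) / sigma
    f["cprom"] = sum((i + j + 2 - mu_x - mu_y) ** 4 * g[i, j]
                     for i in range(ng) for j in range(ng))
    f["cshad"] = sum((i + j + 2 - mu_x - mu_y) ** 3 * g[i, j]
                     for i in range(ng) for j in range(ng))
    f["dissi"] = sum(abs(i - j) * g[i, j]
                     for i in range(ng) for j in range(ng))
    f["energ"] = sum(g[i, j] ** 2 for i in range(ng) for j in range(ng))
    f["entro"] = -sum(g[i, j] * math.log2(g[i, j] + EPS)
                      for i in range(ng) for j in range(ng))
    f["homom"] = sum(g[i, j] / (1 + (i - j) ** 2)
                     for i in range(ng) for j in range(ng))
    f["homop"] = sum(g[i, j] / (1 + abs(i - j))
                     for i in range(ng) for j in range(ng))
    f["maxpr"] = max(g[i, j] for i in range(ng) for j in range(ng))
    f["sosvh"] = sum((i + 1 - mu_x) ** 2 * g[i, j]
                     for i in range(ng) for j in range(ng))
    f["savgh"] = mu_plus
    f["svarh"] = sum((k - mu_plus) ** 2 * v for k, v in pxy_sum.items())
    f["senth"] = -sum(v * math.log2(v + EPS) for v in pxy_sum.values())
    f["dvarh"] = sum((k - mu_minus) ** 2 * v for k, v in pxy_diff.items())
    f["denth"] = -sum(v * math.log2(v + EPS) for v in pxy_diff.values())
    f["inf1h"] = (hxy - hxy1) / max(hx, hy)
    f["inf2h"] = 1 - math.exp(-2 * (hxy2 - hxy))
    f["homom1"] = f["homop"]
    f["indnc"] = sum(g[i, j] / (1 + abs(i - j) / ng)
                     for i in range(ng) for j in range(ng))
    f["idmnc"] = sum(g[i, j] / (1 + (i - j) ** 2 / ng)
                     for i in range(ng) for j in range(ng))
    return f


# ------------------------------------------------------------------ tests

class TestQuantize:
    @pytest.mark.parametrize("value,ng,expected", [
        (0, 9, 1), (255, 9, 9), (10, 2, 1), (200, 2, 2),
        (100, 9, int(100 // (256 / 9)) + 1),
    ])
    def test_bin_arithmetic(self, value, ng, expected):
        q = quantize(np.full((2, 2), value, dtype=np.uint8), ng=ng)
        assert np.all(q == expected)

    def test_off_mask_pixels_flagged_zero(self):
        img = np.full((2, 2), 100, dtype=np.uint8)
        mask = np.array([[1, 0], [0, 1]], dtype=np.uint8)
        q = quantize(img, mask, ng=9)
        assert q[0, 1] == 0 and q[1, 0] == 0 and q[0, 0] > 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            quantize(np.zeros((3, 3), dtype=np.uint8),
                     np.zeros((3, 3), dtype=np.uint8))


class TestGLCM:
    def test_constant_region_single_entry(self):
        q = np.full((4, 4), 5)
        g = glcm(q, GLCMConfig())
        assert g[4, 4] == 1.0 and g.sum() == pytest.approx(1.0)

    def test_four_pixel_strip_enumeration(self):
        # levels (1,2,1,2): pairs (1,2),(2,1),(1,2) plus reverses
        q = np.array([[1, 2, 1, 2]])
        g = glcm(q, GLCMConfig(ng=2))
        assert g[0, 1] == pytest.approx(0.5)
        assert g[1, 0] == pytest.approx(0.5)
        assert g[0, 0] == g[1, 1] == 0.0

    def test_asymmetric_counts_ordered_pairs_only(self):
        q = np.array([[1, 2, 2]])
        g = glcm(q, GLCMConfig(ng=2, symmetric=False))
        assert g[0, 1] == pytest.approx(0.5)
        assert g[1, 1] == pytest.approx(0.5)
        assert g[1, 0] == 0.0

    def test_matches_naive_oracle_random_images(self, rng):
        cfg = GLCMConfig(ng=9)
        for _ in range(20):
            q = rng.integers(1, 10, (8, 8))
            q[rng.random((8, 8)) < 0.2] = 0  # off-mask holes
            if (q > 0).sum() < 4:
                continue
            assert np.allclose(glcm(q, cfg), naive_glcm(q), atol=1e-12)

    def test_row_offset_matches_naive_oracle(self, rng):
        cfg = GLCMConfig(ng=5, offset=(1, 0))
        q = rng.integers(1, 6, (8, 8))
        assert np.allclose(glcm(q, cfg), naive_glcm(q, offset=(1, 0), ng=5),
                           atol=1e-12)

    def test_no_valid_pair_rejected(self):
        q = np.array([[1, 0, 1]])
        with pytest.raises(ValueError, match="pair"):
            glcm(q, GLCMConfig(ng=2))


class TestMarginals:
    def test_distributions_sum_to_one(self, rng):
        g = rng.random((9, 9))
        g = (g + g.T) / (2 * g.sum())
        m = marginals(g)
        for dist in (m.px, m.py, m.p_xplusy, m.p_xminusy):
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_matrix_has_equal_marginals(self, rng):
        g = rng.random((6, 6))
        g = (g + g.T) / (2 * g.sum())
        m = marginals(g)
        assert np.allclose(m.px, m.py)
        assert m.mu_x == pytest.approx(m.mu_y)
        assert m.var_x == pytest.approx(m.var_y)
        assert m.hx == pytest.approx(m.hy)

    def test_single_entry_matrix(self):
        g = np.zeros((5, 5))
        k = 2  # level 3 (1-based)
        g[k, k] = 1.0
        m = marginals(g)
        assert m.hxy == pytest.approx(0.0, abs=1e-9)
        assert m.p_xminusy[0] == pytest.approx(1.0)
        assert m.p_xplusy[2 * (k + 1) - 2] == pytest.approx(1.0)

    def test_uniform_two_by_two_entropies(self):
        g = np.full((2, 2), 0.25)
        m = marginals(g)
        assert m.hx == pytest.approx(1.0, abs=1e-9)
        assert m.hy == pytest.approx(1.0, abs=1e-9)
        assert m.hxy == pytest.approx(2.0, abs=1e-9)


class TestFeatures:
    def test_one_hot_limits(self):
        g = np.zeros((9, 9))
        g[3, 3] = 1.0
        f = features(g)
        assert f["energ"] == 1.0
        assert f["entro"] == pytest.approx(0.0, abs=1e-9)
        assert f["contr"] == 0.0
        assert f["dissi"] == 0.0
        assert f["maxpr"] == 1.0
        assert f["homom"] == 1.0

    def test_uniform_two_by_two_hand_sums(self):
        g = np.full((2, 2), 0.25)
        f = features(g)
        assert f["contr"] == pytest.approx(0.5)
        assert f["energ"] == pytest.approx(0.25)

    def test_correlation_flagged_nan_for_constant_texture(self):
        g = np.zeros((4, 4))
        g[1, 1] = 1.0
        f = features(g)
        assert math.isnan(f["corrm"]) and math.isnan(f["corrp"])

    def test_exactly_23_named_traits_in_order(self, rng):
        g = rng.random((9, 9))
        g = (g + g.T) / (2 * g.sum())
        f = features(g)
        assert list(f) == list(FEATURE_NAMES)
        assert len(f) == 23

    def test_matches_naive_oracle_random_matrices(self, rng):
        for _ in range(20):
            g = rng.random((5, 5))
            g = (g + g.T) / (2 * g.sum())
            fast = features(g)
            slow = naive_features(g)
            for name in FEATURE_NAMES:
                assert fast[name] == pytest.approx(slow[name], abs=1e-10), name

    def test_energ_below_maxpr_property(self, rng):
        for _ in range(10):
            g = rng.random((6, 6))
            g /= g.sum()
            f = features(g)
            assert f["energ"] <= f["maxpr"] + 1e-12 <= 1 + 1e-12

    def test_inf2h_sqrt_variant_bounded(self, rng):
        cfg = GLCMConfig(inf2h_sqrt=True)
        for _ in range(10):
            g = rng.random((9, 9))
            g = (g + g.T) / (2 * g.sum())
            f = features(g, config=cfg)
            assert 0.0 <= f["inf2h"] <= 1.0

    def test_sosvh_printed_variant_toggle(self):
        g = np.full((2, 2), 0.25)
        standard = features(g, config=GLCMConfig(sosvh_standard=True))
        printed = features(g, config=GLCMConfig(sosvh_standard=False))
        assert standard["sosvh"] == pytest.approx(0.25)   # var of levels 1,2
        assert printed["sosvh"] == pytest.approx(0.25)    # (1-1.5)^2
        g2 = np.zeros((3, 3))
        g2[2, 2] = 1.0
        assert features(g2, config=GLCMConfig(sosvh_standard=True))["sosvh"] \
            == pytest.approx(0.0)
        assert features(g2, config=GLCMConfig(sosvh_standard=False))["sosvh"] \
            == pytest.approx(4.0)  # (1-3)^2


class TestExtractTable:
    def test_shape_and_round_trip(self, tmp_path, rng):
        entries = []
        for i in range(10):
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            mask = np.ones((16, 16), dtype=np.uint8)
            entries.append((img, mask, "control" if i % 2 else "drought"))
        table = extract_table(entries)
        assert table.shape == (10, 24)
        assert list(table.columns[:-1]) == list(FEATURE_NAMES)
        path = tmp_path / "features.csv"
        table.to_csv(path, index=False)
        import pandas as pd
        back = pd.read_csv(path)
        for name in FEATURE_NAMES:
            assert np.allclose(back[name], table[name], atol=1e-12)

    def test_duplicate_images_give_identical_rows(self, rng):
        img = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        mask = np.ones((12, 12), dtype=np.uint8)
        table = extract_table([(img, mask, "a"), (img, mask, "a")])
        assert table.iloc[0].equals(table.iloc[1])

    def test_degenerate_image_skipped_not_fatal(self, rng):
        good = rng.integers(0, 256, (12, 12), dtype=np.uint8)
        ones = np.ones((12, 12), dtype=np.uint8)
        lonely = np.zeros((12, 12), dtype=np.uint8)  # mask with 1 px: no pair
        lonely_mask = np.zeros((12, 12), dtype=np.uint8)
        lonely_mask[0, 0] = 1
        table = extract_table([(good, ones, "a"), (lonely, lonely_mask, "b")])
        assert len(table) == 1
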