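"""Segmentation, GLCM, and the 13 Haralick statistics against brute-force oracles."""

import numpy as np
import pytest

from histomics.image_features import (
    FeatureMatrix,
    extract_features,
    feature_names,
    filter_pieces,
    glcm,
    haralick13,
    normalize_features,
    segment_tissue,
)


def haralick_oracle(P):
    """Independent brute-force double-sum evaluation of the 13 statistics."""
    n = P.shape[0]

    def log2s(v):
        return np.log2(v) if v > 0 else 0.0

    px = [sum(P[i][j] for j in range(n)) for i in range(n)]
    py = [sum(P[i][j] for i in range(n)) for j in range(n)]
    mu_x = sum(i * px[i] for i in range(n))
    mu_y = sum(j * py[j] for j in range(n))
    sd_x = sum((i - mu_x) ** 2 * px[i] for i in range(n)) ** 0.5
    sd_y = sum((j - mu_y) ** 2 * py[j] for j in range(n)) ** 0.5
    asm = sum(P[i][j] ** 2 for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * P[i][j] for i in range(n) for j in range(n))
    corr = (
        (sum(i * j * P[i][j] for i in range(n) for j in range(n)) - mu_x * mu_y)
        / (sd_x * sd_y)
        if sd_x * sd_y > 0
        else 1.0
    )
    var = sum((i - mu_x) ** 2 * P[i][j] for i in range(n) for j in range(n))
    idm = sum(P[i][j] / (1 + (i - j) ** 2) for i in range(n) for j in range(n))
    psum = [sum(P[i][j] for i in range(n) for j in range(n) if i + j == k)
            for k in range(2 * n - 1)]
    pdif = [sum(P[i][j] for i in range(n) for j in range(n) if abs(i - j) == k)
            for k in range(n)]
    sum_avg = sum(k * psum[k] for k in range(2 * n - 1))
    sum_var = sum((k - sum_avg) ** 2 * psum[k] for k in range(2 * n - 1))
    sum_ent = -sum(psum[k] * log2s(psum[k]) for k in range(2 * n - 1))
    ent = -sum(P[i][j] * log2s(P[i][j]) for i in range(n) for j in range(n))
    dmean = sum(k * pdif[k] for k in range(n))
    dvar = sum((k - dmean) ** 2 * pdif[k] for k in range(n))
    dent = -sum(pdif[k] * log2s(pdif[k]) for k in range(n))
    hxy1 = -sum(
        P[i][j] * log2s(px[i] * py[j]) for i in range(n) for j in range(n)
        if P[i][j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * log2s(px[i] * py[j]) for i in range(n) for j in range(n)
    )
    hx = -sum(px[i] * log2s(px[i]) for i in range(n))
    hy = -sum(py[j] * log2s(py[j]) for j in range(n))
    imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    imc2 = (max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - ent)))) ** 0.5
    return np.array([asm, contrast, corr, var, idm, sum_avg, sum_var, sum_ent,
                     ent, dvar, dent, imc1, imc2])


class TestSegmentation:
    def test_uniform_white_image_has_no_pieces(self):
        img = np.ones((200, 200, 3))
        seg = segment_tissue(img)
        assert seg.n_pieces == 0

    def test_dark_disk_area_recovered(self):
        img = np.ones((300, 300, 3))
        yy, xx = np.mgrid[:300, :300]
        disk = (yy - 150) ** 2 + (xx - 150) ** 2 <= 30**2
        img[disk] = 0.3
        seg = segment_tissue(img)
        assert seg.n_pieces == 1
        assert abs(seg.piece_areas[0] - int(disk.sum())) <= 0.05 * disk.sum()

    def test_two_disks_labeled_by_area(self):
        img = np.ones((300, 300, 3))
        yy, xx = np.mgrid[:300, :300]
        small = (yy - 70) ** 2 + (xx - 70) ** 2 <= 20**2
        big = (yy - 200) ** 2 + (xx - 200) ** 2 <= 40**2
        img[small] = 0.3
        img[big] = 0.3
        seg = segment_tissue(img)
        assert seg.n_pieces == 2
        assert seg.piece_areas[0] > seg.piece_areas[1]
        assert (seg.labels[200, 200]) == 1  # biggest piece labeled 1

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            segment_tissue(np.ones((50, 50, 3)), window=10)


class TestFilterPieces:
    def _seg(self):
        img = np.ones((300, 300, 3))
        yy, xx = np.mgrid[:300, :300]
        for cy, cx, r in [(60, 60, 15), (150, 150, 4), (240, 240, 25)]:
            img[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = 0.3
        return segment_tissue(img)

    def test_min_area_zero_is_identity(self):
        seg = self._seg()
        out = filter_pieces(seg, 0)
        assert np.array_equal(out.labels, seg.labels)
        assert np.array_equal(out.piece_areas, seg.piece_areas)

    def test_small_pieces_removed_order_preserved(self):
        out = filter_pieces(self._seg(), min_area=200)
        assert out.n_pieces == 2
        assert (np.diff(out.piece_areas) <= 0).all()
        assert set(np.unique(out.labels)) == {0, 1, 2}

    def test_all_pieces_removed(self):
        out = filter_pieces(self._seg(), min_area=10**6)
        assert out.n_pieces == 0
        assert (out.labels == 0).all()


class TestGLCM:
    def test_constant_channel_single_diagonal_cell(self):
        P = glcm(np.full((20, 20), 0.5), np.ones((20, 20), bool), 1, levels=8)
        assert P.sum() == pytest.approx(1.0)
        assert P[0, 0] == pytest.approx(1.0)

    def test_checkerboard_horizontal_hand_enumeration(self):
        """2x2 checkerboard, d=1, horizontal: 4 ordered pairs, all off-diagonal."""
        chan = np.array([[0.0, 1.0], [1.0, 0.0]])
        P = glcm(chan, np.ones((2, 2), bool), 1, levels=2, directions=[(0, 1)])
        assert P[0, 1] == pytest.approx(0.5)
        assert P[1, 0] == pytest.approx(0.5)
        assert P[0, 0] == P[1, 1] == 0.0

    def test_symmetry_and_unit_mass(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            chan = rng.random((30, 30))
            mask = rng.random((30, 30)) > 0.3
            P = glcm(chan, mask, distance=int(rng.integers(1, 5)), levels=8)
            assert np.allclose(P, P.T)
            if P.sum() > 0:
                assert P.sum() == pytest.approx(1.0)

    def test_empty_when_distance_exceeds_mask(self):
        mask = np.zeros((50, 50), bool)
        mask[10, 10] = True
        P = glcm(np.random.default_rng(1).random((50, 50)), mask, 5, levels=4)
        assert P.sum() == 0.0


class TestHaralick13:
    def test_degenerate_single_cell(self):
        P = np.zeros((8, 8))
        P[3, 3] = 1.0
        h = haralick13(P)
        assert h[0] == pytest.approx(1.0)  # ASM
        assert h[1] == pytest.approx(0.0)  # contrast
        assert h[8] == pytest.approx(0.0)  # entropy

    def test_uniform_distribution_closed_form(self):
        P = np.full((4, 4), 1 / 16)
        h = haralick13(P)
        assert h[0] == pytest.approx(1 / 16)
        assert h[8] == pytest.approx(4.0)  # entropy in bits

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            P = rng.random((8, 8))
            P = P + P.T
            P /= P.sum()
            np.testing.assert_allclose(haralick13(P), haralick_oracle(P), atol=1e-10)

    def test_empty_matrix_gives_sentinels(self):
        assert np.isnan(haralick13(np.zeros((4, 4)))).all()


class TestExtractFeatures:
    def _disk_image(self, texture_seed=0):
        rng = np.random.default_rng(texture_seed)
        img = np.ones((200, 200, 3))
        yy, xx = np.mgrid[:200, :200]
        disk = (yy - 100) ** 2 + (xx - 100) ** 2 <= 50**2
        for ch in range(3):
            vals = 0.5 + 0.2 * rng.standard_normal(disk.sum())
            img[:, :, ch][disk] = np.clip(vals, 0, 0.9)
        return img

    def test_feature_count_117(self):
        img = self._disk_image()
        seg = segment_tissue(img)
        vec = extract_features(img, seg)
        assert vec.shape == (117,)
        assert np.isfinite(vec).all()
        assert len(feature_names()) == 117
        assert len(set(feature_names())) == 117

    def test_single_piece_equals_averaging_identity(self):
        img = self._disk_image()
        seg = segment_tissue(img)
        assert seg.n_pieces == 1

    def test_two_identical_pieces_average_to_one(self):
        rng = np.random.default_rng(3)
        patch = np.clip(0.5 + 0.2 * rng.standard_normal((40, 40, 3)), 0, 0.9)
        img = np.ones((200, 200, 3))
        img[30:70, 30:70] = patch
        img[130:170, 130:170] = patch
        seg = segment_tissue(img)
        assert seg.n_pieces == 2
        two = extract_features(img, seg, distances=(1, 10))
        solo = np.ones((200, 200, 3))
        solo[30:70, 30:70] = patch
        one = extract_features(solo, segment_tissue(solo), distances=(1, 10))
        np.testing.assert_allclose(two, one, rtol=1e-6)

    def test_zero_pieces_flagged_missing(self):
        img = np.ones((150, 150, 3))
        seg = segment_tissue(img)
        assert extract_features(img, seg) is None

    def test_rotation_robustness_of_direction_averaged_features(self):
        img = self._disk_image(5)
        seg = segment_tissue(img)
        f = extract_features(img, seg, distances=(1, 10))
        rot = np.rot90(img, axes=(0, 1)).copy()
        f_rot = extract_features(rot, segment_tissue(rot), distances=(1, 10))
        denom = np.maximum(np.abs(f), 1e-6)
        assert np.max(np.abs(f - f_rot) / denom) < 0.01


class TestNormalizeFeatures:
    def test_signed_log_fixed_points(self):
        import pandas as pd

        fm = FeatureMatrix(pd.DataFrame({"a": [0.0, 1.0, -1.0, 3.0]}))
        out = normalize_features(fm)
        x = np.sign([0, 1, -1, 3]) * np.log2(1 + np.abs([0, 1, -1, 3]))
        expect = (x - x.mean()) / x.std()
        np.testing.assert_allclose(out.data["a"].to_numpy(), expect, atol=1e-12)

    def test_columns_standardized_and_constants_zeroed(self):
        import pandas as pd

        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.random((30, 5)), columns=list("abcde"))
        df["e"] = 7.0
        out = normalize_features(FeatureMatrix(df))
        z = out.data.to_numpy()
        np.testing.assert_allclose(z[:, :4].mean(0), 0, atol=1e-8)
        np.testing.assert_allclose(z[:, :4].var(0), 1, atol=1e-8)
        assert (z[:, 4] == 0).all()
        assert out.transform == "log2+standardized"

    def test_single_sample_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            normalize_features(FeatureMatrix(pd.DataFrame({"a": [1.0]})))
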