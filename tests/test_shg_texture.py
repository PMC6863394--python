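"""Masked GLCM texture profiling: oracle agreement and Haralick identities."""

import numpy as np
import pytest

from chemomech import shg_texture as tex
from chemomech.shg_texture import (DIRECTION_OFFSETS, GlcmConfig, GlcmError,
                                   cohort_texture, glcm, haralick_params,
                                   max_projection, quantize, texture_profile,
                                   threshold_mask)
from chemomech.synthetic import simulate_shg_texture


def brute_force_glcm(levels, mask, distance, direction, n_levels, symmetric):
    """Independent O(N·pairs) pair-enumeration oracle."""
    dy, dx = DIRECTION_OFFSETS[direction]
    dy, dx = dy * distance, dx * distance
    P = np.zeros((n_levels, n_levels))
    h, w = levels.shape
    for y in range(h):
        for x in range(w):
            y2, x2 = y + dy, x + dx
            if 0 <= y2 < h and 0 <= x2 < w:
                if mask is None or (mask[y, x] and mask[y2, x2]):
                    P[levels[y, x], levels[y2, x2]] += 1
                    if symmetric:
                        P[levels[y2, x2], levels[y, x]] += 1
    total = P.sum()
    return P / total if total else P


class TestProjectionAndMask:
    def test_single_slice_identity(self, rng):
        img = rng.random((16, 16))
        assert np.array_equal(max_projection(img[None]), img)

    def test_disjoint_bright_pixels_union(self):
        a = np.zeros((4, 4)); a[0, 0] = 9
        b = np.zeros((4, 4)); b[3, 3] = 7
        proj = max_projection(np.stack([a, b]))
        assert proj[0, 0] == 9 and proj[3, 3] == 7

    def test_projection_dominates_slices(self, rng):
        stack = rng.random((5, 16, 16))
        proj = max_projection(stack)
        assert (proj[None] >= stack).all()

    def test_bimodal_threshold_between_modes(self, rng):
        truth = rng.random((64, 64)) > 0.5
        img = np.where(truth, 200.0, 20.0) + rng.normal(0, 3, truth.shape)
        mask, frac = threshold_mask(img)
        assert abs(frac - truth.mean()) < 0.02
        assert (mask == truth).mean() > 0.98

    def test_constant_image_empty_mask_warns(self):
        with pytest.warns(UserWarning, match="constant"):
            mask, frac = threshold_mask(np.full((8, 8), 3.0))
        assert frac == 0.0 and not mask.any()

    def test_inverted_method_complements(self, rng):
        img = np.where(rng.random((32, 32)) > 0.5, 200.0, 20.0)
        m1, _ = threshold_mask(img)
        m2, _ = threshold_mask(img, invert=True)
        assert np.array_equal(m1, ~m2)


class TestGlcm:
    @pytest.mark.parametrize("direction", [0.0, 45.0, 90.0, 135.0])
    @pytest.mark.parametrize("distance", [1, 2, 5])
    def test_agrees_with_brute_force_oracle(self, direction, distance, rng):
        levels = rng.integers(0, 8, (24, 24))
        mask = rng.random((24, 24)) > 0.3
        cfg = GlcmConfig(n_levels=8)
        P, _ = glcm(levels, mask, distance, direction, cfg)
        oracle = brute_force_glcm(levels, mask, distance, direction, 8, True)
        np.testing.assert_allclose(P, oracle, atol=1e-12)

    def test_agrees_with_skimage_unmasked(self, rng):
        # independent library cross-check; 45°/135° swap between the y-up
        # convention used here and skimage's row-down angles
        from skimage.feature import graycomatrix
        img = rng.integers(0, 8, (20, 20)).astype(np.uint8)
        cfg = GlcmConfig(n_levels=8, masked=False)
        # axis-aligned offsets agree at any distance; diagonal offsets only
        # at d = 1 (skimage rounds d·sinθ so its d=2 diagonal is not (2,2))
        cases = [(0.0, 0.0, 1), (0.0, 0.0, 2), (0.0, 0.0, 3),
                 (90.0, np.pi / 2, 1), (90.0, np.pi / 2, 3),
                 (45.0, 3 * np.pi / 4, 1), (135.0, np.pi / 4, 1)]
        for mine, theirs, d in cases:
            P, _ = glcm(img, None, d, mine, cfg)
            Q = graycomatrix(img, [d], [theirs], levels=8, symmetric=True,
                             normed=True)[:, :, 0, 0]
            np.testing.assert_allclose(P, Q, atol=1e-12)

    def test_constant_foreground_single_entry(self):
        levels = np.full((10, 10), 5)
        mask = np.ones((10, 10), bool)
        P, n = glcm(levels, mask, 1, 0.0, GlcmConfig(n_levels=8))
        assert P[5, 5] == 1.0 and P.sum() == 1.0 and n == 90

    def test_stripes_concentrate_off_diagonal(self):
        levels = np.tile(np.array([0, 1]), (8, 4))       # vertical stripes
        cfg = GlcmConfig(n_levels=2, masked=False)
        P, _ = glcm(levels, None, 1, 0.0, cfg)           # horizontal pairs
        assert P[0, 0] == 0 and P[1, 1] == 0
        assert P[0, 1] == pytest.approx(0.5) and P[1, 0] == pytest.approx(0.5)

    def test_mask_removes_only_background_pairs(self, rng):
        levels = rng.integers(0, 4, (16, 16))
        background = np.zeros((16, 16), bool)
        background[:4] = True
        cfg = GlcmConfig(n_levels=4)
        P_masked, n_masked = glcm(levels, ~background, 1, 0.0, cfg)
        oracle = brute_force_glcm(levels, ~background, 1, 0.0, 4, True)
        np.testing.assert_allclose(P_masked, oracle, atol=1e-12)
        _, n_all = glcm(levels, None, 1, 0.0,
                        GlcmConfig(n_levels=4, masked=False))
        assert n_masked < n_all

    def test_empty_mask_raises_with_offset_named(self):
        levels = np.zeros((8, 8), dtype=int)
        with pytest.raises(GlcmError, match="distance 3"):
            glcm(levels, np.zeros((8, 8), bool), 3, 90.0, GlcmConfig(n_levels=2))

    def test_normalization_and_symmetry(self, rng):
        levels = rng.integers(0, 16, (32, 32))
        cfg = GlcmConfig(n_levels=16)
        for d in (1, 7, 31):
            P, _ = glcm(levels, None, d, 45.0, cfg)
            assert P.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(P, P.T)


class TestHaralick:
    def test_degenerate_single_entry(self):
        P = np.zeros((8, 8)); P[3, 3] = 1.0
        h = haralick_params(P)
        assert h["ASM"] == 1.0 and h["contrast"] == 0.0
        assert h["IDM"] == 1.0 and h["entropy"] == 0.0
        assert np.isnan(h["correlation"])

    def test_uniform_matrix_closed_forms(self):
        G = 8
        P = np.full((G, G), 1.0 / G**2)
        h = haralick_params(P)
        assert h["ASM"] == pytest.approx(1.0 / G**2)
        assert h["entropy"] == pytest.approx(2 * np.log(G))

    def test_random_matrix_against_summation_oracle(self, rng):
        P = rng.random((8, 8)); P /= P.sum()
        h = haralick_params(P)
        asm = contrast = idm = ent = 0.0
        mu_i = sum(i * P[i, j] for i in range(8) for j in range(8))
        mu_j = sum(j * P[i, j] for i in range(8) for j in range(8))
        var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(8) for j in range(8))
        var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(8) for j in range(8))
        corr = 0.0
        for i in range(8):
            for j in range(8):
                p = P[i, j]
                asm += p * p
                contrast += (i - j) ** 2 * p
                idm += p / (1 + (i - j) ** 2)
                ent -= p * np.log(p) if p > 0 else 0.0
                corr += (i - mu_i) * (j - mu_j) * p
        corr /= np.sqrt(var_i * var_j)
        assert h["ASM"] == pytest.approx(asm, abs=1e-12)
        assert h["contrast"] == pytest.approx(contrast, abs=1e-12)
        assert h["IDM"] == pytest.approx(idm, abs=1e-12)
        assert h["entropy"] == pytest.approx(ent, abs=1e-12)
        assert h["correlation"] == pytest.approx(corr, abs=1e-12)

    def test_asm_permutation_invariant_contrast_not(self, rng):
        levels = rng.integers(0, 8, (32, 32))
        cfg = GlcmConfig(n_levels=8, masked=False)
        P, _ = glcm(levels, None, 1, 0.0, cfg)
        perm = rng.permutation(8)
        P_perm, _ = glcm(perm[levels], None, 1, 0.0, cfg)
        h, hp = haralick_params(P), haralick_params(P_perm)
        assert h["ASM"] == pytest.approx(hp["ASM"], abs=1e-12)
        assert h["contrast"] != pytest.approx(hp["contrast"], abs=1e-9)

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            haralick_params(np.ones((4, 4)))


class TestProfiles:
    def test_default_config_emits_2000_values(self):
        stack, _ = simulate_shg_texture("homogeneous", size=128, seed=0)
        profile = texture_profile(stack)
        assert len(profile) == 2000                 # 100 × 4 × 5

    def test_single_distance_emits_20_values(self):
        stack, _ = simulate_shg_texture("homogeneous", size=128, seed=0)
        profile = texture_profile(stack, GlcmConfig(distances=(1,)))
        assert len(profile) == 20

    def test_homogeneous_more_uniform_than_fibrous(self):
        distances = tuple(range(20, 101, 20))
        cfg = GlcmConfig(distances=distances)
        asm = {}
        for mode in ("homogeneous", "fibrous"):
            stack, _ = simulate_shg_texture(mode, size=256, seed=2)
            asm[mode] = tex.asm_vs_distance(texture_profile(stack, cfg))
        assert (asm["homogeneous"] >= asm["fibrous"]).all()

    def test_cohort_mean_and_sem(self):
        stack, _ = simulate_shg_texture("homogeneous", size=128, seed=3)
        cfg = GlcmConfig(distances=(5, 10))
        p = texture_profile(stack, cfg)
        out = cohort_texture([p, p])
        assert np.allclose(out["sem_asm"], 0.0)
        p2 = p.copy()
        p2.loc[p2["parameter"] == "ASM", "value"] *= 3.0
        out = cohort_texture([p, p2])
        expected = 2.0 * tex.asm_vs_distance(p).to_numpy()
        assert out["mean_asm"].to_numpy() == pytest.approx(expected)

    def test_sem_scales_inverse_sqrt_n(self, rng):
        # i.i.d. noise profiles: SEM(4n) should be about half SEM(n)
        def fake_profile(seed):
            r = np.random.default_rng(seed)
            rows = [(0, d, a, "ASM", 0.5 + 0.1 * r.standard_normal())
                    for d in range(1, 21) for a in (0.0, 45.0, 90.0, 135.0)]
            import pandas as pd
            return pd.DataFrame(rows, columns=["image", "distance",
                                               "direction", "parameter",
                                               "value"])
        sems = {}
        for n in (8, 32):
            out = cohort_texture([fake_profile(s) for s in range(n)])
            sems[n] = out["sem_asm"].mean()
        assert sems[32] / sems[8] == pytest.approx(0.5, rel=0.35)

    def test_mismatched_grids_rejected(self):
        stack, _ = simulate_shg_texture("homogeneous", size=128, seed=3)
        p1 = texture_profile(stack, GlcmConfig(distances=(1, 2)))
        p2 = texture_profile(stack, GlcmConfig(distances=(1, 3)))
        with pytest.raises(ValueError, match="mismatched"):
            cohort_texture([p1, p2])
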