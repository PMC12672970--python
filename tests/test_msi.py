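"""The 120-feature spatial-heterogeneity catalog: oracles and invariants."""
import numpy as np
import pytest

from habitatrisk._types import HabitatMap
from habitatrisk.msi import (
    MSI_GROUP_SIZES,
    MSI_NAMES,
    PAIR_ORDER,
    fscore_rank,
    msi_complexity,
    msi_extract,
    msi_glcm_stats,
    msi_global,
    msi_intensity_moments,
    msi_morphology,
    msi_normalized_interactions,
    msi_texture_bank,
    msi_volumes_and_interactions,
)


def _habmap(labels):
    lab = np.asarray(labels, dtype=np.int64)
    inside = lab > 0
    counts = np.bincount(lab[inside], minlength=6)[1:]
    present = counts[counts > 0]
    fr = counts / counts.sum()
    return HabitatMap(labels=lab, n_habitats=5, fractions=fr)


def _ball(radius, size=None):
    size = size or (2 * radius + 3)
    zz, yy, xx = np.mgrid[:size, :size, :size]
    c = (size - 1) / 2
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2


# ---------------------------------------------------------------------------
# exhaustive neighbour-enumeration oracle

def _oracle_counts(lab):
    """Triple-loop enumeration of volumes, border and pair interactions."""
    shape = lab.shape
    vols = np.zeros(5)
    border = np.zeros(5)
    pairs = {p: 0 for p in PAIR_ORDER}
    offs = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                v = lab[z, y, x]
                if v == 0:
                    continue
                vols[v - 1] += 1
                touches = False
                for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    q = (z + dz, y + dy, x + dx)
                    if not all(0 <= q[i] < shape[i] for i in range(3)):
                        touches = True
                    elif lab[q] == 0:
                        touches = True
                if touches:
                    border[v - 1] += 1
                for dz, dy, dx in offs:
                    q = (z + dz, y + dy, x + dx)
                    if all(0 <= q[i] < shape[i] for i in range(3)):
                        u = lab[q]
                        if u > 0 and u != v:
                            key = (min(u, v), max(u, v))
                            pairs[key] += 1
    return vols, border, np.array([float(pairs[p]) for p in PAIR_ORDER])


class TestCountingOracles:
    def test_hand_enumerated_strip(self):
        lab = np.array([[[1, 2, 2]]])
        hm = _habmap(lab)
        vols, border, pairs, norm = msi_volumes_and_interactions(hm, lab > 0)
        assert list(vols) == [1, 2, 0, 0, 0]
        assert list(border) == [1, 2, 0, 0, 0]
        assert pairs[PAIR_ORDER.index((1, 2))] == 1
        assert pairs.sum() == 1
        assert norm.sum() == pytest.approx(1.0)

    def test_single_habitat_map(self):
        lab = np.full((2, 3, 2), 3, dtype=np.int64)
        hm = _habmap(lab)
        vols, border, pairs, norm = msi_volumes_and_interactions(hm, lab > 0)
        assert vols[2] == lab.size
        assert pairs.sum() == 0
        assert norm[2] == 1.0

    def test_random_maps_match_exhaustive_enumeration(self, rng):
        for _ in range(60):
            lab = rng.integers(0, 6, size=(3, 3, 3))
            if not (lab > 0).any():
                continue
            hm = _habmap(lab)
            vols, border, pairs, _ = msi_volumes_and_interactions(hm, lab > 0)
            ovols, oborder, opairs = _oracle_counts(lab)
            assert np.array_equal(vols, ovols)
            assert np.array_equal(border, oborder)
            assert np.array_equal(pairs, opairs)

    def test_pair_counts_invariant_to_scan_order(self, rng):
        lab = rng.integers(0, 6, size=(4, 5, 4))
        lab[0, 0, 0] = 1
        hm = _habmap(lab)
        _, _, pairs, _ = msi_volumes_and_interactions(hm, lab > 0)
        flipped = lab[::-1, ::-1, ::-1].copy()
        hm2 = _habmap(flipped)
        _, _, pairs2, _ = msi_volumes_and_interactions(hm2, flipped > 0)
        assert np.array_equal(pairs, pairs2)


class TestGLCM:
    def test_constant_label_map(self):
        lab = np.full((3, 3, 3), 2, dtype=np.int64)
        contrast, corr, energy, homog = msi_glcm_stats(_habmap(lab))
        assert contrast == 0.0
        assert energy == 1.0
        assert homog == 1.0

    def test_alternating_strip_contrast_one(self):
        lab = np.array([[[1, 2, 1, 2]]])
        contrast, _, energy, homog = msi_glcm_stats(_habmap(lab))
        assert contrast == pytest.approx(1.0)
        # off-diagonal only: energy = 2 * 0.5^2
        assert energy == pytest.approx(0.5)
        assert homog == pytest.approx(0.5)

    def test_single_voxel_raises(self):
        lab = np.zeros((3, 3, 3), dtype=np.int64)
        lab[1, 1, 1] = 1
        with pytest.raises(ValueError):
            msi_glcm_stats(_habmap(lab))


class TestNormalizedInteractions:
    def test_zeros_and_error(self):
        out = msi_normalized_interactions(np.zeros(5), np.zeros(10), 10.0)
        assert np.all(out == 0)
        with pytest.raises(ZeroDivisionError):
            msi_normalized_interactions(np.zeros(5), np.zeros(10), 0.0)

    def test_hand_example_h4_h5(self):
        lab = np.array([[[4, 5, 5]]])
        hm = _habmap(lab)
        vols, border, pairs, _ = msi_volumes_and_interactions(hm, lab > 0)
        out = msi_normalized_interactions(border, pairs, vols.sum())
        # MSI 44 analogue: (H4 n H5) / Vol(total) = 1/3
        assert out[5 + PAIR_ORDER.index((4, 5))] == pytest.approx(1 / 3)

    def test_resolution_stability_of_normalized_features(self):
        """Doubling resolution changes normalized volumes by < 15%."""
        ball = _ball(8)
        lab = np.where(ball, 1, 0)
        half = ball.shape[0] // 2
        lab[half:][ball[half:]] = 2
        hm = _habmap(lab)
        vols, border, pairs, norm = msi_volumes_and_interactions(hm, lab > 0)
        up = np.repeat(np.repeat(np.repeat(lab, 2, 0), 2, 1), 2, 2)
        hm2 = _habmap(up)
        vols2, border2, pairs2, norm2 = msi_volumes_and_interactions(
            hm2, up > 0)
        assert np.allclose(norm, norm2, rtol=0.15)


class TestTextureBank:
    def test_constant_volume_degenerate_texture(self):
        lab = np.where(_ball(6), 1, 0)
        vol = np.full(lab.shape, 7.0)
        values, missing = msi_texture_bank(vol, _habmap(lab))
        gabor_f, wave, lbp = values[:5], values[5:10], values[10:]
        assert wave[0] == pytest.approx(0.0, abs=1e-12)
        assert lbp[0] == pytest.approx(0.0)
        assert missing[1:].all() and not missing[0]

    def test_gabor_orientation_selectivity(self):
        from habitatrisk.msi import _gabor_magnitude, GABOR_FREQUENCY

        y, x = np.mgrid[:64, :64]
        sin_x = np.sin(2 * np.pi * GABOR_FREQUENCY * x)
        along = _gabor_magnitude(sin_x, GABOR_FREQUENCY, 0.0).mean()
        across = _gabor_magnitude(sin_x, GABOR_FREQUENCY, np.pi / 2).mean()
        assert along > 3 * across


class TestMorphology:
    def test_single_voxel(self):
        lab = np.zeros((3, 3, 3), dtype=np.int64)
        lab[1, 1, 1] = 1
        values, missing = msi_morphology(_habmap(lab))
        surf, conv, spher = values[:5], values[5:10], values[10:]
        assert surf[0] == pytest.approx(6.0)
        assert conv[0] == pytest.approx(1.0)

    def test_solid_box_closed_form(self):
        a, b, c = 3, 4, 5
        lab = np.zeros((a + 2, b + 2, c + 2), dtype=np.int64)
        lab[1:1 + a, 1:1 + b, 1:1 + c] = 2
        values, _ = msi_morphology(_habmap(lab))
        assert values[1] == pytest.approx(2 * (a * b + b * c + c * a))
        assert values[5 + 1] == pytest.approx(1.0)    # box is convex

    def test_digital_ball_sphericity_near_one(self):
        lab = np.where(_ball(12), 1, 0)
        values, _ = msi_morphology(_habmap(lab))
        spher = values[10]
        assert 0.85 <= spher <= 1.0

    def test_spacing_scales_surface(self):
        lab = np.zeros((3, 3, 3), dtype=np.int64)
        lab[1, 1, 1] = 1
        values, _ = msi_morphology(_habmap(lab), spacing=(2.0, 1.0, 1.0))
        # 2 faces of 1x1 (perp. to z) + 4 faces of 2x1
        assert values[0] == pytest.approx(2 * 1 + 4 * 2)


class TestIntensityMoments:
    def test_hand_computed_sd(self):
        lab = np.array([[[1, 1, 1]]])
        vol = np.array([[[1.0, 2.0, 3.0]]])
        values, missing = msi_intensity_moments(vol, _habmap(lab))
        mean, sd = values[:5], values[5:10]
        assert mean[0] == pytest.approx(2.0)
        assert sd[0] == pytest.approx(np.sqrt(2 / 3))

    def test_symmetric_distribution_zero_skew(self):
        lab = np.array([[[2, 2, 2]]])
        vol = np.array([[[-4.0, 0.0, 4.0]]])
        values, _ = msi_intensity_moments(vol, _habmap(lab))
        assert values[10 + 1] == pytest.approx(0.0)   # skewness of habitat 2

    def test_degenerate_habitat_flagged(self):
        lab = np.array([[[1, 1, 2]]])
        vol = np.array([[[5.0, 5.0, 9.0]]])
        values, missing = msi_intensity_moments(vol, _habmap(lab))
        # constant habitat 1: sd/skew/kurt zero with flag; habitat 2 single voxel
        assert values[5] == 0.0
        assert missing[0] and missing[1]


class TestComplexity:
    def test_uniform_histogram_entropy_six_bits(self, rng):
        lab = np.ones((4, 4, 4), dtype=np.int64)
        vol = np.repeat(np.arange(64, dtype=float), 1).reshape(4, 4, 4)
        values, _ = msi_complexity(vol, _habmap(lab))
        assert values[0] == pytest.approx(6.0)

    def test_slab_fractal_dimension_near_two(self):
        lab = np.zeros((20, 20, 20), dtype=np.int64)
        lab[10, 2:18, 2:18] = 1
        values, _ = msi_complexity(np.zeros(lab.shape), _habmap(lab))
        assert values[5] == pytest.approx(2.0, abs=0.15)

    def test_connectivity_components(self):
        lab = np.zeros((3, 3, 7), dtype=np.int64)
        lab[1, 1, 0:2] = 1
        lab[1, 1, 4:6] = 1
        values, _ = msi_complexity(np.zeros(lab.shape), _habmap(lab))
        assert values[10] == pytest.approx(0.5)       # two components
        lab2 = np.zeros_like(lab)
        lab2[1, 1, :] = 1
        v2, _ = msi_complexity(np.zeros(lab.shape), _habmap(lab2))
        assert v2[10] == pytest.approx(1.0)

    def test_eccentricity_elongated_vs_ball(self):
        lab_line = np.zeros((3, 3, 9), dtype=np.int64)
        lab_line[1, 1, :] = 1
        v_line, _ = msi_complexity(np.zeros(lab_line.shape), _habmap(lab_line))
        ball = np.where(_ball(5), 1, 0)
        v_ball, _ = msi_complexity(np.zeros(ball.shape), _habmap(ball))
        assert v_line[15] > 0.95
        assert v_ball[15] < 0.3


class TestGlobalDescriptors:
    def _globals(self, lab):
        hm = _habmap(lab)
        vols, border, pairs, norm = msi_volumes_and_interactions(hm, lab > 0)
        return msi_global(hm, lab > 0, border, pairs, norm)

    def test_single_habitat_degenerate(self):
        lab = np.where(_ball(5), 1, 0)
        g = self._globals(lab)
        assert g[0] == 0.0                      # global entropy
        assert g[2] == 0.0                      # pattern complexity
        assert g[4] == pytest.approx(1.0)       # tumor signature

    def test_five_equal_fractions_entropy(self):
        lab = np.zeros((1, 1, 10), dtype=np.int64)
        lab[0, 0] = [1, 1, 2, 2, 3, 3, 4, 4, 5, 5]
        g = self._globals(lab)
        assert g[0] == pytest.approx(np.log2(5))

    def test_checkerboard_vs_solid_halves(self):
        zz, yy, xx = np.mgrid[:8, :8, :8]
        checker = np.where((zz + yy + xx) % 2 == 0, 1, 2).astype(np.int64)
        g_check = self._globals(checker)
        halves = np.where(xx < 4, 1, 2).astype(np.int64)
        g_half = self._globals(halves)
        assert g_check[2] == pytest.approx(0.1)     # one active pair / 10
        assert g_check[1] < g_half[1]  # checkerboard mixes locally everywhere


class TestMSIExtract:
    def test_schema_and_determinism(self, ct_cohort_small, ct_habitats):
        _, _, _, habmaps = ct_habitats
        c = ct_cohort_small
        v1 = msi_extract(c.volumes[0], c.masks[0], habmaps[0])
        v2 = msi_extract(c.volumes[0], c.masks[0], habmaps[0])
        assert len(v1.values) == 120
        assert v1.names == MSI_NAMES
        assert sum(MSI_GROUP_SIZES) == 120
        assert np.array_equal(v1.values, v2.values)
        assert np.all(np.isfinite(v1.values))

    def test_group_conservation_invariants(self, ct_cohort_small,
                                           ct_habitats):
        _, _, _, habmaps = ct_habitats
        c = ct_cohort_small
        s = msi_extract(c.volumes[0], c.masks[0], habmaps[0]).as_series()
        vols = s[[f"MSI_{i}" for i in range(5, 10)]].sum()
        assert vols == c.masks[0].sum()
        normed = s[[f"MSI_{i}" for i in range(25, 30)]].sum()
        assert normed == pytest.approx(1.0)

    def test_palette_order_violation_rejected(self):
        lab = np.zeros((1, 1, 6), dtype=np.int64)
        lab[0, 0] = [1, 1, 1, 2, 2, 2]
        vol = np.zeros((1, 1, 6))
        vol[0, 0] = [0, 0, 0, 9, 9, 9]      # habitat 2 brighter than 1
        with pytest.raises(ValueError, match="ordered"):
            msi_extract(vol, lab > 0, _habmap(lab))

    def test_missing_habitats_flagged_not_fatal(self):
        lab = np.zeros((4, 4, 4), dtype=np.int64)
        lab[:2] = 1
        lab[2:] = 2
        vol = np.where(lab == 1, 50.0, 10.0)
        v = msi_extract(vol, lab > 0, _habmap(lab))
        assert len(v.values) == 120
        assert set(v.missing_habitats) == {3, 4, 5}


class TestFScoreRank:
    def test_hand_computed_fscore(self, rng):
        from habitatrisk._types import FeatureBlock
        import pandas as pd

        # class means 3 vs 1, sample variances 2 and 2 -> F = 0.5
        pos = np.array([3 - np.sqrt(2), 3, 3 + np.sqrt(2)])
        neg = np.array([1 - np.sqrt(2), 1, 1 + np.sqrt(2)])
        x = np.concatenate([pos, neg])
        y = np.array([1, 1, 1, 0, 0, 0])
        block = FeatureBlock(pd.DataFrame({"f": x}), "ct_msi")
        _, scores = fscore_rank(block, y, threshold=10.0)
        assert scores["f"] == pytest.approx(0.5, rel=1e-9)

    def test_uninformative_feature_excluded(self, rng):
        from habitatrisk._types import FeatureBlock
        import pandas as pd

        x = rng.standard_normal(40)
        y = np.r_[np.ones(20), np.zeros(20)].astype(int)
        block = FeatureBlock(pd.DataFrame({"same": np.r_[x[:20], x[:20]]}),
                             "ct_msi")
        sel, scores = fscore_rank(block, y, threshold=1.0)
        assert scores["same"] == pytest.approx(0.0, abs=1e-9)
        assert sel.n_features == 0

    def test_planted_features_rank_above_noise(self, rng):
        from habitatrisk._types import FeatureBlock
        import pandas as pd

        n = 200
        y = rng.binomial(1, 0.5, n)
        x = rng.standard_normal((n, 100))
        x[:, :10] += 3.0 * y[:, None]
        block = FeatureBlock(
            pd.DataFrame(x, columns=[f"f{i}" for i in range(100)]), "ct_msi")
        _, scores = fscore_rank(block, y)
        top10 = set(scores.index[:10])
        assert top10 == {f"f{i}" for i in range(10)}
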