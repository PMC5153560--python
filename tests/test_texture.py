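"""GLCM construction and Haralick features against brute-force oracles."""

import numpy as np
import pytest

from striatex import (
    CooccurrenceMatrix,
    DIRECTIONS_3D,
    DegenerateRegionError,
    FEATURE_NAMES,
    RegionMaskSet,
    Volume,
    build_glcm,
    haralick_features,
    quantize_roi,
    texture_for_region,
)


def glcm_bruteforce(levels, Q, distance=1):
    """Literal pair enumeration: every voxel, every offset, both orders."""
    total = np.zeros((Q, Q))
    shape = levels.shape
    for d in DIRECTIONS_3D:
        counts = np.zeros((Q, Q))
        for i in range(shape[0]):
            for j in range(shape[1]):
                for k in range(shape[2]):
                    a = levels[i, j, k]
                    if a <= 0:
                        continue
                    ii, jj, kk = i + d[0] * distance, j + d[1] * distance, k + d[2] * distance
                    if not (0 <= ii < shape[0] and 0 <= jj < shape[1] and 0 <= kk < shape[2]):
                        continue
                    b = levels[ii, jj, kk]
                    if b <= 0:
                        continue
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
        total += counts
    total /= len(DIRECTIONS_3D)
    return total / total.sum()


def haralick_bruteforce(p):
    """Literal double-loop evaluation of all 13 feature definitions."""
    Q = p.shape[0]
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = sum((i + 1) * px[i] for i in range(Q))
    mu_y = sum((j + 1) * py[j] for j in range(Q))
    sig_x = np.sqrt(sum((i + 1 - mu_x) ** 2 * px[i] for i in range(Q)))
    sig_y = np.sqrt(sum((j + 1 - mu_y) ** 2 * py[j] for j in range(Q)))
    out = dict.fromkeys(FEATURE_NAMES, 0.0)
    po = sum(p[i, i] for i in range(Q))
    pe = sum(px[i] * py[i] for i in range(Q))
    corr_num = 0.0
    for i in range(Q):
        for j in range(Q):
            pij = p[i, j]
            gi, gj = i + 1, j + 1
            out["energy"] += pij**2
            if pij > 0:
                out["entropy"] -= pij * np.log2(pij)
            corr_num += gi * gj * pij
            out["contrast"] += (gi - gj) ** 2 * pij
            out["variance"] += (gi - mu_x) ** 2 * pij
            out["sum_mean"] += 0.5 * (gi + gj) * pij
            out["cluster_shade"] += (gi + gj - mu_x - mu_y) ** 3 * pij
            out["cluster_tendency"] += (gi + gj - mu_x - mu_y) ** 4 * pij
            out["homogeneity"] += pij / (1 + abs(gi - gj))
            if gi != gj:
                out["inverse_variance"] += pij / (gi - gj) ** 2
            out["dissimilarity"] += abs(gi - gj) * pij
    out["correlation"] = (
        (corr_num - mu_x * mu_y) / (sig_x * sig_y) if sig_x > 0 and sig_y > 0 else 0.0
    )
    out["agreement"] = (po - pe) / (1 - pe) if pe < 1 else (1.0 if po >= 1 else 0.0)
    out["max_probability"] = p.max()
    return out


def random_symmetric_glcm(rng, Q=8):
    m = rng.random((Q, Q))
    m = m + m.T
    return CooccurrenceMatrix(p=m / m.sum(), n_pairs_per_direction=np.ones(13, dtype=int))


class TestQuantize:
    def test_constant_roi_all_level_one(self, constant_volume):
        mask = np.ones(constant_volume.shape, bool)
        q = quantize_roi(constant_volume, mask, Q=32)
        assert set(np.unique(q.levels[mask])) == {1}

    def test_four_values_four_levels(self):
        data = np.zeros((1, 1, 4))
        data[0, 0] = [0.0, 1.0, 2.0, 3.0]
        v = Volume(data)
        q = quantize_roi(v, np.ones_like(data, bool), Q=4)
        np.testing.assert_array_equal(q.levels[0, 0], [1, 2, 3, 4])

    def test_maximum_maps_to_level_q(self, rng):
        v = Volume(rng.random((5, 5, 5)))
        q = quantize_roi(v, np.ones(v.shape, bool), Q=32)
        assert q.levels.max() == 32

    def test_empty_mask_and_low_q_rejected(self, constant_volume):
        with pytest.raises(ValueError, match="empty mask"):
            quantize_roi(constant_volume, np.zeros(constant_volume.shape, bool))
        with pytest.raises(ValueError, match="Q=1"):
            quantize_roi(constant_volume, np.ones(constant_volume.shape, bool), Q=1)


class TestGlcm:
    def test_two_voxel_pair_by_hand(self):
        levels = np.zeros((1, 1, 2), dtype=int)
        levels[0, 0] = [1, 2]
        from striatex import QuantizedRegion

        q = QuantizedRegion(levels=levels, Q=2, vmin=0.0, vmax=1.0)
        m = build_glcm(q)
        expected = np.array([[0.0, 0.5], [0.5, 0.0]])
        np.testing.assert_allclose(m.p, expected, atol=1e-15)

    def test_constant_roi_single_cell(self, constant_volume):
        mask = np.ones(constant_volume.shape, bool)
        m = build_glcm(quantize_roi(constant_volume, mask, Q=32))
        assert m.p[0, 0] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_single_voxel_roi_degenerate(self, constant_volume):
        mask = np.zeros(constant_volume.shape, bool)
        mask[3, 3, 3] = True
        with pytest.raises(DegenerateRegionError):
            build_glcm(quantize_roi(constant_volume, mask, Q=4))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        v = Volume(rng.random((5, 5, 5)))
        mask = rng.random((5, 5, 5)) > 0.3
        mask[2, 2, 2] = True
        q = quantize_roi(v, mask, Q=4)
        m = build_glcm(q)
        oracle = glcm_bruteforce(q.levels, 4)
        np.testing.assert_allclose(m.p, oracle, atol=1e-12)
        assert abs(m.p.sum() - 1.0) < 1e-9
        np.testing.assert_allclose(m.p, m.p.T, atol=1e-12)


class TestHaralick:
    def test_constant_roi_closed_form(self, constant_volume):
        mask = np.ones(constant_volume.shape, bool)
        f = texture_for_region(constant_volume, _wrap(mask), "roi", Q=32)
        assert f.energy == pytest.approx(1.0)
        assert f.entropy == pytest.approx(0.0)
        assert f.contrast == pytest.approx(0.0)
        assert f.dissimilarity == pytest.approx(0.0)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.max_probability == pytest.approx(1.0)
        assert f.variance == pytest.approx(0.0)
        assert f.inverse_variance == pytest.approx(0.0)
        assert f.sum_mean == pytest.approx(1.0)
        assert f.correlation == 0.0  # degenerate sigma rule
        assert f.agreement == 1.0  # degenerate Pe rule

    def test_two_cell_matrix_closed_form(self):
        p = np.array([[0.0, 0.5], [0.5, 0.0]])
        m = CooccurrenceMatrix(p=p, n_pairs_per_direction=np.ones(13, dtype=int))
        f = haralick_features(m)
        assert f.entropy == pytest.approx(1.0)  # one bit
        assert f.contrast == pytest.approx(1.0)
        assert f.dissimilarity == pytest.approx(1.0)
        assert f.homogeneity == pytest.approx(0.5)
        assert f.energy == pytest.approx(0.5)
        assert f.agreement == pytest.approx(-1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_matrices_match_literal_sums(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(20):
            m = random_symmetric_glcm(rng)
            f = haralick_features(m)
            oracle = haralick_bruteforce(m.p)
            for name in FEATURE_NAMES:
                assert getattr(f, name) == pytest.approx(oracle[name], abs=1e-10), name

    def test_unnormalized_matrix_rejected(self):
        with pytest.raises(ValueError):
            CooccurrenceMatrix(p=np.ones((4, 4)), n_pairs_per_direction=np.ones(13, int))


def _wrap(mask):
    return RegionMaskSet({"roi": mask})


class TestTextureForRegion:
    def test_affine_intensity_invariance(self, rng):
        v = Volume(rng.random((7, 7, 7)) * 10 + 3)
        mask = np.ones(v.shape, bool)
        f0 = texture_for_region(v, _wrap(mask), "roi", Q=16)
        f1 = texture_for_region(Volume(2.5 * v.data + 11.0), _wrap(mask), "roi", Q=16)
        for name in FEATURE_NAMES:
            assert getattr(f0, name) == pytest.approx(getattr(f1, name), abs=1e-12), name

    def test_striped_volume_rougher_than_constant(self):
        data = np.full((8, 8, 8), 1.0)
        data[:, :, ::2] = 2.0  # period-2 stripes along z
        mask = np.ones(data.shape, bool)
        striped = texture_for_region(Volume(data), _wrap(mask), "roi", Q=8)
        flat = texture_for_region(Volume(np.ones(data.shape)), _wrap(mask), "roi", Q=8)
        assert striped.contrast > flat.contrast
        assert striped.homogeneity < flat.homogeneity

    def test_degenerate_region_yields_nan_features(self, constant_volume):
        mask = np.zeros(constant_volume.shape, bool)
        mask[0, 0, 0] = True
        f = texture_for_region(constant_volume, _wrap(mask), "roi", Q=4)
        assert f.degenerate
        assert np.isnan(f.entropy)

    def test_severity_raises_caudate_entropy(self, default_params, default_masks):
        from striatex import simulate_subject
        from conftest import make_record

        params = type(default_params)(**{**default_params.to_dict(), "noise_sd": 0.0})
        rng_state = 5
        feats = {}
        for s in (0.0, 1.0):
            vol = simulate_subject(
                params, make_record(s), masks=default_masks,
                rng=np.random.default_rng(rng_state),
            )
            feats[s] = texture_for_region(vol, default_masks, "caudate_L")
        assert feats[1.0].entropy > feats[0.0].entropy
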