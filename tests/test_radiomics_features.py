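"""Feature bank: histogram identities, first-order statistics against
closed forms, LBP codes against a bit-arithmetic oracle, sparse GLCM
against a dense brute-force oracle, and whole-vector contracts."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from edemarad.model_pipeline import LesionRecord
from edemarad.radiomics_features import (
    FIRST_ORDER_STATS,
    GLCM_DIRECTIONS,
    GLCM_STATS,
    LBP_VARIANTS,
    IntensityHistogram,
    extract_all,
    feature_manifest,
    feature_names,
    first_order_features,
    glcm_features,
    glcm_pairs,
    intensity_histogram,
    lbp_plane_codes,
    lbp_top_features,
)
from edemarad.roi_geometry import EmptyMaskError, RoiMask, VoxelVolume
from edemarad.synthetic_data import generate_texture_volume


def const_volume(shape, value):
    return VoxelVolume(np.full(shape, value, dtype=np.uint16))


def full_mask_of(shape):
    return RoiMask(np.ones(shape, dtype=bool))


# ---------------------------------------------------------------------------
# histogram
# ---------------------------------------------------------------------------


class TestIntensityHistogram:
    def test_constant_roi(self):
        vol = const_volume((3, 3, 3), 100)
        mask = RoiMask(np.zeros((3, 3, 3), dtype=bool))
        mask.voxels[0, 0, :] = True
        mask.voxels[1, 1, :2] = True  # 5 voxels
        h = intensity_histogram(vol, mask)
        assert list(h.bin_values) == [100]
        assert list(h.counts) == [5]

    def test_range_edges(self):
        arr = np.zeros((2, 2, 2), dtype=np.uint16)
        arr[0, 0, 0] = 65535
        h = intensity_histogram(VoxelVolume(arr), full_mask_of((2, 2, 2)))
        assert set(h.bin_values) == {0, 65535}
        assert h.total == 8

    def test_counts_conserved(self, random_volume, rng):
        mask = RoiMask(rng.random((8, 8, 8)) > 0.4)
        h = intensity_histogram(random_volume, mask)
        assert h.total == mask.count()
        assert h.probabilities.sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_mask_raises(self, random_volume):
        with pytest.raises(EmptyMaskError):
            intensity_histogram(random_volume, RoiMask(np.zeros((8, 8, 8), dtype=bool)))


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------


class TestFirstOrder:
    def test_degenerate_constant_distribution(self):
        vol = const_volume((3, 3, 3), 42)
        fo = first_order_features(intensity_histogram(vol, full_mask_of((3, 3, 3))))
        assert fo["fo_mean"] == 42
        assert fo["fo_sd"] == 0
        assert fo["fo_skewness"] == 0
        assert fo["fo_kurtosis"] == 0
        assert fo["fo_energy"] == 1
        assert fo["fo_entropy"] == 0
        assert fo["fo_max"] == 1
        assert fo["fo_max_position"] == 42
        assert fo["fo_range"] == 0
        assert fo["fo_n_rel_max"] == 1

    def test_symmetric_two_point_case(self):
        h = IntensityHistogram([10, 20], [3, 3])
        fo = first_order_features(h)
        assert fo["fo_mean"] == pytest.approx(15)
        assert fo["fo_energy"] == pytest.approx(0.5)
        assert fo["fo_entropy"] == pytest.approx(1.0)
        assert fo["fo_range"] == 10
        assert fo["fo_max_position"] == 10  # tie -> smallest bin

    def test_three_point_closed_form(self):
        # p = (1/2, 1/4, 1/4): entropy = 1.5 bits, energy = 0.375
        h = IntensityHistogram([0, 1, 2], [2, 1, 1])
        fo = first_order_features(h)
        assert fo["fo_entropy"] == pytest.approx(1.5)
        assert fo["fo_energy"] == pytest.approx(0.375)

    def test_moments_match_voxel_level_under_identity_binning(self, rng):
        vals = rng.integers(0, 50, 200)
        uniq, counts = np.unique(vals, return_counts=True)
        fo = first_order_features(IntensityHistogram(uniq, counts))
        assert fo["fo_mean"] == pytest.approx(vals.mean())
        assert fo["fo_sd"] == pytest.approx(vals.std())

    def test_windowed_energy_and_plateaus(self):
        # peaks at b=0 (0.4) and b=20 (0.4 plateau over two bins? no: equal
        # masses merge into one plateau only when consecutive in sequence)
        h = IntensityHistogram([0, 10, 20], [4, 2, 4])
        fo = first_order_features(h, window=5)
        assert fo["fo_n_rel_max"] == 2
        assert fo["fo_max_energy"] == pytest.approx(0.16)
        assert fo["fo_rel_max_energy"] == pytest.approx(0.16 + 0.16)


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------


def lbp_bit_oracle(plane_img, cy, cx):
    """Direct bit-by-bit 3x3 LBP at (row=second axis, col=first axis?) —
    arguments are (second-axis idx, first-axis idx) of a 2D plane whose
    axes are (second-in-plane, first-in-plane)."""
    ring = [(1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1)]
    c = plane_img[cy, cx]
    code = 0
    for k, (d1, d2) in enumerate(ring):
        if plane_img[cy + d2, cx + d1] >= c:
            code |= 1 << k
    return code


class TestLbp:
    def test_constant_region_codes_255(self):
        vol = const_volume((5, 5, 5), 7)
        codes = lbp_plane_codes(vol, full_mask_of((5, 5, 5)), "XY", "basic")
        assert np.all(codes == 255)

    def test_single_bright_voxel(self):
        arr = np.zeros((5, 5, 5), dtype=np.uint16)
        arr[2, 2, 2] = 100
        vol = VoxelVolume(arr)
        center = np.zeros((5, 5, 5), dtype=bool)
        center[2, 2, 2] = True
        assert lbp_plane_codes(vol, RoiMask(center), "XY", "basic")[0] == 0
        # neighbors of the bright voxel: the tie convention (neighbor >=
        # center sets the bit) makes every dark-dark comparison a 1, so the
        # code is 255; on a strictly descending background exactly one bit
        # (the bright direction) survives
        for dy, dx in [(0, 1), (1, 0), (1, 1)]:
            nb = np.zeros((5, 5, 5), dtype=bool)
            nb[2, 2 + dy, 2 + dx] = True
            assert lbp_plane_codes(vol, RoiMask(nb), "XY", "basic")[0] == 255
        ramp = np.zeros((5, 5, 5), dtype=np.uint16)
        for y in range(5):
            for x in range(5):
                ramp[2, y, x] = 50 - 10 * max(abs(y - 1), abs(x - 1))
        ramp[2, 2, 2] = 100  # bright voxel adjacent to the (2,1,1) center
        nb = np.zeros((5, 5, 5), dtype=bool)
        nb[2, 1, 1] = True
        code = int(lbp_plane_codes(VoxelVolume(ramp), RoiMask(nb), "XY", "basic")[0])
        assert bin(code).count("1") == 1

    def test_riu2_code_cardinality(self, textured_volume):
        mask = full_mask_of(textured_volume.shape)
        codes = lbp_plane_codes(textured_volume, mask, "XZ", "riu2")
        assert codes.min() >= 0 and codes.max() <= 9

    @pytest.mark.parametrize("plane,axes", [("XY", (2, 1)), ("XZ", (2, 0)), ("YZ", (1, 0))])
    def test_codes_match_bit_oracle(self, rng, plane, axes):
        arr = rng.integers(0, 30, size=(6, 6, 6)).astype(np.uint16)
        vol = VoxelVolume(arr)
        ax1, ax2 = axes
        fixed_ax = ({0, 1, 2} - {ax1, ax2}).pop()
        for target in [(2, 3, 1), (3, 2, 4), (1, 1, 2)]:
            m = np.zeros((6, 6, 6), dtype=bool)
            m[target] = True
            got = lbp_plane_codes(vol, RoiMask(m), plane, "basic")[0]
            # build the 2D plane with axes (second-in-plane, first-in-plane)
            sl = [slice(None)] * 3
            sl[fixed_ax] = target[fixed_ax]
            plane_img = arr[tuple(sl)]
            # plane_img axes are the remaining dims in (z,y,x) order
            rem = [d for d in (0, 1, 2) if d != fixed_ax]
            # reorder to (ax2, ax1)
            if rem != [ax2, ax1]:
                plane_img = plane_img.T
            cy, cx = target[ax2], target[ax1]
            assert got == lbp_bit_oracle(plane_img, cy, cx)

    def test_48_finite_features(self, textured_volume, ellipsoid_mask):
        feats = lbp_top_features(textured_volume, ellipsoid_mask)
        assert len(feats) == 48
        assert all(np.isfinite(v) for v in feats.values())

    def test_constant_volume_concatenated_histogram(self):
        vol = const_volume((6, 6, 6), 9)
        feats = lbp_top_features(vol, full_mask_of((6, 6, 6)))
        # per plane all mass lands in the code-255 bin: 3 nonempty bins
        assert feats["lbp_basic_entropy"] == pytest.approx(np.log2(3))
        assert feats["lbp_basic_n_rel_max"] == 1  # equal plateau counts once

    def test_mirror_invariance_of_ri_histograms(self):
        vol = generate_texture_volume((12, 12, 12), 1.0, 1000, 200, seed=3)
        mask = full_mask_of((12, 12, 12))
        mirrored = VoxelVolume(vol.intensities[:, :, ::-1].copy())
        a = lbp_top_features(vol, mask)
        b = lbp_top_features(mirrored, mask)
        for stat in ("mean", "energy", "entropy"):
            assert a[f"lbp_ri_{stat}"] == pytest.approx(b[f"lbp_ri_{stat}"], rel=0.05)


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def dense_glcm_oracle(vol, mask, direction):
    """Exhaustive double loop over all voxels, dense matrix over observed
    gray levels, then direct feature formulas."""
    shape = vol.shape
    pairs = []
    for z in range(shape[0]):
        for y in range(shape[1]):
            for x in range(shape[2]):
                if not mask[z, y, x]:
                    continue
                z2, y2, x2 = z + direction[0], y + direction[1], x + direction[2]
                if 0 <= z2 < shape[0] and 0 <= y2 < shape[1] and 0 <= x2 < shape[2] \
                        and mask[z2, y2, x2]:
                    pairs.append((int(vol[z, y, x]), int(vol[z2, y2, x2])))
    if not pairs:
        return None, {s: 0.0 for s in GLCM_STATS}
    levels = sorted({g for p in pairs for g in p})
    idx = {g: i for i, g in enumerate(levels)}
    M = np.zeros((len(levels), len(levels)))
    for i, j in pairs:
        M[idx[i], idx[j]] += 1
    P = M / M.sum()
    lv = np.array(levels, dtype=float)
    ii, jj = np.meshgrid(lv, lv, indexing="ij")
    mu_i = (ii * P).sum()
    mu_j = (jj * P).sum()
    nz = P > 0
    stats = {
        "autocorr": float((ii * jj * P).sum()),
        "covariance": float(((ii - mu_i) * (jj - mu_j) * P).sum()),
        "inertia": float(((ii - jj) ** 2 * P).sum()),
        "abs_inertia": float((np.abs(ii - jj) * P).sum()),
        "inv_inertia": float((P / (1 + (ii - jj) ** 2)).sum()),
        "energy": float((P**2).sum()),
        "entropy": float(-(P[nz] * np.log2(P[nz])).sum()),
    }
    return pairs, stats


class TestGlcm:
    def test_directed_pair_convention(self):
        arr = np.zeros((1, 1, 2), dtype=np.uint16)
        arr[0, 0, 0], arr[0, 0, 1] = 5, 9
        vol = VoxelVolume(arr)
        mask = full_mask_of((1, 1, 2))
        fwd = glcm_pairs(vol, mask, (0, 0, 1))
        assert fwd.total == 1
        assert (fwd.levels_i[0], fwd.levels_j[0]) == (5, 9)
        bwd = glcm_pairs(vol, mask, (0, 0, -1))
        assert (bwd.levels_i[0], bwd.levels_j[0]) == (9, 5)

    def test_constant_roi_pairs_on_diagonal(self):
        vol = const_volume((4, 4, 4), 77)
        t = glcm_pairs(vol, full_mask_of((4, 4, 4)), (1, 1, 0))
        assert np.all(t.levels_i == 77) and np.all(t.levels_j == 77)

    def test_pair_count_matches_bruteforce(self, random_volume, rng):
        mask = rng.random((8, 8, 8)) > 0.5
        for direction in [(0, 0, 1), (1, -1, 0), (-1, 1, 1)]:
            t = glcm_pairs(random_volume, RoiMask(mask), direction)
            pairs, _ = dense_glcm_oracle(random_volume.intensities, mask, direction)
            assert t.total == (len(pairs) if pairs else 0)

    def test_constant_roi_degenerate_stats(self):
        c = 11
        feats = glcm_features(const_volume((3, 3, 3), c), full_mask_of((3, 3, 3)))
        for d in range(26):
            assert feats[f"glcm_{d:02d}_inertia"] == 0
            assert feats[f"glcm_{d:02d}_abs_inertia"] == 0
            assert feats[f"glcm_{d:02d}_inv_inertia"] == 1
            assert feats[f"glcm_{d:02d}_energy"] == 1
            assert feats[f"glcm_{d:02d}_entropy"] == 0
            assert feats[f"glcm_{d:02d}_autocorr"] == c * c
            assert feats[f"glcm_{d:02d}_covariance"] == 0

    def test_single_pair_table_stats(self):
        arr = np.array([[[0, 1]]], dtype=np.uint16)
        vol = VoxelVolume(arr)
        mask = full_mask_of((1, 1, 2))
        feats = glcm_features(vol, mask)
        d = GLCM_DIRECTIONS.index((0, 0, 1))
        assert feats[f"glcm_{d:02d}_inertia"] == 1
        assert feats[f"glcm_{d:02d}_abs_inertia"] == 1
        assert feats[f"glcm_{d:02d}_inv_inertia"] == 0.5
        assert feats[f"glcm_{d:02d}_energy"] == 1
        assert feats[f"glcm_{d:02d}_entropy"] == 0
        assert feats[f"glcm_{d:02d}_autocorr"] == 0

    def test_all_182_match_dense_oracle(self, rng):
        arr = rng.integers(0, 40, size=(5, 5, 5)).astype(np.uint16)
        vol = VoxelVolume(arr)
        mask = np.ones((5, 5, 5), dtype=bool)
        feats = glcm_features(vol, RoiMask(mask))
        assert len(feats) == 182
        for d_idx, direction in enumerate(GLCM_DIRECTIONS):
            _, expected = dense_glcm_oracle(arr, mask, direction)
            for s in GLCM_STATS:
                assert feats[f"glcm_{d_idx:02d}_{s}"] == pytest.approx(
                    expected[s], abs=1e-9
                ), (direction, s)

    def test_inertia_monotone_in_noise(self):
        """Average GLCM inertia rises with texture noise amplitude."""
        sds = np.linspace(50, 1500, 10)
        mask = full_mask_of((12, 12, 12))
        mean_inertia, levels = [], []
        for rep in range(5):
            for i, sd in enumerate(sds):
                vol = generate_texture_volume((12, 12, 12), 1.5, 3000, sd,
                                              seed=1000 * rep + i)
                feats = glcm_features(vol, mask)
                vals = [feats[f"glcm_{d:02d}_inertia"] for d in range(26)]
                mean_inertia.append(np.mean(vals))
                levels.append(sd)
        rho, _ = spearmanr(levels, mean_inertia)
        assert rho > 0.8


# ---------------------------------------------------------------------------
# full vector
# ---------------------------------------------------------------------------


class TestExtractAll:
    def test_253_named_features_in_canonical_order(self, textured_volume,
                                                   ellipsoid_mask, record):
        fv = extract_all(textured_volume, ellipsoid_mask, record)
        assert len(fv) == 253
        assert list(fv.values) == feature_names()
        assert len(fv.semantic()) == 11
        assert len(fv.radiomic()) == 242

    def test_manifest_matches_canonical_names(self):
        m = feature_manifest()
        assert m["names"] == feature_names()
        assert m["n_features"] == 253
        assert m["blocks"] == {"semantic": 11, "first_order": 12,
                               "lbp_top": 48, "glcm": 182}

    def test_radiomic_block_independent_of_semantics(self, textured_volume,
                                                     ellipsoid_mask, record):
        import dataclasses

        fv1 = extract_all(textured_volume, ellipsoid_mask, record)
        other = dataclasses.replace(record, age=30.0, edema_type=4, margins=3)
        fv2 = extract_all(textured_volume, ellipsoid_mask, other)
        assert fv1.radiomic() == fv2.radiomic()
        assert fv1.semantic() != fv2.semantic()

    def test_translation_invariance_on_interior_roi(self, record):
        base = generate_texture_volume((14, 14, 14), 1.0, 2000, 400, seed=5)
        arr = np.zeros((16, 16, 16), dtype=np.uint16)
        arr[0:14, 0:14, 0:14] = base.intensities
        shifted = np.zeros((16, 16, 16), dtype=np.uint16)
        shifted[1:15, 1:15, 1:15] = base.intensities
        m = np.zeros((16, 16, 16), dtype=bool)
        m[4:9, 4:9, 4:9] = True
        m2 = np.zeros((16, 16, 16), dtype=bool)
        m2[5:10, 5:10, 5:10] = True
        fv1 = extract_all(VoxelVolume(arr), RoiMask(m), record)
        fv2 = extract_all(VoxelVolume(shifted), RoiMask(m2), record)
        assert fv1.radiomic() == fv2.radiomic()

    def test_single_voxel_roi_all_finite(self, textured_volume, record):
        m = np.zeros((16, 16, 16), dtype=bool)
        m[8, 8, 8] = True
        fv = extract_all(textured_volume, RoiMask(m), record)
        assert np.all(np.isfinite(fv.as_array()))

    def test_missing_semantic_field_is_named(self, textured_volume, ellipsoid_mask):
        from edemarad.radiomics_features import SEMANTIC_FIELDS

        sem = {k: 1.0 for k in SEMANTIC_FIELDS}
        sem["edema_type"] = None
        with pytest.raises(ValueError, match="edema_type"):
            extract_all(textured_volume, ellipsoid_mask, sem)
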