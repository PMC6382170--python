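"""Texture matrices and features against exhaustive brute-force oracles."""

import numpy as np
import pytest

import oracles
from radfeat.phantoms import make_grid
from radfeat.preprocess import (
    DiscretizationMethod,
    DiscretizationRule,
    DiscretizedROI,
)
from radfeat.texture import (
    DIRECTIONS_2D,
    DIRECTIONS_3D,
    AggregationScheme,
    aggregate,
    glcm,
    glcm_features,
    gldzm,
    gldzm_features,
    glrlm,
    glrlm_features,
    glszm,
    glszm_features,
    ngldm,
    ngldm_features,
    ngtdm,
    ngtdm_features,
)


def _droi(levels, ng, morph=None):
    levels = np.asarray(levels, dtype=np.int64)
    imask = levels > 0
    morph = imask if morph is None else np.asarray(morph, bool)
    rule = DiscretizationRule(DiscretizationMethod.FBN, n_bins=ng)
    return DiscretizedROI(levels, ng, rule, imask, morph, (1.0, 1.0, 1.0))


def _constant(shape=(2, 3, 3)):
    return _droi(np.ones(shape), 1)


# ---------------------------------------------------------------------------
# Matrix construction vs oracles


class TestMatrixOracles:
    def test_glcm_matches_pair_enumeration_all_3d_offsets(self, seeded_grids):
        for d in seeded_grids:
            lv = d.levels * d.intensity_mask
            for off in DIRECTIONS_3D:
                got = glcm(d, off).counts
                np.testing.assert_array_equal(got, oracles.glcm_pairs(lv, off, d.ng))

    def test_glcm_matches_pair_enumeration_2d(self, seeded_grids):
        d = seeded_grids[0]
        lv = d.levels * d.intensity_mask
        for k in range(lv.shape[0]):
            for off in DIRECTIONS_2D:
                got = glcm(d, off, slice_index=k).counts
                np.testing.assert_array_equal(
                    got, oracles.glcm_pairs(lv[k : k + 1], off, d.ng)
                )

    def test_glrlm_matches_run_enumeration(self, seeded_grids):
        for d in seeded_grids:
            lv = d.levels * d.intensity_mask
            for off in DIRECTIONS_3D:
                got = glrlm(d, off).counts
                np.testing.assert_array_equal(got, oracles.run_lengths(lv, off, d.ng))

    def test_glszm_zone_inventory_matches_flood_fill(self, seeded_grids):
        for d in seeded_grids:
            lv = d.levels * d.intensity_mask
            got = glszm(d).counts
            ref = np.zeros_like(got)
            for g, voxels in oracles.flood_zones(lv, two_d=False):
                ref[g - 1, len(voxels) - 1] += 1
            np.testing.assert_array_equal(got, ref)

    def test_gldzm_distances_match_bfs(self, seeded_grids):
        for d in seeded_grids:
            lv = d.levels * d.intensity_mask
            got = gldzm(d).counts
            dist = oracles.border_distance_bfs(d.morph_mask, two_d=False)
            entries = [
                (g, min(dist[v] for v in voxels))
                for g, voxels in oracles.flood_zones(lv, two_d=False)
            ]
            ref = np.zeros((d.ng, max(dd for _, dd in entries)))
            for g, dd in entries:
                ref[g - 1, dd - 1] += 1
            np.testing.assert_array_equal(got[:, : ref.shape[1]], ref)
            assert got[:, ref.shape[1]:].sum() == 0

    def test_ngtdm_matches_neighbourhood_means(self, seeded_grids):
        for d in seeded_grids:
            lv = d.levels * d.intensity_mask
            got = ngtdm(d).counts
            np.testing.assert_allclose(got, oracles.ngtdm_table(lv, d.ng, two_d=False), atol=1e-10)

    def test_ngldm_matches_neighbour_counts(self, seeded_grids):
        for d in seeded_grids:
            lv = d.levels * d.intensity_mask
            for alpha in (0, 1):
                got = ngldm(d, alpha=alpha).counts
                np.testing.assert_array_equal(
                    got, oracles.ngldm_table(lv, d.ng, two_d=False, alpha=alpha)
                )

    def test_2d_matrices_match_oracles_per_slice(self, seeded_grids):
        d = seeded_grids[-1]  # irregular mask
        lv = d.levels * d.intensity_mask
        for k in range(lv.shape[0]):
            sl = lv[k : k + 1]
            np.testing.assert_allclose(
                ngtdm(d, slice_index=k).counts, oracles.ngtdm_table(sl, d.ng, two_d=True),
                atol=1e-10,
            )
            np.testing.assert_array_equal(
                ngldm(d, slice_index=k).counts, oracles.ngldm_table(sl, d.ng, two_d=True)
            )
            got = glszm(d, slice_index=k).counts
            ref = np.zeros_like(got)
            for g, voxels in oracles.flood_zones(sl, two_d=True):
                ref[g - 1, len(voxels) - 1] += 1
            np.testing.assert_array_equal(got, ref)


# ---------------------------------------------------------------------------
# Hand-checkable closed forms


class TestClosedForms:
    def test_glcm_two_voxel_pair(self):
        d = _droi(np.array([[[1, 2]]]), 2)
        counts = glcm(d, (0, 0, 1)).counts
        np.testing.assert_array_equal(counts, [[0, 1], [1, 0]])

    def test_glcm_constant_roi_point_mass(self):
        f = glcm_features(glcm(_constant(), (0, 0, 1)))
        assert f["joint maximum"] == 1.0
        assert f["angular second moment"] == 1.0
        assert f["contrast"] == 0.0
        assert f["joint entropy"] == 0.0

    def test_glcm_checkerboard_anticorrelated(self):
        z, y, x = np.meshgrid(np.arange(1), np.arange(4), np.arange(4), indexing="ij")
        board = ((y + x) % 2) + 1
        f = glcm_features(glcm(_droi(board, 2), (0, 0, 1)))
        assert f["contrast"] == pytest.approx(1.0)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_glcm_cluster_tendency_equals_sum_variance(self, seeded_grids):
        for d in seeded_grids:
            f = glcm_features(glcm(d, (0, 1, 1)))
            assert f["cluster tendency"] == pytest.approx(f["sum variance"], rel=1e-9)

    def test_glrlm_line_runs(self):
        d = _droi(np.array([[[1, 1, 1, 2]]]), 2)
        m = glrlm(d, (0, 0, 1))
        assert m.counts[0, 2] == 1  # run (level 1, length 3)
        assert m.counts[1, 0] == 1  # run (level 2, length 1)
        f = glrlm_features(m)
        assert f["Run percentage"] == pytest.approx(0.5)

    def test_glrlm_constant_line_closed_form(self):
        n = 6
        d = _droi(np.ones((1, 1, n)), 1)
        f = glrlm_features(glrlm(d, (0, 0, 1)))
        assert f["short run emphasis"] == pytest.approx(1 / n**2)
        assert f["long runs emphasis"] == pytest.approx(n**2)

    def test_glszm_constant_roi_single_zone(self):
        d = _constant((2, 3, 3))
        f = glszm_features(glszm(d))
        assert f["Zone percentage GLSZM"] == pytest.approx(1 / 18)

    def test_glszm_diagonal_touch_is_one_zone(self):
        lv = np.zeros((1, 2, 2), dtype=int)
        lv[0, 0, 0] = lv[0, 1, 1] = 1
        d = _droi(lv, 1)
        counts = glszm(d, slice_index=0).counts
        assert counts[0, 1] == 1  # one zone of size 2 (8-connectivity)
        assert counts.sum() == 1

    def test_gldzm_single_voxel_distance_one(self):
        lv = np.zeros((3, 3, 3), dtype=int)
        lv[1, 1, 1] = 1
        counts = gldzm(_droi(lv, 1)).counts
        assert counts[0, 0] == 1

    def test_gldzm_full_slice_distance_map(self):
        """5x5 single-slice full mask: center voxel sits 3 steps from outside,
        zone distance = min over the zone = 1."""
        d = _droi(np.ones((1, 5, 5)), 1)
        dist = oracles.border_distance_bfs(d.morph_mask, two_d=True)
        assert dist[0, 2, 2] == 3
        counts = gldzm(d, slice_index=0).counts
        assert counts[0, 0] == 1.0  # single zone at distance 1

    def test_ngtdm_constant_roi(self):
        f = ngtdm_features(ngtdm(_constant()))
        assert f["contrast"] == 0.0
        assert f["complexity"] == 0.0
        assert f["coarseness"] == 1e6  # capped: zero differences

    def test_ngtdm_center_in_ring(self):
        """3x3 slice, center level 2 in a ring of 1s: s_2 = |2 - 1| = 1."""
        lv = np.ones((1, 3, 3), dtype=int)
        lv[0, 1, 1] = 2
        counts = ngtdm(_droi(lv, 2), slice_index=0).counts
        assert counts[1, 0] == 1 and counts[1, 1] == pytest.approx(1.0)
        ref = oracles.ngtdm_table(lv, 2, two_d=True)
        np.testing.assert_allclose(counts, ref, atol=1e-12)

    def test_ngldm_full_constant_cube_center_dependence(self):
        lv = np.ones((3, 3, 3), dtype=int)
        counts = ngldm(_droi(lv, 1), alpha=0).counts
        assert counts.shape[1] == 27  # dependence counts 0..26
        assert counts[0, 26] == 1  # the center voxel has all 26 neighbours

    def test_ngldm_dependence_count_percentage_is_one(self, seeded_grids):
        for d in seeded_grids:
            for scheme in ("2Davg", "2Dmrg", "3Dmrg"):
                f = aggregate("NGLDM", d, scheme)
                assert f["Dependence count percentage"] == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Normalization / conservation invariants


class TestInvariants:
    @pytest.mark.parametrize("family", ["GLCM", "GLRLM"])
    def test_directional_matrices_normalize_to_one(self, seeded_grids, family):
        build = glcm if family == "GLCM" else glrlm
        for d in seeded_grids:
            for off in DIRECTIONS_3D:
                counts = build(d, off).counts
                if counts.sum() > 0:
                    assert (counts / counts.sum()).sum() == pytest.approx(1.0)

    def test_glrlm_run_length_conservation(self, seeded_grids):
        """Sum over (run length x count) equals the ROI voxel count per direction."""
        for d in seeded_grids:
            nv = d.n_voxels()
            for off in DIRECTIONS_3D:
                counts = glrlm(d, off).counts
                j = np.arange(1, counts.shape[1] + 1)
                assert (counts * j).sum() == nv

    def test_zone_size_conservation_and_marginal_match(self, seeded_grids):
        """GLSZM conserves voxels; GLDZM shares its grey-level marginal."""
        for d in seeded_grids:
            sz = glszm(d).counts
            dz = gldzm(d).counts
            j = np.arange(1, sz.shape[1] + 1)
            assert (sz * j).sum() == d.n_voxels()
            np.testing.assert_array_equal(sz.sum(axis=1), dz.sum(axis=1))

    def test_glcm_symmetry(self, seeded_grids):
        for off in DIRECTIONS_3D:
            counts = glcm(seeded_grids[0], off).counts
            np.testing.assert_array_equal(counts, counts.T)

    def test_glcm_invariant_under_180_rotation(self, seeded_grids):
        d = seeded_grids[0]
        rot = np.rot90(d.levels, 2, axes=(1, 2)).copy()
        d2 = _droi(rot, d.ng)
        for off in DIRECTIONS_2D:
            a = glcm(d, off).counts
            b = glcm(d2, off).counts
            np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# Aggregation schemes


class TestAggregation:
    def test_merged_2d_is_sum_of_all_2d_matrices(self, seeded_grids):
        """MERGED_2D count matrix equals the elementwise sum over slices x directions."""
        d = seeded_grids[2]  # 2-slice grid
        per = []
        for k in range(d.levels.shape[0]):
            for off in DIRECTIONS_2D:
                per.append(glcm(d, off, slice_index=k).counts)
        ref = oracles.merge_counts(per)
        ref_feat = glcm_features(
            type(glcm(d, (0, 0, 1)))("GLCM", ref, 4 * d.n_voxels())
        )
        got = aggregate("GLCM", d, AggregationScheme.MERGED_2D)
        for key in got:
            assert got[key] == pytest.approx(ref_feat[key], rel=1e-9), key

    def test_single_slice_single_direction_degenerate_merges_agree(self):
        rng = np.random.default_rng(17)
        lv = rng.integers(1, 4, size=(1, 5, 5))
        d = _droi(lv, 3)
        avg = aggregate("GLSZM", d, "2Davg")
        mrg = aggregate("GLSZM", d, "2Dmrg")
        for key in avg:
            assert avg[key] == pytest.approx(mrg[key], rel=1e-9), key

    def test_constant_image_scheme_independent(self):
        d = _constant((3, 4, 4))
        vals = [
            aggregate("GLCM", d, s)["contrast"]
            for s in AggregationScheme
        ]
        assert all(v == 0.0 for v in vals)

    def test_all_schemes_run_on_all_families(self, seeded_grids):
        d = seeded_grids[0]
        for family in ("GLCM", "GLRLM"):
            for scheme in AggregationScheme:
                f = aggregate(family, d, scheme)
                assert all(np.isfinite(v) for v in f.values())
        for family in ("GLSZM", "GLDZM", "NGTDM", "NGLDM"):
            for scheme in ("2Davg", "2Dmrg", "3Dmrg"):
                f = aggregate(family, d, scheme)
                assert all(np.isfinite(v) for v in f.values())

    def test_scheme_family_mismatch_rejected(self, seeded_grids):
        with pytest.raises(ValueError):
            aggregate("NGTDM", seeded_grids[0], AggregationScheme.AVG_3D)
        with pytest.raises(ValueError):
            aggregate("GLSZM", seeded_grids[0], "3Davg")

    def test_degenerate_merge_aliases_for_undirected_families(self, seeded_grids):
        """For one-matrix-per-slice families both direction-resolved merge
        schemes reduce to the plain 2D merge."""
        d = seeded_grids[1]
        ref = aggregate("NGTDM", d, "2Dvmrg")
        for alias in ("2Dmrg", "2DDmrg"):
            got = aggregate("NGTDM", d, alias)
            for key in ref:
                assert got[key] == pytest.approx(ref[key], rel=1e-12), key

    def test_dir_merged_equals_oracle_merge_per_direction(self, seeded_grids):
        d = seeded_grids[0]
        slices = range(d.levels.shape[0])
        ref_feats = []
        for off in DIRECTIONS_2D:
            merged = oracles.merge_counts(
                [glrlm(d, off, slice_index=k).counts for k in slices]
            )
            m = glrlm(d, off)  # template for type
            ref_feats.append(
                glrlm_features(type(m)("GLRLM", merged, d.n_voxels()))
            )
        ref = {k: float(np.mean([f[k] for f in ref_feats])) for k in ref_feats[0]}
        got = aggregate("GLRLM", d, "2DDmrg")
        for key in got:
            assert got[key] == pytest.approx(ref[key], rel=1e-9), key
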