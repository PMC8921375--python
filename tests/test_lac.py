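"""Low attenuation cluster extraction, splitting, classification, regions."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from hypothesis import given, settings, strategies as st

from bprm.core import EXPIRATORY, INSPIRATORY, PhaseError, RegionMask
from bprm.densitometry import PRM_EMPHYSEMA, PRM_FSAD, PRMMap, Thresholds
from bprm.lac import (
    assign_regions,
    classify_predominance,
    erosion_depth_map,
    extract_lacs,
    lac_table,
    records_from_table,
)


def chessboard_depth_oracle(mask: np.ndarray) -> np.ndarray:
    """Independent oracle: erosion depth under a 3^3 element equals the
    chessboard distance to the background minus one."""
    d = ndi.distance_transform_cdt(mask, metric="chessboard")
    return np.maximum(d - 1, 0).astype(np.int32)


class TestErosionDepth:
    def test_single_voxel_depth_zero(self):
        m = np.zeros((5, 5, 5), bool)
        m[2, 2, 2] = True
        assert erosion_depth_map(m)[2, 2, 2] == 0

    def test_cube_depth_profile(self):
        m = np.zeros((9, 9, 9), bool)
        m[2:7, 2:7, 2:7] = True  # 5^3 cube
        d = erosion_depth_map(m)
        assert d[4, 4, 4] == 2
        assert d[2, 4, 4] == 0

    def test_random_blob_matches_distance_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = np.zeros((14, 14, 14), bool)
            idx = rng.integers(3, 11, (50, 3))
            m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
            m = ndi.binary_dilation(m)
            assert np.array_equal(erosion_depth_map(m), chessboard_depth_oracle(m))


def _extract(mask, **kw):
    depth = erosion_depth_map(mask)
    kw.setdefault("parenchyma_count", 10_000)
    return extract_lacs(mask, depth, **kw)


class TestExtractLacs:
    def test_two_disjoint_cubes(self):
        m = np.zeros((20, 20, 20), bool)
        m[1:8, 1:8, 1:8] = True  # 7^3
        m[12:15, 12:15, 12:15] = True  # 3^3
        recs, labels = _extract(m)
        assert sorted(r.voxel_count for r in recs) == [27, 343]
        assert labels.max() == 2

    def test_dumbbell_splits_into_two(self):
        m = np.zeros((12, 30, 12), bool)
        m[1:10, 1:10, 1:10] = True  # 9^3 cube A
        m[1:10, 15:24, 1:10] = True  # 9^3 cube B
        m[5, 10:15, 5] = True  # 1-voxel bridge, 5 long
        recs, labels = _extract(m)
        assert len(recs) == 2
        # each cluster contains exactly one cube center
        la, lb = labels[5, 5, 5], labels[5, 19, 5]
        assert {la, lb} == {1, 2}
        assert sum(r.voxel_count for r in recs) == int(m.sum())

    def test_partition_is_exact(self):
        rng = np.random.default_rng(4)
        m = ndi.binary_dilation(rng.random((16, 16, 16)) > 0.8)
        recs, labels = _extract(m)
        assert int(m.sum()) == sum(r.voxel_count for r in recs)
        assert np.array_equal(labels > 0, m)

    def test_lad_sums_to_lav_fraction(self):
        rng = np.random.default_rng(8)
        m = ndi.binary_dilation(rng.random((16, 16, 16)) > 0.85)
        par = 5000
        recs, _ = _extract(m, parenchyma_count=par)
        assert sum(r.lad for r in recs) == pytest.approx(int(m.sum()) / par,
                                                         abs=1e-15)

    def test_infinite_core_depth_is_plain_components(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = ndi.binary_dilation(rng.random((14, 14, 14)) > 0.82)
            if not m.any():
                continue
            recs, labels = _extract(m, min_core_depth=np.inf)
            ncomp = ndi.label(m, structure=np.ones((3, 3, 3)))[1]
            assert len(recs) == ncomp
            # identical partition as plain labeling (up to label permutation)
            ref = ndi.label(m, structure=np.ones((3, 3, 3)))[0]
            pairs = {(int(a), int(b)) for a, b in
                     zip(labels[m].ravel(), ref[m].ravel())}
            assert len(pairs) == ncomp

    def test_idempotent_on_single_core_cluster(self):
        m = np.zeros((12, 12, 12), bool)
        m[2:9, 2:9, 2:9] = True
        recs, labels = _extract(m)
        assert len(recs) == 1
        recs2, _ = _extract(labels == 1)
        assert len(recs2) == 1
        assert recs2[0].voxel_count == recs[0].voxel_count

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partition_property_random_masks(self, seed):
        rng = np.random.default_rng(seed)
        m = ndi.binary_dilation(rng.random((12, 12, 12)) > 0.85)
        if not m.any():
            return
        recs, labels = _extract(m)
        assert sum(r.voxel_count for r in recs) == int(m.sum())
        ids = np.unique(labels[m])
        assert len(ids) == len(recs)


def _prm_from_classes(classes):
    return PRMMap(classes=classes, thresholds=Thresholds())


class TestClassifyPredominance:
    def _one_cluster(self, n_emph, n_fsad):
        shape = (1, 1, n_emph + n_fsad)
        labels = np.ones(shape, dtype=np.int32)
        classes = np.empty(shape, dtype=np.uint8)
        classes[0, 0, :n_emph] = PRM_EMPHYSEMA
        classes[0, 0, n_emph:] = PRM_FSAD
        from bprm.lac import LACRecord

        rec = LACRecord(id=1, phase=EXPIRATORY, threshold=-856,
                        voxel_count=n_emph + n_fsad,
                        lad=(n_emph + n_fsad) / 1000, max_erosion_depth=0,
                        centroid_mm=(0, 0, 0))
        return [rec], labels, _prm_from_classes(classes)

    def test_pure_emphysema_cluster(self):
        recs, labels, prm = self._one_cluster(10, 0)
        out = classify_predominance(recs, labels, prm)
        assert out[0].lac_class == "emph_predominant"
        assert out[0].fsad_voxels == 0

    def test_pure_fsad_cluster(self):
        recs, labels, prm = self._one_cluster(0, 10)
        out = classify_predominance(recs, labels, prm)
        assert out[0].lac_class == "fsad"
        assert out[0].fsad_voxels == 10

    def test_minority_emphysema_keeps_fsad_fraction(self):
        recs, labels, prm = self._one_cluster(4, 6)
        out = classify_predominance(recs, labels, prm, ratio_cut=0.5)
        assert out[0].lac_class == "fsad"
        assert out[0].fsad_voxels == 6

    def test_inspiratory_cluster_rejected(self):
        recs, labels, prm = self._one_cluster(1, 1)
        recs[0].phase = INSPIRATORY
        with pytest.raises(PhaseError):
            classify_predominance(recs, labels, prm)


class TestAssignRegions:
    def _regions(self, shape=(4, 4, 10)):
        side = np.full(shape, 1, np.uint8)  # all left
        group = np.full(shape, 2, np.uint8)  # lower by default
        airway = np.zeros(shape, bool)
        return side, group, airway

    def _run(self, label_slice, group_labels):
        side, group, airway = self._regions()
        group[..., :] = group_labels
        regions = RegionMask(side=side, group=group, airway=airway)
        labels = np.zeros((4, 4, 10), np.int32)
        labels[label_slice] = 1
        from bprm.lac import LACRecord

        rec = LACRecord(id=1, phase=INSPIRATORY, threshold=-950,
                        voxel_count=int((labels == 1).sum()),
                        lad=0.01, max_erosion_depth=0, centroid_mm=(0, 0, 0))
        return assign_regions([rec], labels, regions)[0]

    def test_fully_inside_one_region(self):
        rec = self._run(np.s_[0, 0, 0:4], 1)  # all upper
        assert (rec.side, rec.group) == ("left", "upper")

    def test_majority_wins(self):
        group = np.full(10, 2, np.uint8)
        group[:6] = 1  # 6 upper, 4 lower along x
        rec = self._run(np.s_[0, 0, 0:10], group)
        assert rec.group == "upper"

    def test_exact_tie_goes_lower(self):
        group = np.full(10, 2, np.uint8)
        group[:5] = 1  # 5 upper, 5 lower
        rec = self._run(np.s_[0, 0, 0:10], group)
        assert rec.group == "lower"


def test_lac_table_round_trip():
    m = np.zeros((10, 10, 10), bool)
    m[2:5, 2:5, 2:5] = True
    m[7:9, 7:9, 7:9] = True
    recs, labels = _extract(m)
    side = np.ones(m.shape, np.uint8)
    group = np.full(m.shape, 2, np.uint8)
    regions = RegionMask(side=side, group=group, airway=np.zeros(m.shape, bool))
    recs = assign_regions(recs, labels, regions)
    df = lac_table(recs)
    back = records_from_table(df)
    assert len(back) == len(recs)
    for a, b in zip(recs, back):
        assert (a.id, a.voxel_count, a.lad, a.side, a.group) == \
            (b.id, b.voxel_count, b.lad, b.side, b.group)
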