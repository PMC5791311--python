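"""Mask extraction, local thresholds, watershed instance separation."""

import math

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from gliamorph.config import SegmentationConfig
from gliamorph.io import ImageStack
from gliamorph.segmentation import (SomaRecord, SomaSet, enhance_local_contrast,
                                    filter_individual_cells, li_threshold,
                                    phansalkar_soma_detect,
                                    phansalkar_threshold, segment_field,
                                    simplify_mask, watershed_split)


def _stack(vox, spacing=(1.0, 1.0, 1.0)):
    return ImageStack(np.asarray(vox), spacing)


class TestEnhanceLocalContrast:
    def test_constant_image_unchanged(self):
        st = _stack(np.full((3, 64, 64), 700, dtype=np.uint16))
        out = enhance_local_contrast(st, block_radius_px=15)
        np.testing.assert_array_equal(out.voxels, st.voxels)

    def test_two_level_order_preserved(self):
        vox = np.full((1, 64, 64), 10, dtype=np.uint16)
        vox[0, 20:40, 20:40] = 200
        out = enhance_local_contrast(_stack(vox), block_radius_px=15)
        lo = out.voxels[0, 5, 5]
        hi = out.voxels[0, 30, 30]
        assert hi > lo

    def test_does_not_degrade_otsu_separability_on_dim_phantom(self):
        """Inter-class variance of the foreground/background split should
        not decrease after enhancement of a dim-process image."""
        rng = np.random.default_rng(0)
        vox = rng.normal(100, 5, size=(1, 96, 96))
        vox[0, 40:56, 10:86] += 25.0      # dim horizontal process
        vox = np.clip(vox, 0, 65535).astype(np.uint16)
        st = _stack(vox)
        out = enhance_local_contrast(st, block_radius_px=23)

        def icv(img):
            t = threshold_otsu(img)
            fg, bg = img[img > t], img[img <= t]
            w = fg.size / img.size
            return w * (1 - w) * (fg.mean() - bg.mean()) ** 2 / img.max() ** 2

        assert icv(out.voxels.astype(float)) >= icv(st.voxels.astype(float)) * 0.99

    def test_block_radius_larger_than_slice_errors(self):
        with pytest.raises(ValueError):
            enhance_local_contrast(_stack(np.zeros((1, 16, 16))), 16)


class TestLiThreshold:
    def test_two_point_histogram_separates_classes(self):
        vox = np.concatenate([np.zeros(1000), np.full(1000, 100.0)])
        t = li_threshold(_stack(vox.reshape(2, 10, 100)))
        assert 0 < t < 100

    def test_constant_image_errors(self):
        with pytest.raises(ValueError):
            li_threshold(_stack(np.full((2, 8, 8), 7.0)))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        vox = np.concatenate([rng.normal(30, 10, 50_000),
                              rng.normal(120, 10, 50_000)])
        vox = np.clip(np.rint(vox), 0, 255).reshape(10, 100, 100)
        t0 = li_threshold(_stack(vox))
        t50 = li_threshold(_stack(vox + 50.0))
        assert abs((t50 - t0) - 50.0) <= 1.0


class TestSimplifyMask:
    def test_opening_removes_isolated_voxel(self):
        m = np.zeros((5, 9, 9), dtype=bool)
        m[2, 4, 4] = True
        assert not simplify_mask(m, 1, 0).any()

    def test_idempotent_on_solid_cube(self):
        m = np.zeros((14, 14, 14), dtype=bool)
        m[2:12, 2:12, 2:12] = True
        once = simplify_mask(m, 1, 1)
        twice = simplify_mask(once, 1, 1)
        np.testing.assert_array_equal(once, twice)

    def test_closing_bridges_one_voxel_gap(self):
        from scipy import ndimage

        m = np.zeros((7, 13, 13), dtype=bool)
        m[1:6, 1:6, 3:8] = True
        m[1:6, 7:12, 3:8] = True      # 1-voxel gap along y
        closed = simplify_mask(m, 0, 1)
        _, n = ndimage.label(closed, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            simplify_mask(np.zeros((2, 2, 2), dtype=bool), -1, 0)


class TestPhansalkar:
    def test_constant_half_slice_matches_closed_form(self):
        t = phansalkar_threshold(np.full((64, 64), 0.5), radius_px=20)
        expected = 0.5 * (1 + 2 * math.exp(-5) - 0.25)
        assert np.all(np.abs(t - expected) < 1e-6)

    def test_all_zero_slice_yields_no_somata(self):
        st = _stack(np.zeros((3, 64, 64)))
        somata = phansalkar_soma_detect(st, SegmentationConfig())
        assert len(somata) == 0

    def test_radius_larger_than_slice_errors(self):
        with pytest.raises(ValueError):
            phansalkar_threshold(np.zeros((16, 16)), radius_px=16)


class TestWatershed:
    def _spheres(self, centers, r, shape=(24, 24, 40)):
        zz, yy, xx = np.meshgrid(*[np.arange(n) + 0.5 for n in shape],
                                 indexing="ij")
        masks = [np.sqrt((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2)
                 for c in centers]
        return masks, (zz, yy, xx)

    def test_disjoint_blobs_one_label_each(self):
        d, _ = self._spheres([(12, 12, 10), (12, 12, 30)], 5)
        mask = (d[0] <= 5) | (d[1] <= 5)
        soma = np.zeros(mask.shape, dtype=np.int32)
        soma[d[0] <= 2] = 1
        soma[d[1] <= 2] = 2
        ss = SomaSet(soma, [SomaRecord(1, np.array([12, 12, 10.]), 1, 1),
                            SomaRecord(2, np.array([12, 12, 30.]), 1, 1)],
                     (1, 1, 1))
        cm = watershed_split(mask, ss, (1, 1, 1))
        assert set(np.unique(cm.labels)) == {0, 1, 2}
        assert ((cm.labels == 1) == (d[0] <= 5)).all()

    def test_overlapping_spheres_split_at_nearer_center(self):
        d, _ = self._spheres([(12, 12, 14), (12, 12, 26)], 8)
        mask = (d[0] <= 8) | (d[1] <= 8)
        soma = np.zeros(mask.shape, dtype=np.int32)
        soma[d[0] <= 2] = 1
        soma[d[1] <= 2] = 2
        ss = SomaSet(soma, [SomaRecord(1, np.array([12, 12, 14.]), 1, 1),
                            SomaRecord(2, np.array([12, 12, 26.]), 1, 1)],
                     (1, 1, 1))
        cm = watershed_split(mask, ss, (1, 1, 1))
        off_mid = np.abs(d[0] - d[1]) > 1.0
        sel = mask & off_mid
        assert ((cm.labels[sel] == 1) == (d[0][sel] < d[1][sel])).mean() > 0.99

    def test_single_blob_single_marker_identity(self):
        d, _ = self._spheres([(12, 12, 20)], 6)
        mask = d[0] <= 6
        soma = np.zeros(mask.shape, dtype=np.int32)
        soma[d[0] <= 2] = 1
        ss = SomaSet(soma, [SomaRecord(1, np.array([12, 12, 20.]), 1, 1)],
                     (1, 1, 1))
        cm = watershed_split(mask, ss, (1, 1, 1))
        np.testing.assert_array_equal(cm.labels > 0, mask)

    def test_soma_outside_mask_rejected_with_warning(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        soma = np.zeros(mask.shape, dtype=np.int32)
        soma[6, 6, 6] = 1
        ss = SomaSet(soma, [SomaRecord(1, np.array([6.5, 6.5, 6.5]), 1, 1)],
                     (1, 1, 1))
        with pytest.warns(UserWarning):
            cm = watershed_split(mask, ss, (1, 1, 1))
        assert not cm.records


class TestFilterIndividualCells:
    def test_border_and_multisoma_rejection_reasons(self):
        from gliamorph.segmentation import CellLabelMap, CellRecord

        labels = np.zeros((6, 12, 12), dtype=np.int32)
        labels[2:4, 0:4, 2:6] = 1          # touches y border
        labels[2:4, 6:10, 6:10] = 2
        records = {1: CellRecord(1, 1, 16, 16.0, False),
                   2: CellRecord(2, 2, 16, 16.0, False)}
        cm = CellLabelMap(labels, records, (1, 1, 1))
        soma = np.zeros_like(labels)
        soma[2, 1, 3] = 1
        soma[2, 7, 7] = 2
        soma[3, 8, 8] = 3                  # second soma inside cell 2
        ss = SomaSet(soma, [SomaRecord(1, np.array([2.5, 1.5, 3.5]), 1, 1),
                            SomaRecord(2, np.array([2.5, 7.5, 7.5]), 1, 1),
                            SomaRecord(3, np.array([3.5, 8.5, 8.5]), 1, 1)],
                     (1, 1, 1))
        cm = filter_individual_cells(cm, ss, min_volume_um3=1, max_volume_um3=1e5)
        assert "border" in cm.records[1].reject_reason
        assert "multi-soma" in cm.records[2].reject_reason

    def test_noiseless_phantom_cell_accepted_and_recovered(
            self, noiseless_young_field, default_config):
        """End-to-end chain on a clean phantom: one soma, one accepted cell,
        Jaccard >= 0.99 against the ground-truth label map."""
        spec, stack, truth = noiseless_young_field
        mask, somata, cm = segment_field(stack, default_config.segmentation)
        assert len(somata) == 1
        acc = cm.accepted_ids()
        assert len(acc) == 1
        cell = cm.labels == acc[0]
        true = truth.label_volume == 1
        jacc = (cell & true).sum() / (cell | true).sum()
        assert jacc >= 0.99
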