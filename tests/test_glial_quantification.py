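"""Glial segmentation, morphometrics and per-region outcomes."""

import math

import numpy as np
import pytest
from scipy import stats
from skimage.draw import disk

from gliovasc.glial_quantification import (CellObject, derive_cohort_threshold,
                                           measure_all_cells, measure_cell,
                                           region_metrics, segment_positive,
                                           subject_candidate_mean)
from gliovasc.imaging_io import RoiSet
from gliovasc.stain_separation import separate_image
from gliovasc.synthetic_cohort import CellSpec, draw_cell_mask, render_slide


def _roi_set(shape, mask):
    return RoiSet(masks={"NAWM": mask}, grid="HISTOLOGY", pixel_size_um=1.0)


class TestCohortThreshold:
    def _map_with_mean(self, mean_od, shape=(40, 40)):
        """Half background (0 OD), half positive at ``mean_od``."""
        m = np.zeros(shape)
        m[:, 20:] = mean_od
        return m

    def test_cohort_mean_arithmetic(self):
        """Candidate means 0.4 and 0.6 with kappa 0.5 give threshold 0.25."""
        roi = np.ones((40, 40), bool)
        maps = {"A": self._map_with_mean(0.4), "B": self._map_with_mean(0.6)}
        rois = {k: _roi_set((40, 40), roi) for k in maps}
        thr = derive_cohort_threshold(maps, rois, "IBA1_DAB", kappa=0.5)
        assert thr.threshold_od == pytest.approx(0.5 * 0.5)
        assert dict(thr.per_subject_means) == pytest.approx({"A": 0.4, "B": 0.6})

    def test_identical_subjects(self):
        roi = np.ones((40, 40), bool)
        maps = {s: self._map_with_mean(0.5) for s in "ABC"}
        rois = {s: _roi_set((40, 40), roi) for s in "ABC"}
        thr = derive_cohort_threshold(maps, rois, "IBA1_DAB", kappa=0.5)
        assert thr.threshold_od == pytest.approx(0.25)

    def test_no_candidates_anywhere(self):
        roi = np.ones((10, 10), bool)
        maps = {"A": np.zeros((10, 10))}
        rois = {"A": _roi_set((10, 10), roi)}
        with pytest.raises(ValueError, match="no positive candidates"):
            derive_cohort_threshold(maps, rois, "IBA1_DAB")

    def test_candidate_mean_empty_roi_is_none(self):
        assert subject_candidate_mean(np.ones((5, 5)), np.zeros((5, 5), bool)) is None


class TestSegmentPositive:
    def test_subthreshold_map_no_objects(self):
        labels, mask = segment_positive(np.full((30, 30), 0.1),
                                        np.ones((30, 30), bool), 0.5)
        assert labels.max() == 0 and not mask.any()

    def test_rendered_cells_counted_exactly(self, rng):
        from gliovasc.synthetic_cohort import scatter_cells
        shape = (400, 400)
        roi = np.zeros(shape, bool)
        roi[20:380, 20:380] = True
        inner = np.zeros(shape, bool)
        inner[60:340, 60:340] = True

        def mk2(x, y):
            if rng.random() < 0.5:
                return CellSpec((x, y), "amoeboid", 3.5, 0, 0.0, 0.8)
            return CellSpec((x, y), "ramified", 3.5, 5, 10.0, 0.8,
                            orientation_rad=rng.uniform(0, 6.28))
        cells = scatter_cells(50, roi & inner, rng, mk2, 32.0)
        img = render_slide(cells, [], shape, "IBA1_DAB", 1.0, noise_sd=0.0)
        maps = separate_image(img)
        labels, _ = segment_positive(maps["dab"], roi, 0.4)
        assert labels.max() == 50

    def test_roi_edge_clipping(self):
        dab = np.zeros((40, 40))
        dab[18:24, 10:30] = 1.0  # bar straddling the ROI boundary at row 20
        roi = np.zeros((40, 40), bool)
        roi[:20] = True
        _, mask = segment_positive(dab, roi, 0.5)
        assert mask.sum() == 2 * 20  # only the in-ROI half of the bar

    def test_min_area_boundary_kept_at_limit(self):
        dab = np.zeros((30, 30))
        dab[5:10, 5:9] = 1.0  # 20 px object, exactly at the default limit
        dab[20:22, 20:22] = 1.0  # 4 px, below limit
        labels, _ = segment_positive(dab, np.ones((30, 30), bool), 0.5,
                                     min_object_area_um2=20.0)
        assert labels.max() == 1

    def test_soma_holes_filled_large_enclosures_kept_open(self):
        dab = np.zeros((60, 60))
        rr, cc = disk((15, 15), 6)
        dab[rr, cc] = 1.0
        dab[15, 15] = 0.0  # 1-px hole in a soma: filled
        dab[35:55, 35:55] = 1.0
        dab[38:52, 38:52] = 0.0  # 196-px enclosure: stays open
        _, mask = segment_positive(dab, np.ones((60, 60), bool), 0.5)
        assert mask[15, 15]
        assert not mask[45, 45]

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            segment_positive(np.zeros((5, 5)), np.ones((6, 6), bool), 0.5)


class TestMeasureCell:
    @pytest.mark.parametrize("radius", [10, 20, 30])
    def test_disk_circularity_near_one(self, radius):
        shape = (2 * radius + 10,) * 2
        mask = np.zeros(shape, bool)
        rr, cc = disk((radius + 5, radius + 5), radius)
        mask[rr, cc] = True
        cell = measure_cell(mask, np.ones(shape), 1.0)
        assert 0.95 <= cell.circularity <= 1.0

    def test_bar_skeleton_length(self):
        mask = np.zeros((20, 80), bool)
        mask[9:12, 10:70] = True  # 3 px wide, 60 px long
        cell = measure_cell(mask, np.ones((20, 80)), 1.0)
        assert cell.skeleton_length_um == pytest.approx(60.0, rel=0.10)

    def test_single_pixel_degenerate(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        cell = measure_cell(mask, np.full((5, 5), 0.7), 1.0)
        assert cell.circularity == 1.0
        assert cell.skeleton_length_um == 0.0
        assert cell.mean_od == pytest.approx(0.7)

    def test_empty_object_rejected(self):
        with pytest.raises(ValueError):
            measure_cell(np.zeros((5, 5), bool), np.zeros((5, 5)), 1.0)

    def test_physical_units_scale(self):
        mask = np.zeros((30, 30), bool)
        rr, cc = disk((15, 15), 8)
        mask[rr, cc] = True
        at1 = measure_cell(mask, np.ones((30, 30)), 1.0)
        at2 = measure_cell(mask, np.ones((30, 30)), 2.0)
        assert at2.area_um2 == pytest.approx(4 * at1.area_um2)
        assert at2.skeleton_length_um == pytest.approx(2 * at1.skeleton_length_um)
        assert at2.circularity == pytest.approx(at1.circularity)


class TestMorphometricDiscrimination:
    def _measure_phenotype(self, cells, shape=(160, 160)):
        out = []
        for c in cells:
            canvas = draw_cell_mask(c, shape, 1.0) > 0
            out.append(measure_cell(canvas, np.ones(shape), 1.0))
        return out

    def test_amoeboid_circularity_exceeds_ramified(self, rng):
        """Activated (amoeboid) morphology reads as higher circularity."""
        amoeboid = [CellSpec((80.0, 80.0), "amoeboid", r, 0, 0.0, 0.5)
                    for r in (3.0, 4.0, 5.0)]
        ramified = [CellSpec((80.0, 80.0), "ramified", 3.5, 5, blen, 0.5,
                             orientation_rad=rng.uniform(0, 6.28))
                    for blen in (10.0, 15.0, 20.0)]
        circ_a = np.mean([c.circularity for c in self._measure_phenotype(amoeboid)])
        circ_r = np.mean([c.circularity for c in self._measure_phenotype(ramified)])
        assert circ_a > circ_r

    def test_skeleton_length_monotone_in_branch_length(self, rng):
        lengths = [8.0, 12.0, 16.0, 20.0, 24.0]
        measured = []
        for blen in lengths:
            cells = [CellSpec((80.0, 80.0), "ramified", 3.5, 5, blen, 0.5,
                              orientation_rad=rng.uniform(0, 6.28))
                     for _ in range(10)]
            ms = self._measure_phenotype(cells)
            measured.append(np.mean([c.skeleton_length_um for c in ms]))
        rho = stats.spearmanr(lengths, measured).statistic
        assert rho > 0.95


class TestRegionMetrics:
    def _one_mm2_roi(self):
        # 1000 x 1000 px at 1 um/px = 1 mm^2
        return np.ones((1000, 1000), bool)

    def test_frequency_arithmetic(self):
        roi = self._one_mm2_roi()
        cells = [CellObject(i, (10.0 * i, 10.0), 30.0, 20.0, 0.9, 5.0, 0.5)
                 for i in range(10)]
        m = region_metrics(cells, np.zeros_like(roi), np.zeros(roi.shape),
                           roi, "IBA1_DAB", "S0", "NAWM", 1.0)
        assert m.frequency_per_mm2 == pytest.approx(10.0)

    def test_fully_positive_roi_area_100(self):
        roi = np.ones((50, 50), bool)
        m = region_metrics([], roi, np.full((50, 50), 1.0), roi, "IBA1_DAB",
                           "S0", "NAWM", 1.0)
        assert m.area_pct == pytest.approx(100.0)
        assert m.intensity_pct == pytest.approx(50.0)  # OD 1.0 of od_max 2.0

    def test_gfap_suppresses_per_cell_outcomes(self):
        roi = np.ones((50, 50), bool)
        cells = [CellObject(1, (5.0, 5.0), 30.0, 20.0, 0.9, 5.0, 0.5)]
        m = region_metrics(cells, np.zeros_like(roi), np.zeros(roi.shape),
                           roi, "GFAP_DAB", "S0", "WMH", 1.0)
        assert math.isnan(m.frequency_per_mm2)
        assert math.isnan(m.avg_length_um)
        assert math.isnan(m.avg_circularity)
        assert m.n_objects == 1

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError):
            region_metrics([], np.zeros((5, 5), bool), np.zeros((5, 5)),
                           np.zeros((5, 5), bool), "IBA1_DAB", "S0", "NAWM", 1.0)

    def test_area_conservation_objects_vs_mask(self, rng):
        """area_pct from labelled objects equals area_pct from the mask."""
        dab = np.zeros((200, 200))
        for _ in range(12):
            rr, cc = disk((rng.integers(20, 180), rng.integers(20, 180)), 5,
                          shape=(200, 200))
            dab[rr, cc] = 1.0
        roi = np.ones((200, 200), bool)
        labels, mask = segment_positive(dab, roi, 0.5)
        cells = measure_all_cells(labels, dab, 1.0)
        from_objects = 100.0 * sum(c.area_um2 for c in cells) / roi.sum()
        m = region_metrics(cells, mask, dab, roi, "IBA1_DAB", "S0", "NAWM", 1.0)
        assert m.area_pct == pytest.approx(from_objects)
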