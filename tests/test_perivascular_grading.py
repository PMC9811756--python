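"""Vessel detection, perivascular zones and the 0-3 astrogliosis grades."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gliovasc.perivascular_grading import (Vessel, close_range_flag,
                                           count_perivascular_astroglia,
                                           detect_scar, detect_vessels,
                                           grade_vessel, perivascular_zone,
                                           summarize_region, vessels_from_outlines)
from gliovasc.stain_separation import separate_image
from gliovasc.synthetic_cohort import VesselSpec, render_slide


def oracle_grade(density, count, scar):
    """Independent piecewise restatement of the printed grading rule."""
    if scar:
        return 3
    if count == 0:
        return 0
    if density > 300:
        return 3
    if density >= 100:
        return 2
    return 1


def circular_vessel(radius_px, shape=(200, 200), center=None):
    center = center or (shape[1] // 2, shape[0] // 2)
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    lumen = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 <= radius_px ** 2
    return Vessel(label=1, lumen_mask=lumen, boundary=np.zeros((0, 2)),
                  centroid_xy=(float(center[0]), float(center[1])),
                  equivalent_diameter_um=2.0 * radius_px)


class TestGradeRule:
    @pytest.mark.parametrize("density,scar,expected", [
        (50.0, False, 1),    # mild: below 100/mm^2
        (350.0, False, 3),   # severe: above 300/mm^2
        (0.0, False, 0),     # none
        (150.0, True, 3),    # scar forces severe
        (100.0, False, 2),   # boundary: 100 is moderate
        (300.0, False, 2),   # boundary: 300 is moderate
    ])
    def test_printed_examples(self, density, scar, expected):
        count = 0 if density == 0 else max(1, int(density // 50))
        assert grade_vessel(density, count, scar) == expected

    def test_exhaustive_against_piecewise_oracle(self):
        for density in range(0, 501):
            for scar in (False, True):
                count = 0 if density == 0 else max(1, round(density / 100))
                assert grade_vessel(float(density), count, scar) == \
                    oracle_grade(float(density), count, scar)

    def test_grade0_requires_literally_no_astroglia(self):
        # one cell in a huge annulus: density ~ 0 but grade is mild, not none
        assert grade_vessel(0.5, 1, False) == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            grade_vessel(-1.0, 0, False)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(0, 1000), st.integers(0, 50))
    def test_adding_a_cell_never_lowers_the_grade(self, area_scale, count):
        area = 0.005 * (1 + area_scale / 1000)
        g1 = grade_vessel(count / area, count, False)
        g2 = grade_vessel((count + 1) / area, count + 1, False)
        assert g2 >= g1


class TestPerivascularZone:
    def test_annulus_area_closed_form(self):
        """Annulus area matches pi((r+15)^2 - r^2) within discretisation."""
        for r in (20, 40, 60):
            vessel = circular_vessel(r, shape=(2 * r + 80,) * 2)
            _, area_mm2 = perivascular_zone(vessel, 1.0, 15.0)
            expected = math.pi * ((r + 15) ** 2 - r ** 2) * 1e-6
            assert area_mm2 == pytest.approx(expected, rel=0.05)

    def test_vanishing_distance_empty_annulus(self):
        vessel = circular_vessel(20)
        annulus, area = perivascular_zone(vessel, 1.0, 0.5)
        assert area == 0.0 and not annulus.any()

    def test_abutting_vessels_exclude_each_other(self):
        a = circular_vessel(15, center=(80, 100))
        b = circular_vessel(15, center=(112, 100))
        annulus, _ = perivascular_zone(a, 1.0, 15.0,
                                       other_lumens=b.lumen_mask)
        assert not (annulus & b.lumen_mask).any()

    def test_zero_distance_rejected(self):
        with pytest.raises(ValueError):
            perivascular_zone(circular_vessel(10), 1.0, 0.0)


class TestCounting:
    def test_density_arithmetic(self):
        vessel = circular_vessel(90, shape=(260, 260), center=(130, 130))
        annulus, area = perivascular_zone(vessel, 1.0, 15.0)
        # place 10 centroids inside the annulus along the +x axis band
        cells = [(130 + 95.0, 130.0 + i) for i in range(-5, 5)]
        count, density = count_perivascular_astroglia(cells, annulus, area)
        assert count == 10
        assert density == pytest.approx(10 / area)

    def test_no_cells(self):
        vessel = circular_vessel(20)
        annulus, area = perivascular_zone(vessel, 1.0, 15.0)
        assert count_perivascular_astroglia([], annulus, area) == (0, 0.0)

    def test_outer_boundary_counted(self):
        """A soma at exactly 15 um from the lumen is inside the zone."""
        vessel = circular_vessel(30, shape=(140, 140), center=(70, 70))
        annulus, area = perivascular_zone(vessel, 1.0, 15.0)
        count, _ = count_perivascular_astroglia([(70 + 45.0, 70.0)], annulus, area)
        assert count == 1

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            count_perivascular_astroglia([], np.zeros((5, 5), bool), 0.0)


class TestScarAndCloseRange:
    def _gfap_ring(self, vessel, inner, outer, frac_angle=1.0):
        ys, xs = np.mgrid[0:vessel.lumen_mask.shape[0],
                          0:vessel.lumen_mask.shape[1]]
        cx, cy = vessel.centroid_xy
        r = np.sqrt((xs - cx) ** 2 + (ys - cy) ** 2)
        ring = (r > inner) & (r <= outer)
        if frac_angle < 1.0:
            ang = np.arctan2(ys - cy, xs - cx)
            ring &= ang <= (-math.pi + 2 * math.pi * frac_angle)
        return ring

    def test_full_ring_is_scar(self):
        v = circular_vessel(25)
        ring = self._gfap_ring(v, 25, 38)
        assert detect_scar(ring, v, 1.0)

    def test_sparse_cells_not_scar(self):
        v = circular_vessel(25)
        sparse = np.zeros_like(v.lumen_mask)
        sparse[100, 130:133] = True  # ~10% coverage at best
        assert not detect_scar(sparse, v, 1.0)

    def test_half_ring_below_default_coverage(self):
        v = circular_vessel(25)
        ring = self._gfap_ring(v, 25, 38, frac_angle=0.5)
        assert not detect_scar(ring, v, 1.0)

    @pytest.mark.parametrize("offset_um,expected", [
        (3.0, True), (12.0, False), (5.0, True),
    ])
    def test_close_range_distance_rule(self, offset_um, expected):
        v = circular_vessel(30, shape=(140, 140), center=(70, 70))
        cell = [(70 + 30.0 + offset_um, 70.0)]
        assert close_range_flag(cell, v, 1.0, 5.0) is expected


class TestSummaries:
    def test_grade_mix_percentages(self):
        from gliovasc.perivascular_grading import VesselAssessment
        mk = lambda g: VesselAssessment(0, 0.01, g, 100.0 * g, g, False, False)
        s = summarize_region([mk(1), mk(2), mk(2), mk(3)], "S0", "WMH")
        assert s.pct_mild == 25 and s.pct_moderate == 50 and s.pct_severe == 25
        assert s.pct_with_inflammation == 100

    def test_all_grade_zero(self):
        from gliovasc.perivascular_grading import VesselAssessment
        mk = lambda: VesselAssessment(0, 0.01, 0, 0.0, 0, False, False)
        s = summarize_region([mk(), mk()], "S0", "NAWM")
        assert s.pct_with_inflammation == 0 == s.pct_mild == s.pct_severe

    def test_single_severe_close_range_vessel(self):
        from gliovasc.perivascular_grading import VesselAssessment
        a = VesselAssessment(0, 0.01, 5, 500.0, 3, True, False)
        s = summarize_region([a], "S0", "WMH")
        assert (s.pct_with_inflammation, s.pct_mild, s.pct_moderate,
                s.pct_severe, s.pct_close_range) == (100, 0, 0, 100, 100)

    def test_percentages_sum_to_100(self):
        from gliovasc.perivascular_grading import VesselAssessment
        rng = np.random.default_rng(0)
        mk = lambda g: VesselAssessment(0, 0.01, g, 120.0 * g, g, False, False)
        grades = rng.integers(0, 4, 17)
        s = summarize_region([mk(int(g)) for g in grades], "S0", "WMH")
        pct0 = 100.0 - s.pct_with_inflammation
        assert pct0 + s.pct_mild + s.pct_moderate + s.pct_severe == \
            pytest.approx(100.0, abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_region([], "S0", "NAWM")


class TestDetectVessels:
    def test_rendered_lumens_detected(self):
        shape = (400, 400)
        vessels = [VesselSpec((c, c), (30.0, 22.0), orientation_rad=0.4)
                   for c in (80.0, 200.0, 320.0)]
        vessels += [VesselSpec((320.0, 90.0), (25.0, 25.0)),
                    VesselSpec((90.0, 320.0), (35.0, 20.0))]
        img = render_slide([], vessels, shape, "HE", 1.0, noise_sd=0.0)
        maps = separate_image(img)
        found = detect_vessels(maps["hematoxylin"], np.ones(shape, bool), 1.0)
        assert len(found) == 5

    def test_uniform_tissue_no_vessels(self):
        img = render_slide([], [], (150, 150), "HE", 1.0, noise_sd=0.0)
        maps = separate_image(img)
        assert detect_vessels(maps["hematoxylin"], np.ones((150, 150), bool),
                              1.0) == []

    def test_small_lumen_excluded(self):
        img = render_slide([], [VesselSpec((75.0, 75.0), (4.0, 4.0))],
                           (150, 150), "HE", 1.0, noise_sd=0.0)
        maps = separate_image(img)
        found = detect_vessels(maps["hematoxylin"], np.ones((150, 150), bool),
                               1.0, min_lumen_area_um2=80.0)
        assert found == []

    def test_manual_outline_input(self):
        poly = [(30, 30), (60, 30), (60, 60), (30, 60)]
        vessels = vessels_from_outlines([poly], (100, 100), 1.0)
        assert len(vessels) == 1
        assert vessels[0].lumen_mask.sum() > 800
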