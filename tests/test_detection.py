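"""Tissue detection, cell counting/segmentation and contextual features."""

import math

import numpy as np
import pytest
from shapely.geometry import Polygon

from histoquant.detection import (CELL_FEATURE_CATALOG, DetectionParams,
                                  add_smoothed_features, detect_cells,
                                  detect_tissue, fast_cell_counts,
                                  local_density)
from histoquant.objects import PathObject, ROI
from histoquant.stains import od_to_rgb
from histoquant.synthetic import CoreSpec, gen_core

PSZ = 0.5


def _disc_image(hdab, diameter_um=400.0, od=0.2, psz=PSZ):
    n = int(diameter_um / psz * 1.2)
    yy, xx = np.mgrid[0:n, 0:n]
    r = diameter_um / 2 / psz
    conc = np.zeros((n, n, 2))
    conc[(xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= r**2, 0] = od
    return od_to_rgb(conc, hdab, 0.0)


class TestDetectTissue:
    def test_blank_image_zero_area(self, hdab):
        white = np.full((200, 200, 3), 254, np.uint8)
        _, area = detect_tissue(white, PSZ)
        assert area == 0.0

    def test_full_disc_area(self, hdab):
        img = _disc_image(hdab)
        _, area = detect_tissue(img, PSZ)
        expected = math.pi / 4 * 0.4**2  # mm²
        assert abs(area - expected) / expected < 0.05

    def test_punched_hole_excluded(self, hdab):
        img = _disc_image(hdab, od=0.2)
        n = img.shape[0]
        hole_r_px = math.sqrt(0.1e6 / math.pi) / PSZ  # 0.1 mm² hole
        yy, xx = np.mgrid[0:n, 0:n]
        hole = (xx - n / 2) ** 2 + (yy - n / 2) ** 2 <= hole_r_px**2
        img[hole] = 254
        _, area_holed = detect_tissue(img, PSZ, min_hole_um2=1000.0)
        _, area_full = detect_tissue(_disc_image(hdab), PSZ)
        assert abs((area_full - area_holed) - 0.1) < 0.02


class TestFastCellCounts:
    def test_blank_core(self, hdab, params):
        blank = np.full((200, 200, 3), 254, np.uint8)
        _, counts = fast_cell_counts(blank, hdab, params, PSZ)
        assert counts["total"] == 0

    def test_count_recovery_on_synthetic_core(self, hdab, params, ihc_core):
        image, truth, spec = ihc_core
        dets, counts = fast_cell_counts(image, hdab, params, spec.pixel_size_um)
        n_true_pos = int((truth["class"] == "positive").sum())
        assert abs(counts["total"] - len(truth)) <= 5
        assert abs(counts["positive"] - n_true_pos) <= 3
        assert counts["positive"] + counts["negative"] == counts["total"]

    def test_hematoxylin_plus_dab_channel(self, hdab, params, ihc_core):
        image, truth, spec = ihc_core
        _, counts = fast_cell_counts(image, hdab, params, spec.pixel_size_um,
                                     detection_channel="hematoxylin_plus_dab")
        assert abs(counts["total"] - len(truth)) <= 5

    def test_positive_threshold_monotonicity(self, hdab, ihc_core):
        image, _, spec = ihc_core
        base = DetectionParams()
        doubled = DetectionParams(positive_dab_threshold_od=2 * base.positive_dab_threshold_od)
        _, c1 = fast_cell_counts(image, hdab, base, spec.pixel_size_um)
        _, c2 = fast_cell_counts(image, hdab, doubled, spec.pixel_size_um)
        assert c2["positive"] <= c1["positive"]

    def test_missing_stain_rejected(self, params):
        from histoquant.stains import he_profile
        blank = np.full((50, 50, 3), 254, np.uint8)
        with pytest.raises(ValueError, match="hematoxylin and DAB"):
            fast_cell_counts(blank, he_profile(), params, PSZ)


class TestDetectCells:
    def test_isolated_nucleus_geometry(self, hdab, params):
        conc = np.zeros((100, 100, 2))
        yy, xx = np.mgrid[0:100, 0:100]
        conc[(xx - 50) ** 2 + (yy - 50) ** 2 <= (3 / PSZ) ** 2, 0] = 0.8
        cells = detect_cells(od_to_rgb(conc, hdab, 0.0), hdab, params, PSZ)
        assert len(cells) == 1
        c = cells[0]
        # 3 µm nucleus + 5 µm expansion -> ~8 µm cell radius
        assert abs(c.measurements["Cell: Area µm^2"] - math.pi * 64) / (math.pi * 64) < 0.10
        assert abs(c.measurements["Nucleus/Cell area ratio"] - 9 / 64) < 0.02

    def test_adjacent_cells_are_disjoint(self, hdab, params):
        conc = np.zeros((120, 120, 2))
        yy, xx = np.mgrid[0:120, 0:120]
        for cx in (54, 66):  # 6 µm apart, expansion 5 µm
            conc[(xx - cx) ** 2 + (yy - 60) ** 2 <= (2.5 / PSZ) ** 2, 0] = 0.8
        cells = detect_cells(od_to_rgb(conc, hdab, 0.0), hdab, params, PSZ)
        assert len(cells) == 2
        p0, p1 = (Polygon(c.roi.vertices) for c in cells)
        assert p0.intersection(p1).area == 0.0
        # boundary near the perpendicular bisector (x = 60 px)
        for c in cells:
            nucleus = Polygon(c.nucleus_roi.vertices)
            assert Polygon(c.roi.vertices).buffer(1.5).contains(nucleus)

    def test_catalog_complete_and_finite(self, hdab, params, ihc_core):
        image, truth, spec = ihc_core
        cells = detect_cells(image, hdab, params, spec.pixel_size_um)
        assert abs(len(cells) - len(truth)) <= 5
        for c in cells:
            assert set(c.measurements) == set(CELL_FEATURE_CATALOG)
            assert all(np.isfinite(v) for v in c.measurements.values())
            assert 0 < c.measurements["Nucleus: Circularity"] <= 1

    def test_raising_threshold_weakly_decreases_count(self, hdab, ihc_core):
        image, _, spec = ihc_core
        lo = detect_cells(image, hdab, DetectionParams(nucleus_threshold_od=0.1),
                          spec.pixel_size_um)
        hi = detect_cells(image, hdab, DetectionParams(nucleus_threshold_od=0.3),
                          spec.pixel_size_um)
        assert len(hi) <= len(lo)


def _obj_at(x, y, value=None):
    o = PathObject("detection", ROI("point", center=(x, y), pixel_size_um=1.0))
    if value is not None:
        o.set_measurement("m", value)
    return o


class TestLocalDensity:
    def test_single_cell_zero(self):
        cells = [_obj_at(0, 0)]
        local_density(cells)
        assert cells[0].measurements["Density: counts/mm^2"] == 0.0

    def test_ten_cells_in_one_disc(self):
        rng = np.random.default_rng(1)
        cells = [_obj_at(*rng.uniform(0, 5, 2)) for _ in range(10)]
        local_density(cells, radius_um=25.0)
        expected = 9 / (math.pi * 0.025**2)
        for c in cells:
            assert c.measurements["Density: counts/mm^2"] == pytest.approx(expected)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 300, size=(400, 2))
        cells = [_obj_at(x, y) for x, y in pts]
        local_density(cells, radius_um=25.0)
        d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
        counts = (d2 <= 25.0**2).sum(axis=1) - 1
        expected = counts / (math.pi * 0.025**2)
        got = np.array([c.measurements["Density: counts/mm^2"] for c in cells])
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestSmoothedFeatures:
    def test_isolated_object_identity(self):
        objs = [_obj_at(0, 0, 7.5)]
        add_smoothed_features(objs, ["m"], sigma_um=25.0)
        assert objs[0].measurements["m (smoothed 25)"] == 7.5

    def test_two_objects_closed_form(self):
        objs = [_obj_at(0, 0, 0.0), _obj_at(25, 0, 1.0)]
        add_smoothed_features(objs, ["m"], sigma_um=25.0)
        w = math.exp(-0.5)
        assert objs[0].measurements["m (smoothed 25)"] == pytest.approx(w / (1 + w))
        assert objs[1].measurements["m (smoothed 25)"] == pytest.approx(1 / (1 + w))

    def test_matches_bruteforce_allpairs(self):
        rng = np.random.default_rng(9)
        pts = rng.uniform(0, 400, size=(300, 2))
        vals = rng.normal(size=300)
        objs = [_obj_at(x, y, v) for (x, y), v in zip(pts, vals)]
        add_smoothed_features(objs, ["m"], sigma_um=25.0)
        d2 = np.sum((pts[:, None] - pts[None]) ** 2, axis=-1)
        w = np.exp(-d2 / (2 * 25.0**2)) * (d2 <= (3 * 25.0) ** 2)
        expected = (w @ vals) / w.sum(axis=1)
        got = np.array([o.measurements["m (smoothed 25)"] for o in objs])
        np.testing.assert_allclose(got, expected, atol=1e-10)
        # convex-combination bounds
        assert got.min() >= vals.min() - 1e-12 and got.max() <= vals.max() + 1e-12

    def test_unnormalized_mode_is_weighted_sum(self):
        objs = [_obj_at(0, 0, 1.0), _obj_at(25, 0, 1.0)]
        add_smoothed_features(objs, ["m"], sigma_um=25.0, normalized=False)
        assert objs[0].measurements["m (smoothed 25)"] == pytest.approx(1 + math.exp(-0.5))

    def test_missing_feature_names_object(self):
        objs = [_obj_at(0, 0, 1.0), _obj_at(5, 5)]
        objs[1].id = 42
        with pytest.raises(ValueError, match="42.*'m'"):
            add_smoothed_features(objs, ["m"], sigma_um=25.0)


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(gaussian_sigma_um=-1.0)
    with pytest.raises(ValueError):
        DetectionParams(min_nucleus_area_um2=500.0, max_nucleus_area_um2=400.0)
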