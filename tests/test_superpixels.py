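"""SLIC partition properties, hue statistics and Haralick texture oracle."""

import math

import numpy as np
import pytest
from skimage import measure

from histoquant.objects import PathObject, ROI
from histoquant.superpixels import (GLCMSpec, HARALICK_NAMES, glcm,
                                    haralick_features, mean_hue, slic_segment)


def _rect_annotation(w, h, psz=1.0):
    return ROI("rectangle", center=((w - 1) / 2, (h - 1) / 2),
               radii=((w - 1) / 2, (h - 1) / 2), pixel_size_um=psz)


def _patch_sp(shape):
    sp = PathObject("detection", ROI("rectangle", center=(0, 0), radii=(1, 1)))
    sp.metadata["pixels"] = tuple(np.mgrid[0:shape[0], 0:shape[1]].reshape(2, -1))
    return sp


class TestSLIC:
    def test_uniform_grid_counts_and_areas(self):
        img = np.full((220, 220, 3), 200, np.uint8)
        ann = ROI("rectangle", center=(109.5, 109.5), radii=(100, 100), pixel_size_um=1.0)
        sps, labels = slic_segment(img, ann, 1.0, spacing_um=50.0)
        assert len(sps) == 16
        mean_area = (labels > 0).sum() / len(sps)
        for sp in sps:
            area = len(sp.metadata["pixels"][0])
            assert abs(area - mean_area) / mean_area < 0.20

    @pytest.mark.parametrize("seed", [0, 1])
    def test_partition_and_4_connectivity(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(100, 220, size=(150, 150, 3), dtype=np.uint8)
        ann = _rect_annotation(150, 130)
        sps, labels = slic_segment(img, ann, 1.0, spacing_um=30.0)
        support = labels > 0
        # exact tiling: sum of superpixel sizes equals the annotation support
        assert sum(len(s.metadata["pixels"][0]) for s in sps) == int(support.sum())
        for sp in sps:
            rows, cols = sp.metadata["pixels"]
            assert np.all(labels[rows, cols] == sp.metadata["label"])
            comp = measure.label(labels == sp.metadata["label"], connectivity=1)
            assert comp.max() == 1

    def test_sharp_edge_respected(self):
        img = np.zeros((100, 200, 3), np.uint8)
        img[:, :100] = (200, 60, 60)
        img[:, 100:] = (60, 60, 200)
        sps, labels = slic_segment(img, _rect_annotation(200, 100), 1.0, spacing_um=25.0)
        for sp in sps:
            _, cols = sp.metadata["pixels"]
            if (cols < 100).any() and (cols >= 100).any():
                depth = min(100 - cols.min(), cols.max() - 99)
                assert depth <= 2

    def test_tiny_annotation_single_superpixel(self):
        img = np.full((60, 60, 3), 180, np.uint8)
        ann = ROI("rectangle", center=(30, 30), radii=(10, 10), pixel_size_um=1.0)
        with pytest.warns(UserWarning, match="single"):
            sps, _ = slic_segment(img, ann, 1.0, spacing_um=50.0)
        assert len(sps) == 1


class TestMeanHue:
    def _solid(self, rgb):
        img = np.tile(np.asarray(rgb, np.uint8), (4, 4, 1))
        return _patch_sp((4, 4)), img

    def test_primary_colors(self):
        assert mean_hue(*self._solid((255, 0, 0))) == pytest.approx(0.0)
        assert mean_hue(*self._solid((0, 255, 255))) == pytest.approx(180.0)

    def test_circular_mean_wraps(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[:2] = (255, 0, 0)      # 0°
        img[2:] = (255, 0, 255)    # 300°
        assert mean_hue(_patch_sp((4, 4)), img) == pytest.approx(330.0)

    def test_gray_flagged(self):
        sp, img = self._solid((128, 128, 128))
        assert mean_hue(sp, img) == 0.0
        assert sp.metadata.get("hue_undefined") is True


def _bruteforce_haralick(patch, spec):
    """Independent pair-enumeration implementation of the 13 features."""
    lo, hi = spec.od_range
    n = spec.n_levels
    q = np.clip(np.floor((patch - lo) / (hi - lo) * n), 0, n - 1).astype(int)
    h, w = q.shape
    per_direction = []
    for dr, dc in spec.directions:
        counts = {}
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    for pair in ((q[r, c], q[r2, c2]), (q[r2, c2], q[r, c])):
                        counts[pair] = counts.get(pair, 0) + 1
        total = sum(counts.values())
        p = {k: v / total for k, v in counts.items()}
        px = [sum(v for (i, _), v in p.items() if i == a) for a in range(n)]
        py = [sum(v for (_, j), v in p.items() if j == b) for b in range(n)]
        mu_x = sum(a * px[a] for a in range(n))
        mu_y = sum(b * py[b] for b in range(n))
        sd_x = math.sqrt(sum((a - mu_x) ** 2 * px[a] for a in range(n)))
        sd_y = math.sqrt(sum((b - mu_y) ** 2 * py[b] for b in range(n)))
        asm = sum(v * v for v in p.values())
        contrast = sum((i - j) ** 2 * v for (i, j), v in p.items())
        if sd_x > 0 and sd_y > 0:
            corr = (sum(i * j * v for (i, j), v in p.items()) - mu_x * mu_y) / (sd_x * sd_y)
        else:
            corr = 0.0
        mu = sum(i * v for (i, _), v in p.items())
        ssq = sum((i - mu) ** 2 * v for (i, _), v in p.items())
        idm = sum(v / (1 + (i - j) ** 2) for (i, j), v in p.items())
        psum = {}
        pdiff = {}
        for (i, j), v in p.items():
            psum[i + j] = psum.get(i + j, 0) + v
            pdiff[abs(i - j)] = pdiff.get(abs(i - j), 0) + v
        s_avg = sum(k * v for k, v in psum.items())
        s_var = sum((k - s_avg) ** 2 * v for k, v in psum.items())
        s_ent = -sum(v * math.log(v) for v in psum.values() if v > 0)
        ent = -sum(v * math.log(v) for v in p.values() if v > 0)
        d_mean = sum(k * v for k, v in pdiff.items())
        d_var = sum((k - d_mean) ** 2 * v for k, v in pdiff.items())
        d_ent = -sum(v * math.log(v) for v in pdiff.values() if v > 0)
        hx = -sum(v * math.log(v) for v in px if v > 0)
        hy = -sum(v * math.log(v) for v in py if v > 0)
        hxy1 = -sum(v * math.log(px[i] * py[j]) for (i, j), v in p.items()
                    if px[i] * py[j] > 0)
        hxy2 = -sum(px[i] * py[j] * math.log(px[i] * py[j])
                    for i in range(n) for j in range(n) if px[i] * py[j] > 0)
        imc1 = (ent - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
        imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - ent))))
        per_direction.append([asm, contrast, corr, ssq, idm, s_avg, s_var,
                              s_ent, ent, d_var, d_ent, imc1, imc2])
    return np.mean(per_direction, axis=0)


class TestHaralick:
    def test_constant_patch(self):
        sp = _patch_sp((8, 8))
        f = haralick_features(sp, np.full((8, 8), 0.7))
        assert f["Haralick: Angular second moment"] == 1.0
        assert f["Haralick: Contrast"] == 0.0
        assert f["Haralick: Entropy"] == 0.0
        assert f["Haralick: Correlation"] == 0.0  # undefined -> flagged 0

    def test_checkerboard_contrast_closed_form(self):
        # two adjacent quantization levels: horizontal/vertical pairs all
        # differ by 1 level (contrast 1), diagonal pairs are equal
        # (contrast 0); the direction average is 0.5
        spec = GLCMSpec()
        step = (spec.od_range[1] / spec.n_levels) * 1.0001
        board = (np.indices((8, 8)).sum(axis=0) % 2) * step
        f = haralick_features(_patch_sp((8, 8)), board, spec)
        assert f["Haralick: Contrast"] == pytest.approx(0.5)
        assert f["Haralick: Inverse difference moment"] == pytest.approx(0.75)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        patch = rng.uniform(0.0, 2.5, size=(8, 8))
        spec = GLCMSpec()
        got = haralick_features(_patch_sp((8, 8)), patch, spec)
        expected = _bruteforce_haralick(patch, spec)
        np.testing.assert_allclose([got[n] for n in HARALICK_NAMES], expected, atol=1e-10)

    def test_constant_shift_below_quantization_invariant(self):
        rng = np.random.default_rng(3)
        spec = GLCMSpec()
        # bin centers, then shift by a quarter bin: same quantization
        width = spec.od_range[1] / spec.n_levels
        patch = (rng.integers(0, spec.n_levels, (8, 8))) * width + width / 2
        f1 = haralick_features(_patch_sp((8, 8)), patch, spec)
        f2 = haralick_features(_patch_sp((8, 8)), patch + width / 4, spec)
        for name in HARALICK_NAMES:
            assert f1[name] == pytest.approx(f2[name], abs=1e-12)

    def test_glcm_normalized_sums_to_one(self):
        rng = np.random.default_rng(1)
        q = rng.integers(0, 32, (10, 10))
        member = np.ones((10, 10), bool)
        p = glcm(q, member, GLCMSpec(), (0, 1))
        assert p.sum() == pytest.approx(1.0)

    def test_too_small_superpixel_rejected(self):
        sp = PathObject("detection", ROI("point", center=(0, 0)))
        sp.metadata["pixels"] = (np.array([0]), np.array([0]))
        with pytest.raises(ValueError, match="too small"):
            haralick_features(sp, np.zeros((4, 4)))
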