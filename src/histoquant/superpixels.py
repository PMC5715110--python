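"""SLIC superpixels and per-superpixel color/texture features.

Whole-section compartment classification (epithelium vs stroma vs other)
works on compact superpixels rather than raw pixels: each annotated
region is tiled by SLIC (localized k-means in CIELab + position space),
and every superpixel is summarized by its saturation-weighted mean hue
plus the 13 classical Haralick co-occurrence statistics computed on the
mean optical-density plane.

The gray-level co-occurrence matrix (GLCM) is accumulated only over pixel
pairs that both lie inside the superpixel, at distance 1 in the four
standard directions, symmetrized and normalized, and the 13 features are
averaged across directions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage import color, measure, segmentation

from .objects import ROI, PathObject
from .stains import rgb_to_od

__all__ = [
    "GLCMSpec",
    "HARALICK_NAMES",
    "slic_segment",
    "mean_hue",
    "haralick_features",
    "compute_superpixel_features",
    "glcm",
]

HARALICK_NAMES: tuple[str, ...] = (
    "Haralick: Angular second moment",
    "Haralick: Contrast",
    "Haralick: Correlation",
    "Haralick: Sum of squares",
    "Haralick: Inverse difference moment",
    "Haralick: Sum average",
    "Haralick: Sum variance",
    "Haralick: Sum entropy",
    "Haralick: Entropy",
    "Haralick: Difference variance",
    "Haralick: Difference entropy",
    "Haralick: Information measure of correlation 1",
    "Haralick: Information measure of correlation 2",
)

# row/col offsets for 0, 45, 90, 135 degrees (distance multiplies these)
_DIRECTIONS = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class GLCMSpec:
    """Quantization and accumulation parameters for the OD co-occurrence
    matrix.  32 levels over OD [0, 2.5] keep features comparable across
    images regardless of per-image dynamic range."""

    n_levels: int = 32
    od_range: tuple[float, float] = (0.0, 2.5)
    distance_px: int = 1
    directions: tuple[tuple[int, int], ...] = _DIRECTIONS
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.od_range[1] <= self.od_range[0]:
            raise ValueError("od_range must be increasing")

    def quantize(self, plane: np.ndarray) -> np.ndarray:
        lo, hi = self.od_range
        q = np.floor((np.asarray(plane, dtype=float) - lo) / (hi - lo) * self.n_levels)
        return np.clip(q, 0, self.n_levels - 1).astype(np.int32)


# ---------------------------------------------------------------------------
# segmentation


def _enforce_4_connectivity(labels: np.ndarray) -> np.ndarray:
    """Split 4-disconnected label components and merge orphans into their
    largest 4-adjacent neighbor; guarantees each final label is a single
    4-connected region and the labeled support is unchanged."""
    out = measure.label(labels, connectivity=1, background=0)
    if out.max() == 0:
        return out
    changed = True
    while changed:
        changed = False
        props = sorted(measure.regionprops(out), key=lambda p: p.area)
        areas = {p.label: p.area for p in props}
        # only merge components that are fragments of an original label
        # sharing support with a bigger sibling, or tiny orphans
        for p in props[:-1]:
            rows, cols = np.nonzero(out == p.label)
            neigh: dict[int, int] = {}
            for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                rr, cc = rows + dr, cols + dc
                ok = (rr >= 0) & (rr < out.shape[0]) & (cc >= 0) & (cc < out.shape[1])
                for lab in np.unique(out[rr[ok], cc[ok]]):
                    if lab not in (0, p.label):
                        neigh[lab] = neigh.get(lab, 0) + 1
            if not neigh:
                continue
            # merge only fragments below half the median area
            med = np.median(list(areas.values()))
            if p.area < 0.25 * med:
                target = max(neigh, key=lambda l: (neigh[l], areas.get(l, 0)))
                out[out == p.label] = target
                changed = True
                break
    # relabel compactly
    return measure.label(out, connectivity=1, background=0)


def slic_segment(
    region_image: np.ndarray,
    annotation: ROI,
    pixel_size_um: float,
    spacing_um: float = 50.0,
    compactness: float = 10.0,
    n_iter: int = 10,
) -> tuple[list[PathObject], np.ndarray]:
    """Tile the annotated part of ``region_image`` with SLIC superpixels.

    Returns superpixel detection objects (raster order by first pixel)
    and the label map (0 outside the annotation).  Superpixels exactly
    partition the annotation mask and each is 4-connected.
    """
    h, w = region_image.shape[:2]
    rr, cc = np.mgrid[0:h, 0:w]
    mask = np.zeros((h, w), dtype=bool)
    # rasterize the annotation by centroid-in-ROI per pixel center
    if annotation.kind == "rectangle":
        cx, cy = annotation.center
        rx, ry = annotation.radii
        mask = (np.abs(cc - cx) <= rx) & (np.abs(rr - cy) <= ry)
    elif annotation.kind == "ellipse":
        cx, cy = annotation.center
        rx, ry = annotation.radii
        mask = ((cc - cx) / rx) ** 2 + ((rr - cy) / ry) ** 2 <= 1.0
    else:
        from matplotlib.path import Path

        mask = (
            Path(annotation.vertices)
            .contains_points(np.c_[cc.ravel(), rr.ravel()])
            .reshape(h, w)
        )
    n_px = int(mask.sum())
    if n_px == 0:
        raise ValueError("annotation covers no pixels")
    s_px = spacing_um / pixel_size_um
    n_segments = max(1, int(round(n_px / s_px**2)))
    if n_segments == 1:
        warnings.warn("annotation smaller than one superpixel; returning a single segment")
        labels = mask.astype(np.int32)
    else:
        labels = segmentation.slic(
            region_image,
            n_segments=n_segments,
            compactness=compactness,
            max_num_iter=n_iter,
            mask=mask,
            start_label=1,
            enforce_connectivity=True,
        ).astype(np.int32)
        labels[~mask] = 0
    labels = _enforce_4_connectivity(labels)

    sps: list[PathObject] = []
    for p in measure.regionprops(labels):
        r0, c0, r1, c1 = p.bbox
        from .detection import _region_polygon

        poly = _region_polygon(labels[r0:r1, c0:c1] == p.label, offset=(r0, c0))
        sp = PathObject(
            "detection",
            ROI("polygon", vertices=poly, pixel_size_um=pixel_size_um),
        )
        sp.metadata["label"] = int(p.label)
        sp.metadata["pixels"] = tuple(np.nonzero(labels == p.label))
        sp.set_measurement("Area µm^2", float(p.area) * pixel_size_um**2)
        sps.append(sp)
    return sps, labels


# ---------------------------------------------------------------------------
# features


def mean_hue(sp: PathObject, image: np.ndarray) -> float:
    """Saturation-weighted circular mean hue of the superpixel, in degrees.

    A naive arithmetic mean of angles fails at the 0/360 wrap-around, so
    hue is averaged on the unit circle with saturation weights (gray
    pixels carry no hue information).  An all-gray superpixel has no
    defined hue; it reports 0 and sets ``hue_undefined`` in metadata.
    """
    rows, cols = sp.metadata["pixels"]
    if len(rows) == 0:
        raise ValueError("empty superpixel")
    rgb = image[rows, cols].reshape(-1, 1, 3)
    hsv = color.rgb2hsv(rgb).reshape(-1, 3)
    ang = hsv[:, 0] * 2.0 * math.pi
    sat = hsv[:, 1]
    sx, sy = float(np.sum(sat * np.cos(ang))), float(np.sum(sat * np.sin(ang)))
    if math.hypot(sx, sy) < 1e-12:
        sp.metadata["hue_undefined"] = True
        return 0.0
    deg = math.degrees(math.atan2(sy, sx)) % 360.0
    return deg


def glcm(quantized: np.ndarray, member: np.ndarray, spec: GLCMSpec,
         direction: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix for one direction over
    pixel pairs both inside ``member``."""
    n = spec.n_levels
    dr, dc = direction[0] * spec.distance_px, direction[1] * spec.distance_px
    h, w = quantized.shape
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    a = quantized[r0:r1, c0:c1]
    b = quantized[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = member[r0:r1, c0:c1] & member[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    p = np.zeros((n, n), dtype=float)
    np.add.at(p, (a[ok], b[ok]), 1.0)
    if spec.symmetric:
        p = p + p.T
    if spec.normalized and p.sum() > 0:
        p = p / p.sum()
    return p


def _haralick_from_glcm(p: np.ndarray) -> np.ndarray:
    """The 13 classical co-occurrence statistics of one normalized GLCM."""
    n = p.shape[0]
    i = np.arange(n, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(i @ px)
    mu_y = float(i @ py)
    sd_x = math.sqrt(float(((i - mu_x) ** 2) @ px))
    sd_y = math.sqrt(float(((i - mu_y) ** 2) @ py))

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    asm = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if sd_x > 0 and sd_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sd_x * sd_y))
    else:
        correlation = 0.0  # constant patch: undefined, reported as 0
    mu = float((ii * p).sum())
    sum_squares = float(((ii - mu) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())

    # p_{x+y}(k), k = 0..2n-2 and p_{x-y}(k), k = 0..n-1
    pxy_sum = np.zeros(2 * n - 1)
    np.add.at(pxy_sum, (ii + jj).astype(int), p)
    pxy_diff = np.zeros(n)
    np.add.at(pxy_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2 * n - 1, dtype=float)
    k_diff = np.arange(n, dtype=float)
    sum_average = float(k_sum @ pxy_sum)
    sum_variance = float(((k_sum - sum_average) ** 2) @ pxy_sum)
    sum_entropy = ent(pxy_sum)
    entropy = ent(p.ravel())
    diff_mean = float(k_diff @ pxy_diff)
    diff_variance = float(((k_diff - diff_mean) ** 2) @ pxy_diff)
    diff_entropy = ent(pxy_diff)

    hx, hy = ent(px), ent(py)
    with np.errstate(divide="ignore"):
        lpq = np.where(px[:, None] * py[None, :] > 0,
                       np.log(np.clip(px[:, None] * py[None, :], 1e-300, None)), 0.0)
    hxy1 = float(-(p * lpq).sum())
    hxy2 = ent((px[:, None] * py[None, :]).ravel())
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    arg = 1.0 - math.exp(-2.0 * (hxy2 - entropy))
    imc2 = math.sqrt(max(arg, 0.0))
    return np.array([asm, contrast, correlation, sum_squares, idm, sum_average,
                     sum_variance, sum_entropy, entropy, diff_variance,
                     diff_entropy, imc1, imc2])


def haralick_features(sp: PathObject, od_plane: np.ndarray,
                      spec: GLCMSpec | None = None) -> dict[str, float]:
    """Direction-averaged Haralick features of the superpixel's OD texture.

    Features are computed per direction from the within-superpixel GLCM
    and averaged; directions whose GLCM is empty (too-thin shapes) are
    skipped.  Values are also stored on the superpixel's measurements.
    """
    spec = spec or GLCMSpec()
    rows, cols = sp.metadata["pixels"]
    if len(rows) < 4:
        raise ValueError("superpixel too small for texture (need >= 4 px)")
    member = np.zeros(od_plane.shape, dtype=bool)
    member[rows, cols] = True
    q = spec.quantize(od_plane)
    feats = []
    for direction in spec.directions:
        p = glcm(q, member, spec, direction)
        if p.sum() == 0:
            continue
        feats.append(_haralick_from_glcm(p))
    if not feats:
        raise ValueError("no valid pixel pairs in any direction")
    avg = np.mean(feats, axis=0)
    out = dict(zip(HARALICK_NAMES, (float(v) for v in avg)))
    for k, v in out.items():
        sp.set_measurement(k, v)
    return out


def compute_superpixel_features(
    superpixels: list[PathObject],
    image: np.ndarray,
    background=(255.0, 255.0, 255.0),
    spec: GLCMSpec | None = None,
) -> list[str]:
    """Attach hue + Haralick features to every superpixel; returns the
    feature-name list (for training/applying classifiers)."""
    od = rgb_to_od(image, background).mean(axis=2)
    for sp in superpixels:
        sp.set_measurement("Hue mean", mean_hue(sp, image))
        haralick_features(sp, od, spec)
    return ["Hue mean", *HARALICK_NAMES]
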