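"""Ground-truth synthetic histology generators.

Every pipeline stage is validated against images synthesized from known
truth: TMA slide overviews (jittered grids of ~1 mm circular tissue
cores), single IHC cores populated with elliptical nuclei whose
hematoxylin/DAB absorbances follow the Beer–Lambert forward model plus
Gaussian read noise, H&E-like sections with epithelium-dense and
stroma-fibrous compartments at a controlled tumor stromal percentage, and
right-censored survival tables.  Each generator emits machine-readable
truth (cell tables, grid positions, compartment masks, exact scores)
alongside the image, and is byte-deterministic under a fixed seed.

These images are deliberately idealized: nuclei never overlap, stain
vectors are exact, illumination is flat and noise is i.i.d. Gaussian.
They exercise the algorithms' contracts, not the full difficulty of real
tissue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as draw_ellipse

from .stains import StainProfile, hdab_profile, he_profile, od_to_rgb
from .survival import SurvivalRecord

__all__ = [
    "CellClass",
    "CoreSpec",
    "TMASpec",
    "HESectionSpec",
    "gen_core",
    "gen_tma_slide",
    "gen_he_section",
    "gen_survival",
]


@dataclass(frozen=True)
class CellClass:
    """One synthetic cell population.

    Nucleus radii are Gaussian (µm, clipped at 1 µm), ``elongation`` is
    the major/minor axis ratio, and hematoxylin/DAB nuclear absorbances
    are Gaussian (clipped at 0).
    """

    name: str
    fraction: float
    radius_um: tuple[float, float] = (3.0, 0.4)
    elongation: float = 1.0
    hematoxylin: tuple[float, float] = (0.7, 0.08)
    dab: tuple[float, float] = (0.03, 0.02)


#: default IHC population: 70% DAB-negative, 30% strongly DAB-positive
DEFAULT_CLASSES = (
    CellClass("negative", 0.7, dab=(0.05, 0.02)),
    CellClass("positive", 0.3, dab=(0.8, 0.1)),
)


@dataclass(frozen=True)
class CoreSpec:
    """A single circular tissue core with a stated cell population."""

    seed: int = 0
    pixel_size_um: float = 0.25
    diameter_um: float = 1000.0
    n_cells: int = 100
    classes: tuple[CellClass, ...] = DEFAULT_CLASSES
    diffuse_hematoxylin: float = 0.05  # faint cytoplasmic haze over the core
    min_center_distance_um: float = 10.0
    noise_sd: float = 3.0
    profile: StainProfile = field(default_factory=hdab_profile)

    def __post_init__(self) -> None:
        if abs(sum(c.fraction for c in self.classes) - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")
        if self.diameter_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("dimensions must be positive")


def _draw_soft_ellipse(plane: np.ndarray, cx: float, cy: float, rx: float,
                       ry: float, theta: float, value: float) -> None:
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=plane.shape, rotation=theta)
    plane[rr, cc] += value


def gen_core(spec: CoreSpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one IHC core; returns (RGB8 image, truth cell table).

    Cells are non-overlapping ellipses placed by rejection sampling inside
    the core disc (capped at 10^4 attempts per cell); per-cell class,
    center, radius and DAB level are recorded in the truth table with
    coordinates in pixels and micrometre sizes.
    """
    rng = np.random.default_rng(spec.seed)
    psz = spec.pixel_size_um
    r_core = spec.diameter_um / 2.0 / psz
    margin = 8.0 / psz
    size = int(math.ceil(2 * r_core + 2 * margin))
    center = size / 2.0

    # class assignment with exact counts (largest remainder)
    counts = [int(math.floor(c.fraction * spec.n_cells)) for c in spec.classes]
    rem = spec.n_cells - sum(counts)
    order = np.argsort([-(c.fraction * spec.n_cells) % 1.0 for c in spec.classes])
    for i in range(rem):
        counts[order[i % len(counts)]] += 1
    labels = [c for c, n in zip(spec.classes, counts) for _ in range(n)]
    rng.shuffle(labels)

    placed: list[tuple[float, float]] = []
    rows = []
    min_d = spec.min_center_distance_um / psz
    for cls in labels:
        radius = max(1.0, rng.normal(*cls.radius_um))
        for attempt in range(10_000):
            rho = r_core * 0.92 * math.sqrt(rng.uniform())
            phi = rng.uniform(0.0, 2.0 * math.pi)
            x = center + rho * math.cos(phi)
            y = center + rho * math.sin(phi)
            if all((x - px) ** 2 + (y - py) ** 2 >= min_d**2 for px, py in placed):
                break
        else:
            raise ValueError(
                "could not place all cells without overlap; lower n_cells or density"
            )
        placed.append((x, y))
        rows.append(
            {
                "x_px": x, "y_px": y, "class": cls.name,
                "radius_um": radius, "elongation": cls.elongation,
                "theta": rng.uniform(0.0, math.pi),
                "hematoxylin": max(0.0, rng.normal(*cls.hematoxylin)),
                "dab": max(0.0, rng.normal(*cls.dab)),
            }
        )
    truth = pd.DataFrame(rows)

    h_plane = np.zeros((size, size))
    d_plane = np.zeros((size, size))
    yy, xx = np.mgrid[0:size, 0:size]
    disc = (xx - center) ** 2 + (yy - center) ** 2 <= r_core**2
    h_plane[disc] += spec.diffuse_hematoxylin
    for r in rows:
        r_maj = r["radius_um"] * math.sqrt(r["elongation"]) / psz
        r_min = r["radius_um"] / math.sqrt(r["elongation"]) / psz
        _draw_soft_ellipse(h_plane, r["x_px"], r["y_px"], r_maj, r_min,
                           r["theta"], r["hematoxylin"])
        _draw_soft_ellipse(d_plane, r["x_px"], r["y_px"], r_maj, r_min,
                           r["theta"], r["dab"])
    conc = np.dstack([h_plane, d_plane])
    image = od_to_rgb(conc, spec.profile, noise_sd=spec.noise_sd, rng=rng)
    return image, truth


@dataclass(frozen=True)
class TMASpec:
    """A jittered rectangular grid of tissue cores on a slide overview."""

    seed: int = 0
    pixel_size_um: float = 16.0
    n_rows: int = 3
    n_cols: int = 4
    spacing_um: float = 1500.0
    diameter_um: float = 1000.0
    jitter_frac: float = 0.05  # of spacing, per axis, uniform
    missing: tuple[tuple[int, int], ...] = ()  # explicit absent cells
    missing_fraction: float = 0.0  # or a random fraction
    core_od: float = 0.35
    noise_sd: float = 2.0
    profile: StainProfile = field(default_factory=hdab_profile)

    def __post_init__(self) -> None:
        if self.spacing_um * (1 - 2 * self.jitter_frac) < self.diameter_um:
            raise ValueError("cores would overlap at the requested spacing/jitter")


def gen_tma_slide(spec: TMASpec) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a TMA slide overview; returns (RGB8 image, truth grid table).

    Each present core is a uniform absorbing disc (hematoxylin-toned) at
    its jittered grid position; absent cells are recorded in the truth
    with ``missing=True``.
    """
    rng = np.random.default_rng(spec.seed)
    psz = spec.pixel_size_um
    sp = spec.spacing_um / psz
    r = spec.diameter_um / 2.0 / psz
    h = int(math.ceil(sp * spec.n_rows + sp))
    w = int(math.ceil(sp * spec.n_cols + sp))

    missing = set(spec.missing)
    if spec.missing_fraction > 0:
        n_miss = int(round(spec.missing_fraction * spec.n_rows * spec.n_cols))
        all_cells = [(i, j) for i in range(spec.n_rows) for j in range(spec.n_cols)]
        idx = rng.choice(len(all_cells), size=n_miss, replace=False)
        missing |= {all_cells[i] for i in idx}

    h_plane = np.zeros((h, w))
    d_plane = np.zeros((h, w))
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            cx = sp * (j + 1) + rng.uniform(-1, 1) * spec.jitter_frac * sp
            cy = sp * (i + 1) + rng.uniform(-1, 1) * spec.jitter_frac * sp
            absent = (i, j) in missing
            rows.append({"row": i, "col": j, "center_x": cx, "center_y": cy,
                         "radius_px": r, "missing": absent})
            if not absent:
                disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
                h_plane[disc] += spec.core_od
    conc = np.dstack([h_plane, d_plane])
    image = od_to_rgb(conc, spec.profile, noise_sd=spec.noise_sd, rng=rng)
    return image, pd.DataFrame(rows)


@dataclass(frozen=True)
class HESectionSpec:
    """An H&E-like section with epithelium/stroma/other compartments at a
    target tumor stromal percentage."""

    seed: int = 0
    pixel_size_um: float = 2.0
    size_px: int = 512
    target_tsp: float = 50.0
    other_fraction: float = 0.1  # whitespace / non-tissue share of the image
    blob_scale_um: float = 150.0  # compartment granularity
    epithelium_nucleus_density_per_mm2: float = 4000.0
    stroma_fiber_density_per_mm2: float = 500.0
    noise_sd: float = 2.0
    profile: StainProfile = field(default_factory=he_profile)

    def __post_init__(self) -> None:
        if not 0.0 <= self.target_tsp <= 100.0:
            raise ValueError("target_tsp must lie in [0, 100]")


def gen_he_section(spec: HESectionSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Render an H&E section; returns (RGB8 image, compartment mask, true TSP).

    The mask codes 0 = other (whitespace), 1 = epithelium, 2 = stroma.
    Compartments are carved from thresholded smooth Gaussian random
    fields, so the realized stroma share among tissue matches the target
    TSP up to quantile discreteness (well within 2 percentage points).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size_px
    psz = spec.pixel_size_um
    sigma = spec.blob_scale_um / psz / 2.0

    field_tissue = gaussian_filter(rng.normal(size=(n, n)), sigma)
    field_split = gaussian_filter(rng.normal(size=(n, n)), sigma)
    other = field_tissue < np.quantile(field_tissue, spec.other_fraction)
    tissue = ~other
    # stroma share among tissue pixels = target TSP
    split_vals = field_split[tissue]
    thr = np.quantile(split_vals, 1.0 - spec.target_tsp / 100.0)
    stroma = tissue & (field_split > thr)
    epithelium = tissue & ~stroma

    mask = np.zeros((n, n), dtype=np.uint8)
    mask[epithelium] = 1
    mask[stroma] = 2
    a_e, a_s = int(epithelium.sum()), int(stroma.sum())
    true_tsp = 100.0 * a_s / (a_e + a_s) if (a_e + a_s) else float("nan")

    h_plane = np.zeros((n, n))
    e_plane = np.zeros((n, n))
    # epithelium: eosinophilic cytoplasm + densely packed round nuclei
    e_plane[epithelium] += 0.18
    h_plane[epithelium] += 0.10
    area_mm2 = a_e * psz**2 / 1e6
    n_nuc = rng.poisson(spec.epithelium_nucleus_density_per_mm2 * area_mm2)
    er, ec = np.nonzero(epithelium)
    if len(er) and n_nuc:
        pick = rng.integers(0, len(er), size=n_nuc)
        for k in pick:
            rad = max(1.0, rng.normal(3.0, 0.5)) / psz
            _draw_soft_ellipse(h_plane, ec[k], er[k], rad, rad, 0.0,
                               max(0.0, rng.normal(0.65, 0.1)))
    # stroma: pale eosin ground + sparse elongated fibers, few nuclei
    e_plane[stroma] += 0.12
    area_mm2 = a_s * psz**2 / 1e6
    n_fib = rng.poisson(spec.stroma_fiber_density_per_mm2 * area_mm2)
    sr, sc = np.nonzero(stroma)
    if len(sr) and n_fib:
        pick = rng.integers(0, len(sr), size=n_fib)
        for k in pick:
            _draw_soft_ellipse(e_plane, sc[k], sr[k], rng.uniform(8, 20) / psz,
                               rng.uniform(1.0, 2.0) / psz,
                               rng.uniform(0, math.pi),
                               max(0.0, rng.normal(0.35, 0.08)))
    # confine rendered stain to its compartment (nuclei near borders)
    h_plane[other] = 0.0
    e_plane[other] = 0.0
    conc = np.dstack([h_plane, e_plane])
    image = od_to_rgb(conc, spec.profile, noise_sd=spec.noise_sd, rng=rng)
    return image, mask, true_tsp


def gen_survival(
    n_patients: int,
    hazard_by_group: dict[str, float],
    censor_rate: float = 0.0,
    seed: int = 0,
    max_time: float = 120.0,
) -> list[SurvivalRecord]:
    """Exponential event times per group with independent exponential
    censoring; administrative censoring at ``max_time`` months.

    Patients are split evenly across groups (remainder to the first
    groups); true group labels ride on the records.
    """
    if any(h <= 0 for h in hazard_by_group.values()):
        raise ValueError("hazards must be positive")
    rng = np.random.default_rng(seed)
    groups = list(hazard_by_group)
    records = []
    base, extra = divmod(n_patients, len(groups))
    pid = 0
    for gi, g in enumerate(groups):
        n_g = base + (1 if gi < extra else 0)
        t_event = rng.exponential(1.0 / hazard_by_group[g], size=n_g)
        if censor_rate > 0:
            t_cens = rng.exponential(1.0 / censor_rate, size=n_g)
        else:
            t_cens = np.full(n_g, np.inf)
        t_cens = np.minimum(t_cens, max_time)
        for te, tc in zip(t_event, t_cens):
            t = min(te, tc)
            records.append(
                SurvivalRecord(f"P{pid:04d}", max(t, 1e-6), event=bool(te <= tc), group=g)
            )
            pid += 1
    return records
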