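"""TMA dearraying: locate circular tissue cores on a low-resolution slide
overview and fit a labeled rectangular grid.

Pipeline: Otsu threshold on inverted luminance -> morphological opening ->
connected-component size filter -> 1-D gap clustering of centroids into
rows and columns -> grid snap.  Detected cores snap to their nearest grid
cell; empty cells are materialized as cores flagged ``missing`` at the
interpolated position so the grid stays rectangular for export.

Labels follow the visible TMA convention: rows A..Z top to bottom,
columns 1..N left to right, joined as ``"A-1"``.
"""

from __future__ import annotations

import csv
import math
import string
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage import filters, measure, morphology

from .objects import ROI, PathObject

__all__ = ["TMAGrid", "dearray", "refine_grid", "import_core_metadata"]


@dataclass
class TMAGrid:
    """Rows x cols arrangement of tma_core objects."""

    n_rows: int
    n_cols: int
    cores: list[PathObject] = field(default_factory=list)  # raster order

    def __post_init__(self) -> None:
        if self.cores and len(self.cores) != self.n_rows * self.n_cols:
            raise ValueError("core count must equal n_rows * n_cols")
        labels = [c.metadata["core_label"] for c in self.cores]
        if len(set(labels)) != len(labels):
            raise ValueError("core labels must be unique")

    def core(self, label: str) -> PathObject:
        for c in self.cores:
            if c.metadata["core_label"] == label:
                return c
        raise KeyError(f"unknown core label {label!r}")

    @property
    def labels(self) -> list[str]:
        return [c.metadata["core_label"] for c in self.cores]

    def valid_cores(self) -> list[PathObject]:
        return [c for c in self.cores if not c.metadata.get("missing", False)]

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["core_label", "row", "col", "center_x", "center_y",
                 "radius_px", "missing", "patient_id"]
            )
            for i, c in enumerate(self.cores):
                r, k = divmod(i, self.n_cols)
                cx, cy = c.roi.center
                w.writerow(
                    [c.metadata["core_label"], r, k, f"{cx:.2f}", f"{cy:.2f}",
                     f"{c.roi.radii[0]:.2f}", int(bool(c.metadata.get("missing", False))),
                     c.metadata.get("patient_id", "")]
                )


def _core_label(row: int, col: int) -> str:
    return f"{string.ascii_uppercase[row]}-{col + 1}"


def _cluster_1d(values: np.ndarray, gap: float) -> list[float]:
    """Sort ``values`` and split into clusters wherever the gap to the
    running cluster mean exceeds ``gap``; returns cluster means."""
    order = np.sort(values)
    groups: list[list[float]] = [[order[0]]]
    for v in order[1:]:
        if v - np.mean(groups[-1]) > gap:
            groups.append([v])
        else:
            groups[-1].append(v)
    return [float(np.mean(g)) for g in groups]


def dearray(
    slide: np.ndarray,
    core_diameter_um: float,
    pixel_size_um: float,
    n_rows: Optional[int] = None,
    n_cols: Optional[int] = None,
    gap_factor: float = 0.6,
) -> TMAGrid:
    """Detect tissue cores on an RGB overview image and fit a labeled grid.

    The overview should be downsampled so the nominal core diameter spans
    roughly 20–100 px.  ``n_rows``/``n_cols`` are optional hints checked
    against the fitted grid (a mismatch warns, detection wins).
    """
    if core_diameter_um <= 0 or pixel_size_um <= 0:
        raise ValueError("core_diameter_um and pixel_size_um must be positive")
    slide = np.asarray(slide)
    if slide.ndim == 3:
        lum = slide[..., :3].astype(float).mean(axis=2)
    else:
        lum = slide.astype(float)
    d_px = core_diameter_um / pixel_size_um
    inverted = lum.max() - lum
    thresh = filters.threshold_otsu(inverted)
    mask = inverted > thresh
    mask = morphology.opening(mask, morphology.disk(max(1, int(round(d_px / 8)))))

    nominal_area = math.pi * (d_px / 2.0) ** 2
    labeled = measure.label(mask)
    comps = [
        r for r in measure.regionprops(labeled)
        if 0.2 * nominal_area <= r.area <= 2.0 * nominal_area
    ]
    if not comps:
        raise ValueError("no cores detected")

    centers = np.array([(r.centroid[1], r.centroid[0]) for r in comps])  # (x, y)
    radii = np.array([math.sqrt(r.area / math.pi) for r in comps])

    # core spacing estimate: median nearest-neighbor distance
    if len(centers) > 1:
        d2 = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
        np.fill_diagonal(d2, np.inf)
        spacing = float(np.median(d2.min(axis=1)))
    else:
        spacing = d_px
    gap = gap_factor * spacing

    row_pos = _cluster_1d(centers[:, 1], gap)
    col_pos = _cluster_1d(centers[:, 0], gap)
    # stability check: row clustering should be robust to +-10% gap changes
    if (len(_cluster_1d(centers[:, 1], 0.9 * gap)) != len(row_pos)
            or len(_cluster_1d(centers[:, 1], 1.1 * gap)) != len(row_pos)):
        warnings.warn("ambiguous row clustering; proceeding with best-effort grid")
    if n_rows is not None and n_rows != len(row_pos):
        warnings.warn(f"expected {n_rows} rows, detected {len(row_pos)}")
    if n_cols is not None and n_cols != len(col_pos):
        warnings.warn(f"expected {n_cols} cols, detected {len(col_pos)}")
    nr, nc = len(row_pos), len(col_pos)

    # snap each detected core to its nearest (row, col) cell
    assigned: dict[tuple[int, int], tuple[np.ndarray, float]] = {}
    for c, rad in zip(centers, radii):
        ri = int(np.argmin([abs(c[1] - y) for y in row_pos]))
        ci = int(np.argmin([abs(c[0] - x) for x in col_pos]))
        if (ri, ci) in assigned:  # keep the larger component
            if rad <= assigned[(ri, ci)][1]:
                continue
        assigned[(ri, ci)] = (c, rad)

    default_radius = float(np.median(radii))
    cores = []
    for ri in range(nr):
        for ci in range(nc):
            if (ri, ci) in assigned:
                (cx, cy), rad = assigned[(ri, ci)]
                missing = False
            else:
                cx, cy, rad = col_pos[ci], row_pos[ri], default_radius
                missing = True
            roi = ROI("ellipse", center=(float(cx), float(cy)),
                      radii=(float(rad), float(rad)), pixel_size_um=pixel_size_um)
            cores.append(
                PathObject(
                    "tma_core", roi,
                    metadata={"core_label": _core_label(ri, ci), "missing": missing},
                )
            )
    return TMAGrid(nr, nc, cores)


def refine_grid(grid: TMAGrid, edits: Sequence[dict]) -> TMAGrid:
    """Apply manual edits in order; each edit names a core label and one of
    ``new_center=(x, y)``, ``set_missing=True`` or ``set_valid=True``."""
    known = set(grid.labels)
    for e in edits:
        if e.get("label") not in known:
            raise KeyError(f"unknown core label {e.get('label')!r}")
    for e in edits:
        core = grid.core(e["label"])
        if "new_center" in e:
            x, y = e["new_center"]
            core.roi = ROI("ellipse", center=(float(x), float(y)),
                           radii=core.roi.radii, pixel_size_um=core.roi.pixel_size_um)
        if e.get("set_missing"):
            core.metadata["missing"] = True
        if e.get("set_valid"):
            core.metadata["missing"] = False
    return grid


def import_core_metadata(grid: TMAGrid, table) -> tuple[TMAGrid, list[str]]:
    """Attach patient identifiers from a CSV (columns core_label, patient_id).

    ``table`` may be a path or a pandas DataFrame.  Returns the grid and
    the list of table labels that matched no core.
    """
    import pandas as pd

    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, dtype=str)
    if not {"core_label", "patient_id"} <= set(df.columns):
        raise ValueError("table must have columns core_label, patient_id")
    if df["core_label"].duplicated().any():
        dupes = sorted(df.loc[df["core_label"].duplicated(), "core_label"].unique())
        raise ValueError(f"duplicate core_label rows: {dupes}")
    known = set(grid.labels)
    unmatched = []
    for _, row in df.iterrows():
        if row["core_label"] in known:
            grid.core(row["core_label"]).metadata["patient_id"] = str(row["patient_id"])
        else:
            unmatched.append(str(row["core_label"]))
    return grid, unmatched
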