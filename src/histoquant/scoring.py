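"""Core- and patient-level IHC summary scores.

Four per-core scores cover the usual brightfield readouts:

* ``positive_density`` — positive cells per mm² of detected tissue
  (lymphocyte markers such as CD3/CD8);
* ``h_score`` — 1·%weak + 2·%moderate + 3·%strong over graded tumor
  nuclei, range 0 (all negative) to 300 (all strong);
* ``percent_positive`` — % of positive cells with an exclusion class
  ("Other") removed from the denominator (PD-L1-style scoring);
* ``tsp`` — tumor stromal percentage, AS/(AE+AS)·100 over classified
  superpixel areas, ignoring non-tissue area entirely.

A patient's biomarker score is the median of their valid core scores —
robust to a single artefactual core when up to three cores per tumor are
available.  Degenerate cores (no tumor cells, zero area) yield a
flagged-invalid score rather than an exception so batch runs complete.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .objects import PathObject

__all__ = [
    "CoreScore",
    "positive_density",
    "h_score",
    "percent_positive",
    "tsp",
    "patient_score",
]

GRADES = ("negative", "weak", "moderate", "strong")


@dataclass
class CoreScore:
    score_name: str
    value: float
    valid: bool = True
    core_label: Optional[str] = None
    patient_id: Optional[str] = None
    n_cells: Optional[int] = None
    reason: Optional[str] = None

    def __post_init__(self) -> None:
        if self.valid:
            checks = {
                "h_score": (0.0, 300.0),
                "percent_positive": (0.0, 100.0),
                "tsp": (0.0, 100.0),
                "cd_density": (0.0, math.inf),
            }
            lo, hi = checks.get(self.score_name, (-math.inf, math.inf))
            if not lo <= self.value <= hi:
                raise ValueError(f"{self.score_name}={self.value} outside [{lo}, {hi}]")


def positive_density(n_positive: int, tissue_area_mm2: float, **ids) -> CoreScore:
    """Positive cells per mm² of tissue; invalid when no tissue was found."""
    if tissue_area_mm2 <= 0:
        return CoreScore("cd_density", float("nan"), valid=False,
                         reason="zero tissue area", **ids)
    return CoreScore("cd_density", n_positive / tissue_area_mm2,
                     n_cells=int(n_positive), **ids)


def _grade_of(obj: PathObject, base_class: str) -> Optional[str]:
    cls = obj.classification or ""
    prefix = f"{base_class}: "
    return cls[len(prefix):] if cls.startswith(prefix) else None


def h_score(cells: Sequence[PathObject], base_class: str = "Tumor", **ids) -> CoreScore:
    """H-score over graded tumor nuclei: 1·%weak + 2·%moderate + 3·%strong."""
    counts = dict.fromkeys(GRADES, 0)
    for c in cells:
        g = _grade_of(c, base_class)
        if g is not None:
            if g not in counts:
                raise ValueError(f"unknown grade {g!r} on object {c.id}")
            counts[g] += 1
    n = sum(counts.values())
    if n == 0:
        return CoreScore("h_score", float("nan"), valid=False,
                         reason="no graded tumor cells", **ids)
    pct = {g: 100.0 * counts[g] / n for g in GRADES}
    h = 1.0 * pct["weak"] + 2.0 * pct["moderate"] + 3.0 * pct["strong"]
    return CoreScore("h_score", min(300.0, max(0.0, h)), n_cells=n, **ids)


def percent_positive(cells: Sequence[PathObject], exclude_class: str = "Other",
                     **ids) -> CoreScore:
    """Percentage of positive cells after removing the exclusion class.

    A cell counts as positive when its classification is ``positive`` or
    ends with ``": positive"`` (compound labels from sub-classification).
    """
    n_total = n_pos = n_excl = 0
    for c in cells:
        cls = c.classification or ""
        base = cls.split(":")[0].strip()
        n_total += 1
        if base == exclude_class:
            n_excl += 1
        elif cls == "positive" or cls.endswith(": positive"):
            n_pos += 1
    denom = n_total - n_excl
    if denom <= 0:
        return CoreScore("percent_positive", float("nan"), valid=False,
                         reason="no scorable cells", **ids)
    return CoreScore("percent_positive", min(100.0, 100.0 * n_pos / denom),
                     n_cells=denom, **ids)


def tsp(superpixels: Sequence[PathObject], epithelium_class: str = "Tumor",
        stroma_class: str = "Stroma", area_measurement: str = "Area µm^2",
        **ids) -> CoreScore:
    """Tumor stromal percentage: AS/(AE+AS)·100 over classified areas.

    Area classified as anything other than epithelium or stroma (e.g.
    whitespace, mucin, necrosis) is ignored entirely.
    """
    a_e = a_s = 0.0
    for sp in superpixels:
        area = sp.measurements.get(area_measurement, sp.roi.area_um2)
        if sp.classification == epithelium_class:
            a_e += area
        elif sp.classification == stroma_class:
            a_s += area
    if a_e + a_s <= 0:
        return CoreScore("tsp", float("nan"), valid=False,
                         reason="no epithelium or stroma area", **ids)
    # guard against 1-ulp float excursions past the bounds
    return CoreScore("tsp", min(100.0, max(0.0, 100.0 * a_s / (a_e + a_s))), **ids)


def patient_score(core_scores: Sequence[CoreScore]) -> float:
    """Median of the valid core scores for one patient and biomarker.

    The median (mean of the middle two for even counts) keeps a single
    artefactual core from driving the patient's score.  Raises when no
    valid cores remain so callers can report the excluded patient.
    """
    vals = [s.value for s in core_scores if s.valid]
    if not vals:
        raise ValueError("no valid core scores for patient")
    return float(np.median(vals))
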