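"""Random-trees object classification and intensity sub-classification.

Detections (cells or superpixels) are classified from their measurement
tables with a seeded random forest; IHC positivity grading is then a
separate, deliberately simple step: fixed intensity thresholds applied to
one named measurement, gated on a base class (e.g. only ``Tumor`` cells
are graded for nuclear p53).

The boundary rule is "bin downward": a value exactly equal to a threshold
takes the lower grade.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .objects import PathObject

__all__ = [
    "TrainingSet",
    "IntensityBins",
    "ClassifierModel",
    "P53_FEATURE_SUBSET",
    "train_classifier",
    "apply_classifier",
    "subclassify_intensity",
    "training_set_from_objects",
]

#: Empirical 16-measurement subset used for tumor-vs-other cell
#: classification: 4 nucleus shape, the nucleus/cell area ratio, all 5
#: nucleus hematoxylin statistics, 3 nucleus DAB statistics, 2 cell DAB
#: statistics and the local cell density.  Fully overridable.
P53_FEATURE_SUBSET: tuple[str, ...] = (
    "Nucleus: Area µm^2",
    "Nucleus: Circularity",
    "Nucleus: Eccentricity",
    "Nucleus: Max caliper µm",
    "Nucleus/Cell area ratio",
    "Nucleus: Hematoxylin mean",
    "Nucleus: Hematoxylin std",
    "Nucleus: Hematoxylin min",
    "Nucleus: Hematoxylin max",
    "Nucleus: Hematoxylin range",
    "Nucleus: DAB mean",
    "Nucleus: DAB std",
    "Nucleus: DAB max",
    "Cell: DAB mean",
    "Cell: DAB max",
    "Density: counts/mm^2",
)
assert len(P53_FEATURE_SUBSET) == 16


@dataclass
class TrainingSet:
    """Feature vectors + labels for classifier training."""

    feature_names: list[str]
    features: np.ndarray  # (n, p)
    labels: list[str]
    ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if self.features.ndim != 2 or self.features.shape[1] != len(self.feature_names):
            raise ValueError("features must be (n, len(feature_names))")
        if len(self.labels) != self.features.shape[0]:
            raise ValueError("labels and features disagree in length")
        if np.isnan(self.features).any():
            raise ValueError("training features contain missing values")
        classes = sorted(set(self.labels))
        if len(classes) not in (2, 3):
            raise ValueError("training requires 2 or 3 classes")


@dataclass
class IntensityBins:
    """Thresholds for IHC positivity grading on one measurement.

    ``three_thresholds`` grades negative/weak/moderate/strong (H-score
    style, mean nuclear chromogen OD); ``single_threshold`` grades
    negative/positive (e.g. max cell chromogen OD).
    """

    measurement: str
    mode: str = "three_thresholds"
    thresholds: tuple[float, ...] = (0.2, 0.4, 0.6)

    def __post_init__(self) -> None:
        if self.mode not in ("three_thresholds", "single_threshold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        need = 3 if self.mode == "three_thresholds" else 1
        if len(self.thresholds) != need:
            raise ValueError(f"{self.mode} needs {need} thresholds")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")

    def grade(self, value: float) -> str:
        t = self.thresholds
        if self.mode == "single_threshold":
            return "negative" if value <= t[0] else "positive"
        if value <= t[0]:
            return "negative"
        if value <= t[1]:
            return "weak"
        if value <= t[2]:
            return "moderate"
        return "strong"


@dataclass
class ClassifierModel:
    """A trained random forest plus the metadata needed to apply it."""

    forest: RandomForestClassifier
    feature_names: list[str]
    classes: list[str]
    oob_accuracy: float = float("nan")
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path) -> "ClassifierModel":
        model = joblib.load(path)
        if not isinstance(model, cls):
            raise ValueError("file does not contain a ClassifierModel")
        return model

    def predict(self, features: np.ndarray) -> list[str]:
        return [str(c) for c in self.forest.predict(np.asarray(features, dtype=float))]


def train_classifier(
    ts: TrainingSet,
    n_trees: int = 100,
    max_depth: Optional[int] = None,
    seed: int = 0,
    min_per_class: int = 10,
) -> ClassifierModel:
    """Fit a seeded random forest and report its out-of-bag accuracy."""
    counts = {c: ts.labels.count(c) for c in sorted(set(ts.labels))}
    small = [c for c, n in counts.items() if n < min_per_class]
    if small:
        raise ValueError(f"classes with fewer than {min_per_class} examples: {small}")
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=max_depth,
        max_features="sqrt",
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(ts.features, ts.labels)
    return ClassifierModel(
        forest=forest,
        feature_names=list(ts.feature_names),
        classes=[str(c) for c in forest.classes_],
        oob_accuracy=float(forest.oob_score_),
        seed=seed,
    )


def _feature_matrix(objects: Sequence[PathObject], names: Sequence[str]) -> np.ndarray:
    rows = []
    for obj in objects:
        row = []
        for n in names:
            if n not in obj.measurements:
                raise ValueError(f"object {obj.id} is missing feature {n!r}")
            row.append(obj.measurements[n])
        rows.append(row)
    return np.asarray(rows, dtype=float)


def apply_classifier(model: ClassifierModel, objects: Sequence[PathObject]) -> None:
    """Assign every object one of the model's classes (overwrites any
    prior classification).  Order-invariant: each prediction depends only
    on the object's own features."""
    if not objects:
        return
    x = _feature_matrix(objects, model.feature_names)
    for obj, cls in zip(objects, model.predict(x)):
        obj.classification = cls


def subclassify_intensity(
    objects: Sequence[PathObject],
    bins: IntensityBins,
    base_class: str = "Tumor",
) -> None:
    """Grade objects of ``base_class`` by intensity; compound label
    ``"Base: grade"``.  Objects of other classes are untouched."""
    targets = [o for o in objects if o.classification == base_class]
    for obj in targets:
        if bins.measurement not in obj.measurements:
            raise ValueError(f"object {obj.id} lacks measurement {bins.measurement!r}")
    for obj in targets:
        grade = bins.grade(obj.measurements[bins.measurement])
        obj.classification = f"{base_class}: {grade}"


def training_set_from_objects(
    objects: Sequence[PathObject],
    feature_names: Sequence[str],
    labeled_regions: Sequence[tuple[str, "object"]],
) -> TrainingSet:
    """Build a training set from labeled regions: each object inherits the
    label of the region containing its centroid (first match wins);
    unlabeled objects are skipped."""
    feats, labels, ids = [], [], []
    for obj in objects:
        cx, cy = obj.roi.centroid
        for label, roi in labeled_regions:
            if roi.contains_point(cx, cy):
                feats.append([obj.measurements[n] for n in feature_names])
                labels.append(label)
                ids.append(obj.id)
                break
    if not feats:
        raise ValueError("no objects fell inside any labeled region")
    return TrainingSet(list(feature_names), np.asarray(feats), labels, ids)
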