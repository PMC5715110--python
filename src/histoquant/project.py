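"""Project layer: declarative configuration, validation and batch
workflow execution.

A project is a JSON/YAML document naming the images (with pixel size),
the stain profile, per-workflow parameter blocks and an output directory.
Four batch workflows glue the library stages together:

* ``cd_counts``   — tissue detection + fast cell counts -> positive cells/mm²
* ``p53_hscore``  — cell detection + classifier + 3-threshold grading -> H-score
* ``pdl1_percent``— cell detection + classifier + single threshold -> % positive
* ``he_tsp``      — background + SLIC + texture + classifier -> tumor stromal %

Each run writes per-core and per-patient CSV tables, a markup PNG per
image, and a JSONL log recording parameters and per-image status.
Re-running with identical inputs reproduces identical CSV bytes; images
are independent, so any execution order yields the same outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from skimage.draw import disk as draw_disk

from . import scoring
from .classify import ClassifierModel, IntensityBins, apply_classifier, subclassify_intensity
from .detection import (DetectionParams, add_smoothed_features, detect_cells,
                        detect_tissue, fast_cell_counts, local_density)
from .stains import StainProfile, estimate_background, hdab_profile, he_profile
from .superpixels import compute_superpixel_features, slic_segment
from .objects import ROI

__all__ = ["Project", "validate_config", "run_workflow", "WORKFLOWS"]

WORKFLOWS = ("cd_counts", "p53_hscore", "pdl1_percent", "he_tsp")

# key -> (type, check, description); nested blocks validated recursively
_DETECTION_KEYS = {
    "gaussian_sigma_um": (float, lambda v: v > 0),
    "nucleus_threshold_od": (float, lambda v: v > 0),
    "min_nucleus_area_um2": (float, lambda v: v > 0),
    "max_nucleus_area_um2": (float, lambda v: v > 0),
    "cell_expansion_um": (float, lambda v: v > 0),
    "peak_min_separation_um": (float, lambda v: v > 0),
    "positive_dab_threshold_od": (float, lambda v: v > 0),
}
_SCHEMA = {
    "images": (list, lambda v: len(v) > 0),
    "stain_profile": ((str, dict), lambda v: True),
    "output_dir": (str, lambda v: True),
    "detection": (dict, None),
    "tissue_od_threshold": (float, lambda v: v > 0),
    "detection_channel": (str, lambda v: v in ("hematoxylin", "hematoxylin_plus_dab")),
    "classifier_path": (str, lambda v: True),
    "intensity_thresholds": (list, lambda v: len(v) in (1, 3)),
    "intensity_measurement": (str, lambda v: True),
    "base_class": (str, lambda v: True),
    "exclude_class": (str, lambda v: True),
    "superpixel_spacing_um": (float, lambda v: v > 0),
    "superpixel_smoothing_sigma_um": (float, lambda v: v > 0),
    "smoothing_sigma_um": (float, lambda v: v > 0),
    "seed": (int, lambda v: True),
}


def validate_config(config: dict | str | Path) -> dict:
    """Check a config mapping against the schema.

    Returns ``{"errors": [...], "warnings": [...], "config": filled}``
    listing every violation (not fail-fast); unknown keys get a
    nearest-valid-key suggestion.  Defaults are filled and echoed.
    """
    if not isinstance(config, dict):
        text = Path(config).read_text()
        config = yaml.safe_load(text)
    errors, warnings_ = [], []
    filled = dict(config)

    def check_block(block: dict, schema: dict, prefix: str = "") -> None:
        for key, value in block.items():
            if key not in schema:
                close = difflib.get_close_matches(key, schema, n=1)
                hint = f"; did you mean {close[0]!r}?" if close else ""
                errors.append(f"unknown key {prefix}{key!r}{hint}")
                continue
            typ, check = schema[key]
            if typ is float and isinstance(value, int):
                value = float(value)
            if not isinstance(value, typ):
                errors.append(f"{prefix}{key}: expected {typ}, got {type(value).__name__}")
                continue
            if key == "detection":
                check_block(value, _DETECTION_KEYS, prefix="detection.")
            elif check is not None and not check(value):
                errors.append(f"{prefix}{key}: invalid value {value!r}")

    check_block(config, _SCHEMA)
    for key, default in (("tissue_od_threshold", 0.05), ("detection_channel", "hematoxylin"),
                         ("smoothing_sigma_um", 25.0), ("superpixel_spacing_um", 50.0),
                         ("superpixel_smoothing_sigma_um", 100.0),
                         ("base_class", "Tumor"), ("exclude_class", "Other"), ("seed", 0),
                         ("output_dir", "results")):
        filled.setdefault(key, default)
    if "images" in config:
        for i, entry in enumerate(config.get("images", []) or []):
            if not isinstance(entry, dict) or "path" not in entry:
                errors.append(f"images[{i}]: each entry needs at least a 'path'")
            elif "pixel_size_um" not in entry:
                warnings_.append(f"images[{i}]: pixel_size_um missing, assuming 1.0")
    return {"errors": errors, "warnings": warnings_, "config": filled}


@dataclass
class Project:
    """A validated analysis project."""

    config: dict
    root: Path = field(default_factory=Path.cwd)

    @classmethod
    def load(cls, path) -> "Project":
        path = Path(path)
        report = validate_config(path)
        if report["errors"]:
            raise ValueError("invalid project config:\n" + "\n".join(report["errors"]))
        return cls(report["config"], root=path.parent)

    @classmethod
    def from_dict(cls, config: dict, root=None) -> "Project":
        report = validate_config(config)
        if report["errors"]:
            raise ValueError("invalid project config:\n" + "\n".join(report["errors"]))
        return cls(report["config"], root=Path(root) if root else Path.cwd())

    # -- pieces -----------------------------------------------------------

    def stain_profile(self) -> StainProfile:
        sp = self.config.get("stain_profile", "hdab")
        if isinstance(sp, dict):
            return StainProfile(
                tuple(sp["background"]),
                [(s["name"], np.asarray(s["vector"], dtype=float)) for s in sp["stains"]],
            )
        if sp == "hdab":
            return hdab_profile()
        if sp == "he":
            return he_profile()
        return StainProfile.from_json(self.root / sp)

    def detection_params(self) -> DetectionParams:
        return DetectionParams(**self.config.get("detection", {}))

    def images(self, subset: Optional[Sequence[str]] = None) -> list[dict]:
        entries = []
        for e in self.config["images"]:
            name = e.get("name", Path(e["path"]).stem)
            if subset is not None and name not in subset:
                continue
            entries.append({**e, "name": name,
                            "pixel_size_um": float(e.get("pixel_size_um", 1.0))})
        return entries

    def out_dir(self) -> Path:
        out = self.root / self.config["output_dir"]
        out.mkdir(parents=True, exist_ok=True)
        return out


def _markup(image: np.ndarray, detections, path: Path) -> None:
    """Low-resolution verification overlay: detections drawn over the
    image, color-coded by classification."""
    canvas = image.copy()
    palette = {"positive": (180, 30, 30), "negative": (30, 80, 200),
               "Tumor": (180, 30, 30), "Stroma": (30, 160, 60)}
    for obj in detections:
        cls = (obj.classification or "").split(":")[0].strip()
        color = palette.get(obj.classification or "", palette.get(cls, (220, 180, 30)))
        cx, cy = obj.roi.centroid
        rr, cc = draw_disk((cy, cx), 3, shape=canvas.shape[:2])
        canvas[rr, cc] = color
    iio.imwrite(path, canvas)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6f")


def _param_hash(params: dict) -> str:
    return hashlib.sha256(json.dumps(params, sort_keys=True, default=str).encode()).hexdigest()[:12]


def run_workflow(project: Project, workflow: str,
                 image_subset: Optional[Sequence[str]] = None) -> dict[str, pd.DataFrame]:
    """Run one named workflow over the project's images.

    Writes ``<workflow>_cores.csv``, ``<workflow>_patients.csv`` (when
    patient ids are present), per-image markup PNGs and a
    ``<workflow>_log.jsonl`` run log.  Individual image failures are
    logged and flagged; the batch continues.
    """
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {WORKFLOWS}")
    cfg = project.config
    out = project.out_dir()
    needs_model = workflow in ("p53_hscore", "pdl1_percent", "he_tsp")
    model = None
    if needs_model:
        model_path = cfg.get("classifier_path")
        if not model_path:
            raise ValueError(
                f"workflow {workflow!r} needs a trained classifier: set 'classifier_path' "
                "(train one with histoquant.classify.train_classifier and save it)"
            )
        model = ClassifierModel.load(project.root / model_path)

    profile = project.stain_profile()
    params = project.detection_params()
    log_path = out / f"{workflow}_log.jsonl"
    phash = _param_hash({k: v for k, v in cfg.items() if k != "images"})
    core_rows = []
    with open(log_path, "w") as log:
        log.write(json.dumps({"event": "start", "workflow": workflow,
                              "param_hash": phash, "seed": cfg["seed"],
                              "time": time.strftime("%Y-%m-%dT%H:%M:%S")}) + "\n")
        for entry in project.images(image_subset):
            try:
                image = np.asarray(iio.imread(project.root / entry["path"]))[..., :3]
                image = np.ascontiguousarray(image, dtype=np.uint8)
                row, detections = _run_one(workflow, image, entry, profile, params,
                                           model, cfg)
                core_rows.append(row)
                _markup(image, detections, out / f"{workflow}_{entry['name']}_markup.png")
                log.write(json.dumps({"event": "image", "name": entry["name"],
                                      "status": "ok", "param_hash": phash}) + "\n")
            except Exception as exc:  # noqa: BLE001 — batch must continue
                core_rows.append({"core_label": entry.get("core_label", entry["name"]),
                                  "patient_id": entry.get("patient_id", ""),
                                  "value": float("nan"), "valid": False,
                                  "reason": str(exc)})
                log.write(json.dumps({"event": "image", "name": entry["name"],
                                      "status": "error", "error": str(exc)}) + "\n")

    cores = pd.DataFrame(core_rows).sort_values("core_label").reset_index(drop=True)
    result = {"cores": cores}
    _write_csv(cores, out / f"{workflow}_cores.csv")

    if cores["patient_id"].astype(str).str.len().gt(0).any():
        rows = []
        for pid, sub in cores[cores["valid"]].groupby("patient_id"):
            if pid == "":
                continue
            rows.append({"patient_id": pid, "score": float(np.median(sub["value"])),
                         "n_cores": len(sub)})
        patients = pd.DataFrame(rows).sort_values("patient_id").reset_index(drop=True)
        result["patients"] = patients
        _write_csv(patients, out / f"{workflow}_patients.csv")
    return result


def _run_one(workflow, image, entry, profile, params, model, cfg):
    psz = entry["pixel_size_um"]
    label = entry.get("core_label", entry["name"])
    pid = entry.get("patient_id", "")
    ids = {"core_label": label, "patient_id": pid}

    if workflow == "cd_counts":
        _, area_mm2 = detect_tissue(image, psz, background=profile.background,
                                    od_threshold=cfg["tissue_od_threshold"])
        detections, counts = fast_cell_counts(image, profile, params, psz,
                                              detection_channel=cfg["detection_channel"])
        score = scoring.positive_density(counts["positive"], area_mm2, **ids)
        row = {**_score_row(score), "n_total": counts["total"],
               "tissue_area_mm2": area_mm2}
        return row, detections

    if workflow in ("p53_hscore", "pdl1_percent"):
        cells = detect_cells(image, profile, params, psz)
        if cells:
            local_density(cells)
            add_smoothed_features(cells, [n for n in model.feature_names
                                          if "(smoothed" not in n and n in cells[0].measurements],
                                  sigma_um=cfg["smoothing_sigma_um"])
            apply_classifier(model, cells)
        if workflow == "p53_hscore":
            bins = IntensityBins(cfg.get("intensity_measurement", "Nucleus: DAB mean"),
                                 "three_thresholds",
                                 tuple(cfg.get("intensity_thresholds", (0.2, 0.4, 0.6))))
            subclassify_intensity(cells, bins, base_class=cfg["base_class"])
            score = scoring.h_score(cells, base_class=cfg["base_class"], **ids)
        else:
            bins = IntensityBins(cfg.get("intensity_measurement", "Cell: DAB max"),
                                 "single_threshold",
                                 tuple(cfg.get("intensity_thresholds", (0.3,))))
            for base in model.classes:
                if base != cfg["exclude_class"]:
                    subclassify_intensity(cells, bins, base_class=base)
            for c in cells:  # strip the base for counting: positive/negative
                if c.classification and ": " in c.classification:
                    base, grade = c.classification.split(": ", 1)
                    c.classification = grade if base != cfg["exclude_class"] else base
            score = scoring.percent_positive(cells, exclude_class=cfg["exclude_class"], **ids)
        return _score_row(score), cells

    # he_tsp
    bg = estimate_background(image)
    h, w = image.shape[:2]
    annotation = ROI("rectangle", center=((w - 1) / 2.0, (h - 1) / 2.0),
                     radii=((w - 1) / 2.0, (h - 1) / 2.0), pixel_size_um=psz)
    sps, _ = slic_segment(image, annotation, psz,
                          spacing_um=cfg["superpixel_spacing_um"])
    names = compute_superpixel_features(sps, image, background=bg)
    add_smoothed_features(sps, names, sigma_um=cfg["superpixel_smoothing_sigma_um"])
    apply_classifier(model, sps)
    score = scoring.tsp(sps, **ids)
    return _score_row(score), sps


def _score_row(score: scoring.CoreScore) -> dict:
    return {"core_label": score.core_label, "patient_id": score.patient_id or "",
            "score_name": score.score_name, "value": score.value,
            "valid": score.valid, "n_cells": score.n_cells,
            "reason": score.reason or ""}
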