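"""Config validation and batch workflow execution on synthetic projects."""

import imageio.v3 as iio
import numpy as np
import pandas as pd
import pytest

from histoquant.classify import TrainingSet, train_classifier
from histoquant.detection import (DetectionParams, add_smoothed_features,
                                  detect_cells, local_density)
from histoquant.classify import P53_FEATURE_SUBSET
from histoquant.project import Project, run_workflow, validate_config
from histoquant.stains import hdab_profile
from histoquant.synthetic import CellClass, CoreSpec, gen_core

PSZ = 1.0
CORE = dict(pixel_size_um=PSZ, diameter_um=300.0, n_cells=60)


class TestValidateConfig:
    def test_minimal_valid_fills_defaults(self):
        report = validate_config({"images": [{"path": "a.png", "pixel_size_um": 1.0}]})
        assert report["errors"] == []
        assert report["config"]["tissue_od_threshold"] == 0.05
        assert report["config"]["seed"] == 0

    def test_negative_parameter_named(self):
        report = validate_config({"images": [{"path": "a.png", "pixel_size_um": 1.0}],
                                  "detection": {"cell_expansion_um": -5.0}})
        assert any("cell_expansion_um" in e for e in report["errors"])

    def test_unknown_key_suggestion(self):
        report = validate_config({"images": [{"path": "a.png", "pixel_size_um": 1.0}],
                                  "detection": {"cell_expansionUM": 5.0}})
        assert any("cell_expansion_um" in e and "did you mean" in e
                   for e in report["errors"])

    def test_all_violations_reported_not_fail_fast(self):
        report = validate_config({"images": [],
                                  "tissue_od_threshold": -1.0,
                                  "bogus_key": 1})
        assert len(report["errors"]) >= 3


@pytest.fixture(scope="module")
def cd_project(tmp_path_factory):
    root = tmp_path_factory.mktemp("cdproj")
    for i, seed in enumerate((11, 12)):
        img, _ = gen_core(CoreSpec(seed=seed, n_cells=80, pixel_size_um=PSZ,
                                   diameter_um=400.0))
        iio.imwrite(root / f"core{i}.png", img)
    config = {
        "images": [{"path": f"core{i}.png", "pixel_size_um": PSZ,
                    "core_label": f"A-{i + 1}", "patient_id": "P001"}
                   for i in range(2)],
        "tissue_od_threshold": 0.02,
        "output_dir": "out",
    }
    return Project.from_dict(config, root=root)


class TestCDCountsWorkflow:
    def test_row_per_core_and_patient_median(self, cd_project):
        result = run_workflow(cd_project, "cd_counts")
        cores = result["cores"]
        assert len(cores) == 2
        assert cores["valid"].all()
        assert (cores["value"] > 0).all()
        patients = result["patients"]
        assert len(patients) == 1
        assert patients.loc[0, "score"] == pytest.approx(np.median(cores["value"]))

    def test_rerun_byte_identical(self, cd_project):
        run_workflow(cd_project, "cd_counts")
        first = (cd_project.out_dir() / "cd_counts_cores.csv").read_bytes()
        run_workflow(cd_project, "cd_counts")
        assert (cd_project.out_dir() / "cd_counts_cores.csv").read_bytes() == first

    def test_markup_images_written(self, cd_project):
        run_workflow(cd_project, "cd_counts")
        assert (cd_project.out_dir() / "cd_counts_core0_markup.png").exists()

    def test_missing_classifier_actionable_error(self, cd_project):
        with pytest.raises(ValueError, match="classifier_path"):
            run_workflow(cd_project, "p53_hscore")


# grade DAB levels sit mid-bin for the default 0.2/0.4/0.6 thresholds
GRADE_MIX = (
    CellClass("negative", 0.40, radius_um=(3.5, 0.3), dab=(0.05, 0.02)),
    CellClass("weak", 0.30, radius_um=(3.5, 0.3), dab=(0.30, 0.03)),
    CellClass("moderate", 0.15, radius_um=(3.5, 0.3), dab=(0.50, 0.03)),
    CellClass("strong", 0.15, radius_um=(3.5, 0.3), dab=(0.80, 0.05)),
)


def _train_tumor_model(seeds, sigma=25.0):
    """Two-way tumor-vs-other model from synthetic cores with both
    populations (tumor = larger round nuclei)."""
    classes = (CellClass("Tumor", 0.6, radius_um=(3.5, 0.3), dab=(0.3, 0.15)),
               CellClass("Other", 0.4, radius_um=(1.8, 0.2), elongation=2.5,
                         hematoxylin=(0.45, 0.05)),)
    prof, params = hdab_profile(), DetectionParams()
    names = list(P53_FEATURE_SUBSET) + [f"{n} (smoothed {sigma:g})"
                                        for n in P53_FEATURE_SUBSET]
    feats, labels = [], []
    from scipy.spatial import cKDTree
    for seed in seeds:
        img, truth = gen_core(CoreSpec(seed=seed, classes=classes, **CORE))
        cells = detect_cells(img, prof, params, PSZ)
        local_density(cells)
        add_smoothed_features(cells, list(P53_FEATURE_SUBSET), sigma_um=sigma)
        tree = cKDTree(truth[["x_px", "y_px"]].values)
        for c in cells:
            d, idx = tree.query(c.roi.centroid)
            if d < 3.0 / PSZ:
                feats.append([c.measurements[n] for n in names])
                labels.append(truth.iloc[idx]["class"])
    return train_classifier(TrainingSet(names, np.asarray(feats), labels), seed=0)


def test_p53_hscore_end_to_end(tmp_path):
    """Per-core H-scores from the full pipeline land within 10 points of the
    truth implied by the generator's grade mix."""
    model = _train_tumor_model(seeds=(21, 22))
    model.save(tmp_path / "model.joblib")
    expected = []
    for i, seed in enumerate((31, 32)):
        img, truth = gen_core(CoreSpec(seed=seed, classes=GRADE_MIX, **CORE))
        iio.imwrite(tmp_path / f"core{i}.png", img)
        frac = truth["class"].value_counts(normalize=True)
        expected.append(100 * (1 * frac.get("weak", 0) + 2 * frac.get("moderate", 0)
                               + 3 * frac.get("strong", 0)))
    config = {
        "images": [{"path": f"core{i}.png", "pixel_size_um": PSZ,
                    "core_label": f"A-{i + 1}", "patient_id": "P9"} for i in range(2)],
        "classifier_path": "model.joblib",
        "intensity_thresholds": [0.2, 0.4, 0.6],
        "output_dir": "out",
    }
    project = Project.from_dict(config, root=tmp_path)
    cores = run_workflow(project, "p53_hscore")["cores"]
    assert cores["valid"].all()
    for got, want in zip(cores["value"], expected):
        assert abs(got - want) <= 10.0


def test_failed_image_flagged_run_continues(tmp_path):
    img, _ = gen_core(CoreSpec(seed=41, n_cells=50, pixel_size_um=PSZ, diameter_um=300.0))
    iio.imwrite(tmp_path / "good.png", img)
    (tmp_path / "bad.png").write_bytes(b"not an image")
    config = {"images": [{"path": "good.png", "pixel_size_um": PSZ, "core_label": "A-1"},
                         {"path": "bad.png", "pixel_size_um": PSZ, "core_label": "A-2"}],
              "tissue_od_threshold": 0.02, "output_dir": "out"}
    cores = run_workflow(Project.from_dict(config, root=tmp_path), "cd_counts")["cores"]
    assert len(cores) == 2
    assert cores.set_index("core_label").loc["A-1", "valid"]
    assert not cores.set_index("core_label").loc["A-2", "valid"]
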