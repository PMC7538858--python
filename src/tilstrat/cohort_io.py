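"""Cohort manifests, pipeline configuration, and run orchestration.

The manifest is a TSV with one row per patient (id, channel image paths,
pixel size, outcome label, grade, nodal status, cohort tag).  Outcome labels
follow the relapse rule: relapse within 3 years of surgery -> poor;
relapse-free for at least 5 years -> good; patients in between are labeled
unknown and excluded from training and threshold selection (they may still
be scored).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classifier import TrainConfig
from .preprocess import PreprocessConfig

__all__ = [
    "PatientRecord",
    "PipelineConfig",
    "read_manifest",
    "write_manifest",
    "load_reference_training_table",
    "run_pipeline",
]

_OUTCOMES = {"good", "poor", "unknown"}
_GRADES = {"I", "II", "III", "NA"}
_NODAL = {"yes", "no", "NA"}
_REQUIRED_COLS = [
    "patient_id",
    "panck_path",
    "cd8_path",
    "pixel_size_um",
    "outcome",
]


@dataclass(frozen=True)
class PatientRecord:
    """Identity, outcome and imaging metadata for one patient."""

    patient_id: str
    outcome: str = "unknown"
    grade: str = "NA"
    nodal: str = "NA"
    cohort: str = ""
    pixel_size_um: float = 0.5
    panck_path: str = ""
    cd8_path: str = ""

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")
        if self.outcome not in _OUTCOMES:
            raise ValueError(
                f"patient {self.patient_id!r}: outcome {self.outcome!r} not in "
                f"{sorted(_OUTCOMES)}"
            )
        if self.grade not in _GRADES:
            raise ValueError(
                f"patient {self.patient_id!r}: grade {self.grade!r} not in "
                f"{sorted(_GRADES)}"
            )
        if self.nodal not in _NODAL:
            raise ValueError(
                f"patient {self.patient_id!r}: nodal {self.nodal!r} not in "
                f"{sorted(_NODAL)}"
            )
        if not (self.pixel_size_um > 0):
            raise ValueError(f"patient {self.patient_id!r}: pixel_size_um must be > 0")


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters, round-trippable through YAML."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    target_um: float = 10.0
    patch_size: int = 64
    min_panck_frac: float = 0.25
    min_cd8: int = 1
    train: TrainConfig = field(default_factory=TrainConfig)
    realizations: int = 5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "preprocess" in d:
            d["preprocess"] = PreprocessConfig(**d["preprocess"])
        if "train" in d:
            d["train"] = TrainConfig(**d["train"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def read_manifest(path) -> list[PatientRecord]:
    """Read and validate a cohort manifest TSV.

    Raises with the offending column/value named on missing columns,
    duplicate patient ids, or invalid enum values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing required columns: {missing}")
    dupes = df["patient_id"][df["patient_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate patient_id values in manifest: {sorted(set(dupes))}")
    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                patient_id=row["patient_id"],
                outcome=row["outcome"],
                grade=row.get("grade", "NA") or "NA",
                nodal=row.get("nodal_status", "NA") or "NA",
                cohort=row.get("cohort", "") or "",
                pixel_size_um=float(row["pixel_size_um"]),
                panck_path=row["panck_path"],
                cd8_path=row["cd8_path"],
            )
        )
    return records


def write_manifest(records: list[PatientRecord], path) -> None:
    df = pd.DataFrame(
        {
            "patient_id": [r.patient_id for r in records],
            "panck_path": [r.panck_path for r in records],
            "cd8_path": [r.cd8_path for r in records],
            "pixel_size_um": [r.pixel_size_um for r in records],
            "outcome": [r.outcome for r in records],
            "grade": [r.grade for r in records],
            "nodal_status": [r.nodal for r in records],
            "cohort": [r.cohort for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def load_reference_training_table() -> pd.DataFrame:
    """Per-patient patch counts and clinical annotation of the published
    24-patient City-of-Hope IF training cohort (columns: patient_id,
    n_patches, outcome, grade, nodal_status)."""
    path = Path(__file__).parent / "data" / "training_cohort_patch_counts.tsv"
    return pd.read_csv(path, sep="\t")


def _load_channel(path, pixel_size_um):
    import tifffile

    from .preprocess import IntensityImage

    return IntensityImage(
        np.asarray(tifffile.imread(path), dtype=float), pixel_size_um
    )


def run_pipeline(
    manifest,
    config: PipelineConfig | None = None,
    mode: str = "full",
    outdir=None,
    seed: int = 0,
    model_path=None,
    rc: float | None = None,
    train_cohort: str | None = None,
    test_cohort: str | None = None,
):
    """Run preprocess -> patchify -> train/predict -> stratify on a manifest.

    mode "train": train on outcome-labeled patients, select Rc over
    ``config.realizations`` realizations, persist the model and report.
    mode "predict": load ``model_path`` and ``rc``, score every patient on
    all of its surviving patches.
    mode "full": both — patients whose ``cohort`` equals ``train_cohort``
    (default: all labeled patients if no cohort tags distinguish them) are
    used for training, the rest (or ``test_cohort``) for testing.

    All intermediates (masks, patch indices, predictions) are written under
    ``outdir`` when given; the returned report dict carries seeds, config,
    per-stage counts and final metrics.
    """
    from .model import RelapseStratification, prepare_patient_patches

    cfg = config or PipelineConfig()
    records = read_manifest(manifest) if not isinstance(manifest, list) else manifest
    outdir = Path(outdir) if outdir is not None else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    cohorts = {r.cohort for r in records}
    if mode == "full" and train_cohort is None and len(cohorts) > 1:
        raise ValueError(
            f"mode='full' with multiple cohort tags {sorted(cohorts)} requires "
            "train_cohort (and optionally test_cohort)"
        )

    report: dict = {
        "mode": mode,
        "seed": seed,
        "config": cfg.to_dict(),
        "n_patients": len(records),
        "warnings": [],
    }

    # stage 1+2: masks and patches for every patient
    prepared = {}
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for rec in records:
            panck = _load_channel(rec.panck_path, rec.pixel_size_um)
            cd8 = _load_channel(rec.cd8_path, rec.pixel_size_um)
            prepared[rec.patient_id] = prepare_patient_patches(
                rec.patient_id, panck, cd8, cfg, outdir=outdir
            )
    report["warnings"].extend(str(w.message) for w in wlist)
    report["patch_counts"] = {
        pid: len(patches) for pid, (patches, _) in prepared.items()
    }
    unpredictable = [pid for pid, (patches, _) in prepared.items() if not patches]
    report["unpredictable_patients"] = unpredictable

    def _records_for(tag):
        if tag is None:
            return [r for r in records if r.outcome != "unknown"]
        return [r for r in records if r.cohort == tag]

    if mode in ("train", "full"):
        train_records = [
            r
            for r in _records_for(train_cohort)
            if r.outcome in ("good", "poor") and prepared[r.patient_id][0]
        ]
        model = RelapseStratification.from_prepared(
            {r.patient_id: prepared[r.patient_id][0] for r in train_records},
            {r.patient_id: r.outcome for r in train_records},
            config=cfg,
        )
        results = model.fit(realizations=cfg.realizations, seed=seed)
        report["rc_final"] = results.rc_final
        report["realization_intervals"] = results.selection.intervals
        report["train_max_accuracy"] = max(
            s.max_accuracy for s in results.scans
        )
        report["n_train_patients"] = len(train_records)
        if outdir:
            results.classifier.save(outdir / "model.ckpt.npz")
        model_obj, rc_val = results.classifier, results.rc_final
    if mode == "predict":
        from .classifier import PatchModel

        if model_path is None or rc is None:
            raise ValueError("mode='predict' requires model_path and rc")
        model_obj = PatchModel.load(model_path)
        rc_val = rc

    if mode in ("predict", "full"):
        from .classifier import predict_patches
        from .stratify import clamp_rc, evaluate, predict_outcome, score_patients

        rc_val = clamp_rc(rc_val)

        if mode == "full":
            test_records = (
                _records_for(test_cohort)
                if test_cohort is not None or train_cohort is not None
                else [r for r in records if r.outcome != "unknown"]
            )
            if train_cohort is not None and test_cohort is None:
                test_records = [r for r in records if r.cohort != train_cohort]
        else:
            test_records = records
        preds = []
        for rec in test_records:
            patches, _ = prepared[rec.patient_id]
            preds.extend(
                predict_patches(model_obj, patches, cfg.train.patch_cutoff)
            )
        scores = score_patients(preds)
        outcomes = {s.patient_id: predict_outcome(s, rc_val) for s in scores}
        report["patient_scores"] = {s.patient_id: s.r_good for s in scores}
        report["predicted_outcomes"] = outcomes
        truths = {
            r.patient_id: r.outcome
            for r in test_records
            if r.outcome in ("good", "poor") and r.patient_id in outcomes
        }
        if truths:
            cm = evaluate({p: outcomes[p] for p in truths}, truths)
            report["confusion"] = {
                "tp": cm.tp,
                "fp": cm.fp,
                "fn": cm.fn,
                "tn": cm.tn,
                "recall": cm.recall,
                "precision": cm.precision,
                "accuracy": cm.accuracy,
            }
        if outdir:
            pd.DataFrame(
                [
                    {
                        "patient_id": p.patient_id,
                        "row": p.row,
                        "col": p.col,
                        "prob_poor": p.prob_poor,
                        "label": p.label,
                    }
                    for p in preds
                ]
            ).to_csv(outdir / "predictions.tsv", sep="\t", index=False)

    if outdir:
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
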