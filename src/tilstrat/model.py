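"""Model/results surface tying the pipeline stages together.

``RelapseStratification`` is built from a cohort (synthetic patients, raw
channel images, or pre-computed patches) and a :class:`PipelineConfig`;
``fit`` runs the full training protocol — per-patient holdout splits, class
balancing, CNN training, and cut-off (Rc) selection over several
realizations — and returns a :class:`RelapseStratificationResults` carrying
the fitted classifier, the chosen cut-off with its per-realization optimal
intervals, per-patient scores, and ``summary()``/``predict()``/plotting.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from ._util import mix_seed
from .classifier import (
    PatchModel,
    balance_by_replication,
    predict_patches,
    split_train_holdout,
    train_classifier,
)
from .cohort_io import PipelineConfig
from .patchify import Patch, filter_patches, rescale_mask_pair, tile_patches
from .preprocess import IntensityImage, MaskPair, make_mask_pair
from .stratify import (
    ConfusionSummary,
    RcSelection,
    ThresholdScan,
    evaluate,
    predict_outcome,
    scan_rc,
    score_patients,
    select_rc,
)

__all__ = [
    "RelapseStratification",
    "RelapseStratificationResults",
    "prepare_patient_patches",
]


def prepare_patient_patches(
    patient_id: str,
    panck: IntensityImage,
    cd8: IntensityImage,
    config: PipelineConfig | None = None,
    outdir=None,
) -> tuple[list[Patch], MaskPair]:
    """Raw channels -> cleaned masks -> filtered patches for one patient.

    Optionally persists the cleaned masks (8-bit TIFF, 0/255) and a JSON
    sidecar with the cleaning parameters under ``outdir``.
    """
    cfg = config or PipelineConfig()
    mp = make_mask_pair(panck, cd8, cfg.preprocess)
    smp = rescale_mask_pair(mp, target_um=cfg.target_um)
    patches = filter_patches(
        tile_patches(smp, size_px=cfg.patch_size, patient_id=patient_id),
        min_panck_frac=cfg.min_panck_frac,
        min_cd8=cfg.min_cd8,
    )
    if outdir is not None:
        import json
        from pathlib import Path

        import tifffile

        outdir = Path(outdir)
        masks_dir = outdir / "masks"
        masks_dir.mkdir(parents=True, exist_ok=True)
        for name, m in (("panck", mp.panck), ("cd8", mp.cd8)):
            tifffile.imwrite(
                masks_dir / f"{patient_id}_{name}_mask.tif",
                (m.astype(np.uint8) * 255),
            )
        (masks_dir / f"{patient_id}_mask.json").write_text(
            json.dumps(
                {
                    "percentile_q": cfg.preprocess.percentile_q,
                    "min_component_um2": cfg.preprocess.min_component_um2,
                    "max_hole_um2": cfg.preprocess.max_hole_um2,
                    "pixel_size_um": mp.pixel_size_um,
                    "n_surviving_patches": len(patches),
                }
            )
        )
    return patches, mp


def _prepare_cohort(patients, config) -> tuple[dict[str, list[Patch]], dict[str, str]]:
    """Accept synthetic patients / (record, panck, cd8) triples / patch dicts."""
    patches_by_pid: dict[str, list[Patch]] = {}
    outcomes: dict[str, str] = {}
    for item in patients:
        if hasattr(item, "panck") and hasattr(item, "record"):  # SyntheticPatient
            pid = item.record.patient_id
            panck, cd8, outcome = item.panck, item.cd8, item.truth_outcome
        else:  # (PatientRecord, panck, cd8)
            rec, panck, cd8 = item
            pid, outcome = rec.patient_id, rec.outcome
        patches, _ = prepare_patient_patches(pid, panck, cd8, config)
        patches_by_pid[pid] = patches
        outcomes[pid] = outcome
    return patches_by_pid, outcomes


class RelapseStratification:
    """Relapse-risk stratification model for a two-channel IF cohort.

    Parameters
    ----------
    patches_by_patient : dict mapping patient_id -> surviving patches
    outcomes : dict mapping patient_id -> "good" | "poor" | "unknown"
    config : PipelineConfig, optional

    Use :meth:`from_patients` to build directly from generated or loaded
    image pairs, or :meth:`from_manifest` from a manifest TSV.
    """

    def __init__(self, patches_by_patient, outcomes, config=None):
        self.config = config or PipelineConfig()
        self.outcomes = dict(outcomes)
        self.patches_by_patient = {
            pid: list(ps) for pid, ps in patches_by_patient.items()
        }
        empty = [pid for pid, ps in self.patches_by_patient.items() if not ps]
        if empty:
            warnings.warn(
                f"{len(empty)} patient(s) have no surviving patches and cannot "
                f"be scored: {empty[:5]}"
            )
            for pid in empty:
                self.patches_by_patient.pop(pid)

    @classmethod
    def from_patients(cls, patients, config=None) -> "RelapseStratification":
        cfg = config or PipelineConfig()
        patches, outcomes = _prepare_cohort(patients, cfg)
        return cls(patches, outcomes, cfg)

    @classmethod
    def from_prepared(cls, patches_by_patient, outcomes, config=None):
        return cls(patches_by_patient, outcomes, config)

    @classmethod
    def from_manifest(cls, manifest_path, config=None) -> "RelapseStratification":
        import tifffile

        from .cohort_io import read_manifest

        cfg = config or PipelineConfig()
        triples = []
        for rec in read_manifest(manifest_path):
            panck = IntensityImage(
                np.asarray(tifffile.imread(rec.panck_path), dtype=float),
                rec.pixel_size_um,
            )
            cd8 = IntensityImage(
                np.asarray(tifffile.imread(rec.cd8_path), dtype=float),
                rec.pixel_size_um,
            )
            triples.append((rec, panck, cd8))
        return cls.from_patients(triples, cfg)

    # ------------------------------------------------------------------
    def fit(self, realizations: int | None = None, seed: int = 0):
        """Train the classifier and select the cut-off Rc.

        Each realization redraws the per-patient 80/20 split and the CNN
        initialization/minibatch order, trains on the balanced training
        patches, scores the holdout patches per patient (Rtn), and scans the
        cut-off.  The final Rc averages the optimal-interval midpoints of
        the realizations achieving the best accuracy; the returned results
        carry the classifier of the first such realization.
        """
        realizations = realizations or self.config.realizations
        labeled = {
            pid: ps
            for pid, ps in self.patches_by_patient.items()
            if self.outcomes.get(pid) in ("good", "poor")
        }
        if not labeled:
            raise ValueError("no outcome-labeled patients with patches to fit on")
        truths = {pid: self.outcomes[pid] for pid in labeled}
        scans: list[ThresholdScan] = []
        models: list[PatchModel] = []
        holdout_scores = []
        base_cfg = self.config.train
        for r in range(realizations):
            split_seed = mix_seed(seed, 2 * r)
            train_seed = mix_seed(seed, 2 * r + 1)
            train_p, holdout_p = split_train_holdout(
                labeled, base_cfg.train_frac, seed=split_seed
            )
            y_train = [1 if truths[p.patient_id] == "poor" else 0 for p in train_p]
            bal_p, bal_y = balance_by_replication(
                train_p, y_train, base_cfg.extra_copies_minority, seed=train_seed
            )
            model = train_classifier(
                bal_p, bal_y, replace(base_cfg, seed=train_seed)
            )
            preds = predict_patches(model, holdout_p, base_cfg.patch_cutoff)
            scores = score_patients(preds)
            scans.append(scan_rc(scores, truths))
            models.append(model)
            holdout_scores.append(scores)
        selection = select_rc(scans)
        best_idx = selection.used.index(True)
        return RelapseStratificationResults(
            model=self,
            classifier=models[best_idx],
            scans=scans,
            selection=selection,
            holdout_scores=holdout_scores,
            seed=seed,
        )


class RelapseStratificationResults:
    """Fitted classifier + validated cut-off and per-realization diagnostics."""

    def __init__(self, model, classifier, scans, selection, holdout_scores, seed):
        self.model = model
        self.classifier = classifier
        self.scans: list[ThresholdScan] = scans
        self.selection: RcSelection = selection
        self.holdout_scores = holdout_scores
        self.seed = seed

    @property
    def rc_final(self) -> float:
        return self.selection.rc_final

    @property
    def train_max_accuracy(self) -> float:
        return max(s.max_accuracy for s in self.scans)

    def patient_scores(self) -> pd.DataFrame:
        """Holdout good-patch fractions (Rtn) per patient and realization."""
        rows = []
        for r, scores in enumerate(self.holdout_scores):
            for s in scores:
                rows.append(
                    {
                        "realization": r,
                        "patient_id": s.patient_id,
                        "n_patches": s.n_patches_evaluated,
                        "r_good": s.r_good,
                        "outcome": self.model.outcomes.get(s.patient_id),
                    }
                )
        return pd.DataFrame(rows)

    def predict(self, cohort=None, rc: float | None = None):
        """Score a cohort on all surviving patches and predict outcomes.

        ``cohort`` may be a list of synthetic patients / (record, panck, cd8)
        triples, a dict patient_id -> patches, or None to re-score the
        training cohort's full sections.  Returns (DataFrame, ConfusionSummary
        or None); the confusion summary is computed over patients with known
        outcome.
        """
        from .stratify import clamp_rc

        rc = clamp_rc(self.rc_final if rc is None else rc)
        if cohort is None:
            patches_by_pid = self.model.patches_by_patient
            outcomes = self.model.outcomes
        elif isinstance(cohort, dict):
            patches_by_pid, outcomes = cohort, {}
        else:
            patches_by_pid, outcomes = _prepare_cohort(cohort, self.model.config)
        preds = []
        cutoff = self.model.config.train.patch_cutoff
        for pid in sorted(patches_by_pid):
            preds.extend(predict_patches(self.classifier, patches_by_pid[pid], cutoff))
        scores = score_patients(preds)
        rows = [
            {
                "patient_id": s.patient_id,
                "n_patches": s.n_patches_evaluated,
                "r_good": s.r_good,
                "predicted": predict_outcome(s, rc),
                "outcome": outcomes.get(s.patient_id, "unknown"),
            }
            for s in scores
        ]
        df = pd.DataFrame(rows)
        cm: ConfusionSummary | None = None
        known = df[df["outcome"].isin(["good", "poor"])]
        if len(known) and set(known["outcome"]) == {"good", "poor"}:
            cm = evaluate(
                dict(zip(known["patient_id"], known["predicted"])),
                dict(zip(known["patient_id"], known["outcome"])),
            )
        return df, cm

    def summary(self) -> str:
        """Human-readable fit summary."""
        sel = self.selection
        lines = [
            "Relapse stratification results",
            "==============================",
            f"patients (labeled):        {sum(1 for o in self.model.outcomes.values() if o in ('good', 'poor'))}",
            f"realizations:              {sel.realizations}",
            f"best patient accuracy:     {self.train_max_accuracy:.3f}",
            f"cut-off Rc:                {sel.rc_final:.3f}",
            "per-realization optimal Rc intervals:",
        ]
        for i, ((lo, hi), used) in enumerate(zip(sel.intervals, sel.used)):
            mark = "*" if used else " "
            lines.append(
                f"  {mark} realization {i}: ({lo:.3f}, {hi:.3f})  "
                f"acc={self.scans[i].max_accuracy:.3f}"
            )
        lines.append("(* = contributes to the averaged Rc)")
        return "\n".join(lines)

    def plot_rc_scan(self, ax=None):
        """Plot patient-level accuracy vs cut-off for each realization."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, scan in enumerate(self.scans):
            ax.step(
                scan.candidates, scan.accuracies, where="post", label=f"realization {i}"
            )
        ax.axvline(self.rc_final, color="k", ls="--", label=f"Rc={self.rc_final:.2f}")
        ax.set_xlabel("cut-off $R_c$ on good-patch fraction")
        ax.set_ylabel("fraction of correctly predicted patients")
        ax.legend(fontsize="small")
        return ax
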