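"""Canned desk-scale experiments on synthetic cohorts.

These drive the full pipeline under the package's reference synthetic
conditions: a training cohort of 15 good / 9 poor patients (mirroring the
original training-cohort composition) with infiltration ranges p_in in
[0.6, 0.9] (good) vs [0.0, 0.2] (poor), an independent test cohort, an
infiltration sweep for monotonicity checks, and section-subsampling
robustness probes.  Everything is deterministic given the experiment seed.
"""

from __future__ import annotations

import pandas as pd

from ._util import mix_seed
from .baselines import cd8_density_in_islands
from .classifier import desk_scale_train_config, predict_patches
from .cohort_io import PipelineConfig
from .model import RelapseStratification, prepare_patient_patches
from .stratify import clamp_rc, evaluate, score_patients, subsample_robustness
from .synthetic import (
    desk_scale_params,
    generate_heterogeneous_patient,
    generate_patient,
    iter_cohort,
)

__all__ = [
    "GOOD_P_IN_RANGE",
    "POOR_P_IN_RANGE",
    "recovery_experiment",
    "infiltration_sweep",
    "robustness_experiment",
]

GOOD_P_IN_RANGE = (0.6, 0.9)
POOR_P_IN_RANGE = (0.0, 0.2)


def recovery_experiment(
    seed: int,
    n_train_good: int = 15,
    n_train_poor: int = 9,
    n_test_good: int = 5,
    n_test_poor: int = 5,
    realizations: int = 3,
    train_cfg=None,
    base_params=None,
) -> dict:
    """Train on a synthetic cohort and classify an independent test cohort.

    Returns a dict with the fitted results object, the test score table and
    test confusion summary, and both cohorts.
    """
    base = base_params or desk_scale_params()
    cfg = PipelineConfig(
        train=train_cfg or desk_scale_train_config(),
        realizations=realizations,
    )

    def _prepare(n_good, n_poor, tag, prefix):
        # stream: raw images of one patient at a time are held in memory
        patches_by_pid, outcomes, p_ins = {}, {}, {}
        cohort = iter_cohort(
            n_good,
            n_poor,
            GOOD_P_IN_RANGE,
            POOR_P_IN_RANGE,
            base=base,
            seed=mix_seed(seed, tag),
            id_prefix=prefix,
        )
        for pt in cohort:
            pid = pt.record.patient_id
            patches_by_pid[pid], _ = prepare_patient_patches(
                pid, pt.panck, pt.cd8, cfg
            )
            outcomes[pid] = pt.truth_outcome
            p_ins[pid] = pt.truth_p_in
        return patches_by_pid, outcomes, p_ins

    train_patches, train_outcomes, train_p_ins = _prepare(
        n_train_good, n_train_poor, 101, "T"
    )
    model = RelapseStratification.from_prepared(train_patches, train_outcomes, cfg)
    results = model.fit(realizations=realizations, seed=seed)

    test_patches, test_outcomes, test_p_ins = _prepare(
        n_test_good, n_test_poor, 202, "X"
    )
    test_df, _ = results.predict(test_patches)
    test_df["outcome"] = test_df["patient_id"].map(test_outcomes)
    test_df["truth_p_in"] = test_df["patient_id"].map(test_p_ins)
    test_cm = evaluate(
        dict(zip(test_df["patient_id"], test_df["predicted"])),
        {pid: test_outcomes[pid] for pid in test_df["patient_id"]},
    )
    return {
        "results": results,
        "test_scores": test_df,
        "test_confusion": test_cm,
        "train_p_ins": train_p_ins,
        "test_p_ins": test_p_ins,
    }


def infiltration_sweep(
    classifier,
    p_ins,
    reps: int = 3,
    seed: int = 0,
    base_params=None,
    patch_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Good-patch fraction and CD8-in-island density across infiltration levels.

    Generates ``reps`` patients at each ``p_in``, scores each on all its
    surviving patches with ``classifier`` (Rtn column), and computes the
    density baseline on the cleaned masks.  Patients with no surviving
    patches get a missing Rtn.
    """
    import dataclasses

    base = base_params or desk_scale_params()
    rows = []
    for i, p_in in enumerate(p_ins):
        for rep in range(reps):
            pt_params = dataclasses.replace(
                base, p_in=float(p_in), seed=mix_seed(seed, 1000 + 10 * i + rep)
            )
            pid = f"sweep_{i}_{rep}"
            pt = generate_patient(pt_params, patient_id=pid)
            patches, mp = prepare_patient_patches(pid, pt.panck, pt.cd8, None)
            density = cd8_density_in_islands(mp) if mp.panck.any() else float("nan")
            if patches:
                preds = predict_patches(classifier, patches, patch_cutoff)
                (score,) = score_patients(preds)
                rtn = score.r_good
            else:
                rtn = float("nan")
            rows.append(
                {
                    "p_in": float(p_in),
                    "rep": rep,
                    "n_patches": len(patches),
                    "rtn": rtn,
                    "cd8_density_in_islands": density,
                }
            )
    return pd.DataFrame(rows)


def robustness_experiment(
    classifier,
    rc: float,
    seed: int = 0,
    base_params=None,
    n_repeats: int = 10,
) -> dict:
    """Section-subsampling stability on heterogeneous vs homogeneous tumors.

    The heterogeneous patient is stitched from two halves with p_in 0.9 and
    0.1 — its two contiguous half-sections should predict opposite outcomes.
    The homogeneous patient has uniform p_in 0.8 (firmly in the good range)
    — random half-subsamples should agree with the full-section prediction.
    """
    base = base_params or desk_scale_params()
    import dataclasses

    rc = clamp_rc(rc)
    hetero = generate_heterogeneous_patient(
        dataclasses.replace(base, p_in=0.9, seed=mix_seed(seed, 31)),
        dataclasses.replace(base, p_in=0.1, seed=mix_seed(seed, 32)),
        patient_id="hetero",
    )
    het_patches, _ = prepare_patient_patches(
        "hetero", hetero.panck, hetero.cd8, None
    )
    het_report = subsample_robustness(
        het_patches, 0.5, "contiguous", classifier, rc
    )
    homog = generate_patient(
        dataclasses.replace(base, p_in=0.8, seed=mix_seed(seed, 33)),
        patient_id="homog",
    )
    hom_patches, _ = prepare_patient_patches("homog", homog.panck, homog.cd8, None)
    hom_report = subsample_robustness(
        hom_patches, 0.5, "random", classifier, rc, n_repeats=n_repeats, seed=seed
    )
    return {"heterogeneous": het_report, "homogeneous": hom_report}
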