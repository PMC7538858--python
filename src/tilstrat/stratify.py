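"""Patient-level aggregation, cut-off selection, prediction and evaluation.

The per-patient statistic is the fraction of that patient's evaluated patches
classified as "good" (written Rtn when computed on a validation holdout, Rt on
test patients).  A patient is predicted to relapse ("poor") when the fraction
falls strictly below a cut-off Rc; Rc is chosen by scanning all effective cut
points on the validation cohort across several holdout/training realizations
and averaging the accuracy-optimal intervals' midpoints.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._util import mix_seed
from .classifier import PatchPrediction, predict_patches
from .patchify import Patch

__all__ = [
    "PatientScore",
    "ThresholdScan",
    "RcSelection",
    "ConfusionSummary",
    "RobustnessReport",
    "score_patients",
    "scan_rc",
    "select_rc",
    "predict_outcome",
    "evaluate",
    "subsample_robustness",
]


@dataclass(frozen=True)
class PatientScore:
    """Good-patch fraction of one patient over the patches evaluated."""

    patient_id: str
    n_patches_evaluated: int
    r_good: float

    def __post_init__(self):
        if self.n_patches_evaluated < 1:
            raise ValueError("a score requires at least one evaluated patch")
        if not (0.0 <= self.r_good <= 1.0):
            raise ValueError("r_good must lie in [0, 1]")


@dataclass(frozen=True)
class ThresholdScan:
    """Accuracy of the rule (poor iff r_good < Rc) over all effective cut-offs."""

    candidates: np.ndarray  # evaluated cut-off values
    accuracies: np.ndarray  # patient-level accuracy at each candidate
    lo: float  # maximal accuracy-optimal open interval (lo, hi)
    hi: float
    max_accuracy: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)


@dataclass(frozen=True)
class RcSelection:
    """Final cut-off chosen from several holdout/training realizations."""

    intervals: list[tuple[float, float]]  # per-realization optimal intervals
    used: list[bool]  # which realizations attained the global max accuracy
    realizations: int
    rc_final: float


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with poor outcome as the positive class."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


def score_patients(
    predictions: list[PatchPrediction],
) -> list[PatientScore]:
    """Aggregate patch predictions into per-patient good-patch fractions.

    Returns one score per patient (sorted by id).  Patients appear only if
    they have at least one evaluated patch; callers track unpredictable
    patients (zero surviving patches) separately.
    """
    by_pid: dict[str, list[PatchPrediction]] = defaultdict(list)
    for pred in predictions:
        by_pid[pred.patient_id].append(pred)
    scores = []
    for pid in sorted(by_pid):
        preds = by_pid[pid]
        n_good = sum(1 for p in preds if p.label == "good")
        scores.append(
            PatientScore(
                patient_id=pid,
                n_patches_evaluated=len(preds),
                r_good=n_good / len(preds),
            )
        )
    return scores


def _scan_cutoffs(values: np.ndarray, is_poor: np.ndarray, lo_end: float, hi_end: float):
    """Evaluate the rule (predict poor iff value < c) at all effective cut points.

    Candidates are the midpoints of consecutive distinct sorted values plus
    the two endpoints; accuracy is piecewise constant between distinct
    values, so this scan is exhaustive.  Returns (candidates, accuracies,
    (lo, hi), max_accuracy) where (lo, hi) is the maximal-accuracy open
    interval; if several disjoint intervals tie, the widest (then lowest) is
    returned.
    """
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([lo_end], mids, [hi_end]))
    accs = np.array(
        [((values < c) == is_poor).mean() for c in candidates]
    )
    max_acc = accs.max()
    best = accs == max_acc
    # bounding values for each candidate interval
    knots = np.concatenate(([lo_end], distinct, [hi_end]))
    # candidate i lies in (knots[i], knots[i+1]) except endpoints; build runs
    runs: list[tuple[int, int]] = []
    start = None
    for i, b in enumerate(best):
        if b and start is None:
            start = i
        if not b and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(best) - 1))

    def _bounds(run):
        i0, i1 = run
        lo = lo_end if i0 == 0 else distinct[i0 - 1]
        hi = hi_end if i1 == len(candidates) - 1 else distinct[i1]
        return float(lo), float(hi)

    bounds = [_bounds(r) for r in runs]
    # widest optimal interval; ties broken toward the lowest cut-off
    lo, hi = max(bounds, key=lambda b: (b[1] - b[0], -b[0]))
    return candidates, accs, (lo, hi), float(max_acc)


def scan_rc(
    scores: list[PatientScore], truths: dict[str, str]
) -> ThresholdScan:
    """Scan the good-patch-fraction cut-off Rc over a labeled cohort.

    ``truths`` maps patient_id -> "good"/"poor".  Both outcome groups must be
    present.  Accuracy is evaluated at the midpoints between consecutive
    distinct scores plus the endpoints 0 and 1; the maximal-accuracy open
    interval of Rc values is reported.
    """
    vals = np.array([s.r_good for s in scores])
    try:
        is_poor = np.array([truths[s.patient_id] == "poor" for s in scores])
    except KeyError as e:
        raise ValueError(f"missing truth label for patient {e.args[0]!r}") from None
    if len(vals) == 0 or is_poor.all() or not is_poor.any():
        raise ValueError("scan_rc requires at least one patient per outcome group")
    candidates, accs, (lo, hi), max_acc = _scan_cutoffs(vals, is_poor, 0.0, 1.0)
    return ThresholdScan(
        candidates=candidates, accuracies=accs, lo=lo, hi=hi, max_accuracy=max_acc
    )


def select_rc(realization_scans: list[ThresholdScan]) -> RcSelection:
    """Average the optimal-interval midpoints over the best realizations.

    Realizations whose maximal accuracy falls short of the best accuracy seen
    across realizations (e.g. those failing the perfect separation others
    achieve) are excluded from the average.
    """
    if not realization_scans:
        raise ValueError("select_rc requires at least one realization")
    best = max(s.max_accuracy for s in realization_scans)
    used = [s.max_accuracy == best for s in realization_scans]
    mids = [s.midpoint for s, u in zip(realization_scans, used) if u]
    return RcSelection(
        intervals=[(s.lo, s.hi) for s in realization_scans],
        used=used,
        realizations=len(realization_scans),
        rc_final=float(np.mean(mids)),
    )


def clamp_rc(rc: float) -> float:
    """Clamp a degenerate cut-off (0 or 1, from a failed scan) into (0, 1)."""
    if not (0.0 < rc < 1.0):
        warnings.warn(f"cut-off {rc} outside (0, 1); clamping")
        rc = min(max(rc, 1e-9), 1.0 - 1e-9)
    return rc


def predict_outcome(score: PatientScore, rc: float) -> str:
    """Predict poor iff the good-patch fraction is strictly below rc.

    Equality (r_good == rc) is predicted good: the defining inequalities are
    strict on both sides and the tie must be broken one way; ties are
    measure-zero for continuous scores.
    """
    if not (0.0 < rc < 1.0):
        raise ValueError("rc must lie in (0, 1)")
    return "poor" if score.r_good < rc else "good"


def evaluate(predictions: dict[str, str], truths: dict[str, str]) -> ConfusionSummary:
    """Confusion counts and derived statistics, with poor as positive class."""
    if set(predictions) != set(truths):
        missing = set(predictions) ^ set(truths)
        raise ValueError(f"prediction/truth patient ids differ: {sorted(missing)[:5]}")
    tp = fp = fn = tn = 0
    for pid, pred in predictions.items():
        truth = truths[pid]
        if pred not in ("good", "poor") or truth not in ("good", "poor"):
            raise ValueError(f"invalid label for patient {pid!r}: {pred!r}/{truth!r}")
        if truth == "poor" and pred == "poor":
            tp += 1
        elif truth == "good" and pred == "poor":
            fp += 1
        elif truth == "poor" and pred == "good":
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class RobustnessReport:
    """Stability of one patient's prediction under section subsampling."""

    patient_id: str
    full_outcome: str
    fraction: float
    mode: str
    subsample_outcomes: list[str] = field(default_factory=list)
    agreement_rate: float = float("nan")


def subsample_robustness(
    patches: list[Patch],
    fraction: float,
    mode: str,
    model,
    rc: float,
    n_repeats: int = 10,
    seed: int = 0,
    patch_cutoff: float = 0.5,
) -> RobustnessReport:
    """How stable is a patient's prediction when only part of the section is used?

    ``mode="contiguous"`` splits the tile grid into ``round(1/fraction)``
    spatially contiguous column blocks (halves or quarters of the section)
    and predicts each block; ``mode="random"`` draws ``n_repeats`` random
    patch subsets of the given fraction without replacement.  The report
    records each subsample's predicted outcome and the agreement rate with
    the full-section prediction.
    """
    if len(patches) < 4:
        raise ValueError("subsample robustness requires at least 4 patches")
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must lie in (0, 1]")
    pid = patches[0].patient_id
    if any(p.patient_id != pid for p in patches):
        raise ValueError("all patches must come from one patient")

    def _outcome(subset: list[Patch]) -> str:
        preds = predict_patches(model, subset, patch_cutoff)
        (score,) = score_patients(preds)
        return predict_outcome(score, rc)

    full = _outcome(patches)
    if fraction == 1.0:
        return RobustnessReport(pid, full, fraction, mode, [full], 1.0)

    outcomes: list[str] = []
    if mode == "contiguous":
        n_blocks = max(int(round(1.0 / fraction)), 2)
        ordered = sorted(patches, key=lambda p: (p.col, p.row))
        for block in np.array_split(np.arange(len(ordered)), n_blocks):
            if len(block) == 0:
                continue
            outcomes.append(_outcome([ordered[i] for i in block]))
    elif mode == "random":
        rng = np.random.default_rng(mix_seed(seed, 0x5AB5))
        k = max(int(round(fraction * len(patches))), 1)
        for _ in range(n_repeats):
            idx = rng.choice(len(patches), size=k, replace=False)
            outcomes.append(_outcome([patches[i] for i in idx]))
    else:
        raise ValueError("mode must be 'contiguous' or 'random'")
    agreement = float(np.mean([o == full for o in outcomes]))
    return RobustnessReport(pid, full, fraction, mode, outcomes, agreement)
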