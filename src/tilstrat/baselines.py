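"""Density/area baselines the patch pipeline is benchmarked against.

Two conventional TIL metrics computed directly on the cleaned masks: the
density of CD8+ pixels inside cancer-cell islands (CD8 pixels within the
hole-filled PanCK mask divided by PanCK pixels) and the absolute stained
areas in um^2.  Stratifying on either with a manually optimized cut-off is
the comparison point for the learned patch statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import MaskPair
from .stratify import _scan_cutoffs

__all__ = [
    "BaselineMetrics",
    "cd8_density_in_islands",
    "absolute_areas",
    "best_cutoff_accuracy",
    "compute_baseline_metrics",
]


@dataclass(frozen=True)
class BaselineMetrics:
    patient_id: str
    cd8_density_in_islands: float
    cd8_area_um2: float
    panck_area_um2: float


def cd8_density_in_islands(mp: MaskPair) -> float:
    """CD8+ pixels inside the (hole-filled) PanCK mask per PanCK+ pixel.

    The standard pipeline's PanCK mask is already hole-filled, so intra-islet
    stroma gaps below the hole limit count as island interior.  Raises when
    the PanCK mask is empty (density undefined).
    """
    n_panck = int(mp.panck.sum())
    if n_panck == 0:
        raise ValueError("empty PanCK mask: CD8-in-island density is undefined")
    n_inside = int((mp.cd8 & mp.panck).sum())
    return n_inside / n_panck


def absolute_areas(mp: MaskPair) -> tuple[float, float]:
    """(CD8 area, PanCK area) in um^2: pixel counts x pixel_size^2."""
    a = mp.pixel_size_um**2
    return float(mp.cd8.sum() * a), float(mp.panck.sum() * a)


def compute_baseline_metrics(patient_id: str, mp: MaskPair) -> BaselineMetrics:
    cd8_area, panck_area = absolute_areas(mp)
    return BaselineMetrics(
        patient_id=patient_id,
        cd8_density_in_islands=cd8_density_in_islands(mp),
        cd8_area_um2=cd8_area,
        panck_area_um2=panck_area,
    )


def best_cutoff_accuracy(
    values: dict[str, float],
    truths: dict[str, str],
    direction: str = "low_is_poor",
) -> tuple[float, float]:
    """Accuracy-maximizing manual cut-off on one scalar metric.

    Scans all effective cut points (midpoints of consecutive distinct values
    plus outer sentinels).  With ``direction="low_is_poor"`` a patient is
    predicted poor when its value is strictly below the cut-off;
    ``"high_is_poor"`` flips the rule.  Returns (cutoff, max_accuracy) where
    the cutoff is the midpoint of the optimal interval.
    """
    if direction not in ("low_is_poor", "high_is_poor"):
        raise ValueError("direction must be 'low_is_poor' or 'high_is_poor'")
    pids = sorted(values)
    if set(pids) != set(truths):
        raise ValueError("values and truths must cover the same patients")
    v = np.array([values[p] for p in pids], dtype=float)
    is_poor = np.array([truths[p] == "poor" for p in pids])
    if is_poor.all() or not is_poor.any():
        raise ValueError("both outcome groups must be present")
    sign = 1.0 if direction == "low_is_poor" else -1.0
    sv = sign * v
    lo_end, hi_end = sv.min() - 1.0, sv.max() + 1.0
    _, _, (lo, hi), max_acc = _scan_cutoffs(sv, is_poor, lo_end, hi_end)
    cutoff = sign * 0.5 * (lo + hi)
    return float(cutoff), float(max_acc)
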