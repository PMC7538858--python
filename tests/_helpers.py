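"""Tiny deterministic helpers shared across test modules."""

from __future__ import annotations

import numpy as np

from tilstrat.patchify import Patch
from tilstrat.synthetic import SyntheticParams


def tiny_params(**overrides) -> SyntheticParams:
    """A small, fast synthetic patient (512x512 px at 2 um/px, ~3% island cover)."""
    base = dict(
        canvas_size_px=(512, 512),
        pixel_size_um=2.0,
        n_islands=5,
        island_radius_um=(30.0, 60.0),
        n_tcells=60,
        p_in=0.5,
        tumor_axes_frac=(0.35, 0.35),
        seed=0,
    )
    base.update(overrides)
    return SyntheticParams(**base)


def toy_patch(
    poor: bool,
    rng: np.random.Generator,
    patient_id: str = "toy",
    row: int = 0,
    col: int = 0,
    n_cells: int = 6,
) -> Patch:
    """Separable 64x64 toy patch: CD8 blobs inside (good) or outside (poor)
    a central PanCK square."""
    panck = np.zeros((64, 64), bool)
    panck[16:48, 16:48] = True
    cd8 = np.zeros((64, 64), bool)
    for _ in range(n_cells):
        if poor:
            while True:
                r, c = rng.integers(2, 62, 2)
                if not panck[r, c]:
                    break
        else:
            r, c = rng.integers(18, 46, 2)
        cd8[r - 2 : r + 2, c - 2 : c + 2] = True
    return Patch(panck=panck, cd8=cd8, patient_id=patient_id, row=row, col=col)


def toy_patch_set(n_per_class: int, seed: int = 0, patient_id: str = "toy"):
    """Balanced separable toy patches with labels (poor=1, good=0)."""
    rng = np.random.default_rng(seed)
    patches, labels = [], []
    for i in range(n_per_class):
        patches.append(toy_patch(False, rng, patient_id, row=0, col=i))
        labels.append(0)
        patches.append(toy_patch(True, rng, patient_id, row=1, col=i))
        labels.append(1)
    return patches, labels


class OracleModel:
    """Deterministic stand-in classifier scoring the generative rule directly.

    prob_poor = fraction of CD8 pixels lying *outside* the PanCK mask.  Used
    where a test needs consistent patch labels without CNN training.
    """

    def predict_proba(self, patches):
        from tilstrat.patchify import patches_to_array

        x = patches if isinstance(patches, np.ndarray) else patches_to_array(patches)
        panck, cd8 = x[:, 0] > 0.5, x[:, 1] > 0.5
        n_cd8 = cd8.sum(axis=(1, 2))
        outside = (cd8 & ~panck).sum(axis=(1, 2))
        with np.errstate(invalid="ignore"):
            frac = np.where(n_cd8 > 0, outside / np.maximum(n_cd8, 1), 0.5)
        return frac
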