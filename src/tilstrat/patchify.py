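"""Rescale cleaned masks to a common micron grid and tile into filtered patches.

All cohorts are brought to the same physical scale (default 10 um/px) by
integer block reduction, then cut into adjacent 64x64 patches.  Patches with
too little cancer tissue (< 1/4 PanCK-positive pixels) or with no CD8 signal
are discarded; the survivors are the classifier's input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._util import as_bool_mask
from .preprocess import MaskPair

__all__ = [
    "ScaledMaskPair",
    "Patch",
    "rescale_mask_pair",
    "tile_patches",
    "filter_patches",
    "patches_to_array",
    "render_patch_rgb",
]


@dataclass(frozen=True, eq=False)
class ScaledMaskPair:
    """Binary mask pair on the common coarse grid (default 10 um/px)."""

    panck: np.ndarray
    cd8: np.ndarray
    pixel_size_um: float = 10.0

    def __post_init__(self):
        pk = as_bool_mask(self.panck, "panck")
        cd = as_bool_mask(self.cd8, "cd8")
        if pk.shape != cd.shape:
            raise ValueError(f"mask shapes differ: {pk.shape} vs {cd.shape}")
        object.__setattr__(self, "panck", pk)
        object.__setattr__(self, "cd8", cd)


@dataclass(frozen=True, eq=False)
class Patch:
    """One two-channel binary tile with provenance.

    ``row``/``col`` are 0-based tile indices from the top-left corner of the
    scaled image; ``n_panck``/``n_cd8`` are positive-pixel counts per channel.
    """

    panck: np.ndarray
    cd8: np.ndarray
    patient_id: str
    row: int
    col: int
    n_panck: int = field(default=-1)
    n_cd8: int = field(default=-1)

    def __post_init__(self):
        pk = as_bool_mask(self.panck, "panck")
        cd = as_bool_mask(self.cd8, "cd8")
        if pk.shape != cd.shape:
            raise ValueError("patch channel shapes differ")
        object.__setattr__(self, "panck", pk)
        object.__setattr__(self, "cd8", cd)
        if self.n_panck < 0:
            object.__setattr__(self, "n_panck", int(pk.sum()))
        if self.n_cd8 < 0:
            object.__setattr__(self, "n_cd8", int(cd.sum()))

    @property
    def size(self) -> int:
        return self.panck.shape[0]


def rescale_mask_pair(
    mp: MaskPair, target_um: float = 10.0, ratio_tol: float = 0.03
) -> ScaledMaskPair:
    """Downscale a MaskPair to ``target_um`` per pixel by integer block reduction.

    The block size is ``k = round(target_um / pixel_size_um)``; the image is
    cropped to whole blocks.  A coarse PanCK pixel is positive when at least
    half the fine pixels in its block are (majority vote, preserves islet
    area); a coarse CD8 pixel is positive when *any* fine pixel in the block
    is (presence vote: a single T-cell cluster is sub-pixel at 10 um and a
    majority vote would erase it).

    Raises on upscaling requests and when the scale ratio deviates from an
    integer by more than ``ratio_tol`` (then the input should be resampled to
    a compatible grid first).
    """
    px = mp.pixel_size_um
    if target_um < px:
        raise ValueError(
            f"upscaling not supported: target {target_um} um < native {px} um"
        )
    ratio = target_um / px
    k = max(int(round(ratio)), 1)
    if abs(ratio - k) / ratio > ratio_tol:
        raise ValueError(
            f"scale ratio {ratio:.4f} is not within {ratio_tol:.0%} of an integer "
            "block size; resample the input to a compatible pixel size first"
        )
    if k == 1:
        return ScaledMaskPair(mp.panck.copy(), mp.cd8.copy(), pixel_size_um=target_um)
    h, w = mp.panck.shape
    hh, ww = (h // k) * k, (w // k) * k
    if hh == 0 or ww == 0:
        empty = np.zeros((h // k, w // k), dtype=bool)
        return ScaledMaskPair(empty, empty.copy(), pixel_size_um=target_um)

    def _blocks(m):
        return m[:hh, :ww].reshape(hh // k, k, ww // k, k)

    panck = _blocks(mp.panck).mean(axis=(1, 3)) >= 0.5
    cd8 = _blocks(mp.cd8).any(axis=(1, 3))
    return ScaledMaskPair(panck, cd8, pixel_size_um=target_um)


def tile_patches(
    smp: ScaledMaskPair, size_px: int = 64, patient_id: str = ""
) -> list[Patch]:
    """Cut a scaled mask pair into adjacent, non-overlapping size_px tiles.

    The grid starts at the top-left corner; partial tiles at the right/bottom
    edges are dropped (no padding).  Images smaller than one tile yield an
    empty list.
    """
    if size_px < 1:
        raise ValueError("size_px must be positive")
    h, w = smp.panck.shape
    out: list[Patch] = []
    for r in range(h // size_px):
        for c in range(w // size_px):
            sl = (
                slice(r * size_px, (r + 1) * size_px),
                slice(c * size_px, (c + 1) * size_px),
            )
            out.append(
                Patch(
                    panck=smp.panck[sl].copy(),
                    cd8=smp.cd8[sl].copy(),
                    patient_id=patient_id,
                    row=r,
                    col=c,
                )
            )
    return out


def filter_patches(
    patches: list[Patch], min_panck_frac: float = 0.25, min_cd8: int = 1
) -> list[Patch]:
    """Keep patches with enough cancer tissue and at least some CD8 signal.

    A patch survives iff ``n_panck >= ceil(min_panck_frac * size**2)`` (for the
    default quarter rule on 64x64 patches: >= 1024 of 4096 pixels) and
    ``n_cd8 >= min_cd8``.  Pure subset operation: surviving patches are the
    original tiles, order preserved.
    """
    out = []
    for p in patches:
        need = math.ceil(min_panck_frac * p.size**2)
        if p.n_panck >= need and p.n_cd8 >= min_cd8:
            out.append(p)
    return out


def patches_to_array(patches: list[Patch]) -> np.ndarray:
    """Stack patches into a float32 array (N, 2, H, W), channels (PanCK, CD8)."""
    if not patches:
        s = 64
        return np.zeros((0, 2, s, s), dtype=np.float32)
    return np.stack(
        [np.stack([p.panck, p.cd8]).astype(np.float32) for p in patches]
    )


def render_patch_rgb(patch: Patch) -> np.ndarray:
    """Render a patch as uint8 RGB: PanCK white, CD8 red (on top), stroma black."""
    h, w = patch.panck.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    rgb[patch.panck] = (255, 255, 255)
    rgb[patch.cd8] = (255, 0, 0)
    return rgb
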