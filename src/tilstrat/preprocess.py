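"""Raw two-channel intensity images -> cleaned co-registered binary masks.

This is the first processing stage of the pipeline: each immunofluorescence
channel (PanCK marking cancer cells, CD8 marking cytotoxic T cells) is
binarized with a per-image percentile threshold, small connected components
(IF noise) are removed from both channels, and small enclosed holes (dark
cancer-cell cytosol under a membrane stain) are filled in the PanCK channel
only.  The cleaned pair of masks at native resolution is the unit passed to
rescaling/patch extraction and to the density baselines.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import as_bool_mask

__all__ = [
    "IntensityImage",
    "MaskPair",
    "PreprocessConfig",
    "binarize_channel",
    "remove_small_components",
    "fill_small_holes",
    "make_mask_pair",
]

# 8-connected foreground, 4-connected background (standard digital-topology duality)
_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True, eq=False)
class IntensityImage:
    """One channel of raw IF intensity with a physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative, finite intensities.
    pixel_size_um : float
        Physical edge length of one pixel in micrometres (> 0).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=float)
        if p.ndim != 2 or p.size == 0:
            raise ValueError(f"pixels must be a non-empty 2-D array, got shape {p.shape}")
        if not np.isfinite(p).all():
            raise ValueError("pixels must be finite")
        if p.min() < 0:
            raise ValueError("pixels must be non-negative")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", p)

    @property
    def shape(self):
        return self.pixels.shape


@dataclass(frozen=True, eq=False)
class MaskPair:
    """Co-registered cleaned binary PanCK / CD8 masks at native resolution."""

    panck: np.ndarray
    cd8: np.ndarray
    pixel_size_um: float

    def __post_init__(self):
        pk = as_bool_mask(self.panck, "panck")
        cd = as_bool_mask(self.cd8, "cd8")
        if pk.shape != cd.shape:
            raise ValueError(f"mask shapes differ: {pk.shape} vs {cd.shape}")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "panck", pk)
        object.__setattr__(self, "cd8", cd)


@dataclass(frozen=True)
class PreprocessConfig:
    """Binarization/cleaning parameters.

    percentile_q : per-image threshold percentile (positive = strictly above it)
    min_component_um2 : connected components with area strictly below this are removed
    max_hole_um2 : enclosed background holes with area strictly below this are
        filled, PanCK channel only
    """

    percentile_q: float = 90.0
    min_component_um2: float = 200.0
    max_hole_um2: float = 200.0


def binarize_channel(img: IntensityImage, percentile_q: float = 90.0) -> np.ndarray:
    """Threshold one channel at its own nearest-rank percentile.

    The threshold t is the nearest-rank ``percentile_q``-th percentile of all
    pixel intensities of *this* image (rank ``ceil(q/100 * N)`` of the sorted
    values); output is 1 where intensity is strictly greater than t.  The
    threshold is per-image, so staining/exposure differences between patients
    do not require a global calibration.

    A constant image yields an all-zero mask (and a warning): under the strict
    inequality nothing exceeds its own value.
    """
    if not (0 < percentile_q < 100):
        raise ValueError("percentile_q must be in (0, 100)")
    flat = img.pixels.ravel()
    n = flat.size
    rank = int(math.ceil(percentile_q / 100.0 * n))  # 1-based nearest rank
    rank = min(max(rank, 1), n)
    t = np.partition(flat, rank - 1)[rank - 1]
    mask = img.pixels > t
    if not mask.any() and flat.min() == flat.max():
        warnings.warn("constant image: binarization produced an all-zero mask")
    return mask


def remove_small_components(
    mask: np.ndarray, min_area_um2: float, pixel_size_um: float
) -> np.ndarray:
    """Drop 8-connected foreground components with physical area < min_area_um2.

    Idempotent; components with area exactly equal to the limit are kept
    (strict "smaller than" rule).
    """
    m = as_bool_mask(mask)
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be positive")
    labels, n = ndimage.label(m, structure=_STRUCT_8)
    if n == 0:
        return m.copy()
    counts = np.bincount(labels.ravel())
    area_um2 = counts * pixel_size_um**2
    small = area_um2 < min_area_um2
    small[0] = False  # background
    return m & ~small[labels]


def fill_small_holes(
    mask: np.ndarray, max_area_um2: float, pixel_size_um: float
) -> np.ndarray:
    """Fill enclosed 4-connected background holes with physical area < max_area_um2.

    A hole is a background component not touching the image border.  Used on
    the PanCK channel, where the membrane stain leaves the cytosol dark and
    the cancer-islet area would otherwise be under-counted.  Idempotent.
    """
    m = as_bool_mask(mask)
    if not (pixel_size_um > 0):
        raise ValueError("pixel_size_um must be positive")
    labels, n = ndimage.label(~m, structure=_STRUCT_4)
    if n == 0:
        return m.copy()
    border_labels = np.unique(
        np.concatenate([labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])
    )
    counts = np.bincount(labels.ravel())
    area_um2 = counts * pixel_size_um**2
    fill = area_um2 < max_area_um2
    fill[0] = False
    fill[border_labels] = False
    return m | fill[labels]


def make_mask_pair(
    panck_img: IntensityImage,
    cd8_img: IntensityImage,
    config: PreprocessConfig | None = None,
) -> MaskPair:
    """Binarize and clean both channels into a co-registered MaskPair.

    PanCK: binarize -> remove small components -> fill small holes.
    CD8:   binarize -> remove small components (no hole filling; CD8 puncta
    are solid at this scale and holes are a membrane-stain artifact specific
    to PanCK).
    """
    cfg = config or PreprocessConfig()
    if panck_img.shape != cd8_img.shape:
        raise ValueError(
            f"channel shapes differ: {panck_img.shape} vs {cd8_img.shape}"
        )
    if panck_img.pixel_size_um != cd8_img.pixel_size_um:
        raise ValueError("channel pixel sizes differ")
    px = panck_img.pixel_size_um
    panck = remove_small_components(
        binarize_channel(panck_img, cfg.percentile_q), cfg.min_component_um2, px
    )
    panck = fill_small_holes(panck, cfg.max_hole_um2, px)
    cd8 = remove_small_components(
        binarize_channel(cd8_img, cfg.percentile_q), cfg.min_component_um2, px
    )
    return MaskPair(panck=panck, cd8=cd8, pixel_size_um=px)
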