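"""Synthetic two-channel IF-like cohorts with a known infiltration ground truth.

The generator emulates the structure the stratification pipeline keys on:
bright, irregular cancer-cell islands (PanCK channel) clustered in a central
tumor bed on dark stroma, and small punctate CD8 blobs (CD8 channel) placed
either inside the island union or in the stroma.  A single per-patient
parameter ``p_in`` — the probability that a T-cell cluster lands inside an
island — encodes the relative infiltration level of CD8+ T cells into
cancer-cell islands, and the outcome label is tied to it (high infiltration
-> good outcome).  The exact island union used for placement is stored on the
generated patient so placement can be checked against it.

Everything is deterministic given the parameter seed; cohort generation
derives per-patient child seeds through a fixed integer mix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._util import mix_seed
from .cohort_io import PatientRecord, write_manifest
from .preprocess import IntensityImage

__all__ = [
    "SyntheticParams",
    "SyntheticPatient",
    "desk_scale_params",
    "generate_patient",
    "generate_cohort",
    "generate_heterogeneous_patient",
    "write_cohort",
]


@dataclass(frozen=True)
class SyntheticParams:
    """Parameters of one synthetic patient image pair.

    canvas_size_px : (height, width) of both channels in pixels
    pixel_size_um : physical pixel size (um/px)
    n_islands : number of cancer islands drawn in the tumor bed
    island_radius_um : (lo, hi) range of island semi-axis lengths in um
    n_tcells : number of CD8 puncta (small T-cell clusters) placed
    tcell_radius_um : disc radius of one CD8 punctum in um; the default 8.5 um
        (~227 um^2) represents a tight cluster of a few adjacent CD8+ cells
        whose membrane stain merges, and is deliberately above the 200 um^2
        noise-removal floor of the cleaning stage so that genuine CD8 signal
        survives preprocessing
    p_in : probability that a punctum is placed inside the island union
        (the infiltration parameter driving outcome)
    signal_level : mean intensity added on signal pixels
    noise_sd : sd of additive zero-mean Gaussian noise (clipped at 0)
    tumor_axes_frac : semi-axes of the central tumor-bed ellipse, as a
        fraction of (width, height); islands are seeded inside it
    seed : RNG seed; identical params -> bit-identical images
    """

    canvas_size_px: tuple[int, int] = (3840, 3840)
    pixel_size_um: float = 0.5
    n_islands: int = 70
    island_radius_um: tuple[float, float] = (70.0, 140.0)
    n_tcells: int = 300
    tcell_radius_um: float = 8.5
    p_in: float = 0.5
    signal_level: float = 200.0
    noise_sd: float = 20.0
    tumor_axes_frac: tuple[float, float] = (0.32, 0.26)
    seed: int = 0

    def __post_init__(self):
        h, w = self.canvas_size_px
        if h < 1 or w < 1:
            raise ValueError("canvas_size_px must be positive")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        lo, hi = self.island_radius_um
        if not (0 < lo <= hi):
            raise ValueError("island_radius_um must be a positive (lo, hi) range")
        if not (self.tcell_radius_um > 0):
            raise ValueError("tcell_radius_um must be positive")
        if not (0.0 <= self.p_in <= 1.0):
            raise ValueError("p_in must lie in [0, 1]")
        if self.n_islands < 0 or self.n_tcells < 0:
            raise ValueError("counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (self.signal_level > 0):
            raise ValueError("signal_level must be positive")


def desk_scale_params(**overrides) -> SyntheticParams:
    """Desk-scale study conditions used for cohort-level experiments.

    A 3.84 x 3.84 mm section sampled at 2 um/px: large enough that several
    64x64 patches at 10 um/px survive filtering per patient, small enough
    that whole-cohort experiments run on one CPU in minutes.
    """
    base = dict(canvas_size_px=(1920, 1920), pixel_size_um=2.0)
    base.update(overrides)
    return SyntheticParams(**base)


@dataclass(frozen=True, eq=False)
class SyntheticPatient:
    """Generated image pair plus the ground truth used to build it."""

    panck: IntensityImage
    cd8: IntensityImage
    truth_outcome: str  # "good" | "poor" | "unknown"
    truth_p_in: float
    record: PatientRecord
    island_mask: np.ndarray = field(repr=False, default=None)
    tcell_centers: np.ndarray = field(repr=False, default=None)  # (n, 2) row, col
    tcell_inside: np.ndarray = field(repr=False, default=None)  # (n,) bool


def _rasterize_island(mask, cy, cx, a_px, b_px, theta, rng):
    """Draw one randomly perturbed ellipse into ``mask`` (in place).

    The boundary radius is modulated by a low-order Fourier series so islands
    have irregular, but hole-free, margins.
    """
    h, w = mask.shape
    rmax = max(a_px, b_px) * 1.35  # head-room for boundary perturbation
    r0 = max(int(cy - rmax), 0)
    r1 = min(int(cy + rmax) + 1, h)
    c0 = max(int(cx - rmax), 0)
    c1 = min(int(cx + rmax) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - cy
    dx = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a_px
    v = (-dx * st + dy * ct) / b_px
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    amp = rng.uniform(0.0, 0.12, size=4)
    phase = rng.uniform(0.0, 2 * np.pi, size=4)
    bound = 1.0
    for k, (a_k, p_k) in enumerate(zip(amp, phase), start=2):
        bound = bound + a_k * np.cos(k * phi + p_k)
    mask[r0:r1, c0:c1] |= rho <= bound


def _rasterize_disc(img, cy, cx, r_px, value):
    h, w = img.shape
    r0 = max(int(cy - r_px), 0)
    r1 = min(int(cy + r_px) + 1, h)
    c0 = max(int(cx - r_px), 0)
    c1 = min(int(cx + r_px) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
    sub = img[r0:r1, c0:c1]
    sub[inside] = np.maximum(sub[inside], value)


def generate_patient(
    params: SyntheticParams,
    patient_id: str = "synthetic",
    outcome: str = "unknown",
) -> SyntheticPatient:
    """Generate one synthetic two-channel patient image pair.

    PanCK channel: ``n_islands`` perturbed ellipses seeded inside the central
    tumor-bed ellipse, at intensity ``signal_level`` on a dark background.
    CD8 channel: ``n_tcells`` discs, each placed with probability ``p_in``
    uniformly inside the island union and otherwise uniformly in stroma.
    Zero-mean Gaussian noise of sd ``noise_sd`` is added to both channels and
    intensities are clipped at 0.  Deterministic given ``params.seed``.
    """
    h, w = params.canvas_size_px
    px = params.pixel_size_um
    rlo, rhi = params.island_radius_um
    if params.n_islands > 0 and min(h, w) * px < 2 * rhi:
        raise ValueError(
            f"canvas {h}x{w} px at {px} um/px cannot hold an island of radius "
            f"{rhi} um"
        )
    if params.n_islands == 0 and params.p_in > 0 and params.n_tcells > 0:
        raise ValueError("p_in > 0 requires at least one island")

    rng = np.random.default_rng(params.seed)
    island_mask = np.zeros((h, w), dtype=bool)
    ax = params.tumor_axes_frac[0] * w
    ay = params.tumor_axes_frac[1] * h
    cy0, cx0 = h / 2.0, w / 2.0
    for _ in range(params.n_islands):
        # island center uniform in the tumor-bed ellipse (polar sampling)
        t = rng.uniform(0, 2 * np.pi)
        r = np.sqrt(rng.uniform())
        cy = cy0 + r * ay * np.sin(t)
        cx = cx0 + r * ax * np.cos(t)
        a_px = rng.uniform(rlo, rhi) / px
        b_px = rng.uniform(rlo, rhi) / px
        theta = rng.uniform(0, np.pi)
        _rasterize_island(island_mask, cy, cx, a_px, b_px, theta, rng)

    panck = np.where(island_mask, params.signal_level, 0.0)

    cd8 = np.zeros((h, w), dtype=float)
    centers = np.zeros((params.n_tcells, 2), dtype=float)
    inside_flags = np.zeros(params.n_tcells, dtype=bool)
    island_px = np.argwhere(island_mask) if island_mask.any() else None
    r_t = params.tcell_radius_um / px
    for i in range(params.n_tcells):
        inside = island_px is not None and rng.random() < params.p_in
        if inside:
            cy, cx = island_px[rng.integers(len(island_px))]
        else:
            # rejection-sample a stroma pixel (stroma dominates the canvas)
            while True:
                cy = rng.integers(h)
                cx = rng.integers(w)
                if not island_mask[cy, cx]:
                    break
        centers[i] = (cy, cx)
        inside_flags[i] = inside
        _rasterize_disc(cd8, cy, cx, r_t, params.signal_level)

    if params.noise_sd > 0:
        panck = panck + rng.normal(0.0, params.noise_sd, size=(h, w))
        cd8 = cd8 + rng.normal(0.0, params.noise_sd, size=(h, w))
    panck = np.clip(panck, 0.0, None)
    cd8 = np.clip(cd8, 0.0, None)

    record = PatientRecord(
        patient_id=patient_id,
        outcome=outcome,
        grade="NA",
        nodal="NA",
        cohort="synthetic",
        pixel_size_um=px,
    )
    return SyntheticPatient(
        panck=IntensityImage(panck, px),
        cd8=IntensityImage(cd8, px),
        truth_outcome=outcome,
        truth_p_in=params.p_in,
        record=record,
        island_mask=island_mask,
        tcell_centers=centers,
        tcell_inside=inside_flags,
    )


def iter_cohort(
    n_good: int,
    n_poor: int,
    good_p_in_range: tuple[float, float] = (0.6, 0.9),
    poor_p_in_range: tuple[float, float] = (0.0, 0.2),
    base: SyntheticParams | None = None,
    seed: int = 0,
    id_prefix: str = "S",
):
    """Yield the patients of :func:`generate_cohort` one at a time.

    Streaming form for pipelines that process each patient and discard the
    raw images; the sequence is identical to ``generate_cohort`` with the
    same arguments.
    """
    if n_good < 0 or n_poor < 0:
        raise ValueError("group sizes must be non-negative")
    for lo, hi in (good_p_in_range, poor_p_in_range):
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("p_in ranges must be ordered and within [0, 1]")
    if n_good and n_poor and good_p_in_range[0] <= poor_p_in_range[1]:
        warnings.warn(
            "good and poor p_in ranges overlap; the cohort may not be separable"
        )
    base = base or SyntheticParams()
    rng = np.random.default_rng(mix_seed(seed, 0x5EED))
    specs = [("good", good_p_in_range)] * n_good + [("poor", poor_p_in_range)] * n_poor
    for idx, (outcome, (lo, hi)) in enumerate(specs):
        p_in = float(rng.uniform(lo, hi))
        child = mix_seed(seed, idx + 1)
        params = replace(base, p_in=p_in, seed=child)
        pid = f"{id_prefix}{idx + 1:03d}_{outcome}"
        yield generate_patient(params, patient_id=pid, outcome=outcome)


def generate_cohort(
    n_good: int,
    n_poor: int,
    good_p_in_range: tuple[float, float] = (0.6, 0.9),
    poor_p_in_range: tuple[float, float] = (0.0, 0.2),
    base: SyntheticParams | None = None,
    seed: int = 0,
    id_prefix: str = "S",
) -> list[SyntheticPatient]:
    """Generate a labeled cohort with infiltration tied to outcome.

    ``n_good`` patients draw ``p_in`` uniformly from ``good_p_in_range`` and
    are labeled good; ``n_poor`` likewise from ``poor_p_in_range`` labeled
    poor.  Per-patient child seeds are derived from ``seed`` through a fixed
    integer mix, so the cohort is reproducible and patients are independent.
    Default group sizes elsewhere in the package follow the 15 good / 9 poor
    composition of the original training cohort.
    """
    return list(
        iter_cohort(
            n_good, n_poor, good_p_in_range, poor_p_in_range, base, seed, id_prefix
        )
    )


def generate_heterogeneous_patient(
    params_left: SyntheticParams,
    params_right: SyntheticParams,
    patient_id: str = "hetero",
    outcome: str = "unknown",
) -> SyntheticPatient:
    """Stitch two independently generated halves into one wide section.

    Emulates an inhomogeneous tumor whose left and right halves have
    different infiltration levels — the situation in which a prediction from
    half a section can contradict the whole-section prediction.  Both halves
    must share canvas size and pixel size.
    """
    if params_left.canvas_size_px != params_right.canvas_size_px:
        raise ValueError("halves must share canvas_size_px")
    if params_left.pixel_size_um != params_right.pixel_size_um:
        raise ValueError("halves must share pixel_size_um")
    left = generate_patient(params_left, patient_id + "_L")
    right = generate_patient(params_right, patient_id + "_R")
    px = params_left.pixel_size_um
    w = params_left.canvas_size_px[1]
    panck = np.concatenate([left.panck.pixels, right.panck.pixels], axis=1)
    cd8 = np.concatenate([left.cd8.pixels, right.cd8.pixels], axis=1)
    island = np.concatenate([left.island_mask, right.island_mask], axis=1)
    centers = np.concatenate(
        [left.tcell_centers, right.tcell_centers + [0.0, w]], axis=0
    )
    inside = np.concatenate([left.tcell_inside, right.tcell_inside])
    record = PatientRecord(
        patient_id=patient_id,
        outcome=outcome,
        grade="NA",
        nodal="NA",
        cohort="synthetic",
        pixel_size_um=px,
    )
    return SyntheticPatient(
        panck=IntensityImage(panck, px),
        cd8=IntensityImage(cd8, px),
        truth_outcome=outcome,
        truth_p_in=float("nan"),
        record=record,
        island_mask=island,
        tcell_centers=centers,
        tcell_inside=inside,
    )


def write_cohort(patients: list[SyntheticPatient], outdir) -> Path:
    """Write per-patient TIFF pairs plus a manifest TSV; returns manifest path."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for p in patients:
        pid = p.record.patient_id
        panck_path = outdir / f"{pid}_panck.tif"
        cd8_path = outdir / f"{pid}_cd8.tif"
        tifffile.imwrite(panck_path, p.panck.pixels.astype(np.float32))
        tifffile.imwrite(cd8_path, p.cd8.pixels.astype(np.float32))
        records.append(
            replace(
                p.record,
                panck_path=str(panck_path),
                cd8_path=str(cd8_path),
            )
        )
    manifest = outdir / "manifest.tsv"
    write_manifest(records, manifest)
    return manifest
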