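"""Patch-level binary classifier: does a patch look like a poor-outcome tumor?

Implements the training protocol around the CNN: a per-patient 80/20
train/holdout split, class balancing by replicating minority-class patches,
RMSProp training with a step-decay learning-rate schedule, and thresholded
per-patch predictions (probability > 0.5 -> "poor" patch).  Class encoding is
poor = 1, good = 0.
"""

from __future__ import annotations

import json
import warnings
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ._cnn import ARCHITECTURES, RMSProp, SmallCNN
from ._util import mix_seed, stable_str_seed
from .patchify import Patch, patches_to_array

__all__ = [
    "TrainConfig",
    "desk_scale_train_config",
    "PatchPrediction",
    "PatchModel",
    "split_train_holdout",
    "balance_by_replication",
    "train_classifier",
    "predict_patches",
]

POOR, GOOD = 1, 0


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (RMSProp schedule and protocol constants)."""

    learning_rate: float = 0.0005
    weight_decay: float = 0.01
    lr_factor: float = 0.25
    factor_epoch: int = 10
    batch_size: int = 20
    epochs: int = 100
    extra_copies_minority: int = 3
    train_frac: float = 0.8
    patch_cutoff: float = 0.5
    seed: int = 0
    architecture: str = "small_cnn"

    def __post_init__(self):
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("train_frac must be in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 < self.patch_cutoff < 1.0):
            raise ValueError("patch_cutoff must be in (0, 1)")
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"choose from {sorted(ARCHITECTURES)}"
            )


def desk_scale_train_config(**overrides) -> TrainConfig:
    """Training schedule for desk-scale synthetic experiments.

    The default schedule (100 epochs at base rate 5e-4 with step decay) is
    sized for cohorts with thousands of patches.  Desk-scale cohorts have a
    few hundred training patches, so 15 epochs give only a few hundred
    parameter updates; the base learning rate is raised to 2e-3 so the total
    optimization travel matches the long schedule.
    """
    base = dict(epochs=15, learning_rate=2e-3)
    base.update(overrides)
    return TrainConfig(**base)


@dataclass(frozen=True)
class PatchPrediction:
    """Per-patch classifier output; label is poor iff prob_poor > cutoff."""

    patient_id: str
    row: int
    col: int
    prob_poor: float
    label: str  # "good" | "poor"


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_train_holdout(
    patches: list[Patch] | dict[str, list[Patch]],
    train_frac: float = 0.8,
    seed: int = 0,
) -> tuple[list[Patch], list[Patch]]:
    """Per-patient random split into training and holdout patches.

    For each patient with n patches, ``round(train_frac * n)`` (half-up) go to
    the training set and the rest to the holdout used for threshold
    selection.  The split is performed independently per patient with a seed
    derived from (seed, patient_id), so adding or removing one patient does
    not reshuffle the others.  Patients whose holdout ends up empty (e.g. a
    single patch) are flagged with a warning: no holdout good-patch fraction
    can be computed for them.
    """
    if isinstance(patches, dict):
        grouped = {pid: list(ps) for pid, ps in patches.items()}
    else:
        grouped = defaultdict(list)
        for p in patches:
            grouped[p.patient_id].append(p)
    train: list[Patch] = []
    holdout: list[Patch] = []
    for pid in sorted(grouped):
        ps = sorted(grouped[pid], key=lambda p: (p.row, p.col))
        if not ps:
            warnings.warn(f"patient {pid} has no patches and is excluded")
            continue
        rng = np.random.default_rng(stable_str_seed(seed, pid))
        order = rng.permutation(len(ps))
        n_train = _round_half_up(train_frac * len(ps))
        if n_train >= len(ps):
            n_train = len(ps)
            warnings.warn(
                f"patient {pid}: all {len(ps)} patches assigned to training; "
                "no holdout fraction computable"
            )
        train.extend(ps[i] for i in order[:n_train])
        holdout.extend(ps[i] for i in order[n_train:])
    return train, holdout


def balance_by_replication(
    patches: list[Patch],
    labels: np.ndarray | list[int],
    extra_copies: int = 3,
    seed: int = 0,
) -> tuple[list[Patch], np.ndarray]:
    """Balance classes by replicating each minority-class patch.

    Every patch of the minority class appears ``extra_copies + 1`` times in
    the returned sequence (for the reference cohort composition the minority
    is the poor class); the majority class is unchanged.  The sequence is
    shuffled deterministically.  Replication changes multiplicities only,
    never the set of distinct patches.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != len(patches):
        raise ValueError("patches and labels must align")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        warnings.warn("single-class training data: balancing is a no-op")
        return list(patches), labels.copy()
    minority = classes[np.argmin(counts)]
    out_patches = list(patches)
    out_labels = list(labels)
    if extra_copies > 0 and counts.min() != counts.max():
        for _ in range(extra_copies):
            for p, y in zip(patches, labels):
                if y == minority:
                    out_patches.append(p)
                    out_labels.append(y)
    elif counts.min() == counts.max():
        # already balanced; keep multiset unchanged
        pass
    rng = np.random.default_rng(mix_seed(seed, 0xBA1A))
    order = rng.permutation(len(out_patches))
    return [out_patches[i] for i in order], np.asarray(out_labels)[order]


class PatchModel:
    """Trained patch classifier with its config and training history."""

    def __init__(self, net: SmallCNN, cfg: TrainConfig, history: list[dict]):
        self.net = net
        self.cfg = cfg
        self.history = history  # per-epoch dicts: epoch, loss, accuracy, lr

    def predict_proba(self, patches: list[Patch] | np.ndarray) -> np.ndarray:
        """Probability that each patch comes from a poor-outcome patient."""
        x = patches if isinstance(patches, np.ndarray) else patches_to_array(patches)
        if len(x) == 0:
            return np.zeros(0)
        if x.ndim != 4 or x.shape[1] != 2:
            raise ValueError(f"expected (N, 2, H, W) patches, got {x.shape}")
        return self.net.predict_proba(x)

    def save(self, path) -> None:
        """Write weights (.npz) plus a JSON sidecar with config and history."""
        path = Path(path)
        np.savez(path, **self.net.state_arrays())
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps(
                {"config": asdict(self.cfg), "history": self.history}, indent=2
            )
        )

    @classmethod
    def load(cls, path) -> "PatchModel":
        path = Path(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        cfg = TrainConfig(**meta["config"])
        net = SmallCNN(channels=ARCHITECTURES[cfg.architecture], seed=cfg.seed)
        with np.load(path) as state:
            net.load_state_arrays(dict(state))
        return cls(net, cfg, meta["history"])


def train_classifier(
    patches: list[Patch],
    labels: np.ndarray | list[int],
    cfg: TrainConfig | None = None,
) -> PatchModel:
    """Train the patch CNN with RMSProp on a (balanced) training sequence.

    ``labels`` are 1 for patches from poor-outcome patients, 0 for good.  The
    loss is binary cross-entropy on a single logit; the learning rate is
    multiplied by ``cfg.lr_factor`` every ``cfg.factor_epoch`` epochs.  Each
    epoch's mean loss and thresholded training accuracy are recorded in the
    returned model's ``history``.  Deterministic given ``cfg.seed`` (and a
    fixed BLAS thread count).
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(labels, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    x = patches_to_array(patches) if not isinstance(patches, np.ndarray) else patches
    x = np.asarray(x, dtype=np.float32)
    net = SmallCNN(channels=ARCHITECTURES[cfg.architecture], seed=cfg.seed)
    opt = RMSProp(
        net,
        learning_rate=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
        lr_factor=cfg.lr_factor,
        factor_epoch=cfg.factor_epoch,
    )
    rng = np.random.default_rng(mix_seed(cfg.seed, 0x7EA1))
    n = len(x)
    history: list[dict] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x[idx], y[idx]
            z = net.forward(xb)
            p = 1.0 / (1.0 + np.exp(-z))
            eps = 1e-12
            loss = -np.mean(yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, batch {i // cfg.batch_size}; "
                    f"lr={opt.lr_at(epoch):.2e}, |z|max={np.abs(z).max():.2e}"
                )
            net.backward((p - yb) / len(yb))
            opt.step(epoch)
            losses.append(loss)
            correct += int(((p > cfg.patch_cutoff) == (yb > 0.5)).sum())
        history.append(
            {
                "epoch": epoch,
                "loss": float(np.mean(losses)),
                "accuracy": correct / n,
                "lr": opt.lr_at(epoch),
            }
        )
    return PatchModel(net, cfg, history)


def predict_patches(
    model, patches: list[Patch], patch_cutoff: float = 0.5
) -> list[PatchPrediction]:
    """Classify patches; label is poor iff prob_poor strictly exceeds cutoff."""
    if not patches:
        return []
    probs = model.predict_proba(patches)
    return [
        PatchPrediction(
            patient_id=p.patient_id,
            row=p.row,
            col=p.col,
            prob_poor=float(pr),
            label="poor" if pr > patch_cutoff else "good",
        )
        for p, pr in zip(patches, probs)
    ]
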