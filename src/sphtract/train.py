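"""Training recipe: per-tract binary segmentation with BCE, Adam and cosine
annealing, early-stopped on validation Dice.

Each tract is trained as an independent binary task; voxels belonging to
several tracts are kept in the positive class of every relevant tract's model,
so overlapping regions are represented in all single-tract models (the
multi-label alternative trains one model with C sigmoid output channels).
Validation Dice is computed on fused, thresholded 3D volumes — the same
quantity reported at test time — and the checkpoint with the highest
validation Dice is the one returned.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from sphtract.data import extract_slices
from sphtract.infer import segment_volume
from sphtract.metrics import confusion_counts, compute_metrics
from sphtract.nn import sigmoid
from sphtract.unet import UNet2D, UNetSpec, build_network

_EPS = 1e-7


@dataclass(frozen=True)
class Subject:
    """One subject: an fODF volume plus its per-tract reference masks."""

    id: str
    fodf: np.ndarray  # (S, S, S, n_coeffs)
    masks: dict[str, np.ndarray]  # tract name -> (S, S, S) binary


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the training recipe.

    Defaults are the reference recipe: Adam from an initial learning rate of
    0.002 under cosine annealing to ``eta_min``, batch size 200, up to 400
    epochs, early stopping on validation Dice with a patience of 50 epochs,
    dropout 0.4.  Tests and desk-scale runs shrink batch/epochs via config.
    """

    learning_rate0: float = 0.002
    eta_min: float = 0.0
    batch_size: int = 200
    max_epochs: int = 400
    patience: int = 50
    dropout: float = 0.4
    seed: int = 0
    mode: str = "single_class"  # or "multi_class"
    tract: str | None = None  # required in single_class mode
    val_interval: int = 1

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if not 0 < self.patience <= self.max_epochs:
            raise ValueError("need 0 < patience <= max_epochs")
        if self.mode not in ("single_class", "multi_class"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "single_class" and not self.tract:
            raise ValueError("single_class mode requires a tract name")


@dataclass
class TrainState:
    """Progress record; best validation Dice is monotone non-decreasing."""

    epoch: int = 0
    best_val_dice: float = -np.inf
    best_epoch: int = -1
    log: list[dict] = field(default_factory=list)


def bce_loss(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy -[y log p + (1-y) log(1-p)].

    Predictions are clipped into [eps, 1-eps] (eps = 1e-7); in multi-label
    mode the mean runs over channels as well.
    """
    p = np.asarray(predictions, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64)
    if p.shape != y.shape:
        raise ValueError(f"shape mismatch: predictions {p.shape} vs labels {y.shape}")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def cosine_lr(t: int, T_max: int, lr0: float, eta_min: float = 0.0) -> float:
    """Cosine annealing: eta_min + 0.5 (lr0 - eta_min)(1 + cos(pi t / T_max)).

    Monotone non-increasing from ``lr0`` at t=0 to ``eta_min`` at t=T_max.
    """
    if not 0 <= t <= T_max:
        raise ValueError(f"epoch {t} outside [0, {T_max}]")
    return eta_min + 0.5 * (lr0 - eta_min) * (1.0 + np.cos(np.pi * t / T_max))


def make_labels(subject: Subject, config: TrainConfig,
                tract_order: list[str] | None = None) -> np.ndarray:
    """Training label volume for one subject under the configured mode.

    single_class: the chosen tract's binary mask — voxels shared with other
    tracts stay positive because each tract's reference mask is independent.
    multi_class: (S, S, S, C) stack, one sigmoid channel per tract; a voxel
    may be positive in several channels.
    """
    if config.mode == "single_class":
        if config.tract not in subject.masks:
            raise KeyError(
                f"subject {subject.id!r} has no tract {config.tract!r}"
            )
        return (subject.masks[config.tract] > 0).astype(np.float32)
    order = tract_order or sorted(subject.masks)
    return np.stack(
        [(subject.masks[t] > 0) for t in order], axis=-1
    ).astype(np.float32)


def validation_dice(model: UNet2D, subjects: list[Subject], tract: str | None,
                    tract_order: list[str] | None = None,
                    tau: float = 0.5) -> float:
    """Mean over subjects of the 3D Dice of the fused, thresholded prediction.

    In multi-label mode (``tract is None``) the Dice is additionally averaged
    over channels with a non-empty reference.
    """
    if not subjects:
        raise ValueError("need at least one validation subject")
    dices = []
    for s in subjects:
        mask, _ = segment_volume(model, s.fodf, tau=tau)
        if tract is not None:
            ref = (s.masks[tract] > 0).astype(np.uint8)
            d = compute_metrics(confusion_counts(mask, ref)).dice
            dices.append(0.0 if np.isnan(d) else d)
        else:
            order = tract_order or sorted(s.masks)
            per_ch = []
            for c, t in enumerate(order):
                ref = (s.masks[t] > 0).astype(np.uint8)
                d = compute_metrics(confusion_counts(mask[..., c], ref)).dice
                if not np.isnan(d):
                    per_ch.append(d)
            dices.append(float(np.mean(per_ch)) if per_ch else 0.0)
    return float(np.mean(dices))


def train(
    spec: UNetSpec,
    train_subjects: list[Subject],
    val_subjects: list[Subject],
    config: TrainConfig,
    tract_order: list[str] | None = None,
    val_metric_fn=None,
) -> tuple[UNet2D, TrainState]:
    """Train a network on tri-planar slices of the training subjects.

    Runs up to ``config.max_epochs`` epochs, stopping early once validation
    Dice has not improved for ``config.patience`` evaluations; the returned
    model carries the best-validation-Dice weights.  Fully deterministic
    given ``config.seed`` on a fixed platform (weight init, shuffling and
    dropout masks all derive from it).  ``val_metric_fn(model, epoch)`` may
    replace the fused-3D-Dice evaluator (used to test the early-stopping
    contract in isolation).
    """
    if not train_subjects or not val_subjects:
        raise ValueError("train and validation subject lists must be non-empty")
    if config.mode == "multi_class" and tract_order is None:
        tract_order = sorted(train_subjects[0].masks)
    spec = UNetSpec(**{**spec.to_dict(), "dropout": config.dropout})

    records = []
    for s in train_subjects:
        labels = make_labels(s, config, tract_order)
        records.extend(extract_slices(s.fodf, labels, subject=s.id))
    images = np.stack([r.image for r in records]).astype(np.float32)
    labels = np.stack([r.label for r in records]).astype(np.float32)
    if labels.ndim == 3:
        labels = labels[..., None]
    if labels.shape[-1] != spec.out_channels:
        raise ValueError(
            f"label channels {labels.shape[-1]} != spec.out_channels "
            f"{spec.out_channels}"
        )

    model = build_network(spec, seed=config.seed)
    opt = model.make_optimizer(config.learning_rate0)
    rng = np.random.default_rng(config.seed + 1)
    n = images.shape[0]
    state = TrainState()
    best_weights = None
    stale = 0

    for epoch in range(config.max_epochs):
        lr = cosine_lr(epoch, config.max_epochs, config.learning_rate0,
                       config.eta_min)
        opt.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start: start + config.batch_size]
            x, y = images[idx], labels[idx]
            logits = model.forward_logits(x, training=True)
            p = sigmoid(logits)
            loss = bce_loss(p, y)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}; aborting "
                    f"(lr={lr:.2e}, batch of {len(idx)})"
                )
            losses.append(loss)
            opt.zero_grad()
            model.backward((p - y).astype(np.float32) / p.size)
            opt.step()

        entry = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses)),
                 "val_dice": np.nan}
        state.epoch = epoch
        if epoch % config.val_interval == 0 or epoch == config.max_epochs - 1:
            if val_metric_fn is not None:
                vd = float(val_metric_fn(model, epoch))
            else:
                vd = validation_dice(
                    model, val_subjects,
                    config.tract if config.mode == "single_class" else None,
                    tract_order,
                )
            entry["val_dice"] = vd
            if vd > state.best_val_dice:
                state.best_val_dice = vd
                state.best_epoch = epoch
                best_weights = copy.deepcopy(model.state_arrays())
                stale = 0
            else:
                stale += 1
        state.log.append(entry)
        if stale >= config.patience:
            break

    if best_weights is not None:
        model.load_state_arrays(best_weights)
    return model, state
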