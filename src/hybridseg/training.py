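"""Semi-supervised training of the refinement network, splits, inference.

The hybrid pipeline's final stage is trained on a mix of manually labelled
volumes and *pseudo-labelled* volumes: for volumes without a reference
standard, the estimate produced by the variational + registration stages
stands in for the training target, down-weighted by ``pseudo_label_weight``.
The hybrid network sees the scan plus one-hot channels of the estimated
segmentation; the ``standard`` baseline sees the scan alone.

Everything is seeded: example shuffling, flip augmentation and weight
initialisation all derive from ``TrainConfig.rng_seed``, so a repeated run
produces bit-identical results.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import LabelMask, Volume
from .network import Adam, UNet3D, build_network, segmentation_loss, softmax

__all__ = [
    "SplitPlan",
    "TrainingExample",
    "TrainConfig",
    "make_split",
    "train",
    "infer",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class SplitPlan:
    """Cohort partition: labelled train/val/test plus unlabelled train ids."""

    train: tuple
    val: tuple
    test: tuple
    unlabelled: tuple = ()

    def __post_init__(self) -> None:
        groups = [set(self.train), set(self.val), set(self.test)]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError("labelled split groups must be disjoint")
        if set(self.unlabelled) & (set(self.val) | set(self.test)):
            raise ValueError("unlabelled ids must not appear in val or test")

    @property
    def training_pool_size(self) -> int:
        """Labelled + pseudo-labelled volumes available during training."""
        return len(self.train) + len(self.unlabelled)


def make_split(
    labelled_ids,
    unlabelled_ids=(),
    ratio: tuple[int, int, int] = (60, 20, 20),
    seed: int = 0,
) -> SplitPlan:
    """Shuffle labelled ids by seed and split train/val/test by ratio.

    Sizes are floor-based with the remainder going to train, so 50 labelled
    volumes at 60:20:20 give 30/10/10 and 5 give 3/1/1.
    """
    if sum(ratio) != 100:
        raise ValueError(f"ratio must sum to 100, got {ratio}")
    ids = list(labelled_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 labelled ids to form a 3-way split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    ids = [ids[i] for i in order]
    n = len(ids)
    n_val = n * ratio[1] // 100
    n_test = n * ratio[2] // 100
    n_train = n - n_val - n_test  # remainder to train
    return SplitPlan(
        train=tuple(ids[:n_train]),
        val=tuple(ids[n_train : n_train + n_val]),
        test=tuple(ids[n_train + n_val :]),
        unlabelled=tuple(unlabelled_ids),
    )


@dataclass
class TrainingExample:
    image: Volume
    target: LabelMask
    estimate: LabelMask | None = None  # second input channel group (hybrid)
    supervision: str = "manual"  # or "pseudo"

    def __post_init__(self) -> None:
        if self.supervision not in ("manual", "pseudo"):
            raise ValueError(f"unknown supervision {self.supervision!r}")
        if self.image.shape != self.target.shape:
            raise ValueError("image and target grids differ")
        if self.estimate is not None and self.estimate.shape != self.image.shape:
            raise ValueError("image and estimate grids differ")


@dataclass
class TrainConfig:
    mode: str = "hybrid"  # or "standard"
    n_classes: int = 3
    epochs: int = 60
    batch_size: int = 2
    patch_size: int = 64
    learning_rate: float = 1e-3
    w_dice: float = 0.5
    w_ce: float = 0.5
    pseudo_label_weight: float = 0.5
    base_width: int = 16
    rng_seed: int = 0
    patience: int = 15  # early stop on validation Dice
    augment_flips: bool = True
    estimate_dropout_p: float = 0.3  # hybrid: train-time zeroing of estimate channels

    def __post_init__(self) -> None:
        if self.mode not in ("hybrid", "standard"):
            raise ValueError(f"mode must be 'hybrid' or 'standard', got {self.mode!r}")
        if not (0.0 <= self.pseudo_label_weight <= 1.0):
            raise ValueError("pseudo_label_weight must lie in [0,1]")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


def _onehot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    out = np.zeros((n_classes,) + mask.shape, dtype=np.float32)
    for c in range(n_classes):
        out[c] = mask == c
    return out


def _input_channels(image: Volume, estimate: LabelMask | None, config: TrainConfig) -> np.ndarray:
    chans = [image.data.astype(np.float32)]
    if config.mode == "hybrid":
        if estimate is None:
            raise ValueError("hybrid mode requires an estimate channel")
        # one-hot per foreground class avoids spurious ordinality of label ids
        for c in range(1, config.n_classes):
            chans.append((estimate.data == c).astype(np.float32))
    return np.stack(chans)


def _random_patch(shape, patch: int, rng: np.random.Generator):
    starts = []
    for n in shape:
        size = min(patch, n)
        size -= size % 4  # network stride requirement
        starts.append((rng.integers(0, n - size + 1) if n > size else 0, size))
    return tuple(slice(s, s + sz) for s, sz in starts)


def _foreground_dice(pred: np.ndarray, target: np.ndarray, n_classes: int) -> float:
    scores = []
    for c in range(1, n_classes):
        p = pred == c
        t = target == c
        den = p.sum() + t.sum()
        scores.append(1.0 if den == 0 else 2.0 * np.logical_and(p, t).sum() / den)
    return float(np.mean(scores))


def train(
    examples: list[TrainingExample],
    val_examples: list[TrainingExample],
    config: TrainConfig,
) -> tuple[UNet3D, pd.DataFrame]:
    """Train the refinement network; returns the best-on-validation model.

    The loss on a pseudo-labelled example is the same Dice+cross-entropy,
    scaled by ``pseudo_label_weight``; at weight 0 pseudo examples contribute
    no gradient at all and are dropped from the epoch loop, so the run is
    identical to one without them.
    """
    if not any(e.supervision == "manual" for e in examples):
        raise ValueError("training set needs at least one manually supervised example")
    if not val_examples:
        raise ValueError("validation set must be nonempty")
    if config.pseudo_label_weight == 0.0:
        examples = [e for e in examples if e.supervision == "manual"]

    model = build_network(config.mode, config.n_classes, config.base_width, seed=config.rng_seed)
    opt = Adam(model, lr=config.learning_rate)
    rng = np.random.default_rng(config.rng_seed + 1)

    best_state = model.state_dict()
    best_val = -1.0
    since_best = 0
    log_rows = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(examples))
        losses = []
        model.zero_grad()
        in_batch = 0
        for idx in order:
            ex = examples[int(idx)]
            sl = _random_patch(ex.image.shape, config.patch_size, rng)
            x = _input_channels(ex.image, ex.estimate, config)[(slice(None),) + sl]
            t = _onehot(ex.target.data[sl], config.n_classes)
            if config.augment_flips:
                for ax in (1, 2, 3):
                    if rng.random() < 0.5:
                        x = np.flip(x, axis=ax)
                        t = np.flip(t, axis=ax)
            if config.mode == "hybrid" and config.estimate_dropout_p > 0:
                # randomly blank the estimate channels so the network learns
                # the image-only mapping too instead of copying the estimate
                if rng.random() < config.estimate_dropout_p:
                    x = x.copy()
                    x[1:] = 0.0
            weight = 1.0 if ex.supervision == "manual" else config.pseudo_label_weight
            logits = model.forward(np.ascontiguousarray(x))
            loss, grad = segmentation_loss(
                logits, np.ascontiguousarray(t), config.w_dice, config.w_ce
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch} (lr={config.learning_rate}); aborting"
                )
            losses.append(weight * loss)
            model.backward(weight * grad)
            in_batch += 1
            if in_batch == config.batch_size:
                opt.step()
                model.zero_grad()
                in_batch = 0
        if in_batch:
            opt.step()
            model.zero_grad()

        val_scores = [
            _foreground_dice(
                infer(model, ex.image, ex.estimate, config)[1].data,
                ex.target.data,
                config.n_classes,
            )
            for ex in val_examples
        ]
        val_dice = float(np.mean(val_scores))
        log_rows.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)), "val_dice": val_dice}
        )
        if val_dice > best_val:
            best_val = val_dice
            best_state = model.state_dict()
            since_best = 0
        else:
            since_best += 1
            if since_best > config.patience:
                break

    model.load_state_dict(best_state)
    return model, pd.DataFrame(log_rows)


def infer(
    model: UNet3D,
    image: Volume,
    estimate: LabelMask | None = None,
    config: TrainConfig | None = None,
) -> tuple[np.ndarray, LabelMask]:
    """Full-volume inference: class probabilities and the argmax mask.

    Volumes larger than the patch size are processed by a sliding window with
    half-patch stride and overlap averaging of the probability maps; smaller
    volumes are padded to the network stride and run in one pass, so patched
    and full-volume inference coincide on a single-window input.
    """
    mode = "hybrid" if model.in_channels > 1 else "standard"
    if mode == "hybrid" and estimate is None:
        raise ValueError("a hybrid model requires an estimate mask at inference time")
    cfg = config or TrainConfig(mode=mode, n_classes=model.n_classes)
    x = _input_channels(image, estimate, cfg) if mode == "hybrid" else np.stack(
        [image.data.astype(np.float32)]
    )

    shape = x.shape[1:]
    patch = max(cfg.patch_size - cfg.patch_size % 4, 4)
    # pad so every dim is a multiple of 4 (network stride requirement)
    pad = []
    for s in shape:
        target = max(s, 4)
        target += (4 - target % 4) % 4
        pad.append((0, target - s))
    xp = np.pad(x, [(0, 0)] + pad, mode="reflect") if any(p[1] for p in pad) else x
    pshape = xp.shape[1:]
    win = tuple(min(patch, s) for s in pshape)

    prob = np.zeros((model.n_classes,) + pshape, dtype=np.float64)
    count = np.zeros(pshape, dtype=np.float64)
    starts = []
    for s, w in zip(pshape, win):
        stride = max(w // 2, 4)
        ss = list(range(0, max(s - w, 0) + 1, stride))
        if ss[-1] != s - w:
            ss.append(s - w)
        starts.append(sorted(set(ss)))
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (
                    slice(z0, z0 + win[0]),
                    slice(y0, y0 + win[1]),
                    slice(x0, x0 + win[2]),
                )
                logits = model.forward(np.ascontiguousarray(xp[(slice(None),) + sl]))
                prob[(slice(None),) + sl] += softmax(logits)
                count[sl] += 1.0
    prob /= count
    crop = tuple(slice(0, s) for s in shape)
    prob = prob[(slice(None),) + crop]
    labels = np.argmax(prob, axis=0).astype(np.int16)
    return prob, LabelMask(labels, image.spacing)


def save_checkpoint(model: UNet3D, config: TrainConfig, path: str | Path) -> None:
    """Weights as .npz plus a JSON sidecar describing mode and shape."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    meta = {
        "mode": config.mode,
        "n_classes": model.n_classes,
        "in_channels": model.in_channels,
        "base_width": model.base_width,
        "config": asdict(config),
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_checkpoint(path: str | Path) -> tuple[UNet3D, TrainConfig]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    config = TrainConfig(**meta["config"])
    model = UNet3D(meta["in_channels"], meta["n_classes"], meta["base_width"])
    with np.load(path.with_suffix(".npz")) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model, config
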