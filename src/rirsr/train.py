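"""Patch-based training: L1 objective, ADAM, stepped learning-rate decay.

Patches are scaled to [0, 1] for optimization (loss histories are
reported back on the 0-255 intensity scale); the learning rate follows
``lr0 * decay_factor ** floor(epoch / decay_every)``, i.e. a reduction
by ``decay_factor`` every ``decay_every`` epochs.  The last incomplete
batch of each epoch is dropped so every update sees a full batch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .degrade import PatchPair
from .model import ModelConfig, RIRNetwork, count_parameters
from .nn import AdamState, adam_step

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "l1_loss",
    "lr_at_epoch",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule hyperparameters.

    Defaults follow the reference recipe: ADAM with beta1 = 0.9,
    beta2 = 0.999, eps = 1e-8, initial learning rate 2e-4 decayed by a
    factor of 0.1 every 120 epochs, batch size 32.  The total epoch
    count is not part of the recipe and defaults to 300.
    """

    lr0: float = 2e-4
    decay_factor: float = 0.1
    decay_every: int = 120
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    n_epochs: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.decay_factor <= 1.0:
            raise ValueError("decay_factor must lie in (0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.decay_every < 1:
            raise ValueError("decay_every must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch mean L1 loss (0-255 scale) and learning rate."""

    loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    n_steps: int = 0


def l1_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean absolute difference over all pixels of a batch."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs target {target.shape}"
        )
    return float(np.mean(np.abs(pred - target)))


def lr_at_epoch(epoch: int, cfg: TrainConfig) -> float:
    """Stepped exponential schedule: lr0 * factor ** floor(epoch / every)."""
    if epoch < 0:
        raise ValueError(f"epoch={epoch}: must be >= 0")
    return cfg.lr0 * cfg.decay_factor ** (epoch // cfg.decay_every)


def _stack_pairs(
    pairs: list[PatchPair], scale: int, dtype
) -> tuple[np.ndarray, np.ndarray]:
    """Validate pairs against the model scale and stack to [0, 1] batches."""
    if not pairs:
        raise ValueError("no training pairs supplied")
    p = pairs[0].lr_patch.shape[0]
    for pair in pairs:
        if pair.lr_patch.shape != (p, p):
            raise ValueError("all LR patches must share one size")
        if pair.hr_patch.shape != (scale * p, scale * p):
            raise ValueError(
                f"HR patch {pair.hr_patch.shape} inconsistent with model "
                f"scale {scale} and LR patch size {p}"
            )
    x = np.stack([pair.lr_patch for pair in pairs]).astype(dtype) / 255.0
    y = np.stack([pair.hr_patch for pair in pairs]).astype(dtype) / 255.0
    return x[..., None], y[..., None]


def train(
    cfg_model: ModelConfig | RIRNetwork,
    pairs: list[PatchPair],
    cfg_train: TrainConfig,
    log_fn=None,
) -> tuple[RIRNetwork, TrainHistory]:
    """Train a network on LR/HR patch pairs.

    Each epoch shuffles the pairs with a seeded generator, iterates full
    batches (the trailing incomplete batch is dropped), and applies one
    ADAM update per batch with the epoch's scheduled learning rate.
    Deterministic given the model seed and ``cfg_train.seed``.
    """
    model = cfg_model if isinstance(cfg_model, RIRNetwork) else RIRNetwork(cfg_model)
    x, y = _stack_pairs(pairs, model.cfg.scale, model.dtype)
    n = x.shape[0]
    bs = cfg_train.batch_size
    if n < bs:
        raise ValueError(
            f"{n} pairs with batch_size={bs}: need at least one full batch"
        )
    params = model.params()
    state = AdamState(params)
    rng = np.random.default_rng(cfg_train.seed)
    history = TrainHistory()
    for epoch in range(cfg_train.n_epochs):
        lr = lr_at_epoch(epoch, cfg_train)
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n - bs + 1, bs):
            idx = perm[start : start + bs]
            xb, yb = x[idx], y[idx]
            pred = model.forward(xb, train=True)
            diff = pred - yb
            losses.append(float(np.mean(np.abs(diff))))
            g = np.sign(diff).astype(model.dtype) / diff.size
            model.zero_grad()
            model.backward(g)
            adam_step(params, state, lr, cfg_train.beta1, cfg_train.beta2,
                      cfg_train.epsilon)
            history.n_steps += 1
        epoch_loss = 255.0 * float(np.mean(losses))
        history.loss.append(epoch_loss)
        history.lr.append(lr)
        if log_fn is not None:
            log_fn(epoch, epoch_loss, lr)
    return model, history


def save_checkpoint(model: RIRNetwork, path: str | Path) -> Path:
    """Write config + named weight arrays to a single-file archive (.npz)."""
    path = Path(path)
    cfg_json = json.dumps(asdict(model.cfg))
    arrays = {
        key.replace(".", "--"): val for key, val in model.state_dict().items()
    }
    with open(path, "wb") as fh:
        np.savez(fh, __config__=np.array(cfg_json), **arrays)
    return path


def load_checkpoint(path: str | Path, expect_scale: int | None = None) -> RIRNetwork:
    """Restore a network with bit-identical forward behavior.

    Raises a ``ValueError`` for missing/corrupt files or when
    ``expect_scale`` disagrees with the checkpoint's declared scale.
    """
    path = Path(path)
    if not path.exists():
        raise ValueError(f"checkpoint not found: {path}")
    try:
        with np.load(path, allow_pickle=False) as data:
            cfg_dict = json.loads(str(data["__config__"]))
            state = {
                key.replace("--", "."): data[key]
                for key in data.files
                if key != "__config__"
            }
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"corrupt checkpoint {path}: {exc}") from exc
    cfg = ModelConfig(**cfg_dict)
    if expect_scale is not None and cfg.scale != expect_scale:
        raise ValueError(
            f"checkpoint declares scale {cfg.scale}, expected {expect_scale}"
        )
    model = RIRNetwork(cfg)
    model.load_state_dict(state)
    if model.n_parameters != count_parameters(cfg):
        raise ValueError("checkpoint parameter count inconsistent with config")
    return model
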