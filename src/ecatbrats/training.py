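"""Training and evaluation loops.

The recipe: Dice-loss minimisation with AdamW (decoupled weight decay) and a
single-cycle cosine-annealed learning rate,

    lr_t = lr_min + (lr_max − lr_min) · (1 + cos(π · E_curr / E_max)) / 2,

stepped once per epoch, starting from lr_max = 5e-5.  Everything is seeded:
the same configuration and cohort reproduce the same loss history bit for
bit on the same hardware.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .data_io import CaseRecord
from .metrics import aggregate, dice_loss, dsc, hausdorff, iou
from .model import ECATBraTS, ModelConfig, tiny_model_config
from .nn import Parameter, Tensor, no_grad
from .decoder import predict_mask
from .synthetic import CohortJitter, PhantomSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "TrainState", "AdamW", "cosine_lr", "train",
           "evaluate", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    lr_max: float = 5e-5
    lr_min: float = 0.0
    epochs: int = 100            # E_max; the schedule spans all epochs
    batch_size: int = 1
    weight_decay: float = 0.01
    betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0
    val_interval: int = 1        # epochs between validation passes
    threshold: float = 0.5

    def __post_init__(self):
        if self.lr_min > self.lr_max:
            raise ValueError("lr_min must be <= lr_max")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


def cosine_lr(e_curr: int, cfg: TrainConfig) -> float:
    """Cosine-annealed learning rate at epoch ``e_curr`` in [0, E_max]."""
    if not 0 <= e_curr <= cfg.epochs:
        raise ValueError(f"epoch {e_curr} outside [0, {cfg.epochs}]")
    if cfg.epochs == 0:
        return cfg.lr_max
    return cfg.lr_min + 0.5 * (cfg.lr_max - cfg.lr_min) * (
        1.0 + math.cos(math.pi * e_curr / cfg.epochs))


class AdamW:
    """Adam with decoupled weight decay (weight decay applied to the
    parameter directly, not through the gradient moments)."""

    def __init__(self, params: list[Parameter], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = float(lr)
        self.betas = betas
        self.eps = float(eps)
        self.weight_decay = float(weight_decay)
        self.t = 0
        self.m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self.v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            p.data = (p.data - self.lr * (update + self.weight_decay * p.data)
                      ).astype(p.data.dtype)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]


@dataclass
class TrainState:
    """Mutable training record: epoch counter, history and best validation."""

    epoch: int = 0
    history: list[dict] = field(default_factory=list)
    best_val_dsc: float = -1.0
    best_weights: dict | None = None


def _case_arrays(case: CaseRecord) -> tuple[np.ndarray, np.ndarray]:
    if case.mask is None:
        raise ValueError(f"case {case.case_id} has no mask; cannot train on it")
    return (case.volume.intensities.astype(np.float32),
            case.mask.channels.astype(np.float32))


def train(model: ECATBraTS, cohort: list[CaseRecord], cfg: TrainConfig,
          val_cohort: list[CaseRecord] | None = None,
          checkpoint_path: str | Path | None = None) -> TrainState:
    """Run ``cfg.epochs`` epochs of Dice-loss minimisation with AdamW.

    Logs (epoch, lr, train loss, validation DSC) into the returned
    :class:`TrainState`; tracks the best-validation weights (validating on
    the training cohort when no validation cohort is given) and optionally
    writes them to ``checkpoint_path``.
    """
    if not cohort:
        raise ValueError("training cohort is empty")
    data = [_case_arrays(c) for c in cohort]
    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=cfg.lr_max, betas=cfg.betas,
                weight_decay=cfg.weight_decay)
    state = TrainState()
    val_cases = val_cohort if val_cohort is not None else cohort

    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg)
        opt.lr = lr
        model.train()
        order = rng.permutation(len(data))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(np.stack([data[i][0] for i in idx]))
            tb = np.stack([data[i][1] for i in idx])
            probs = model(xb)
            loss = dice_loss(probs, tb)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // cfg.batch_size},"
                    f" lr {lr:.3g}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(value)

        record = {"epoch": epoch, "lr": lr, "train_loss": float(np.mean(losses))}
        if (epoch + 1) % cfg.val_interval == 0 or epoch == cfg.epochs - 1:
            val_dsc = _mean_dsc(model, val_cases, cfg.threshold)
            record["val_dsc"] = val_dsc
            if val_dsc > state.best_val_dsc:
                state.best_val_dsc = val_dsc
                state.best_weights = model.state_dict()
                if checkpoint_path is not None:
                    save_checkpoint(checkpoint_path, model, cfg, state)
        state.history.append(record)
        state.epoch = epoch + 1
        logger.info("epoch %d lr %.3g loss %.4f val_dsc %s", epoch, lr,
                    record["train_loss"], record.get("val_dsc"))
    return state


def _mean_dsc(model: ECATBraTS, cases: list[CaseRecord], threshold: float) -> float:
    scores = []
    for case in cases:
        if case.mask is None:
            continue
        probs = model.predict(case.volume.intensities)
        pred = predict_mask(probs, threshold)
        scores.extend(dsc(case.mask.channels[r], pred.channels[r])
                      for r in range(3))
    return float(np.mean(scores)) if scores else float("nan")


def evaluate(model: ECATBraTS, cohort: list[CaseRecord],
             threshold: float = 0.5, hd_mode: str = "symmetric",
             hd_percentile: float = 100.0):
    """Forward pass per case, binarise, score all three metrics per region,
    aggregate into a :class:`~ecatbrats.metrics.MetricReport`.

    Cases without masks are skipped with a warning and counted in the report
    footer; an empty cohort is an error.
    """
    if not cohort:
        raise ValueError("evaluation cohort is empty")
    from .data_io import REGIONS
    rows, skipped = [], 0
    for case in cohort:
        if case.mask is None:
            logger.warning("case %s has no mask; skipped", case.case_id)
            skipped += 1
            continue
        probs = model.predict(case.volume.intensities)
        pred = predict_mask(probs, threshold)
        if not pred.nesting_ok():
            logger.warning("case %s: predicted subregions violate nesting "
                           "(QC flag)", case.case_id)
        spacing = case.volume.spacing
        for r, region in enumerate(REGIONS):
            g, p = case.mask.channels[r], pred.channels[r]
            hd, flagged = hausdorff(g, p, spacing=spacing, mode=hd_mode,
                                    percentile=hd_percentile)
            rows.append({"case_id": case.case_id, "region": region,
                         "dsc": dsc(g, p), "iou": iou(g, p), "hd": hd,
                         "hd_flagged": flagged})
    if not rows:
        raise ValueError("no cases with masks to evaluate")
    report = aggregate(rows)
    report.skipped = skipped
    return report


# -- checkpointing ------------------------------------------------------------

def save_checkpoint(path: str | Path, model: ECATBraTS, cfg: TrainConfig,
                    state: TrainState) -> None:
    """Write weights + full provenance (model and train config, history)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {f"param:{k}": v for k, v in model.state_dict().items()}
    meta = {"model_config": model.cfg.to_dict(),
            "train_config": asdict(cfg),
            "epoch": state.epoch,
            "best_val_dsc": state.best_val_dsc,
            "history": state.history}
    payload["meta_json"] = np.array(json.dumps(meta))
    np.savez(path, **payload)


def load_checkpoint(path: str | Path) -> tuple[ECATBraTS, dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata)."""
    with np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz")
                 else path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta_json"]))
        weights = {k[len("param:"):]: data[k] for k in data.files
                   if k.startswith("param:")}
    model = ECATBraTS(ModelConfig.from_dict(meta["model_config"]))
    model.load_state_dict(weights)
    return model, meta


# -- the documented tiny-scale experiment -------------------------------------

def tiny_train_config(seed: int = 0, epochs: int = 200) -> TrainConfig:
    """Training configuration for the CPU-scale overfitting demonstration:
    a higher peak learning rate suits the small model, and the whole
    4-phantom cohort fits in one batch."""
    return TrainConfig(lr_max=1e-2, epochs=epochs, batch_size=4, seed=seed,
                       val_interval=20)


def tiny_cohort(n: int = 4, seed: int = 0):
    """Four 16-cubed phantoms (radii 6/4/2.5 voxels, noise sigma 0.05) with
    mild geometric jitter — the training set of the overfitting demo."""
    spec = PhantomSpec(grid_shape=(16, 16, 16), radii=(6.0, 4.0, 2.5),
                       noise_sigma=0.05, seed=seed)
    jitter = CohortJitter(radius_scale=(0.85, 1.15), centre_shift=1.5,
                          contrast_scale=(0.9, 1.1))
    return generate_cohort(n, spec, jitter, seed=seed)


def tiny_overfit(seed: int = 0, epochs: int = 200):
    """Train the tiny model on its own 4-phantom cohort; returns
    (final train-set mean DSC, TrainState)."""
    cohort = tiny_cohort(4, seed)
    model = ECATBraTS(tiny_model_config(seed))
    cfg = tiny_train_config(seed, epochs)
    state = train(model, cohort, cfg)
    return _mean_dsc(model, cohort, cfg.threshold), state
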