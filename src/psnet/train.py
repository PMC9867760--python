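"""Training loop, initialization, learning-rate schedule, evaluation, reporting.

The recipe: Adam, batch size 16, 400 epochs at full scale, a warm-up
polynomial learning-rate schedule (linear ramp from 2.1052e-5 over the first
20 epochs, then polynomial decay with power 0.98), weights drawn from
N(0, 0.02²) for convolutional/linear layers and exactly (1, 0) for
normalization scale/shift.  The post-warm-up peak rate is not part of the
published recipe; the default here is ten times the initial rate and is
configuration-exposed.

Evaluation reports per-source-dataset mean Dice/IoU of thresholded
predictions and their unweighted cross-dataset mean; ablation impact is the
percent decrease 100·(full − ablated)/full at one-decimal display rounding.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import TrainConfig
from .data import SampleRecord, load_sample
from .model import PSNet, dice_iou, iou_loss, save_checkpoint
from .nn import Adam, Tensor, no_grad

__all__ = ["lr_at", "init_weights", "train", "evaluate", "MetricsReport",
           "report_ablation_delta", "TrainingDiverged"]


class TrainingDiverged(RuntimeError):
    pass


# -- schedule ------------------------------------------------------------------

def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Learning rate for ``epoch``: linear warm-up then polynomial decay.

    The ramp reaches exactly ``peak_lr`` at ``epoch == warmup_epochs`` and
    decays as peak·(1 − (e−w)/(E−w))^power thereafter, so the schedule is
    continuous at the boundary and strictly decreasing after it.
    """
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    w = cfg.warmup_epochs
    if epoch <= w:
        return cfg.initial_lr + (cfg.peak_lr - cfg.initial_lr) * epoch / w
    frac = (epoch - w) / (cfg.epochs - w)
    return cfg.peak_lr * (1.0 - frac) ** cfg.poly_power


# -- initialization ------------------------------------------------------------

def init_weights(model: PSNet, seed: int = 0) -> None:
    """Reset all parameters to the published initialization, deterministically.

    Convolution and linear weights ~ N(0, 0.02²); their biases 0; all
    normalization scales exactly 1.0 and shifts exactly 0.0; learnable
    rectifier slopes reset to 0.25; positional embeddings ~ N(0, 0.02²).
    """
    from .nn import BatchNorm2d, Conv2d, LayerNorm, Linear, PReLU
    rng = np.random.default_rng(seed)
    for name, module in model.named_modules():
        if isinstance(module, (Conv2d, Linear)):
            module.weight.data = rng.normal(
                0.0, 0.02, module.weight.data.shape).astype(np.float32)
            if module.bias is not None:
                module.bias.data = np.zeros_like(module.bias.data)
        elif isinstance(module, (BatchNorm2d, LayerNorm)):
            module.weight.data = np.ones_like(module.weight.data)
            module.bias.data = np.zeros_like(module.bias.data)
            if isinstance(module, BatchNorm2d):
                module._set_buffer("running_mean",
                                   np.zeros_like(module.running_mean))
                module._set_buffer("running_var",
                                   np.ones_like(module.running_var))
        elif isinstance(module, PReLU):
            module.slope.data = np.full_like(module.slope.data, 0.25)
    for name, p in model.named_parameters():
        if name.endswith("pos_embed"):
            p.data = rng.normal(0.0, 0.02, p.data.shape).astype(np.float32)


# -- data plumbing -------------------------------------------------------------

def _load_batch(records: list[SampleRecord], size: int
                ) -> tuple[np.ndarray, np.ndarray]:
    images, masks = zip(*(load_sample(r, size) for r in records))
    return np.stack(images), np.stack(masks)


# -- evaluation ----------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-source mean Dice/IoU plus the unweighted cross-source mean."""

    per_source: dict[str, dict[str, float]] = field(default_factory=dict)
    n_images: int = 0

    @property
    def mdice(self) -> float:
        return float(np.mean([v["mdice"] for v in self.per_source.values()]))

    @property
    def miou(self) -> float:
        return float(np.mean([v["miou"] for v in self.per_source.values()]))

    def to_dict(self) -> dict:
        return {"per_source": self.per_source, "mdice": self.mdice,
                "miou": self.miou, "n_images": self.n_images}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_scores(cls, per_source_scores: dict[str, tuple[float, float]]
                    ) -> "MetricsReport":
        """Build a report from already-computed per-source (mdice, miou)."""
        return cls(per_source={k: {"mdice": d, "miou": i, "n": 0}
                               for k, (d, i) in per_source_scores.items()})


def evaluate(model: PSNet, records: list[SampleRecord], *,
             batch_size: int = 4, threshold: float = 0.5) -> MetricsReport:
    """Mean per-image Dice/IoU, grouped by source dataset."""
    if not records:
        raise ValueError("cannot evaluate an empty split")
    model.eval()
    size = model.cfg.image_size
    scores: dict[str, list[tuple[float, float]]] = {}
    for start in range(0, len(records), batch_size):
        chunk = records[start:start + batch_size]
        images, masks = _load_batch(chunk, size)
        with no_grad():
            pred = model(Tensor(images)).prediction(threshold)
        for rec, p, g in zip(chunk, pred, masks):
            d, i = dice_iou(p, g.astype(np.uint8))
            scores.setdefault(rec.source, []).append((d, i))
    report = MetricsReport(n_images=len(records))
    for source in sorted(scores):
        arr = np.array(scores[source])
        report.per_source[source] = {"mdice": float(arr[:, 0].mean()),
                                     "miou": float(arr[:, 1].mean()),
                                     "n": len(arr)}
    return report


def report_ablation_delta(full_score: float, ablated_score: float) -> float:
    """Percent decrease 100·(full − ablated)/full, one-decimal rounding."""
    return round(100.0 * (full_score - ablated_score) / full_score, 1)


# -- training loop -------------------------------------------------------------

def train(model: PSNet, train_records: list[SampleRecord],
          valid_records: list[SampleRecord] | None, cfg: TrainConfig, *,
          log_file: str | Path | None = None,
          target_mdice: float | None = None) -> dict:
    """Optimize ``model``; returns a history dict and keeps the best state.

    Fully seeded: batch order derives from ``cfg.seed``.  Divergence (NaN
    loss) aborts with a diagnostic.  ``max_steps`` caps total optimizer
    steps; ``target_mdice`` stops once the *training-set* mDice reaches the
    target (used for small overfitting probes).
    """
    if not train_records:
        raise ValueError("empty training split")
    rng = np.random.default_rng(cfg.seed)
    size = model.cfg.image_size
    history: dict = {"loss": [], "lr": [], "valid": []}
    best = {"mdice": -1.0, "state": None, "epoch": -1}
    log_fh = open(log_file, "a") if log_file else None
    opt = Adam(model.parameters(), lr=cfg.initial_lr)
    step = 0
    try:
        for epoch in range(cfg.epochs):
            opt.lr = lr_at(epoch, cfg)
            model.train()
            order = rng.permutation(len(train_records))
            for start in range(0, len(order), cfg.batch_size):
                batch = [train_records[i] for i in order[start:start + cfg.batch_size]]
                images, masks = _load_batch(batch, size)
                out = model(Tensor(images))
                loss = iou_loss(out.mean, masks)
                value = loss.item()
                if not np.isfinite(value):
                    raise TrainingDiverged(
                        f"non-finite loss {value} at epoch {epoch}, step {step}")
                opt.zero_grad()
                loss.backward()
                opt.step()
                step += 1
                history["loss"].append(value)
                history["lr"].append(opt.lr)
                if log_fh:
                    log_fh.write(json.dumps({"epoch": epoch, "step": step,
                                             "loss": value, "lr": opt.lr}) + "\n")
                if cfg.max_steps is not None and step >= cfg.max_steps:
                    break
            # end-of-epoch bookkeeping
            if target_mdice is not None:
                rep = evaluate(model, train_records, batch_size=cfg.batch_size)
                history.setdefault("train_mdice", []).append(rep.mdice)
                if rep.mdice >= target_mdice:
                    best.update(mdice=rep.mdice, state=model.state_dict(),
                                epoch=epoch)
                    break
            if valid_records and (epoch + 1) % cfg.eval_interval == 0:
                rep = evaluate(model, valid_records, batch_size=cfg.batch_size)
                history["valid"].append({"epoch": epoch, "mdice": rep.mdice,
                                         "miou": rep.miou})
                print(f"epoch {epoch}: loss {value:.4f} "
                      f"valid mDice {rep.mdice:.4f}", file=sys.stderr)
                if rep.mdice > best["mdice"]:
                    best.update(mdice=rep.mdice, state=model.state_dict(),
                                epoch=epoch)
                    if cfg.checkpoint_dir:
                        Path(cfg.checkpoint_dir).mkdir(parents=True, exist_ok=True)
                        save_checkpoint(model,
                                        Path(cfg.checkpoint_dir) / "best.npz")
            if cfg.max_steps is not None and step >= cfg.max_steps:
                break
    finally:
        if log_fh:
            log_fh.close()
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_mdice"] = best["mdice"]
    history["steps"] = step
    return history
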