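"""Training, evaluation, and ablation orchestration.

Optimization uses SGD (learning rate 1e-2, momentum 0.9) minimizing binary
cross-entropy (soft-Dice and compound losses selectable).  Each cross-validation fold trains from the same initial
weights; the per-fold model is the checkpoint with the best validation IoU,
and fold models are scored on the held-out test subset to produce the
mean +/- SD entries of the ablation tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics, nn
from .architectures import network_from_name
from .metrics import MetricReport, aggregate_folds, confusion_counts
from .synthetic import Dataset, SplitPlan, SyntheticStyle, make_splits, synthesize_dataset

log = logging.getLogger("msunet")

LOSSES = ("bce", "dice", "bce+dice")

METRIC_NAMES = ("IoU", "Dice", "Precision", "AUC")


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-2
    momentum: float = 0.9
    epochs: int = 15
    batch_size: int = 4
    loss: str = "bce"
    seed: int = 0
    threshold: float = 0.5

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")


@dataclass
class TrainResult:
    """Outcome of cross-validated training of one architecture."""

    network: nn.Module                       # loaded with the overall-best fold weights
    history: dict[int, dict[str, list[float]]]   # fold -> {"loss": [...], "val_iou": [...]}
    fold_states: list[dict]                  # best checkpoint per fold
    fold_val_iou: list[float]
    best_fold: int


def _loss_fn(pred: nn.Tensor, target: np.ndarray, kind: str) -> nn.Tensor:
    if kind == "bce":
        return nn.bce_loss(pred, target)
    if kind == "dice":
        return nn.dice_loss(pred, target)
    return nn.add(nn.bce_loss(pred, target), nn.dice_loss(pred, target))


def _stack(data: Dataset, idx) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([data.images[i] for i in idx]).astype(np.float32)
    t = np.stack([data.masks[i] for i in idx]).astype(np.float32)[:, None]
    return x, t


def _predict(net: nn.Module, data: Dataset, indices, batch_size: int = 8) -> np.ndarray:
    """Forward pass in eval mode; returns per-pixel probabilities (N,1,H,W)."""
    was_training = net.training
    net.eval()
    chunks = []
    indices = np.asarray(indices)
    for lo in range(0, len(indices), batch_size):
        x, _ = _stack(data, indices[lo:lo + batch_size])
        chunks.append(net(nn.Tensor(x)).data)
    if was_training:
        net.train()
    return np.concatenate(chunks)


def evaluate(net: nn.Module, data: Dataset, indices, threshold: float = 0.5,
             batch_size: int = 8) -> dict[str, float]:
    """Pooled (micro-averaged) IoU/Dice/Precision at ``threshold`` plus AUC
    on the raw probabilities, over the given image indices."""
    indices = np.asarray(indices)
    if indices.size == 0:
        raise ValueError("empty evaluation index set")
    probs = _predict(net, data, indices, batch_size)
    truth = np.stack([data.masks[i] for i in indices])[:, None]
    c = confusion_counts((probs >= threshold).astype(np.uint8), truth)
    out = {"IoU": metrics.iou(c), "Dice": metrics.dice(c), "Precision": metrics.precision(c)}
    out["AUC"] = metrics.roc_auc(probs, truth)
    return out


def _train_one_fold(net: nn.Module, data: Dataset, train_idx, val_idx,
                    cfg: TrainConfig, rng: np.random.Generator):
    """SGD over the fold's training indices; tracks the best-val-IoU state."""
    if len(train_idx) == 0:
        raise ValueError("empty training fold")
    opt = nn.SGD(net.parameters(), lr=cfg.learning_rate, momentum=cfg.momentum)
    history = {"loss": [], "val_iou": []}
    best = {"iou": -1.0, "state": net.state_dict()}
    for epoch in range(cfg.epochs):
        net.train()
        order = rng.permutation(np.asarray(train_idx))
        epoch_loss = 0.0
        for lo in range(0, len(order), cfg.batch_size):
            x, t = _stack(data, order[lo:lo + cfg.batch_size])
            opt.zero_grad()
            loss = _loss_fn(net(nn.Tensor(x)), t, cfg.loss)
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += lval * len(order[lo:lo + cfg.batch_size])
        epoch_loss /= len(order)
        val_iou = evaluate(net, data, val_idx, cfg.threshold)["IoU"] if len(val_idx) else np.nan
        history["loss"].append(epoch_loss)
        history["val_iou"].append(val_iou)
        log.info("epoch=%d loss=%.4f val_iou=%.4f", epoch, epoch_loss, val_iou)
        if len(val_idx) and val_iou > best["iou"]:
            best = {"iou": val_iou, "state": net.state_dict()}
    if cfg.epochs and not len(val_idx):
        best = {"iou": np.nan, "state": net.state_dict()}
    return best, history


def train(net: nn.Module, splits: SplitPlan, data: Dataset, cfg: TrainConfig,
          folds=None) -> TrainResult:
    """Cross-validated training from a common initialization.

    ``folds`` restricts training to a subset of fold indices (default: all).
    With ``epochs=0`` the initial weights are returned untouched.  The
    returned network carries the weights of the fold with the best validation
    IoU; per-fold best checkpoints are kept for test-set scoring.
    """
    init_state = net.state_dict()
    fold_ids = list(range(len(splits.folds))) if folds is None else list(folds)
    history: dict[int, dict] = {}
    states, vals = [], []
    for k in fold_ids:
        train_idx, val_idx = splits.folds[k]
        net.load_state_dict(init_state)
        rng = np.random.default_rng([cfg.seed, k])
        log.info("fold=%d train=%d val=%d", k, len(train_idx), len(val_idx))
        best, hist = _train_one_fold(net, data, train_idx, val_idx, cfg, rng)
        history[k] = hist
        states.append(best["state"])
        vals.append(best["iou"])
    if not states:
        return TrainResult(net, {}, [], [], -1)
    best_fold = int(np.nanargmax(vals)) if np.any(np.isfinite(vals)) else 0
    net.load_state_dict(states[best_fold])
    return TrainResult(network=net, history=history, fold_states=states,
                       fold_val_iou=[float(v) for v in vals],
                       best_fold=fold_ids[best_fold])


# ---------------------------------------------------------------------------
# ablation driver
# ---------------------------------------------------------------------------

@dataclass
class AblationResult:
    rows: dict[str, dict[str, MetricReport]] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    best: str | None = None      # argmax of mean IoU

    def flag_best(self):
        if self.rows:
            self.best = max(self.rows, key=lambda k: self.rows[k]["IoU"].mean)
        return self


def all31_names() -> list[str]:
    from .blocks import enumerate_block_configs
    return [f"msunet:{c.name}" for c in enumerate_block_configs()]


def run_ablation(config_names, style: SyntheticStyle, cfg: TrainConfig, seed: int,
                 n_images: int = 30, out_dir=None, folds=None,
                 **arch_overrides) -> AblationResult:
    """Train each named architecture on identical data/splits and report
    test-set metrics aggregated over folds.

    Completed rows found in ``out_dir/ablation.json`` are skipped, making an
    interrupted run resumable; unknown names are recorded as failures and the
    run continues.
    """
    data = synthesize_dataset(style, n_images, seed)
    splits = make_splits(n_images, seed)
    result = AblationResult()
    out_path = Path(out_dir) / "ablation.json" if out_dir is not None else None
    done: dict = {}
    if out_path is not None and out_path.exists():
        done = json.loads(out_path.read_text())
    for name in config_names:
        if name in done:
            result.rows[name] = {m: MetricReport(m, done[name][m]) for m in METRIC_NAMES}
            log.info("arch=%s resumed from %s", name, out_path)
            continue
        try:
            net = network_from_name(name, seed=cfg.seed, **arch_overrides)
        except KeyError as exc:
            result.failures[name] = str(exc)
            log.warning("arch=%s failed: %s", name, exc)
            continue
        tr = train(net, splits, data, cfg, folds=folds)
        per_fold = {m: [] for m in METRIC_NAMES}
        for state in tr.fold_states:
            net.load_state_dict(state)
            scores = evaluate(net, data, splits.test_indices, cfg.threshold)
            for m in METRIC_NAMES:
                per_fold[m].append(scores[m])
        result.rows[name] = {m: aggregate_folds(per_fold[m], m) for m in METRIC_NAMES}
        log.info("arch=%s IoU=%s", name, result.rows[name]["IoU"])
        if out_path is not None:
            done[name] = {m: per_fold[m] for m in METRIC_NAMES}
            out_path.parent.mkdir(parents=True, exist_ok=True)
            out_path.write_text(json.dumps(done, indent=2))
    return result.flag_best()


def compare(fold_values_a, fold_values_b) -> dict:
    """Two-sample t-test between two architectures' fold values."""
    t, p = metrics.two_sample_t_test(fold_values_a, fold_values_b)
    mean_a, mean_b = float(np.mean(fold_values_a)), float(np.mean(fold_values_b))
    return {"t": t, "p": p,
            "better": "a" if mean_a >= mean_b else "b",
            "mean_a": mean_a, "mean_b": mean_b}


def config_from_yaml(path) -> TrainConfig:
    import yaml
    raw = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name for f in dataclasses.fields(TrainConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return TrainConfig(**raw)
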