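"""Training loop, dataset splitting, segmentation metrics and run comparison.

Training minimises a Focal-Dice compound loss with AdamW (decoupled L2
weight decay) under a cosine-annealing warm-restarts learning-rate
schedule, stopping early when validation loss stalls and restoring the
best-validation weights. Metrics follow the standard confusion-matrix
definitions with crack = positive:

    IoU = TP/(TP+FP+FN)   Precision = TP/(TP+FP)
    Recall = TP/(TP+FN)   F1 = 2TP/(2TP+FP+FN)

so that F1 = 2·IoU/(1+IoU) identically.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import CrackMask, SpectralCube
from .errors import FormatError, ParameterError
from .io_envi import log
from .nn.layers import BatchNorm3d
from .nn.optim import AdamW, CosineAnnealingWarmRestarts

_LOG_EPS = 1e-7
_DICE_SMOOTH = 1.0


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-4
    weight_decay: float = 1e-4
    patience: int = 15
    focal_gamma: float = 2.0
    focal_alpha: float = 0.8   # favours the rare crack class
    dice_weight: float = 0.5
    crop_size: int | None = 32  # training-crop edge; None trains on full images
    crops_per_image: int = 1    # random crops drawn per image per epoch
    augment: bool = True        # random flips/transposes of training crops
    max_batches_per_epoch: int | None = None  # subsample epochs for quick runs
    scheduler_t0: int = 10
    scheduler_t_mult: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.patience < 1:
            raise ParameterError("patience must be >= 1")
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be non-negative")


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.FN + other.FN, self.TN + other.TN)


@dataclass
class MetricsReport:
    iou: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "iou": self.iou, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "TP": self.counts.TP, "FP": self.counts.FP,
            "FN": self.counts.FN, "TN": self.counts.TN,
        }


def split_dataset(sample_ids: list, ratios=(8, 1, 1), seed: int = 0
                  ) -> tuple[list, list, list]:
    """Random disjoint train/val/test partition by largest-remainder sizes.

    400 ids at ratios 8:1:1 give exactly (320, 40, 40).
    """
    ids = list(sample_ids)
    if not ids:
        raise ParameterError("empty id list")
    if len(ids) < 3:
        raise ParameterError("need at least 3 ids to split three ways")
    ratios = np.asarray(ratios, dtype=np.float64)
    if ratios.size != 3 or np.any(ratios <= 0):
        raise ParameterError("ratios must be 3 positive numbers")
    ratios = ratios / ratios.sum()

    n = len(ids)
    quotas = ratios * n
    sizes = np.floor(quotas).astype(int)
    remainder = n - sizes.sum()
    # Largest remainders get the leftover slots; ties to earlier split.
    order = np.argsort(-(quotas - sizes), kind="stable")
    for j in range(remainder):
        sizes[order[j]] += 1
    # Every split gets at least one id.
    for i in range(3):
        if sizes[i] == 0:
            donor = int(np.argmax(sizes))
            sizes[donor] -= 1
            sizes[i] += 1

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [ids[i] for i in perm]
    a, b = sizes[0], sizes[0] + sizes[1]
    return shuffled[:a], shuffled[a:b], shuffled[b:]


def focal_dice_loss(prob: np.ndarray, target: np.ndarray,
                    gamma: float = 2.0, alpha: float = 0.8,
                    dice_weight: float = 0.5,
                    return_grad: bool = False):
    """Compound loss: dice_weight·(1 − soft-Dice) + (1 − dice_weight)·focal.

    ``prob`` holds probabilities in [0, 1]; the focal term is
    −α_t (1 − p_t)^γ log p_t averaged over pixels with
    p_t = p·t + (1−p)(1−t) and α_t = α·t + (1−α)(1−t). Zero (up to the
    log clamp) when the prediction equals a binary target exactly.
    """
    prob = np.asarray(prob, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if prob.shape != target.shape:
        raise FormatError(f"prob {prob.shape} and target {target.shape} differ")

    inter = float((prob * target).sum())
    denom = float(prob.sum() + target.sum()) + _DICE_SMOOTH
    dice = (2.0 * inter + _DICE_SMOOTH) / denom
    loss_dice = 1.0 - dice

    p_t = np.clip(prob * target + (1.0 - prob) * (1.0 - target), _LOG_EPS, 1.0)
    a_t = alpha * target + (1.0 - alpha) * (1.0 - target)
    one_m = 1.0 - p_t
    focal_pix = -a_t * one_m ** gamma * np.log(p_t)
    loss_focal = float(focal_pix.mean())

    loss = dice_weight * loss_dice + (1.0 - dice_weight) * loss_focal
    if not return_grad:
        return loss

    # d(1-dice)/dp
    g_dice = -(2.0 * target * denom - (2.0 * inter + _DICE_SMOOTH)) / denom ** 2
    # d focal/dp via dp_t/dp = 2t - 1 (zero where p_t hit the clamp)
    df_dpt = -a_t * (one_m ** gamma / p_t - gamma * one_m ** (gamma - 1)
                     * np.log(p_t))
    active = (prob * target + (1.0 - prob) * (1.0 - target)) > _LOG_EPS
    g_focal = df_dpt * (2.0 * target - 1.0) * active / prob.size
    grad = dice_weight * g_dice + (1.0 - dice_weight) * g_focal
    return loss, grad.astype(np.float32)


def confusion_counts(pred, gt) -> ConfusionCounts:
    """Pixelwise confusion counts with crack (1) as the positive class."""
    p = pred.labels if isinstance(pred, CrackMask) else np.asarray(pred)
    g = gt.labels if isinstance(gt, CrackMask) else np.asarray(gt)
    if p.shape != g.shape:
        raise FormatError(f"pred {p.shape} and gt {g.shape} shapes differ")
    p = p.astype(bool)
    g = g.astype(bool)
    tp = int(np.count_nonzero(p & g))
    fp = int(np.count_nonzero(p & ~g))
    fn = int(np.count_nonzero(~p & g))
    tn = int(np.count_nonzero(~p & ~g))
    return ConfusionCounts(tp, fp, fn, tn)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """IoU / Precision / Recall / F1 from confusion counts.

    Degenerate images: if ground truth and prediction are both empty
    (TP=FP=FN=0) every metric is 1 by convention; any other zero
    denominator yields 0.
    """
    if c.TP + c.FP + c.FN == 0:
        return MetricsReport(1.0, 1.0, 1.0, 1.0, c)
    iou = c.TP / (c.TP + c.FP + c.FN)
    precision = c.TP / (c.TP + c.FP) if (c.TP + c.FP) else 0.0
    recall = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    f1 = 2 * c.TP / (2 * c.TP + c.FP + c.FN)
    return MetricsReport(iou, precision, recall, f1, c)


def paired_comparison(metric_runs_a, metric_runs_b) -> tuple[float, float]:
    """Two-sided paired t-test on per-run metric values."""
    a = np.asarray(metric_runs_a, dtype=np.float64)
    b = np.asarray(metric_runs_b, dtype=np.float64)
    if a.size != b.size or a.size < 2:
        raise ParameterError("need two equal-length vectors of >= 2 runs")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        log.warning("paired_comparison: zero variance of differences")
        if np.all(diff == 0):
            return 0.0, 1.0
        return (np.inf if diff.mean() > 0 else -np.inf), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def as_pairs(dataset) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize (SpectralCube, CrackMask) pairs to raw (H,W,D)/(H,W) arrays."""
    pairs = []
    for cube, mask in dataset:
        data = cube.data if isinstance(cube, SpectralCube) else np.asarray(cube)
        lab = mask.labels if isinstance(mask, CrackMask) else np.asarray(mask)
        if data.shape[:2] != lab.shape:
            raise FormatError("cube and mask spatial shapes differ")
        pairs.append((np.asarray(data, np.float32), lab.astype(np.float32)))
    return pairs


def _random_crop(data, lab, size, rng, crack_bias=0.7):
    h, w = lab.shape
    if size is None or (h <= size and w <= size):
        return data, lab
    crack_rc = np.argwhere(lab > 0)
    if crack_rc.size and rng.random() < crack_bias:
        r, c = crack_rc[rng.integers(len(crack_rc))]
        r0 = int(np.clip(r - size // 2 + rng.integers(-4, 5), 0, h - size))
        c0 = int(np.clip(c - size // 2 + rng.integers(-4, 5), 0, w - size))
    else:
        r0 = int(rng.integers(0, h - size + 1))
        c0 = int(rng.integers(0, w - size + 1))
    return data[r0:r0 + size, c0:c0 + size], lab[r0:r0 + size, c0:c0 + size]


def _dihedral(data, lab, rng):
    """Random flip/transpose of a (square) crop and its mask."""
    if rng.random() < 0.5:
        data, lab = data[::-1], lab[::-1]
    if rng.random() < 0.5:
        data, lab = data[:, ::-1], lab[:, ::-1]
    if data.shape[0] == data.shape[1] and rng.random() < 0.5:
        data, lab = data.transpose(1, 0, 2), lab.T
    return np.ascontiguousarray(data), np.ascontiguousarray(lab)


def _snapshot(model):
    params = [p.data.copy() for p in model.parameters()]
    bn = [(l.running_mean.copy(), l.running_var.copy())
          for l in model.layers() if isinstance(l, BatchNorm3d)]
    return params, bn


def _restore(model, snap):
    params, bn = snap
    for p, saved in zip(model.parameters(), params):
        p.data[...] = saved
    bns = [l for l in model.layers() if isinstance(l, BatchNorm3d)]
    for layer, (mean, var) in zip(bns, bn):
        layer.running_mean[...] = mean
        layer.running_var[...] = var


def _full_image_prob(model, data: np.ndarray) -> np.ndarray:
    from .nn.models import PixelSpectralNet, _reflect_pad_hw
    div = 1 if isinstance(model, PixelSpectralNet) else model.cfg.spatial_divisor
    padded, (h, w) = _reflect_pad_hw(data, div)
    prob = model.forward(model.prepare_input(padded[None]), training=False)[0]
    return prob[:h, :w]


def evaluate_model(model, dataset, threshold: float | None = None
                   ) -> tuple[MetricsReport, list[MetricsReport]]:
    """Pooled and per-image metrics of a model over (cube, mask) pairs."""
    if threshold is None:
        threshold = model.cfg.threshold
    pooled = ConfusionCounts(0, 0, 0, 0)
    per_image = []
    for data, lab in as_pairs(dataset):
        prob = _full_image_prob(model, data)
        pred = (prob > threshold).astype(np.uint8)
        c = confusion_counts(pred, lab.astype(np.uint8))
        per_image.append(compute_metrics(c))
        pooled = pooled + c
    return compute_metrics(pooled), per_image


def train(model, train_set, val_set, cfg: TrainConfig | None = None
          ) -> tuple[object, dict]:
    """Fit a segmentation model; returns (model, history).

    History holds per-epoch train loss, validation loss, validation F1
    (pooled) and learning rate. Training stops early once validation loss
    has not improved for ``cfg.patience`` epochs and the best-validation
    weights are restored. Fully seeded and deterministic.
    """
    cfg = cfg or TrainConfig()
    train_pairs = as_pairs(train_set)
    val_pairs = as_pairs(val_set)
    if not train_pairs or not val_pairs:
        raise ParameterError("train and validation sets must be non-empty")

    # Input standardization frozen from the training set.
    flat_mean = float(np.mean([d.mean() for d, _ in train_pairs]))
    flat_sd = float(np.mean([d.std() for d, _ in train_pairs]))
    model.input_mean = flat_mean
    model.input_std = max(flat_sd, 1e-6)

    rng = np.random.default_rng(cfg.seed)
    opt = AdamW(model.parameters(), lr=max(cfg.learning_rate, 1e-30),
                weight_decay=cfg.weight_decay)
    opt.lr = cfg.learning_rate
    sched = CosineAnnealingWarmRestarts(opt, t0=cfg.scheduler_t0,
                                        t_mult=cfg.scheduler_t_mult)
    sched.base_lr = cfg.learning_rate
    opt.lr = cfg.learning_rate

    history = {"train_loss": [], "val_loss": [], "val_f1": [], "lr": []}
    best_loss = np.inf
    best_snap = _snapshot(model)
    stale = 0

    for epoch in range(cfg.epochs):
        order = np.concatenate([rng.permutation(len(train_pairs))
                                for _ in range(max(cfg.crops_per_image, 1))])
        if cfg.max_batches_per_epoch is not None:
            order = order[:cfg.max_batches_per_epoch * cfg.batch_size]
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start:start + cfg.batch_size]
            crops = [
                _random_crop(*train_pairs[i], cfg.crop_size, rng)
                for i in batch_idx
            ]
            if cfg.augment:
                crops = [_dihedral(d, l, rng) for d, l in crops]
            xb = np.stack([c[0] for c in crops])
            yb = np.stack([c[1] for c in crops])
            x = model.prepare_input(xb)
            prob = model.forward(x, training=True)
            loss, grad = focal_dice_loss(
                prob, yb, gamma=cfg.focal_gamma, alpha=cfg.focal_alpha,
                dice_weight=cfg.dice_weight, return_grad=True)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            model.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_losses.append(loss)

        val_counts = ConfusionCounts(0, 0, 0, 0)
        val_losses = []
        for data, lab in val_pairs:
            prob = _full_image_prob(model, data)
            val_losses.append(focal_dice_loss(
                prob, lab, gamma=cfg.focal_gamma, alpha=cfg.focal_alpha,
                dice_weight=cfg.dice_weight))
            pred = (prob > model.cfg.threshold).astype(np.uint8)
            val_counts = val_counts + confusion_counts(pred, lab.astype(np.uint8))
        val_loss = float(np.mean(val_losses))
        val_f1 = compute_metrics(val_counts).f1

        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_f1"].append(float(val_f1))
        history["lr"].append(float(opt.lr))

        if val_loss < best_loss:
            best_loss = val_loss
            best_snap = _snapshot(model)
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                log.info("early stop at epoch %d (patience %d)",
                         epoch + 1, cfg.patience)
                break
        sched.step_epoch()

    _restore(model, best_snap)
    return model, history
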