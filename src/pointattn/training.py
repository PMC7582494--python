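"""Training loop, augmentation, robustness perturbations and metrics.

Optimization is SGD with momentum on a cosine
annealing schedule that decays the learning rate from 0.03 to 0 over the
epoch budget. Augmentation is translation + anisotropic scale + point
shuffle; rotation is deliberately absent from training so that the rotation
robustness protocol measures genuine sensitivity.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from . import autodiff as ad
from .autodiff import Tensor
from .geometry import PointCloud
from .layers import seed_dropout
from .networks import ModelState

__all__ = [
    "TrainConfig", "EvalReport", "cosine_lr",
    "augment", "perturb", "cross_entropy",
    "train", "evaluate", "miou", "perturbation_sweep",
    "segment_predict", "evaluate_segmentation", "predict",
]


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    lr: float = 0.03
    momentum: float = 0.9
    weight_decay: float = 1e-4
    translate_range: float = 0.2          # uniform per-axis offset bound
    scale_low: float = 2.0 / 3.0          # anisotropic scale bounds
    scale_high: float = 3.0 / 2.0
    augment: bool = True
    seed: int = 0


@dataclass
class EvalReport:
    overall_accuracy: float               # percent over instances
    mean_class_accuracy: float            # unweighted mean per-class recall
    per_class: dict[int, float] = field(default_factory=dict)
    n_instances: int = 0

    def as_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "mean_class_accuracy": self.mean_class_accuracy,
            "per_class": {int(k): v for k, v in self.per_class.items()},
            "n_instances": self.n_instances,
        }


def cosine_lr(epoch: int, total_epochs: int, lr0: float = 0.03) -> float:
    """Cosine annealing from lr0 at epoch 0 to 0 at the final epoch."""
    return 0.5 * lr0 * (1.0 + np.cos(np.pi * epoch / total_epochs))


# ---------------------------------------------------------------------------
# augmentation and perturbation

def augment(cloud: PointCloud, cfg: TrainConfig,
            rng: np.random.Generator) -> PointCloud:
    """Per-cloud uniform translation, anisotropic scale and point shuffle."""
    t = rng.uniform(-cfg.translate_range, cfg.translate_range, size=3)
    s = rng.uniform(cfg.scale_low, cfg.scale_high, size=3)
    coords = cloud.coords * s + t
    perm = rng.permutation(len(coords))
    labels = (cloud.point_labels[perm]
              if cloud.point_labels is not None else None)
    return PointCloud(coords[perm], point_labels=labels,
                      cloud_label=cloud.cloud_label)


def _rotation_matrix(angle_deg: float, axis: str | np.ndarray) -> np.ndarray:
    if isinstance(axis, str):
        return Rotation.from_euler(axis, angle_deg, degrees=True).as_matrix()
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * axis).as_matrix()


def perturb(cloud: PointCloud, mode: str,
            rng: np.random.Generator | None = None, *,
            n_keep: int | None = None,
            angle_deg: float = 0.0, axis: str | np.ndarray = "x",
            offset: np.ndarray | float = 0.0) -> PointCloud:
    """Test-time robustness perturbations.

    mode='dropout' keeps a uniform random subset of n_keep points;
    mode='rotate' applies a rigid rotation of angle_deg about ``axis``;
    mode='translate' adds a constant offset.
    """
    if mode == "dropout":
        if n_keep is None or n_keep <= 0:
            raise ValueError("dropout requires n_keep >= 1")
        if n_keep > cloud.n_points:
            raise ValueError("n_keep exceeds point count")
        if rng is None:
            raise ValueError("dropout requires an rng")
        sel = rng.choice(cloud.n_points, size=n_keep, replace=False)
        labels = (cloud.point_labels[sel]
                  if cloud.point_labels is not None else None)
        return PointCloud(cloud.coords[sel], point_labels=labels,
                          cloud_label=cloud.cloud_label)
    if mode == "rotate":
        R = _rotation_matrix(angle_deg, axis)
        return PointCloud(cloud.coords @ R.T,
                          point_labels=cloud.point_labels,
                          cloud_label=cloud.cloud_label)
    if mode == "translate":
        return PointCloud(cloud.coords + np.asarray(offset, dtype=float),
                          point_labels=cloud.point_labels,
                          cloud_label=cloud.cloud_label)
    raise ValueError(f"unknown perturbation mode '{mode}'")


# ---------------------------------------------------------------------------
# loss and optimizer

def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against raw logits.

    Accepts (B, m) with (B,) labels or (B, N, P) with (B, N) labels.
    """
    labels = np.asarray(labels, dtype=np.int64)
    logp = ad.log_softmax(logits, axis=-1)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    np.put_along_axis(onehot, labels[..., None], 1.0, axis=-1)
    n = labels.size
    return ad.tsum(logp * Tensor(onehot)) * (-1.0 / n)


class _SGD:
    def __init__(self, params: list[Tensor], momentum: float,
                 weight_decay: float):
        self.params = params
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def step(self, lr: float) -> None:
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - lr * v
            p.zero_grad()


def _collate(clouds: list[PointCloud], dtype) -> np.ndarray:
    return np.stack([c.coords for c in clouds]).astype(dtype)


def _labels(clouds: list[PointCloud]) -> np.ndarray:
    return np.array([c.cloud_label for c in clouds], dtype=np.int64)


def _onehot(categories: np.ndarray, width: int, dtype) -> np.ndarray:
    out = np.zeros((len(categories), width), dtype=dtype)
    out[np.arange(len(categories)), categories] = 1.0
    return out


def train(dataset: list[PointCloud], model: ModelState, cfg: TrainConfig,
          val_set: list[PointCloud] | None = None,
          part_sets: dict[int, list[int]] | None = None) -> ModelState:
    """Fit a model; deterministic given cfg.seed.

    Classification minimizes cross-entropy on cloud labels; segmentation
    (model.task == 'segment') on per-point part labels, with the cloud
    label interpreted as the category for one-hot tiling. Returns the model
    carrying a per-epoch log of (lr, loss, accuracy); when a validation set
    is supplied the best-on-validation weights are restored at the end.
    """
    if not dataset:
        raise ValueError("empty dataset")
    seg = model.task == "segment"
    rng = np.random.default_rng(cfg.seed)
    module = model.module
    seed_dropout(module, rng)
    params = module.parameters()
    opt = _SGD(params, cfg.momentum, cfg.weight_decay)
    dtype = params[0].dtype
    best_score, best_state = -1.0, None
    model.epoch_log = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        lr = cosine_lr(epoch, cfg.epochs, cfg.lr)
        order = rng.permutation(n)
        module.train()
        losses, correct, total = [], 0, 0
        for start in range(0, n, cfg.batch_size):
            batch = [dataset[i] for i in order[start:start + cfg.batch_size]]
            if cfg.augment:
                batch = [augment(c, cfg, rng) for c in batch]
            coords = _collate(batch, dtype)
            if seg:
                onehot = _onehot(_labels(batch), model.config.n_categories,
                                 dtype)
                y = np.stack([c.point_labels for c in batch])
                logits = module(coords, onehot)
            else:
                y = _labels(batch)
                logits = module(coords)
            loss = cross_entropy(logits, y)
            module.zero_grad()
            loss.backward()
            opt.step(lr)
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=-1) == y).sum())
            total += y.size
        entry = {"epoch": epoch, "lr": float(lr),
                 "loss": float(np.mean(losses)),
                 "train_oa": 100.0 * correct / total}
        if val_set:
            if seg:
                cls_miou, inst_miou = evaluate_segmentation(
                    val_set, model, part_sets)
                entry["val_instance_miou"] = inst_miou
                score = inst_miou
            else:
                report = evaluate(val_set, model)
                entry["val_oa"] = score = report.overall_accuracy
            if score >= best_score:
                best_score = score
                best_state = copy.deepcopy(module.state_dict())
        model.epoch_log.append(entry)
    if best_state is not None:
        module.load_state_dict(best_state)
    module.eval()
    return model


# ---------------------------------------------------------------------------
# evaluation metrics

def predict(dataset: list[PointCloud], model: ModelState,
            batch_size: int = 32) -> np.ndarray:
    """Predicted class ids for a list of equally sized clouds."""
    module = model.module
    module.eval()
    dtype = next(iter(module.parameters())).dtype
    preds = []
    for start in range(0, len(dataset), batch_size):
        batch = dataset[start:start + batch_size]
        logits = module(_collate(batch, dtype))
        preds.append(logits.data.argmax(axis=1))
    return np.concatenate(preds)


def evaluate(dataset: list[PointCloud], model: ModelState) -> EvalReport:
    """Overall accuracy and unweighted mean per-class recall, in percent."""
    if not dataset:
        raise ValueError("empty dataset")
    preds = predict(dataset, model)
    y = _labels(dataset)
    oa = 100.0 * float((preds == y).sum()) / len(y)
    per_class: dict[int, float] = {}
    for cls in sorted(set(int(c) for c in y)):
        sel = y == cls
        per_class[cls] = 100.0 * float((preds[sel] == cls).sum()) / int(sel.sum())
    n_classes_total = getattr(getattr(model, "config", None), "n_classes", None)
    if n_classes_total is not None and len(per_class) < n_classes_total:
        warnings.warn("some classes absent from the dataset are excluded "
                      "from the mean class accuracy")
    mca = float(np.mean(list(per_class.values())))
    return EvalReport(oa, mca, per_class, n_instances=len(y))


def segment_predict(dataset: list[PointCloud], model: ModelState,
                    part_sets: dict[int, list[int]],
                    batch_size: int = 16) -> list[np.ndarray]:
    """Per-point part predictions, argmax restricted to each shape's
    category-admissible parts (the standard part-segmentation protocol)."""
    module = model.module
    module.eval()
    dtype = next(iter(module.parameters())).dtype
    preds: list[np.ndarray] = []
    for start in range(0, len(dataset), batch_size):
        batch = dataset[start:start + batch_size]
        onehot = _onehot(_labels(batch), model.config.n_categories, dtype)
        logits = module(_collate(batch, dtype), onehot).data
        for row, cloud in zip(logits, batch):
            parts = np.asarray(part_sets[int(cloud.cloud_label)])
            preds.append(parts[row[:, parts].argmax(axis=-1)])
    return preds


def evaluate_segmentation(dataset: list[PointCloud], model: ModelState,
                          part_sets: dict[int, list[int]]) -> tuple[float, float]:
    """(class mIoU, instance mIoU) in percent for a part-labeled dataset."""
    preds = segment_predict(dataset, model, part_sets)
    labels = [c.point_labels for c in dataset]
    cats = [int(c.cloud_label) for c in dataset]
    return miou(preds, labels, cats, part_sets)


def miou(point_preds: list[np.ndarray], point_labels: list[np.ndarray],
         categories: list[int],
         category_part_sets: dict[int, list[int]]) -> tuple[float, float]:
    """Class and instance mean IoU over part-labeled shapes, in percent.

    Per shape, IoU is averaged over the parts admissible for its category;
    a part absent from both prediction and ground truth contributes IoU 1.
    Instance mIoU averages shape IoUs over all shapes; class mIoU averages
    within each category first, then across categories.
    """
    if not (len(point_preds) == len(point_labels) == len(categories)):
        raise ValueError("inputs must align per shape")
    shape_ious: list[float] = []
    by_cat: dict[int, list[float]] = {}
    for pred, gt, cat in zip(point_preds, point_labels, categories):
        pred = np.asarray(pred)
        gt = np.asarray(gt)
        parts = category_part_sets[cat]
        if not np.isin(gt, parts).all():
            raise ValueError("ground-truth label outside the category's part set")
        ious = []
        for p in parts:
            inter = int(((pred == p) & (gt == p)).sum())
            union = int(((pred == p) | (gt == p)).sum())
            ious.append(1.0 if union == 0 else inter / union)
        s = float(np.mean(ious))
        shape_ious.append(s)
        by_cat.setdefault(cat, []).append(s)
    instance = 100.0 * float(np.mean(shape_ious))
    cls = 100.0 * float(np.mean([np.mean(v) for v in by_cat.values()]))
    return cls, instance


def perturbation_sweep(dataset: list[PointCloud], model: ModelState,
                       rotations: list[float] = (0.0, 10.0, 20.0, 30.0),
                       dropout_keep: list[int] | None = None,
                       axis: str | np.ndarray = "x",
                       translate: float | None = None,
                       seed: int = 0) -> dict:
    """Robustness table: OA under rotation angles, point dropout and
    translation, evaluated without retraining."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {"rotation": {}, "dropout": {}, "translation": {}}
    for angle in rotations:
        rotated = [perturb(c, "rotate", angle_deg=angle, axis=axis)
                   for c in dataset]
        out["rotation"][f"{angle:g}"] = evaluate(rotated, model).as_dict()
    for keep in (dropout_keep or []):
        kept = [perturb(c, "dropout", rng, n_keep=keep) for c in dataset]
        out["dropout"][str(keep)] = evaluate(kept, model).as_dict()
    if translate is not None:
        t = rng.uniform(-translate, translate, size=3)
        moved = [perturb(c, "translate", offset=t) for c in dataset]
        out["translation"][f"{translate:g}"] = evaluate(moved, model).as_dict()
    return out
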