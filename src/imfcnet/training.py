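"""Loss, optimizer, and the three training regimes.

Training follows the reference recipe: cross-entropy loss minimized by
mini-batch SGD (learning rate 0.001, momentum 0.9, L2 regularization 1e-4,
batch size 10), constant learning rate.  The regimes are

* independent subnet training (IFC-Net and MFC-Net each with a standalone
  4-class head, 13 epochs by default),
* sequential fusion: subnet weights frozen bit-for-bit, JMLP trained from
  scratch on the concatenated features (4 epochs), and
* end-to-end: every parameter of the assembled ensemble updated jointly.

Weight decay is applied to all trainable weights except batch-norm
scale/shift.  Data order is reshuffled every epoch from a seed derived from
(run seed, epoch), so runs are reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import tempfile
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .cp_heads import Subnet
from .data import (AugmentationPolicy, DatasetIndex, FoldSplit, SplitPlan,
                   apply_ria, load_image, online_transform, resize,
                   to_rgb_float)
from .ensemble import JMLP, EnsembleNet
from .evaluation import FoldMetrics, confusion, metrics_from_cm
from .nn import functional as F

logger = logging.getLogger("imfcnet")

CE_EPS = 1e-12


@dataclass
class OptimizerConfig:
    lr: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 1e-4
    batch_size: int = 10
    epochs_ifc: int = 13
    epochs_mfc: int = 13
    epochs_jmlp: int = 4
    epochs_end_to_end: int = 13
    lr_drop_factor: float | None = None   # step schedule available but off
    lr_drop_period: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        for name in ("epochs_ifc", "epochs_mfc", "epochs_jmlp",
                     "epochs_end_to_end"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def lr_at(self, epoch: int) -> float:
        if self.lr_drop_factor and self.lr_drop_period:
            return self.lr * self.lr_drop_factor ** (epoch // self.lr_drop_period)
        return self.lr


def cross_entropy(probabilities, true_class: int) -> float:
    """``-log p_true`` for one probability vector (the per-example loss);
    batch losses are means of these.  A probability of exactly zero is
    clamped at 1e-12 with a warning."""
    p = float(np.asarray(probabilities)[true_class])
    if p <= 0.0:
        warnings.warn(f"true-class probability {p} clamped to {CE_EPS}")
        p = CE_EPS
    return -float(np.log(p))


class SGD:
    """Momentum SGD with decoupled parameter groups.

    L2 decay is added to the gradient *before* the momentum buffer
    (``buf = mu * buf + (g + wd * w); w -= lr * buf``), so two steps on a
    constant gradient g with momentum 0.9 and no decay displace the weight
    by ``lr * g * (1 + 1.9)``.
    """

    def __init__(self, decay_params, no_decay_params=(), lr: float = 0.001,
                 momentum: float = 0.9, weight_decay: float = 1e-4):
        self.groups = [
            {"params": list(decay_params), "wd": weight_decay},
            {"params": list(no_decay_params), "wd": 0.0},
        ]
        self.lr = lr
        self.momentum = momentum
        self._buffers: dict[int, np.ndarray] = {}

    def step(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                if p.grad is None:
                    continue
                g = p.grad
                if group["wd"]:
                    g = g + group["wd"] * p.data
                if self.momentum:
                    buf = self._buffers.get(id(p))
                    buf = g if buf is None else self.momentum * buf + g
                    self._buffers[id(p)] = buf
                else:
                    buf = g
                p.data -= (self.lr * buf).astype(np.float32)

    def zero_grad(self) -> None:
        for group in self.groups:
            for p in group["params"]:
                p.zero_grad()


def sgd_step(theta: np.ndarray, gradient: np.ndarray, cfg: OptimizerConfig,
             buffer: np.ndarray | None = None
             ) -> tuple[np.ndarray, np.ndarray]:
    """One functional momentum-SGD update on a raw parameter array; returns
    ``(theta_new, buffer_new)``.  Same variant as :class:`SGD`."""
    g = np.asarray(gradient, dtype=np.float64) + \
        cfg.weight_decay * np.asarray(theta, dtype=np.float64)
    buf = g if buffer is None or not cfg.momentum else cfg.momentum * buffer + g
    return np.asarray(theta) - cfg.lr * buf, buf


def split_decay_params(module: nn.Module):
    """(decayed, undecayed) parameter lists: batch-norm scale/shift are
    excluded from L2 regularization."""
    decay, no_decay = [], []
    for _, mod in module.named_modules():
        target = no_decay if isinstance(mod, nn.BatchNorm2d) else decay
        for p in mod._parameters.values():
            if p is not None and p.requires_grad:
                target.append(p)
    return decay, no_decay


def state_checksum(module: nn.Module) -> str:
    """SHA-256 over the module's parameters (bit-exact freezing contract)."""
    h = hashlib.sha256()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------

class _TrainingSet:
    """Training images cached as resized grayscale uint8; batches are
    standardized (and optionally online-transformed) on assembly."""

    def __init__(self, records, class_labels, input_size: int,
                 policy: AugmentationPolicy):
        self.policy = policy
        self.input_size = input_size
        self.label_map = {c: i for i, c in enumerate(class_labels)}
        self.images = [resize(load_image(r.path), input_size)
                       for r in records]
        self.targets = np.array([self.label_map[r.label] for r in records])

    def __len__(self):
        return len(self.images)

    def batch(self, ids, rng: np.random.Generator | None = None) -> np.ndarray:
        xs = []
        for i in ids:
            img = self.images[i]
            if self.policy.mode == "online" and rng is not None:
                img = online_transform(img, rng, self.policy)
            xs.append((to_rgb_float(img) - 0.5) / 0.25)
        return np.stack(xs)


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, epoch)))


def _maybe_ria(index: DatasetIndex, fold: FoldSplit,
               policy: AugmentationPolicy, work_dir=None) -> DatasetIndex:
    """Training subset of the fold, RIA-expanded when the policy says so.
    Validation/test records are taken straight from the fold, untouched."""
    train_index = index.subset(fold.train)
    if policy.mode != "ria":
        return train_index
    out = work_dir or tempfile.mkdtemp(prefix="ria_")
    return apply_ria(train_index, policy.ria_angles, out, overwrite=True,
                     fill=policy.fill)


# ---------------------------------------------------------------------------
# evaluation passes
# ---------------------------------------------------------------------------

def _forward_batches(forward, n, batch_size, assemble):
    outs = []
    for lo in range(0, n, batch_size):
        ids = range(lo, min(lo + batch_size, n))
        outs.append(forward(assemble(ids)))
    return np.concatenate(outs)


def evaluate_subnet(subnet: Subnet, records, batch_size: int = 10
                    ) -> tuple[np.ndarray, np.ndarray]:
    """(predicted labels, mean CE loss is not needed here) -> (y_true, y_pred)
    as label strings, eval mode, no augmentation."""
    subnet.eval()
    ts = _TrainingSet(records, subnet.class_labels, subnet.input_size,
                      AugmentationPolicy(mode="none"))
    with nn.no_grad():
        logits = _forward_batches(
            lambda x: subnet.logits(nn.Tensor(x)).data, len(ts), batch_size,
            lambda ids: ts.batch(list(ids)))
    pred = np.argmax(logits, axis=1)
    labels = np.array(subnet.class_labels)
    return labels[ts.targets], labels[pred]


def evaluate_ensemble(ens: EnsembleNet, records, batch_size: int = 10
                      ) -> tuple[np.ndarray, np.ndarray]:
    ens.eval()
    ts_i = _TrainingSet(records, ens.class_labels, ens.subnet_i.input_size,
                        AugmentationPolicy(mode="none"))
    ts_m = _TrainingSet(records, ens.class_labels, ens.subnet_m.input_size,
                        AugmentationPolicy(mode="none"))
    n = len(ts_i)
    logits = []
    with nn.no_grad():
        for lo in range(0, n, batch_size):
            ids = list(range(lo, min(lo + batch_size, n)))
            logits.append(ens(nn.Tensor(ts_i.batch(ids)),
                              nn.Tensor(ts_m.batch(ids))).data)
    pred = np.argmax(np.concatenate(logits), axis=1)
    labels = np.array(ens.class_labels)
    return labels[ts_i.targets], labels[pred]


def _accuracy_and_loss(logits: np.ndarray, targets: np.ndarray
                       ) -> tuple[float, float]:
    probs = F.softmax(logits, axis=1)
    acc = 100.0 * float(np.mean(np.argmax(logits, axis=1) == targets))
    loss = float(np.mean(-np.log(
        np.maximum(probs[np.arange(len(targets)), targets], CE_EPS))))
    return acc, loss


# ---------------------------------------------------------------------------
# training regimes
# ---------------------------------------------------------------------------

def train_subnet(subnet: Subnet, fold: FoldSplit, index: DatasetIndex,
                 policy: AugmentationPolicy, cfg: OptimizerConfig,
                 epochs: int, target_train_acc: float | None = None,
                 work_dir=None, stage: str = "subnet") -> dict:
    """Train a standalone-head subnet on one fold's training set.

    Records per-epoch train/val accuracy and loss; keeps the final-epoch
    weights (no early model selection).  ``target_train_acc`` optionally
    stops as soon as an eval-mode pass over the training set reaches the
    target (used for convergence studies); the reported ``final_train_acc``
    always comes from a full eval-mode pass.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if len(fold.train) == 0:
        raise ValueError("empty training set")
    if subnet.head is None:
        raise ValueError("subnet has no standalone head; build with "
                         "with_head=True for independent training")
    train_index = _maybe_ria(index, fold, policy, work_dir)
    ts = _TrainingSet(train_index.records, subnet.class_labels,
                      subnet.input_size, policy)
    val_records = [index.records[i] for i in fold.val]
    decay, no_decay = split_decay_params(subnet)
    opt = SGD(decay, no_decay, cfg.lr, cfg.momentum, cfg.weight_decay)
    history = []
    n = len(ts)
    final_train_acc = None
    for epoch in range(epochs):
        subnet.train()
        opt.lr = cfg.lr_at(epoch)
        rng = _epoch_rng(cfg.seed, epoch)
        order = rng.permutation(n)
        losses, correct = [], 0
        for lo in range(0, n, cfg.batch_size):
            ids = order[lo:lo + cfg.batch_size]
            x = nn.Tensor(ts.batch(ids, rng))
            logits = subnet.logits(x)
            loss = F.cross_entropy_logits(logits, ts.targets[ids])
            subnet.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            correct += int((np.argmax(logits.data, 1) == ts.targets[ids]).sum())
        train_acc = 100.0 * correct / n
        val_acc, val_loss = np.nan, np.nan
        if val_records:
            y_true, y_pred = evaluate_subnet(subnet, val_records,
                                             cfg.batch_size)
            val_acc = 100.0 * float(np.mean(y_true == y_pred))
        history.append({"epoch": epoch, "stage": stage,
                        "train_loss": float(np.mean(losses)),
                        "train_acc": train_acc,
                        "val_acc": val_acc, "val_loss": val_loss})
        logger.info("[%s] epoch %d loss %.4f train_acc %.1f val_acc %.1f",
                    stage, epoch, history[-1]["train_loss"], train_acc,
                    val_acc)
        if target_train_acc is not None and train_acc >= target_train_acc:
            y_true, y_pred = evaluate_subnet(
                subnet, train_index.records, cfg.batch_size)
            final_train_acc = 100.0 * float(np.mean(y_true == y_pred))
            if final_train_acc >= target_train_acc:
                break
            final_train_acc = None
    if final_train_acc is None:
        y_true, y_pred = evaluate_subnet(subnet, train_index.records,
                                         cfg.batch_size)
        final_train_acc = 100.0 * float(np.mean(y_true == y_pred))
    subnet.trained_fold = fold.fold
    return {"history": pd.DataFrame(history), "fold": fold.fold,
            "final_train_acc": final_train_acc,
            "checksum": state_checksum(subnet)}


def _cached_features(subnet: Subnet, ts: _TrainingSet, batch_size: int
                     ) -> np.ndarray:
    subnet.eval()
    with nn.no_grad():
        return _forward_batches(
            lambda x: subnet.features(nn.Tensor(x)).data, len(ts),
            batch_size, lambda ids: ts.batch(list(ids)))


def train_sequential(ifc: Subnet, mfc: Subnet, jmlp: JMLP, fold: FoldSplit,
                     index: DatasetIndex, policy: AugmentationPolicy,
                     cfg: OptimizerConfig, work_dir=None) -> EnsembleNet:
    """Freeze the trained subnets and train the JMLP on their features.

    The subnets must have been trained on the same fold; their parameters
    are bit-identical before and after (checked by checksum).  Frozen
    batch-norm layers run in inference-statistics mode.
    """
    for sub, name in ((ifc, "IFC"), (mfc, "MFC")):
        trained_fold = getattr(sub, "trained_fold", None)
        if trained_fold is not None and trained_fold != fold.fold:
            raise ValueError(
                f"{name} subnet was trained on fold {trained_fold}, "
                f"sequential fusion requested on fold {fold.fold}")
    before = (state_checksum(ifc), state_checksum(mfc))
    ifc.freeze().eval()
    mfc.freeze().eval()
    train_index = _maybe_ria(index, fold, policy, work_dir)
    ts_i = _TrainingSet(train_index.records, ifc.class_labels,
                        ifc.input_size, policy)
    ts_m = _TrainingSet(train_index.records, mfc.class_labels,
                        mfc.input_size, policy)
    targets = ts_i.targets
    online = policy.mode == "online"
    if not online:  # frozen subnets + fixed images: features are constant
        feats = np.concatenate([
            _cached_features(ifc, ts_i, cfg.batch_size),
            _cached_features(mfc, ts_m, cfg.batch_size)], axis=1)
    decay, no_decay = split_decay_params(jmlp)
    opt = SGD(decay, no_decay, cfg.lr, cfg.momentum, cfg.weight_decay)
    n = len(targets)
    for epoch in range(cfg.epochs_jmlp):
        rng = _epoch_rng(cfg.seed + 1000, epoch)
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            ids = order[lo:lo + cfg.batch_size]
            if online:
                with nn.no_grad():
                    f = np.concatenate([
                        ifc.features(nn.Tensor(ts_i.batch(ids, rng))).data,
                        mfc.features(nn.Tensor(ts_m.batch(ids, rng))).data],
                        axis=1)
            else:
                f = feats[ids]
            loss = F.cross_entropy_logits(jmlp(nn.Tensor(f)), targets[ids])
            jmlp.zero_grad()
            loss.backward()
            opt.step()
    after = (state_checksum(ifc), state_checksum(mfc))
    if before != after:  # pragma: no cover - structural guarantee
        raise RuntimeError("frozen subnet parameters changed during fusion")
    ens = EnsembleNet(ifc, mfc, jmlp)
    ens.trained_fold = fold.fold
    return ens


def train_end_to_end(ens: EnsembleNet, fold: FoldSplit, index: DatasetIndex,
                     policy: AugmentationPolicy, cfg: OptimizerConfig,
                     epochs: int | None = None, work_dir=None) -> EnsembleNet:
    """Joint training of both subnets and the JMLP with CE + SGD."""
    epochs = epochs if epochs is not None else cfg.epochs_end_to_end
    train_index = _maybe_ria(index, fold, policy, work_dir)
    ts_i = _TrainingSet(train_index.records, ens.class_labels,
                        ens.subnet_i.input_size, policy)
    ts_m = _TrainingSet(train_index.records, ens.class_labels,
                        ens.subnet_m.input_size, policy)
    targets = ts_i.targets
    decay, no_decay = split_decay_params(ens)
    opt = SGD(decay, no_decay, cfg.lr, cfg.momentum, cfg.weight_decay)
    n = len(targets)
    for epoch in range(epochs):
        ens.train()
        opt.lr = cfg.lr_at(epoch)
        rng = _epoch_rng(cfg.seed + 2000, epoch)
        order = rng.permutation(n)
        for lo in range(0, n, cfg.batch_size):
            ids = order[lo:lo + cfg.batch_size]
            logits = ens(nn.Tensor(ts_i.batch(ids, rng)),
                         nn.Tensor(ts_m.batch(ids, rng)))
            loss = F.cross_entropy_logits(logits, targets[ids])
            ens.zero_grad()
            loss.backward()
            opt.step()
    ens.trained_fold = fold.fold
    return ens


# ---------------------------------------------------------------------------
# cross-validation driver
# ---------------------------------------------------------------------------

def cross_validate(builders: dict, plan: SplitPlan, index: DatasetIndex,
                   policy: AugmentationPolicy, cfg: OptimizerConfig,
                   mode: str = "sequential", work_dir=None
                   ) -> list[FoldMetrics]:
    """Train and test one model per fold; identical folds across modes make
    the per-fold metric lists pairable for t-tests.

    ``builders`` maps ``'ifc'``/``'mfc'`` to ``callable(seed) -> Subnet``
    and (for ensemble modes) ``'jmlp'`` to ``callable(seed) -> JMLP``.
    Modes: ``'ifc'`` / ``'mfc'`` (subnet-only), ``'sequential'``,
    ``'end_to_end'``.
    """
    results: list[FoldMetrics] = []
    for fold in plan.folds:
        seed = int(np.random.SeedSequence((cfg.seed, fold.fold))
                   .generate_state(1)[0] % (2 ** 31))
        fold_cfg = _with_seed(cfg, seed)
        test_records = [index.records[i] for i in fold.test]
        if set(fold.test) & (set(fold.train) | set(fold.val)):
            raise ValueError(f"fold {fold.fold}: test ids leak into train/val")
        if mode in ("ifc", "mfc"):
            sub = builders[mode](seed)
            epochs = cfg.epochs_ifc if mode == "ifc" else cfg.epochs_mfc
            train_subnet(sub, fold, index, policy, fold_cfg, epochs,
                         work_dir=work_dir, stage=mode.upper())
            y_true, y_pred = evaluate_subnet(sub, test_records,
                                             cfg.batch_size)
            labels = sub.class_labels
        elif mode == "sequential":
            ifc = builders["ifc"](seed)
            mfc = builders["mfc"](seed + 1)
            train_subnet(ifc, fold, index, policy, fold_cfg, cfg.epochs_ifc,
                         work_dir=work_dir, stage="IFC")
            train_subnet(mfc, fold, index, policy, fold_cfg, cfg.epochs_mfc,
                         work_dir=work_dir, stage="MFC")
            ens = train_sequential(ifc, mfc, builders["jmlp"](seed + 2),
                                   fold, index, policy, fold_cfg,
                                   work_dir=work_dir)
            y_true, y_pred = evaluate_ensemble(ens, test_records,
                                               cfg.batch_size)
            labels = ens.class_labels
        elif mode == "end_to_end":
            ifc = builders["ifc"](seed)
            mfc = builders["mfc"](seed + 1)
            ens = EnsembleNet(ifc, mfc, builders["jmlp"](seed + 2))
            train_end_to_end(ens, fold, index, policy, fold_cfg,
                             work_dir=work_dir)
            y_true, y_pred = evaluate_ensemble(ens, test_records,
                                               cfg.batch_size)
            labels = ens.class_labels
        else:
            raise ValueError(f"unknown mode {mode!r}")
        cm = confusion(y_true, y_pred, labels)
        fm = metrics_from_cm(cm)
        fm.fold_id = fold.fold
        fm.model_tag = mode
        results.append(fm)
        logger.info("[%s] fold %d ACC %.2f", mode, fold.fold, fm.acc)
    return results


def _with_seed(cfg: OptimizerConfig, seed: int) -> OptimizerConfig:
    from dataclasses import replace
    return replace(cfg, seed=seed)
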