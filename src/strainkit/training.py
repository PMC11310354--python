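"""Losses, dataset splitting, and the optimization loop.

The classifier is trained with cross-entropy over the three deformation
classes; each regressor is trained only on its own class's samples with
the mean l2 loss over the full symmetric strain tensor.  Note the tensor
double sum counts the shear component twice (epsilon_xy appears at both
off-diagonal positions), so shear errors carry twice the weight of the
normal components — a "3-channel MSE" would weight them equally and give
different numbers.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .model import (
    DeformationClassifier,
    StrainUNet,
    build_classifier,
    build_regressor,
    normalize_pair,
    regressor_input,
    softmax,
)
from .nn import Adam, BatchNorm
from .types import CLASS_NAMES, DeformationClass, StrainField, SyntheticSample

__all__ = [
    "TrainingConfig",
    "TrainingReport",
    "TwoStageModel",
    "cross_entropy",
    "mean_l2_loss",
    "split_dataset",
    "train_all",
    "recalibrate_batchnorm",
]

#: Weight of each stored strain channel (exx, exy, eyy) in the tensor
#: double sum: the off-diagonal entry appears at ij = 12 and ij = 21.
TENSOR_CHANNEL_WEIGHTS = np.array([1.0, 2.0, 1.0])


def cross_entropy(probs: Sequence[float], label: DeformationClass | int) -> float:
    """Cross-entropy -sum_i y_i log p_i of a 3-class prediction."""
    p = np.asarray(probs, dtype=float)
    if p.shape != (len(CLASS_NAMES),):
        raise ValueError(f"expected {len(CLASS_NAMES)} probabilities")
    idx = label.index if isinstance(label, DeformationClass) else int(label)
    return float(-np.log(np.clip(p[idx], 1e-12, 1.0)))


def _truth_channels(fields) -> np.ndarray:
    """Stack StrainFields (or ready (N,H,W,3) arrays) channel-last."""
    if isinstance(fields, np.ndarray):
        return fields
    first = fields[0]
    if isinstance(first, StrainField):
        return np.stack([np.moveaxis(f.channels(), 0, -1) for f in fields])
    return np.stack(fields)


def mean_l2_loss(pred, truth) -> float:
    """Mean squared strain-tensor error over examples and pixels.

    Accepts batches of StrainField or (N, H, W, 3) arrays with channels
    (exx, exy, eyy).  The full 2x2 tensor is expanded with
    eps_yx = eps_xy, so the shear difference is counted twice.
    """
    p = _truth_channels(pred)
    t = _truth_channels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    n = p.shape[0]
    n_pix = p[0, ..., 0].size
    sq = (p - t) ** 2 * TENSOR_CHANNEL_WEIGHTS
    return float(sq.sum() / (n * n_pix))


def split_dataset(
    samples: list[SyntheticSample],
    val_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[SyntheticSample], list[SyntheticSample]]:
    """Random class-stratified split into train and validation sets.

    The total training size is ceil((1 - val_fraction) * n); per-class
    allocations follow largest remainders so every class with at least
    two samples lands in both splits.
    """
    n = len(samples)
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError("val_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    target_train = int(np.ceil((1.0 - val_fraction) * n))

    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.cls.label, []).append(i)
    labels = sorted(by_class)
    quotas = {}
    shares = {c: (1.0 - val_fraction) * len(by_class[c]) for c in labels}
    for c in labels:
        quotas[c] = int(np.floor(shares[c]))
        # keep both splits non-empty per class where possible
        quotas[c] = min(max(quotas[c], 1), len(by_class[c]) - 1) \
            if len(by_class[c]) >= 2 else quotas[c]
    remainders = sorted(labels, key=lambda c: shares[c] - np.floor(shares[c]),
                        reverse=True)
    k = 0
    while sum(quotas.values()) < target_train:
        c = remainders[k % len(remainders)]
        if quotas[c] < len(by_class[c]) - 1:
            quotas[c] += 1
        k += 1
        if k > 10 * len(labels):
            break
    train_idx: list[int] = []
    val_idx: list[int] = []
    for c in labels:
        idx = np.array(by_class[c])
        rng.shuffle(idx)
        train_idx += idx[: quotas[c]].tolist()
        val_idx += idx[quotas[c]:].tolist()
    return [samples[i] for i in sorted(train_idx)], \
           [samples[i] for i in sorted(val_idx)]


@dataclass
class TrainingConfig:
    """Hyperparameters of the four-subnetwork training run.

    Defaults mirror the full-scale recipe (Adam, lr 1e-3, 100 epochs,
    batch 100 for the classifier and 10 for the regressors, 80/20
    split); the ``tiny`` profile shrinks epochs and network widths to
    something a single CPU core trains in minutes.
    """

    learning_rate: float = 1e-3
    epochs: int = 100
    batch_classifier: int = 100
    batch_regressor: int = 10
    val_fraction: float = 0.2
    seed: int = 0
    profile: str = "full"
    classifier_widths: tuple[int, ...] = (16, 32, 64, 128)
    regressor_widths: tuple[int, ...] = (16, 32, 64, 128)
    fc_width: int = 128
    regressor_lr: float | None = None
    lr_schedule: str = "constant"

    def __post_init__(self) -> None:
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if min(self.batch_classifier, self.batch_regressor) < 1:
            raise ValueError("batch sizes must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")

    @classmethod
    def tiny(cls, seed: int = 0, epochs: int = 30) -> "TrainingConfig":
        """Desk-scale profile: 64 px frames, minutes of CPU training.

        Compared with the full recipe it narrows the networks, raises
        the regressor learning rate, and anneals it with a cosine
        schedule — at a few hundred samples and a few hundred optimizer
        steps the higher decaying rate is what lets the regressors
        converge.
        """
        return cls(
            epochs=epochs,
            batch_classifier=8,
            seed=seed,
            profile="tiny",
            classifier_widths=(8, 16, 32, 64),
            regressor_widths=(8, 16, 32, 64),
            fc_width=64,
            regressor_lr=3e-3,
            lr_schedule="cosine",
        )

    def lr_at(self, base: float, epoch: int) -> float:
        if self.lr_schedule == "constant":
            return base
        frac = epoch / max(self.epochs - 1, 1)
        return base * (0.05 + 0.95 * 0.5 * (1 + np.cos(np.pi * frac)))


@dataclass
class TrainingReport:
    """Per-epoch losses and final validation metrics of one run."""

    history: dict[str, dict[str, list[float]]]
    final_val_accuracy: float
    final_val_l2: dict[str, float]
    best_epoch: dict[str, int]
    wall_clock_s: float
    seed: int

    @property
    def mean_val_l2(self) -> float:
        return float(np.mean(list(self.final_val_l2.values())))


@dataclass
class TwoStageModel:
    """The trained pair of stages: one classifier + one regressor per class."""

    classifier: DeformationClassifier
    regressors: dict[str, StrainUNet]

    def __post_init__(self) -> None:
        missing = set(CLASS_NAMES) - set(self.regressors)
        if missing:
            raise ValueError(f"missing regressors for {sorted(missing)}")


def _pair_batch(
    samples: list[SyntheticSample], method: str = "minmax"
) -> np.ndarray:
    return np.concatenate(
        [normalize_pair(s.image_ref, s.image_def, method) for s in samples]
    )


def _regressor_batch(
    samples: list[SyntheticSample], features: str
) -> np.ndarray:
    return np.concatenate(
        [regressor_input(s.image_ref, s.image_def, features)
         for s in samples]
    )


def _snapshot(model) -> list[np.ndarray]:
    state = [p.value.copy() for p in model.params()]
    state += [bn.running_mean.copy() for bn in _bns(model)]
    state += [bn.running_var.copy() for bn in _bns(model)]
    return state


def _restore(model, state: list[np.ndarray]) -> None:
    ps = model.params()
    bns = _bns(model)
    for p, v in zip(ps, state[: len(ps)]):
        p.value[...] = v
    for bn, v in zip(bns, state[len(ps): len(ps) + len(bns)]):
        bn.running_mean[...] = v
    for bn, v in zip(bns, state[len(ps) + len(bns):]):
        bn.running_var[...] = v


def _bns(model) -> list[BatchNorm]:
    from .model import _batchnorms

    return _batchnorms(model)


def recalibrate_batchnorm(model, x: np.ndarray, batch: int = 48) -> None:
    """Re-estimate BatchNorm running statistics on a reference batch.

    Small-batch training leaves the exponential running stats lagging the
    true activation statistics, which corrupts evaluation-mode forward
    passes.  This replaces them with the average batch statistics over
    ``x`` (cumulative-average momenta), leaving weights untouched.
    """
    bns = _bns(model)
    saved = [bn.momentum for bn in bns]
    n_batches = int(np.ceil(len(x) / batch))
    for i in range(n_batches):
        for bn in bns:
            bn.momentum = 1.0 / (i + 1)
        model.forward(x[i * batch: (i + 1) * batch], train=True)
    for bn, m in zip(bns, saved):
        bn.momentum = m


def _train_classifier(
    train: list[SyntheticSample],
    val: list[SyntheticSample],
    config: TrainingConfig,
    log: dict,
) -> tuple[DeformationClassifier, float, int]:
    h, w = train[0].image_ref.shape
    clf = build_classifier((h, w), config.classifier_widths, config.fc_width,
                           seed=config.seed)
    opt = Adam(clf.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    norm = clf.normalization
    x_tr = _pair_batch(train, norm)
    y_tr = np.array([s.cls.index for s in train])
    x_va = _pair_batch(val, norm)
    y_va = np.array([s.cls.index for s in val])
    onehot = np.eye(len(CLASS_NAMES))

    calib = x_tr[: min(len(x_tr), 96)]
    # checkpoint selection: highest validation accuracy, then lowest
    # validation cross-entropy
    best = (-1.0, np.inf, -1, None)
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(config.learning_rate, epoch)
        order = rng.permutation(len(train))
        tr_loss = 0.0
        for start in range(0, len(order), config.batch_classifier):
            idx = order[start: start + config.batch_classifier]
            probs = softmax(clf.forward(x_tr[idx], train=True))
            y = onehot[y_tr[idx]]
            tr_loss += float(
                -(y * np.log(np.clip(probs, 1e-12, 1.0))).sum()
            )
            opt.zero_grad()
            clf.backward((probs - y) / len(idx))
            opt.step()
        recalibrate_batchnorm(clf, calib)
        probs_va = clf.predict_probs(x_va)
        va_loss = float(np.mean(
            [-np.log(np.clip(probs_va[i, y_va[i]], 1e-12, 1.0))
             for i in range(len(val))]
        ))
        va_acc = float(np.mean(np.argmax(probs_va, axis=1) == y_va))
        log["train_loss"].append(tr_loss / len(train))
        log["val_loss"].append(va_loss)
        if (va_acc, -va_loss) > (best[0], -best[1]):
            best = (va_acc, va_loss, epoch, _snapshot(clf))
    _restore(clf, best[3])
    acc = float(np.mean(np.argmax(clf.predict_probs(x_va), axis=1) == y_va))
    return clf, acc, best[2]


def _train_regressor(
    label: str,
    train: list[SyntheticSample],
    val: list[SyntheticSample],
    config: TrainingConfig,
    log: dict,
) -> tuple[StrainUNet, float, int]:
    net = build_regressor(config.regressor_widths,
                          seed=config.seed + 10 + CLASS_NAMES.index(label))
    opt = Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 100 + CLASS_NAMES.index(label))
    x_tr = _regressor_batch(train, net.features)
    t_tr = _truth_channels([s.truth for s in train])
    x_va = _regressor_batch(val, net.features)
    t_va = _truth_channels([s.truth for s in val])
    n_pix = t_tr[0, ..., 0].size

    base_lr = config.regressor_lr or config.learning_rate
    calib = x_tr[: min(len(x_tr), 96)]
    best = (np.inf, -1, None)
    for epoch in range(config.epochs):
        opt.lr = config.lr_at(base_lr, epoch)
        order = rng.permutation(len(train))
        tr_loss = 0.0
        for start in range(0, len(order), config.batch_regressor):
            idx = order[start: start + config.batch_regressor]
            pred = net.forward(x_tr[idx], train=True)
            diff = pred - t_tr[idx]
            tr_loss += float(
                (diff**2 * TENSOR_CHANNEL_WEIGHTS).sum() / n_pix
            )
            opt.zero_grad()
            net.backward(2.0 * TENSOR_CHANNEL_WEIGHTS * diff
                         / (len(idx) * n_pix))
            opt.step()
        recalibrate_batchnorm(net, calib)
        va_pred = net.predict_field(x_va)
        va_loss = mean_l2_loss(va_pred, t_va)
        log["train_loss"].append(tr_loss / len(train))
        log["val_loss"].append(va_loss)
        if va_loss < best[0]:
            best = (va_loss, epoch, _snapshot(net))
    _restore(net, best[2])
    return net, best[0], best[1]


def train_all(
    dataset: list[SyntheticSample],
    config: TrainingConfig | None = None,
) -> tuple[TwoStageModel, TrainingReport]:
    """Train the classifier and the three per-class regressors.

    The dataset is split 80/20 (stratified); the classifier sees every
    pair, each regressor only its own class; the checkpoint with the
    lowest validation loss is retained per subnetwork.
    """
    config = config or TrainingConfig()
    t0 = time.perf_counter()
    train, val = split_dataset(dataset, config.val_fraction, config.seed)
    present = {s.cls.label for s in train}
    if present != set(CLASS_NAMES):
        raise ValueError(
            f"training split is missing classes {set(CLASS_NAMES) - present}"
        )
    history: dict[str, dict[str, list[float]]] = {
        name: {"train_loss": [], "val_loss": []}
        for name in ("classifier",) + CLASS_NAMES
    }
    best_epoch: dict[str, int] = {}

    clf, acc, be = _train_classifier(train, val, config, history["classifier"])
    best_epoch["classifier"] = be

    regressors: dict[str, StrainUNet] = {}
    final_l2: dict[str, float] = {}
    for label in CLASS_NAMES:
        tr = [s for s in train if s.cls.label == label]
        va = [s for s in val if s.cls.label == label] or tr[:1]
        net, l2, be = _train_regressor(label, tr, va, config, history[label])
        regressors[label] = net
        final_l2[label] = l2
        best_epoch[label] = be

    report = TrainingReport(
        history=history,
        final_val_accuracy=acc,
        final_val_l2=final_l2,
        best_epoch=best_epoch,
        wall_clock_s=time.perf_counter() - t0,
        seed=config.seed,
    )
    return TwoStageModel(clf, regressors), report
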