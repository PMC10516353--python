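"""CNN training on reference images and probability inference for queries.

Training follows the usual supervised recipe for this task: a stratified
85:15 train/validation split, label-smoothed cross-entropy (eps = 0.1), and
early stopping on validation loss with best-weight restoration. The default
backbone is the dependency-free :class:`~scpix.nn.SmallCNN`; the
``pretrained_b3`` backbone name is reserved for a torch/EfficientNet adapter
and raises if that backend is unavailable.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .mapping import ImageStack
from .nn import Adam, SmallCNN, smooth_targets, smoothed_ce_loss, soft_ce_loss, softmax


@dataclass
class TrainConfig:
    val_fraction: float = 0.15
    batch_size: int = 128
    max_epochs: int = 50
    patience: int = 5
    label_smoothing_eps: float = 0.1
    learning_rate: float = 3e-3
    weight_decay: float = 0.03
    # L1 (proximal soft-threshold) penalties: the true discriminant over gene
    # images is sparse — class evidence lives at a handful of marker pixels.
    # l1_gate sparsifies the per-pixel input gate so background pixels are
    # silenced before any convolutional mixing, which keeps logits flat for
    # cells matching no reference type; l1_fc sparsifies the classifier layer
    l1_fc: float = 0.0
    l1_gate: float = 0.0
    gate_init: float = 1.0
    # evidence-pixel selection: before CNN training, an L1-regularized linear
    # probe on the training images identifies the sparse pixel set carrying
    # class evidence; the input gate is frozen to that (radius-1 dilated)
    # mask. Classification then rests on class-evidence pixels only, so a
    # cell matching no reference type yields near-uniform probabilities —
    # the property open-set detection relies on.
    pixel_selection: str = "l1_linear"  # or "none"
    pixel_selection_C: float = 0.1
    # augmentation: additive pixel noise regularizes against per-pixel
    # sampling noise; mixup smooths between-class confidence
    noise_sigma: float = 0.05
    mixup_alpha: float = 0.0
    # open-set calibration: fraction of each batch augmented with synthesized
    # evidence-free negatives (per-pixel minimum over random training cells,
    # which erases sparse class-specific bright pixels) trained toward the
    # uniform distribution, so inputs carrying no class evidence score
    # uniformly low probabilities
    negative_frac: float = 0.125
    seed: int = 0
    backbone: str = "small_cnn"
    channels: Tuple[int, ...] = (8, 16, 32)
    head: str = "flatten"
    class_weights: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0,1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if not 0 <= self.label_smoothing_eps < 1:
            raise ValueError("label_smoothing_eps must be in [0,1)")
        self.channels = tuple(self.channels)


class EarlyStopper:
    """Stop when validation loss fails to improve for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch: Optional[int] = None
        self.stale = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record epoch's val loss; return True when training should halt."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.stale = 0
            return False
        self.stale += 1
        return self.stale >= self.patience


@dataclass
class TrainedModel:
    class_names: List[str]
    net: SmallCNN
    history: Dict[str, List[float]]
    config: TrainConfig
    map_ref: str
    best_epoch: Optional[int] = None

    def save(self, path) -> None:
        """Persist as a directory: weights.npz + model.json sidecar."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "weights.npz", **self.net.state_dict())
        sidecar = {
            "class_names": self.class_names,
            "config": asdict(self.config),
            "map_ref": self.map_ref,
            "history": self.history,
            "best_epoch": self.best_epoch,
            "channels": list(self.net.channels),
            "input_size": self.net.input_size,
        }
        (path / "model.json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        sidecar = json.loads((path / "model.json").read_text())
        cfg = TrainConfig(**sidecar["config"])
        net = SmallCNN(
            n_classes=len(sidecar["class_names"]),
            channels=tuple(sidecar["channels"]),
            head=cfg.head,
            input_size=sidecar["input_size"],
            gate_init=cfg.gate_init,
        )
        with np.load(path / "weights.npz") as npz:
            net.load_state_dict({k: npz[k] for k in npz.files})
        return cls(
            class_names=sidecar["class_names"],
            net=net,
            history=sidecar["history"],
            config=cfg,
            map_ref=sidecar["map_ref"],
            best_epoch=sidecar["best_epoch"],
        )


def split_train_val(
    images: ImageStack,
    labels: np.ndarray,
    val_fraction: float = 0.15,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Stratified split; returns (train_idx, val_idx), deterministic per seed.

    Each class contributes ``round(n_class * val_fraction)`` validation cells
    (at least 1), so every class's validation share is within one cell of the
    requested fraction.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != images.n_cells:
        raise ValueError("labels not aligned to images")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(labels.astype(str), return_counts=True)
    singletons = classes[counts < 2]
    if len(singletons):
        raise ValueError(
            f"classes with a single cell cannot be split: {list(singletons)}"
        )
    train_idx, val_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(labels.astype(str) == cls)
        idx = rng.permutation(idx)
        n_val = min(max(1, int(round(len(idx) * val_fraction))), len(idx) - 1)
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.array(train_idx)), np.sort(np.array(val_idx))


def _select_evidence_pixels(
    images: np.ndarray, y: np.ndarray, C: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Binary pixel mask from an L1 multinomial linear probe.

    Fits an L1-penalized logistic regression on the flattened training
    images; pixels with any nonzero coefficient, dilated by one pixel to
    keep local context for the convolutions, form the mask.
    """
    import warnings as _warnings

    from scipy.ndimage import binary_dilation
    from sklearn.linear_model import LogisticRegression

    P = images.shape[1]
    flat = images.reshape(len(images), -1)
    active = flat.std(axis=0) > 0
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        probe = LogisticRegression(
            penalty="l1", solver="saga", C=C, max_iter=1500, tol=1e-3,
            random_state=seed,
        ).fit(flat[:, active], y)
    mask_active = (np.abs(probe.coef_) > 1e-8).any(axis=0)
    mask = np.zeros(P * P, dtype=bool)
    mask[np.flatnonzero(active)[mask_active]] = True
    mask = binary_dilation(mask.reshape(P, P), iterations=1)
    return mask.astype(np.float64)


def _epoch_loss(
    net: SmallCNN, images: np.ndarray, y: np.ndarray, eps: float,
    n_classes: int, batch_size: int,
) -> Tuple[float, float]:
    """Evaluation-mode mean loss and accuracy over a dataset."""
    losses, correct = [], 0
    for s in range(0, len(y), batch_size):
        xb, yb = images[s : s + batch_size], y[s : s + batch_size]
        logits, _ = net.forward(xb, train=False)
        loss, _ = smoothed_ce_loss(logits, yb, eps, n_classes)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(y)), correct / len(y)


def train(images: ImageStack, labels: np.ndarray, cfg: TrainConfig) -> TrainedModel:
    """Fit the CNN; returns the model restored to its best-validation epoch."""
    if cfg.backbone == "pretrained_b3":
        raise NotImplementedError(
            "the pretrained_b3 backbone needs the optional torch backend, "
            "which is not installed; use backbone='small_cnn'"
        )
    if cfg.backbone != "small_cnn":
        raise ValueError(f"unknown backbone {cfg.backbone!r}")
    labels = np.asarray(labels, dtype=object)
    class_names = sorted(set(map(str, labels)))
    if len(class_names) < 2:
        raise ValueError("need at least 2 classes to train")
    class_of = {c: i for i, c in enumerate(class_names)}
    y = np.array([class_of[str(l)] for l in labels])
    P = images.pixel_size
    if P % (2 ** len(cfg.channels)) != 0:
        raise ValueError(
            f"pixel size {P} must be divisible by {2 ** len(cfg.channels)} "
            f"for {len(cfg.channels)} pooling stages"
        )
    train_idx, val_idx = split_train_val(images, labels, cfg.val_fraction, cfg.seed)
    Xtr, ytr = images.pixels[train_idx], y[train_idx]
    Xval, yval = images.pixels[val_idx], y[val_idx]

    rng = np.random.default_rng(cfg.seed)
    net = SmallCNN(
        len(class_names), channels=cfg.channels, rng=rng, head=cfg.head,
        input_size=P, gate_init=cfg.gate_init,
    )
    net.fit_input_standardization(Xtr)
    freeze_gate = False
    if cfg.pixel_selection == "l1_linear":
        net.params["gate"] = _select_evidence_pixels(
            Xtr, ytr, C=cfg.pixel_selection_C, seed=cfg.seed
        ).astype(net.params["gate"].dtype)
        freeze_gate = True
    opt = Adam(net.params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.patience)
    history: Dict[str, List[float]] = {
        "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
    }
    sample_weight = None
    if cfg.class_weights:
        freq = np.bincount(ytr, minlength=len(class_names))
        sample_weight = (len(ytr) / (len(class_names) * freq))[ytr]

    best_state = net.state_dict()
    K = len(class_names)
    for epoch in range(cfg.max_epochs):
        # cosine learning-rate decay stabilizes the final epochs
        opt.lr = cfg.learning_rate * 0.5 * (1 + np.cos(np.pi * epoch / cfg.max_epochs))
        order = rng.permutation(len(ytr))
        batch_losses, batch_correct = [], 0
        for s in range(0, len(ytr), cfg.batch_size):
            b = order[s : s + cfg.batch_size]
            xb = Xtr[b]
            target = smooth_targets(ytr[b], cfg.label_smoothing_eps, K)
            if cfg.negative_frac > 0:
                n_neg = max(1, int(round(cfg.negative_frac * len(b))))
                donors = rng.integers(0, len(Xtr), size=(n_neg, 4))
                negatives = Xtr[donors].min(axis=1)
                xb = np.concatenate([xb, negatives])
                target = np.concatenate(
                    [target, np.full((n_neg, K), 1.0 / K, dtype=target.dtype)]
                )
            if cfg.noise_sigma > 0:
                xb = xb + rng.normal(0.0, cfg.noise_sigma, xb.shape)
            if cfg.mixup_alpha > 0:
                lam = rng.beta(cfg.mixup_alpha, cfg.mixup_alpha)
                perm = rng.permutation(len(b))
                xb = lam * xb + (1 - lam) * xb[perm]
                target = lam * target + (1 - lam) * target[perm]
            logits, cache = net.forward(xb, train=True)
            loss, dlogits = soft_ce_loss(logits, target)
            if sample_weight is not None:
                w = sample_weight[b]
                dlogits = dlogits * (w / w.mean())[:, None]
            grads = net.backward(dlogits, cache)
            if freeze_gate:
                grads.pop("gate", None)
            opt.step(grads)
            for pname, lam in (("Wfc", cfg.l1_fc), ("gate", 0.0 if freeze_gate else cfg.l1_gate)):
                if lam > 0:
                    W = net.params[pname]
                    tau = opt.lr * lam
                    net.params[pname] = np.sign(W) * np.maximum(np.abs(W) - tau, 0.0)
            batch_losses.append(loss * len(b))
            batch_correct += int(
                (logits[: len(b)].argmax(axis=1) == ytr[b]).sum()
            )
        # train metrics are pre-update minibatch averages (one pass, no re-eval)
        tr_loss = float(np.sum(batch_losses) / len(ytr))
        tr_acc = batch_correct / len(ytr)
        val_loss, val_acc = _epoch_loss(
            net, Xval, yval, cfg.label_smoothing_eps, K, cfg.batch_size
        )
        if not np.isfinite(tr_loss):
            raise FloatingPointError(
                "training loss became non-finite; try a lower learning rate"
            )
        history["train_loss"].append(tr_loss)
        history["train_acc"].append(tr_acc)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        if val_loss < stopper.best_loss:
            best_state = net.state_dict()
        if stopper.update(epoch, val_loss):
            break
    net.load_state_dict(best_state)
    return TrainedModel(
        class_names=class_names,
        net=net,
        history=history,
        config=cfg,
        map_ref=images.map_ref,
        best_epoch=stopper.best_epoch,
    )


def predict_proba(
    model: TrainedModel, images: ImageStack, batch_size: int = 256,
    check_map: bool = True,
) -> np.ndarray:
    """Softmax class probabilities per cell (rows sum to 1)."""
    if check_map and model.map_ref != images.map_ref:
        raise ValueError(
            "images were built with a different feature map than the model "
            f"({images.map_ref} vs {model.map_ref})"
        )
    out = []
    for s in range(0, images.n_cells, batch_size):
        logits, _ = model.net.forward(images.pixels[s : s + batch_size], train=False)
        out.append(softmax(logits))
    return np.vstack(out)
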