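"""Minimal numpy CNN: forward, backward, Adam, label-smoothed cross-entropy.

The annotation backbone is a small 3-block convolutional network
(3x3 conv - batch norm - ReLU - 2x2 max pool, repeated) followed by global
average pooling and a linear classifier. Everything is implemented with
vectorized numpy (im2col convolutions), which keeps training deterministic,
dependency-free and fast enough for desk-scale problems; gradients are
validated against finite differences in the test suite.

The backward pass can also stop at the last convolutional block's rectified
activations, which is exactly the gradient Grad-CAM needs.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np

Array = np.ndarray

# Single-precision keeps the BLAS calls fast on one CPU; gradients are still
# finite-difference-checked to ~1e-2 relative in float32.
DTYPE = np.float32


# ---------------------------------------------------------------------------
# layer primitives (stride-1 3x3 conv with pad 1; 2x2 max pool)
# ---------------------------------------------------------------------------
# The 3x3 convolution is evaluated as nine shifted (N*H*W, C) x (C, K)
# matmuls instead of im2col: same arithmetic, far smaller temporaries.


def conv2d_forward(x: Array, W: Array, b: Array) -> Tuple[Array, Array]:
    """3x3 same-padding convolution. x: (N,C,H,W) -> (N,K,H,W).

    Returns the output and the padded-input cache for the backward pass.
    """
    N, C, H, Wd = x.shape
    K = W.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    out = np.zeros((N, H, Wd, K), dtype=x.dtype)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + H, dj : dj + Wd]
            out += np.tensordot(patch, W[:, :, di, dj], axes=([1], [1]))
    out += b
    return np.ascontiguousarray(np.moveaxis(out, 3, 1)), xp


def conv2d_backward(dy: Array, xp: Array, W: Array) -> Tuple[Array, Array, Array]:
    """Gradients of a 3x3 same conv. dy: (N,K,H,W); xp is the padded input."""
    N, K, H, Wd = dy.shape
    dyt = np.ascontiguousarray(np.moveaxis(dy, 1, 3))  # (N,H,W,K)
    db = dy.sum(axis=(0, 2, 3))
    dW = np.zeros_like(W)
    dxp = np.zeros_like(xp)
    for di in range(3):
        for dj in range(3):
            patch = xp[:, :, di : di + H, dj : dj + Wd]
            dW[:, :, di, dj] = np.tensordot(dyt, patch, axes=([0, 1, 2], [0, 2, 3]))
            contrib = np.tensordot(dyt, W[:, :, di, dj], axes=([3], [0]))  # (N,H,W,C)
            dxp[:, :, di : di + H, dj : dj + Wd] += np.moveaxis(contrib, 3, 1)
    return dxp[:, :, 1:-1, 1:-1], dW, db


def maxpool2_forward(x: Array) -> Tuple[Array, Array]:
    """2x2 max pool, stride 2. Caches argmax indices for backward."""
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(N, C, H // 2, W // 2, 4)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    return out, arg


def maxpool2_backward(dy: Array, arg: Array, in_shape: Tuple[int, ...]) -> Array:
    N, C, H, W = in_shape
    dflat = np.zeros((N, C, H // 2, W // 2, 4), dtype=dy.dtype)
    np.put_along_axis(dflat, arg[..., None], dy[..., None], axis=-1)
    dx = dflat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return dx.reshape(N, C, H, W)


def batchnorm_forward(
    x: Array, gamma: Array, beta: Array, running: Dict[str, Array],
    train: bool, momentum: float = 0.9, eps: float = 1e-5,
) -> Tuple[Array, tuple]:
    """Per-channel batch norm over (N,H,W)."""
    if train:
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        running["mean"] = momentum * running["mean"] + (1 - momentum) * mean
        running["var"] = momentum * running["var"] + (1 - momentum) * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xhat, inv, gamma, train)


def batchnorm_backward(dy: Array, cache: tuple) -> Tuple[Array, Array, Array]:
    xhat, inv, gamma, train = cache
    dgamma = (dy * xhat).sum(axis=(0, 2, 3))
    dbeta = dy.sum(axis=(0, 2, 3))
    dxhat = dy * gamma[None, :, None, None]
    if not train:
        return dxhat * inv[None, :, None, None], dgamma, dbeta
    N, _, H, W = dy.shape
    m = N * H * W
    mean_dxhat = dxhat.mean(axis=(0, 2, 3))
    mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3))
    dx = (
        dxhat
        - mean_dxhat[None, :, None, None]
        - xhat * mean_dxhat_xhat[None, :, None, None]
    ) * inv[None, :, None, None]
    return dx, dgamma, dbeta


def softmax(logits: Array) -> Array:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def smooth_targets(y: Array, eps: float, n_classes: int) -> Array:
    """One-hot targets mixed with the uniform distribution (label smoothing)."""
    target = np.full((len(y), n_classes), eps / n_classes, dtype=DTYPE)
    target[np.arange(len(y)), y] += 1.0 - eps
    return target


def soft_ce_loss(logits: Array, target: Array) -> Tuple[float, Array]:
    """Mean cross-entropy against a target distribution matrix, with gradient."""
    p = softmax(logits)
    logp = np.log(np.clip(p, 1e-12, None))
    loss = float(-(target * logp).sum(axis=1).mean())
    dlogits = (p - target) / len(target)
    return loss, dlogits


def smoothed_ce_loss(
    logits: Array, y: Array, eps: float, n_classes: int
) -> Tuple[float, Array]:
    """Mean label-smoothed cross-entropy and its gradient w.r.t. logits.

    The target distribution is (1 - eps) on the true class and eps/K on every
    class; the minimum achievable per-sample loss is the entropy of that
    target.
    """
    return soft_ce_loss(logits, smooth_targets(y, eps, n_classes))


def smoothed_target_entropy(eps: float, n_classes: int) -> float:
    """Entropy of the smoothed target: a hard floor on the achievable loss."""
    t = np.full(n_classes, eps / n_classes)
    t[0] += 1.0 - eps
    t = t[t > 0]
    return float(-(t * np.log(t)).sum())


# ---------------------------------------------------------------------------
# the small CNN
# ---------------------------------------------------------------------------


class SmallCNN:
    """conv-BN-ReLU-pool x len(channels) -> head -> linear classifier.

    Input images must be (N, P, P) with P divisible by 2**len(channels).
    The default head flattens the final feature grid into the linear layer
    (LeNet/VGG style): gene-to-pixel images are location-coded — a class's
    evidence lives at fixed pixels — so the classifier head must be
    location-aware. Translation-invariant global pooling heads (``avg``,
    ``max``) are available for comparison but train poorly on such images.
    """

    def __init__(
        self,
        n_classes: int,
        channels: Tuple[int, ...] = (8, 16, 32),
        rng: np.random.Generator | None = None,
        head: str = "flatten",
        input_size: int = 64,
        gate_init: float = 1.0,
    ):
        rng = rng or np.random.default_rng(0)
        if head not in ("flatten", "max", "avg"):
            raise ValueError("head must be 'flatten', 'max' or 'avg'")
        self.gate_init = gate_init
        if input_size % (2 ** len(channels)) != 0:
            raise ValueError(
                f"input size {input_size} must be divisible by {2 ** len(channels)}"
            )
        self.head = head
        self.channels = tuple(channels)
        self.n_classes = n_classes
        self.input_size = input_size
        # input standardization buffers, fitted on the training split:
        # x -> (x - input_mean) / input_std before the first convolution
        self.input_mean: Array = np.zeros((1, 1), dtype=DTYPE)
        self.input_std: Array = np.ones((1, 1), dtype=DTYPE)
        self.params: Dict[str, Array] = {}
        self.running: List[Dict[str, Array]] = []
        c_in = 1
        for i, c_out in enumerate(self.channels):
            fan_in = c_in * 9
            self.params[f"W{i}"] = rng.normal(
                0, np.sqrt(2.0 / fan_in), (c_out, c_in, 3, 3)
            ).astype(DTYPE)
            self.params[f"b{i}"] = np.zeros(c_out, dtype=DTYPE)
            self.params[f"gamma{i}"] = np.ones(c_out, dtype=DTYPE)
            self.params[f"beta{i}"] = np.zeros(c_out, dtype=DTYPE)
            self.running.append(
                {"mean": np.zeros(c_out, dtype=DTYPE), "var": np.ones(c_out, dtype=DTYPE)}
            )
            c_in = c_out
        side = input_size // (2 ** len(channels))
        n_feat = c_in * side * side if head == "flatten" else c_in
        self.params["Wfc"] = rng.normal(0, np.sqrt(1.0 / n_feat), (n_classes, n_feat)).astype(DTYPE)
        self.params["bfc"] = np.zeros(n_classes, dtype=DTYPE)
        # per-pixel multiplicative input gate: with an L1 penalty it performs
        # feature selection, silencing pixels that carry no class evidence.
        # A small init under L1 training makes informative gates grow while
        # the proximal step pins uninformative ones at zero.
        self.params["gate"] = np.full(
            (input_size, input_size), gate_init, dtype=DTYPE
        )

    # -- forward ----------------------------------------------------------

    def forward(self, images: Array, train: bool = False) -> Tuple[Array, dict]:
        """images: (N, P, P) -> logits (N, K); caches for backward."""
        x = np.ascontiguousarray(images[:, None, :, :], dtype=DTYPE)
        x = (x - self.input_mean) / self.input_std
        cache: dict = {"inputs": [], "train": train, "x_std": x}
        x = x * self.params["gate"]
        for i in range(len(self.channels)):
            z, xp = conv2d_forward(x, self.params[f"W{i}"], self.params[f"b{i}"])
            zb, bn_cache = batchnorm_forward(
                z, self.params[f"gamma{i}"], self.params[f"beta{i}"],
                self.running[i], train,
            )
            a = np.maximum(zb, 0.0)
            p, arg = maxpool2_forward(a)
            cache["inputs"].append((xp, bn_cache, a, arg))
            x = p
        cache["pre_head"] = x
        N, C, H, W = x.shape
        if self.head == "flatten":
            feat = np.ascontiguousarray(x).reshape(N, C * H * W)
        elif self.head == "avg":
            feat = x.mean(axis=(2, 3))  # (N, C_last)
        else:
            flat = x.reshape(N, C, H * W)
            cache["gp_arg"] = flat.argmax(axis=2)
            feat = np.take_along_axis(flat, cache["gp_arg"][:, :, None], axis=2)[:, :, 0]
        cache["feat"] = feat
        logits = feat @ self.params["Wfc"].T + self.params["bfc"]
        return logits, cache

    # -- backward ---------------------------------------------------------

    def backward(
        self, dlogits: Array, cache: dict, stop_at_block: int | None = None
    ) -> Dict[str, Array]:
        """Backprop ``dlogits`` through the network.

        With ``stop_at_block=i`` the return dict additionally holds
        ``d_act{i}``: the gradient w.r.t. block i's rectified (pre-pool)
        activations — the tensor Grad-CAM weights are averaged from.
        """
        grads: Dict[str, Array] = {}
        feat = cache["feat"]
        grads["Wfc"] = dlogits.T @ feat
        grads["bfc"] = dlogits.sum(axis=0)
        dfeat = dlogits @ self.params["Wfc"]
        N, C, H, W = cache["pre_head"].shape
        if self.head == "flatten":
            dx = dfeat.reshape(N, C, H, W)
        elif self.head == "avg":
            dx = np.broadcast_to(dfeat[:, :, None, None] / (H * W), (N, C, H, W)).copy()
        else:
            dflat = np.zeros((N, C, H * W), dtype=dfeat.dtype)
            np.put_along_axis(dflat, cache["gp_arg"][:, :, None], dfeat[:, :, None], axis=2)
            dx = dflat.reshape(N, C, H, W)
        for i in reversed(range(len(self.channels))):
            xp, bn_cache, a, arg = cache["inputs"][i]
            da = maxpool2_backward(dx, arg, a.shape)
            if stop_at_block == i:
                grads[f"d_act{i}"] = da
                return grads
            dzb = da * (a > 0)
            dz, dgamma, dbeta = batchnorm_backward(dzb, bn_cache)
            grads[f"gamma{i}"] = dgamma
            grads[f"beta{i}"] = dbeta
            dx, dW, db = conv2d_backward(dz, xp, self.params[f"W{i}"])
            grads[f"W{i}"] = dW
            grads[f"b{i}"] = db
        grads["gate"] = (dx * cache["x_std"]).sum(axis=(0, 1))
        return grads

    def feature_gradients(
        self, images: Array, class_idx: int, score: str = "logit"
    ) -> Tuple[Array, Array]:
        """Last-block rectified activations and d(score_class)/d(activations).

        Evaluation mode (running BN statistics); this is the Grad-CAM input.
        ``score="logit"`` (default, the usual Grad-CAM choice) uses the raw
        class logit; ``score="probability"`` uses the softmax output, whose
        gradient is class-contrastive but saturates on confident inputs.
        """
        logits, cache = self.forward(images, train=False)
        if score == "probability":
            p = softmax(logits)
            # d p_c / d z_j = p_c (delta_jc - p_j)
            dlogits = -p * p[:, [class_idx]]
            dlogits[:, class_idx] += p[:, class_idx]
        elif score == "logit":
            dlogits = np.zeros_like(logits)
            dlogits[:, class_idx] = 1.0
        else:
            raise ValueError("score must be 'probability' or 'logit'")
        last = len(self.channels) - 1
        grads = self.backward(dlogits, cache, stop_at_block=last)
        activations = cache["inputs"][last][2]  # post-ReLU, pre-pool
        return activations, grads[f"d_act{last}"]

    # -- parameter plumbing ------------------------------------------------

    def fit_input_standardization(self, images: Array) -> None:
        """Per-pixel mean and pooled SD of the training images."""
        self.input_mean = images.mean(axis=0)[None, :, :].astype(DTYPE)
        sd = float(images.std())
        self.input_std = np.full((1, 1), max(sd, 1e-6), dtype=DTYPE)

    def state_dict(self) -> Dict[str, Array]:
        state = {k: v.copy() for k, v in self.params.items()}
        for i, r in enumerate(self.running):
            state[f"run_mean{i}"] = r["mean"].copy()
            state[f"run_var{i}"] = r["var"].copy()
        state["input_mean"] = self.input_mean.copy()
        state["input_std"] = self.input_std.copy()
        return state

    def load_state_dict(self, state: Dict[str, Array]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        for i, r in enumerate(self.running):
            r["mean"] = state[f"run_mean{i}"].copy()
            r["var"] = state[f"run_var{i}"].copy()
        if "input_mean" in state:
            self.input_mean = state["input_mean"].copy()
            self.input_std = state["input_std"].copy()


class Adam:
    """Adaptive-moment optimizer with decoupled weight decay.

    Decay applies only to convolution and classifier weights (names starting
    with ``W``), never to biases or batch-norm parameters. Shrinking weights
    on uninformative pixels keeps logits flat for cells resembling no class,
    which the open-set detector depends on.
    """

    def __init__(self, params: Dict[str, Array], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: Dict[str, Array]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.params:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and k.startswith("W"):
                self.params[k] -= self.lr * self.weight_decay * self.params[k]
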