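"""The slice-fusion CNN: architecture, forward pass, analytic backprop, MSGD.

The architecture is four convolution + 2x2 max-pooling stages with tanh
activations (ReLU available as a flag), a fully connected tanh layer of H
units, and a 2-way softmax. The first convolution spans all input
channels (3 adjacent slices for the 3S variant, 1 for 1S), so its feature
maps fuse inter-slice structure; later stages span all previous feature
maps. Pooling keeps the maximum of each non-overlapping 2x2 window,
halving each spatial dimension (odd sizes are floored).

Training minimizes the negative log-likelihood

    l(W) = - sum_k log p(y_hat_k = y_k | z_k, W)

by mini-batch stochastic gradient descent with momentum; gradients are
hand-derived (verified against finite differences in the test suite).
30% of the training data is held out as a validation set and the weights
of the best-validation-accuracy epoch are returned. Everything is
seed-deterministic under single-threaded execution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import EMBED_SIZE, SliceDataset


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and optimizer settings.

    The default is a deliberately small network sized for CPU training on
    phantom cohorts; :meth:`wide` gives a higher-capacity variant closer
    to what a GPU study would use. Both keep the same four-stage layout.
    """

    in_channels: int = 3
    feature_maps: tuple[int, ...] = (4, 8, 8, 8)
    kernel_sizes: tuple[int, ...] = (5, 5, 5, 5)
    fc_units: int = 32
    activation: str = "tanh"
    dropout: float = 0.0
    input_size: int = EMBED_SIZE
    learning_rate: float = 0.02
    momentum: float = 0.9
    clip_norm: float = 1.0
    batch_size: int = 32
    epochs: int = 10
    val_fraction: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.feature_maps) != len(self.kernel_sizes):
            raise ValueError("feature_maps and kernel_sizes must have equal length")
        if self.activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if min(self.spatial_trace()) < 1:
            raise ValueError("input too small for this stack of conv/pool stages")

    @property
    def n_stages(self) -> int:
        return len(self.feature_maps)

    def spatial_trace(self) -> list[int]:
        """Spatial size after each conv+pool stage ('valid' convs, floor pooling)."""
        size = self.input_size
        trace = []
        for k in self.kernel_sizes:
            size = (size - k + 1) // 2
            trace.append(size)
        return trace

    @property
    def flat_dim(self) -> int:
        """R: length of the flattened final feature-map vector v."""
        return self.feature_maps[-1] * self.spatial_trace()[-1] ** 2

    @classmethod
    def wide(cls, **kw) -> "CNNConfig":
        """Higher-capacity variant: maps (16, 32, 64, 128), 256 FC units."""
        return cls(feature_maps=(16, 32, 64, 128), fc_units=256, **kw)

    def for_variant(self, variant: str) -> "CNNConfig":
        return replace(self, in_channels=3 if variant == "3s" else 1)


def _act(x: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(x) if kind == "tanh" else np.maximum(x, 0.0)


def _act_grad(out: np.ndarray, pre: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed via the activation output (tanh) or input (relu)
    return 1.0 - out**2 if kind == "tanh" else (pre > 0).astype(pre.dtype)


# Layer internals use a channels-last (N, H, W, C) layout. Convolutions are
# computed by shift-and-accumulate: one skinny (C x J) matmul per kernel
# offset, which keeps every memory access nearly contiguous and avoids
# materializing an im2col matrix.

def _conv_forward(x: np.ndarray, k: np.ndarray, b: np.ndarray) -> np.ndarray:
    """'valid' cross-correlation over all input channels.

    x: (N, H, W, C); k: (J, C, kh, kw). Returns the pre-activation
    (N, Ho, Wo, J).
    """
    n, h, w, c = x.shape
    j, _, kh, kw = k.shape
    ho, wo = h - kh + 1, w - kw + 1
    out = np.zeros((n, ho, wo, j), dtype=x.dtype)
    flat = out.reshape(-1, j)
    for u in range(kh):
        for v in range(kw):
            sl = x[:, u : u + ho, v : v + wo, :].reshape(-1, c)
            flat += sl @ k[:, :, u, v].T
    return out + b


def _conv_backward(
    x: np.ndarray, k: np.ndarray, dy: np.ndarray, need_dx: bool = True
):
    """Gradients of the valid cross-correlation. Returns (dx, dk, db)."""
    n, h, w, c = x.shape
    j, _, kh, kw = k.shape
    ho, wo = h - kh + 1, w - kw + 1
    dy_cols = dy.reshape(-1, j)
    db = dy_cols.sum(axis=0)
    dk = np.empty_like(k)
    dx = np.zeros_like(x) if need_dx else None
    for u in range(kh):
        for v in range(kw):
            sl = x[:, u : u + ho, v : v + wo, :].reshape(-1, c)
            dk[:, :, u, v] = dy_cols.T @ sl
            if need_dx:
                dx[:, u : u + ho, v : v + wo, :] += (dy_cols @ k[:, :, u, v]).reshape(
                    n, ho, wo, c
                )
    return dx, dk, db


def _pool_forward(x: np.ndarray):
    """Non-overlapping 2x2 max pooling, flooring odd spatial dims."""
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    xt = x[:, : 2 * h2, : 2 * w2, :].reshape(n, h2, 2, w2, 2, c)
    patches = np.ascontiguousarray(xt.transpose(0, 1, 3, 5, 2, 4)).reshape(
        n, h2, w2, c, 4
    )
    idx = patches.argmax(axis=-1)
    out = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
    return out, idx


def _pool_backward(dy: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    h2, w2 = h // 2, w // 2
    patches = np.zeros((n, h2, w2, c, 4), dtype=dy.dtype)
    np.put_along_axis(patches, idx[..., None], dy[..., None], axis=-1)
    dx = np.zeros(in_shape, dtype=dy.dtype)
    dx[:, : 2 * h2, : 2 * w2, :] = (
        patches.reshape(n, h2, w2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, 2 * h2, 2 * w2, c)
    )
    return dx


@dataclass
class CNNModel:
    """All learnable weights: conv kernels/biases, FC matrix M, softmax Theta."""

    config: CNNConfig
    kernels: list[np.ndarray]
    conv_biases: list[np.ndarray]
    fc_weights: np.ndarray  # M: (R, H)
    fc_bias: np.ndarray  # (H,)
    softmax_weights: np.ndarray  # Theta: (H, 2)
    softmax_bias: np.ndarray  # (2,)
    history: list[dict] = field(default_factory=list)

    @classmethod
    def initialize(cls, config: CNNConfig, rng: np.random.Generator | None = None) -> "CNNModel":
        """Glorot-uniform initialization; softmax weights start at zero."""
        rng = np.random.default_rng(config.seed) if rng is None else rng
        kernels, biases = [], []
        c_in = config.in_channels
        for j, k in zip(config.feature_maps, config.kernel_sizes):
            fan_in = c_in * k * k
            fan_out = j * k * k
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            kernels.append(
                rng.uniform(-limit, limit, size=(j, c_in, k, k)).astype(np.float32)
            )
            biases.append(np.zeros(j, dtype=np.float32))
            c_in = j
        r = config.flat_dim
        h = config.fc_units
        limit = np.sqrt(6.0 / (r + h))
        fc_w = rng.uniform(-limit, limit, size=(r, h)).astype(np.float32)
        return cls(
            config=config,
            kernels=kernels,
            conv_biases=biases,
            fc_weights=fc_w,
            fc_bias=np.zeros(h, dtype=np.float32),
            softmax_weights=np.zeros((h, 2), dtype=np.float32),
            softmax_bias=np.zeros(2, dtype=np.float32),
        )

    # -- forward / backward ------------------------------------------------

    def forward(
        self,
        x: np.ndarray,
        return_cache: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        """Class probabilities for a batch (N, C, 100, 100); rows sum to 1.

        ``dropout_rng`` enables inverted dropout on the FC layer (training
        only; the optional-variant flag in the config, off by default).
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim == 3:
            x = x[None]
        act = self.config.activation
        cache: dict = {
            "inputs": [],
            "pre_pooled": [],
            "post": [],
            "pool_idx": [],
            "pre_shape": [],
        }
        cur = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # to channels-last
        for k, b in zip(self.kernels, self.conv_biases):
            cache["inputs"].append(cur)
            pre = _conv_forward(cur, k, b)
            # tanh/relu are monotone, so pooling before the activation is
            # exactly equivalent and far cheaper on the large early maps
            pre_pooled, idx = _pool_forward(pre)
            post = _act(pre_pooled, act)
            cache["pre_pooled"].append(pre_pooled)
            cache["post"].append(post)
            cache["pool_idx"].append(idx)
            cache["pre_shape"].append(pre.shape)
            cur = post
        v = cur.reshape(cur.shape[0], -1)  # (N, R)
        fc_pre = v @ self.fc_weights + self.fc_bias
        hid_raw = _act(fc_pre, act)
        hid = hid_raw
        drop_mask = None
        if dropout_rng is not None and self.config.dropout > 0.0:
            keep = 1.0 - self.config.dropout
            drop_mask = (
                dropout_rng.random(hid_raw.shape) < keep
            ).astype(hid_raw.dtype) / keep
            hid = hid_raw * drop_mask
        logits = hid @ self.softmax_weights + self.softmax_bias
        logits = logits - logits.max(axis=1, keepdims=True)
        expl = np.exp(logits)
        probs = expl / expl.sum(axis=1, keepdims=True)
        if not np.all(np.isfinite(probs)):
            raise FloatingPointError("non-finite activations in the softmax layer")
        if return_cache:
            cache.update(
                {
                    "v": v,
                    "fc_pre": fc_pre,
                    "hid": hid,
                    "hid_raw": hid_raw,
                    "drop_mask": drop_mask,
                    "pooled_shape": cur.shape,
                }
            )
            return probs, cache
        return probs

    def _backward(self, probs: np.ndarray, y: np.ndarray, cache: dict) -> dict:
        """Gradients of the summed NLL over the batch."""
        act = self.config.activation
        n = len(y)
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0  # d NLL / d logits
        grads: dict = {}
        grads["softmax_weights"] = cache["hid"].T @ dlogits
        grads["softmax_bias"] = dlogits.sum(axis=0)
        dhid = dlogits @ self.softmax_weights.T
        if cache.get("drop_mask") is not None:
            dhid = dhid * cache["drop_mask"]
        dfc_pre = dhid * _act_grad(cache["hid_raw"], cache["fc_pre"], act)
        grads["fc_weights"] = cache["v"].T @ dfc_pre
        grads["fc_bias"] = dfc_pre.sum(axis=0)
        dv = dfc_pre @ self.fc_weights.T
        dcur = dv.reshape(cache["pooled_shape"])
        grads["kernels"] = [None] * len(self.kernels)
        grads["conv_biases"] = [None] * len(self.kernels)
        for s in range(len(self.kernels) - 1, -1, -1):
            dpre_pooled = dcur * _act_grad(
                cache["post"][s], cache["pre_pooled"][s], act
            )
            dpre = _pool_backward(
                dpre_pooled, cache["pool_idx"][s], cache["pre_shape"][s]
            )
            dcur, dk, db = _conv_backward(
                cache["inputs"][s],
                self.kernels[s],
                dpre,
                need_dx=s > 0,  # the input image needs no gradient
            )
            grads["kernels"][s] = dk
            grads["conv_biases"][s] = db
        return grads

    def loss(self, x: np.ndarray, y: np.ndarray) -> float:
        """Summed negative log-likelihood over the given samples."""
        probs = self.forward(x)
        p = probs[np.arange(len(y)), np.asarray(y, dtype=int)]
        return float(-np.log(np.maximum(p, 1e-30)).sum())

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = [self.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
        return np.concatenate(out, axis=0)

    # -- parameter plumbing -------------------------------------------------

    def _params(self) -> list[np.ndarray]:
        return [
            *self.kernels,
            *self.conv_biases,
            self.fc_weights,
            self.fc_bias,
            self.softmax_weights,
            self.softmax_bias,
        ]

    def _grad_list(self, grads: dict) -> list[np.ndarray]:
        return [
            *grads["kernels"],
            *grads["conv_biases"],
            grads["fc_weights"],
            grads["fc_bias"],
            grads["softmax_weights"],
            grads["softmax_bias"],
        ]

    def snapshot(self) -> list[np.ndarray]:
        return [p.copy() for p in self._params()]

    def restore(self, snap: list[np.ndarray]) -> None:
        for p, s in zip(self._params(), snap):
            p[...] = s


def train(
    dataset: SliceDataset,
    config: CNNConfig,
    validation: SliceDataset | None = None,
    verbose: bool = False,
) -> CNNModel:
    """Train a CNN by mini-batch SGD with momentum on the NLL loss.

    If no validation set is given, ``val_fraction`` (default 30%) of the
    samples is held out for epoch selection; the returned model carries
    the weights of the epoch with the best validation accuracy and a
    per-epoch history (train loss, validation accuracy).
    """
    if len(np.unique(dataset.y)) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(config.seed)
    model = CNNModel.initialize(config, rng)

    if validation is None and config.val_fraction > 0:
        # hold out whole tumors, not samples: augmented rotations of one
        # triplet must never straddle the train/validation boundary, or
        # epoch selection rewards memorization
        subjects = np.unique(dataset.subject)
        if len(subjects) >= 4:
            subj_label = {
                s: int(dataset.y[dataset.subject == s][0]) for s in subjects
            }
            val_subjects: set = set()
            for cls in (0, 1):
                cls_subj = np.array([s for s in subjects if subj_label[s] == cls])
                if len(cls_subj) == 0:
                    continue
                n_val_subj = max(1, int(round(config.val_fraction * len(cls_subj))))
                val_subjects |= set(rng.permutation(cls_subj)[:n_val_subj].tolist())
            is_val = np.array([s in val_subjects for s in dataset.subject])
            val_idx = np.flatnonzero(is_val)
            train_idx = np.flatnonzero(~is_val)
        else:
            perm = rng.permutation(len(dataset))
            n_val = max(1, int(round(config.val_fraction * len(dataset))))
            val_idx, train_idx = perm[:n_val], perm[n_val:]
        x_tr, y_tr = dataset.x[train_idx], dataset.y[train_idx]
        x_va, y_va = dataset.x[val_idx], dataset.y[val_idx]
    else:
        x_tr, y_tr = dataset.x, dataset.y
        if validation is not None:
            x_va, y_va = validation.x, validation.y
        else:
            x_va = y_va = None
    if len(np.unique(y_tr)) < 2:
        raise ValueError("both classes must survive the validation split")

    velocity = [np.zeros_like(p) for p in model._params()]
    best_acc, best_snap = -1.0, model.snapshot()
    n = len(y_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            probs, cache = model.forward(
                xb,
                return_cache=True,
                dropout_rng=rng if config.dropout > 0 else None,
            )
            p_true = probs[np.arange(len(yb)), yb]
            total_loss += float(-np.log(np.maximum(p_true, 1e-30)).sum())
            grads = model._backward(probs, yb, cache)
            glist = model._grad_list(grads)
            scale = config.learning_rate / len(yb)
            if config.clip_norm > 0:
                gnorm = np.sqrt(sum(float((g**2).sum()) for g in glist)) / len(yb)
                if gnorm > config.clip_norm:
                    scale *= config.clip_norm / gnorm
            for p, v, g in zip(model._params(), velocity, glist):
                v *= config.momentum
                v -= scale * g.astype(p.dtype)
                p += v
        if not all(np.all(np.isfinite(p)) for p in model._params()):
            raise FloatingPointError(
                f"training diverged at epoch {epoch}: non-finite weights "
                f"(train loss {total_loss:.3g})"
            )
        if x_va is not None:
            probs_va = model.predict_proba(x_va)
            acc = float((probs_va.argmax(axis=1) == y_va).mean())
        else:
            acc = np.nan
        model.history.append(
            {"epoch": epoch, "train_loss": total_loss, "val_accuracy": acc}
        )
        if verbose:
            print(f"epoch {epoch:3d}  loss {total_loss:10.3f}  val acc {acc:.3f}")
        if x_va is not None and acc >= best_acc:
            best_acc, best_snap = acc, model.snapshot()
    if x_va is not None:
        model.restore(best_snap)
    return model
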