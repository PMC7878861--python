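"""Binary patch classifier with the conv -> GAP -> FC topology CAM needs.

The class-activation-map construction requires exactly this topology: a
convolutional feature extractor producing a K-channel spatial feature
stack A^k, a global-average-pooling (GAP) layer reducing each channel to
a scalar, and a final fully connected head whose per-channel weights w_k
produce the class logit  z = <w, GAP(A)> + b.  Any backbone honouring
that contract can be plugged in; this module ships ``TinyCNN``, a small
reference network (three 3x3 conv + ReLU + 2x2 average-pool blocks)
implemented in plain numpy with hand-derived backpropagation, so the full
pipeline trains on a CPU in seconds to minutes.

Training follows SGD with momentum, weight decay, dropout between GAP and
head, binary cross-entropy on the logit, and a staircase learning-rate
schedule lr0 * decay^(epoch // decay_every).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the full-scale recipe)."""

    epochs: int = 500
    lr: float = 1e-3
    lr_decay: float = 0.9
    decay_every: int = 10
    momentum: float = 0.9
    weight_decay: float = 5e-4
    dropout: float = 0.75
    batch_size: int = 128
    threshold: float = 0.5

    def validate(self) -> None:
        if self.lr <= 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr decay must lie in (0, 1]")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")

    def lr_at(self, epoch: int) -> float:
        """Staircase schedule: lr0 * decay^(epoch // decay_every)."""
        return self.lr * self.lr_decay ** (epoch // self.decay_every)


@dataclass
class ClassifierHead:
    """Final fully connected layer: one weight per feature channel."""

    weights: np.ndarray  # (K,)
    bias: float


@dataclass
class ClassifierOutput:
    """Logit, squashed aspecific probability, and thresholded hard label."""

    logit: float
    p_aspecific: float
    threshold: float = 0.5

    @property
    def hard_label(self) -> str:
        return "aspecific" if self.p_aspecific > self.threshold else "benign"


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


# ---------------------------------------------------------------------------
# primitive layers (forward + backward), all pure numpy

def _im2col(x: np.ndarray) -> np.ndarray:
    """(B,C,H,W) -> (B*H*W, C*9) patch matrix for same-padded 3x3 windows."""
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (B,C,H,W,3,3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        b * h * w, c * 9
    )


def _conv3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """Same-padding 3x3 cross-correlation.  x (B,C,H,W), W (O,C,3,3)."""
    bs, c, h, w = x.shape
    cols = _im2col(x)
    out = cols @ W.reshape(W.shape[0], -1).T
    out = out.reshape(bs, h, w, -1).transpose(0, 3, 1, 2)
    return out + b[None, :, None, None], (cols, x.shape)


def _conv3_backward(cache, W, dy):
    cols, (bs, c, h, w) = cache
    o = W.shape[0]
    dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, o)
    dW = (dyf.T @ cols).reshape(o, c, 3, 3)
    db = dyf.sum(axis=0)
    # dx = full correlation of dy with flipped kernels, again as one matmul
    dcols = _im2col(dy)  # (B*H*W, O*9)
    Wf = np.ascontiguousarray(
        W[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
    ).reshape(c, o * 9)
    dx = (dcols @ Wf.T).reshape(bs, h, w, c).transpose(0, 3, 1, 2)
    return dx, dW, db


def _pool2_forward(x):
    b, c, h, w = x.shape
    return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _pool2_backward(dy):
    return np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3) / 4.0


class TinyCNN:
    """Reference numpy backbone: three conv/ReLU/avg-pool blocks.

    ``in_size`` must be divisible by 8; the final feature stack has
    ``channels[-1]`` channels at spatial size ``in_size // 8``.  Layer
    names accepted by :meth:`activations` are ``conv1 .. conv3``
    (post-ReLU, pre-pool).
    """

    LAYER_NAMES = ("conv1", "conv2", "conv3")

    def __init__(
        self,
        in_size: int = 256,
        channels: tuple[int, int, int] = (8, 16, 16),
        seed: int = 0,
        zero_bias: bool = False,
    ):
        if in_size % 8 != 0:
            raise ValueError("input side must be divisible by 8")
        self.in_size = in_size
        self.channels = tuple(channels)
        rng = np.random.default_rng(seed)
        fan_in = [1] + list(channels[:-1])
        self.convs = []
        for cin, cout in zip(fan_in, channels):
            W = rng.standard_normal((cout, cin, 3, 3)) * np.sqrt(2.0 / (cin * 9))
            b = np.zeros(cout)
            self.convs.append([W, b])
        self.head_w = rng.standard_normal(channels[-1]) * np.sqrt(1.0 / channels[-1])
        self.head_b = 0.0 if zero_bias else float(rng.standard_normal() * 0.01)
        if zero_bias:
            self.head_b = 0.0

    # -- inference ---------------------------------------------------------

    @property
    def head(self) -> ClassifierHead:
        return ClassifierHead(weights=self.head_w.copy(), bias=float(self.head_b))

    @property
    def n_channels(self) -> int:
        return self.channels[-1]

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[2] != self.in_size or x.shape[3] != self.in_size:
            raise ValueError(
                f"expected square inputs of side {self.in_size}, got {x.shape}"
            )
        return x

    def activations(self, batch: np.ndarray) -> dict[str, np.ndarray]:
        """Evaluation-mode forward pass returning every named activation,
        the GAP vector, and the logit."""
        x = self._check_input(batch)
        acts: dict[str, np.ndarray] = {}
        for i, (W, b) in enumerate(self.convs):
            y, _ = _conv3_forward(x, W, b)
            y = np.maximum(y, 0.0)
            acts[f"conv{i + 1}"] = y
            x = _pool2_forward(y)
        acts["features"] = acts["conv3"]
        gap = acts["conv3"].mean(axis=(2, 3))
        acts["gap"] = gap
        acts["logit"] = gap @ self.head_w + self.head_b
        return acts

    def forward_features(self, batch: np.ndarray) -> np.ndarray:
        """Final-conv feature stacks A^k, shape (B, K, h, w)."""
        return self.activations(batch)["features"]

    def predict(self, batch: np.ndarray, threshold: float = 0.5) -> list[ClassifierOutput]:
        logits = self.activations(batch)["logit"]
        return [
            ClassifierOutput(logit=float(z), p_aspecific=float(sigmoid(z)),
                             threshold=threshold)
            for z in np.atleast_1d(logits)
        ]

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        return np.asarray(sigmoid(self.activations(batch)["logit"]))

    # -- training ----------------------------------------------------------

    def _params(self):
        ps = []
        for W, b in self.convs:
            ps.extend((W, b))
        ps.append(self.head_w)
        return ps

    def get_state(self):
        return copy.deepcopy(
            {"convs": self.convs, "head_w": self.head_w, "head_b": self.head_b}
        )

    def set_state(self, state) -> None:
        state = copy.deepcopy(state)
        self.convs = state["convs"]
        self.head_w = state["head_w"]
        self.head_b = state["head_b"]

    def _forward_train(self, x, dropout: float, rng: np.random.Generator):
        cache = []
        for W, b in self.convs:
            y, win = _conv3_forward(x, W, b)
            mask = y > 0
            y = y * mask
            cache.append((win, mask, y.shape))
            x = _pool2_forward(y)
        feat = x  # pooled final features (B,K,h',w') feed GAP
        gap = feat.mean(axis=(2, 3))
        if dropout > 0:
            keep = rng.random(gap.shape) >= dropout
            gap_d = gap * keep / (1.0 - dropout)
        else:
            keep, gap_d = None, gap
        logit = gap_d @ self.head_w + self.head_b
        return cache, feat.shape, gap_d, keep, logit

    def train_step(
        self, x, y, lr: float, cfg: TrainConfig, rng: np.random.Generator, velocity
    ) -> float:
        """One SGD-with-momentum minibatch update; returns the batch loss."""
        x = self._check_input(x)
        y = np.asarray(y, dtype=np.float64)
        B = x.shape[0]
        cache, feat_shape, gap_d, keep, logit = self._forward_train(
            x, cfg.dropout, rng
        )
        p = sigmoid(logit)
        loss = float(np.mean(np.logaddexp(0.0, logit) - y * logit))
        dz = (p - y) / B
        grads = {}
        grads["head_w"] = gap_d.T @ dz
        grads["head_b"] = float(dz.sum())
        dgap = np.outer(dz, self.head_w)
        if keep is not None:
            dgap = dgap * keep / (1.0 - cfg.dropout)
        _, k, hh, ww = feat_shape
        dx = np.broadcast_to(
            dgap[:, :, None, None] / (hh * ww), feat_shape
        ).copy()
        conv_grads = []
        for i in range(len(self.convs) - 1, -1, -1):
            win, mask, _ = cache[i]
            dy = _pool2_backward(dx) * mask
            dx, dW, db = _conv3_backward(win, self.convs[i][0], dy)
            conv_grads.append((dW, db))
        conv_grads.reverse()

        # SGD with momentum + decoupled-from-schedule weight decay on weights
        def upd(name, param, grad, decay):
            g = grad + decay * param
            v = velocity.get(name)
            if v is None:
                v = np.zeros_like(np.asarray(param, dtype=np.float64))
            v = cfg.momentum * v - lr * g
            velocity[name] = v
            return param + v

        for i, (dW, db) in enumerate(conv_grads):
            self.convs[i][0] = upd(f"W{i}", self.convs[i][0], dW, cfg.weight_decay)
            self.convs[i][1] = upd(f"b{i}", self.convs[i][1], db, 0.0)
        self.head_w = upd("hw", self.head_w, grads["head_w"], cfg.weight_decay)
        self.head_b = float(upd("hb", self.head_b, grads["head_b"], 0.0))
        return loss


def evaluate_classifier(model: TinyCNN, X, y, threshold: float = 0.5,
                        batch_size: int = 256):
    """Mean BCE loss and accuracy of a labeled patch set."""
    y = np.asarray(y, dtype=np.float64)
    losses, correct = [], 0
    for i in range(0, len(y), batch_size):
        logit = model.activations(X[i : i + batch_size])["logit"]
        yy = y[i : i + batch_size]
        losses.append(np.sum(np.logaddexp(0.0, logit) - yy * logit))
        correct += int(np.sum((sigmoid(logit) > threshold) == (yy > 0.5)))
    return float(np.sum(losses) / len(y)), correct / len(y)


@dataclass
class TrainResult:
    model: TinyCNN
    log: list[dict[str, float]] = field(default_factory=list)
    best_epoch: int = -1


def train_classifier(
    train_X: np.ndarray,
    train_y: np.ndarray,
    val_X: np.ndarray,
    val_y: np.ndarray,
    cfg: TrainConfig,
    seed: int = 0,
    model: TinyCNN | None = None,
    channels: tuple[int, int, int] = (8, 16, 16),
) -> TrainResult:
    """Train the patch classifier, returning the best-by-validation model.

    ``train_X``/``val_X`` are (N, S, S) arrays of augmented crops in [0,1];
    labels are 1 for aspecific, 0 for benign.  The log records, per epoch,
    the scheduled learning rate and train/validation losses plus validation
    accuracy.  Fully deterministic given the seed.
    """
    cfg.validate()
    if len(train_y) == 0 or len(val_y) == 0:
        raise ValueError("train and validation splits must be non-empty")
    rng = np.random.default_rng(seed)
    if model is None:
        model = TinyCNN(
            in_size=train_X.shape[-1], channels=channels,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
    velocity: dict[str, np.ndarray] = {}
    result = TrainResult(model=model)
    best_val = np.inf
    best_state = model.get_state()
    n = len(train_y)
    for epoch in range(cfg.epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        ep_loss, nb = 0.0, 0
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            ep_loss += model.train_step(
                train_X[idx], train_y[idx], lr, cfg, rng, velocity
            )
            nb += 1
        val_loss, val_acc = evaluate_classifier(model, val_X, val_y, cfg.threshold)
        result.log.append(
            {
                "epoch": epoch, "lr": lr, "train_loss": ep_loss / max(nb, 1),
                "val_loss": val_loss, "val_acc": val_acc,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.get_state()
            result.best_epoch = epoch
    model.set_state(best_state)
    return result


def save_checkpoint(path, model: TinyCNN) -> None:
    """Persist backbone identity, geometry and weights as an .npz archive."""
    arrays = {"in_size": np.array(model.in_size),
              "channels": np.array(model.channels),
              "head_w": model.head_w, "head_b": np.array(model.head_b)}
    for i, (W, b) in enumerate(model.convs):
        arrays[f"W{i}"], arrays[f"b{i}"] = W, b
    np.savez(path, backbone=np.array("tinycnn"), **arrays)


def load_checkpoint(path) -> TinyCNN:
    with np.load(path, allow_pickle=False) as z:
        if str(z["backbone"]) != "tinycnn":
            raise ValueError("unknown backbone identifier in checkpoint")
        model = TinyCNN(in_size=int(z["in_size"]),
                        channels=tuple(int(c) for c in z["channels"]))
        model.convs = [[z[f"W{i}"], z[f"b{i}"]] for i in range(len(model.channels))]
        model.head_w = z["head_w"]
        model.head_b = float(z["head_b"])
    return model
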