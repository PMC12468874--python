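"""RAMM: a hybrid residual + attention + MLP-Mixer feature extractor.

Two convolutional branches see the same spectrogram image in parallel — a
residual branch (stacked conv blocks with identity shortcuts) and an
attention branch (squeeze-and-excitation channel weighting) — and their
output maps are concatenated, patchified and passed through MLP-Mixer
blocks (token mixing across patches, channel mixing within patches).  The
head is a dense layer to a wide ReLU feature layer (1000 units by default,
the layer deep features are read from) followed by a two-class softmax.

The default configuration totals ~581k learnable parameters.  Exact block
widths are tunable through :class:`RAMMConfig`; the network trains with
plain SGD + momentum and cross-entropy, seeded and CPU-only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn.layers import (
    Conv2d,
    Dense,
    Layer,
    LayerNorm,
    Param,
    ReLU,
    SGDMomentum,
    Sigmoid,
    softmax,
    softmax_cross_entropy,
)

logger = logging.getLogger(__name__)


@dataclass
class RAMMConfig:
    input_size: int = 200
    input_channels: int = 1
    residual_widths: tuple[int, ...] = (32, 64)  # one stage (stride-2) per width
    attention_kind: str = "channel_SE"
    se_reduction: int = 4
    merge: str = "concat"  # or "add"
    reduce_channels: int = 24  # 1x1 conv before patching
    mixer_patch: int = 20  # in input pixels; /4 on the stride-4 merged map
    mixer_depth: int = 2
    mixer_hidden: int = 128  # token embedding width
    mixer_token_dim: int = 64
    mixer_channel_dim: int = 412
    feature_dim: int = 1000
    n_classes: int = 2

    def __post_init__(self) -> None:
        stride = 2 ** len(self.residual_widths)
        if self.input_size % self.mixer_patch:
            raise ValueError("input_size must be divisible by mixer_patch")
        if self.mixer_patch % stride:
            raise ValueError(
                f"mixer_patch must be divisible by the branch stride ({stride})"
            )
        if self.feature_dim < self.n_classes:
            raise ValueError("feature_dim must be >= n_classes")
        if self.attention_kind != "channel_SE":
            raise ValueError(f"unsupported attention_kind {self.attention_kind!r}")
        if self.merge not in ("concat", "add"):
            raise ValueError(f"merge must be 'concat' or 'add', got {self.merge!r}")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 50
    batch_size: int = 16
    val_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class FeatureMatrix:
    """N x D deep-feature table aligned to record ids and labels."""

    values: np.ndarray
    ids: list[str]
    labels: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != self.values.shape[0] or len(self.labels) != len(self.ids):
            raise ValueError("ids/labels must match the number of feature rows")


class _ConvReLU(Layer):
    def __init__(self, c_in, c_out, rng, stride=1, name="conv"):
        self.conv = Conv2d(c_in, c_out, 3, rng, stride=stride, name=name)
        self.act = ReLU()

    def params(self):
        return self.conv.params()

    def forward(self, x, train=False):
        return self.act.forward(self.conv.forward(x, train), train)

    def backward(self, dy):
        return self.conv.backward(self.act.backward(dy))


class _ResidualBlock(Layer):
    """conv-ReLU-conv plus identity shortcut, ReLU after the sum."""

    def __init__(self, c, rng, name="res"):
        self.conv1 = Conv2d(c, c, 3, rng, name=f"{name}.conv1")
        self.act1 = ReLU()
        self.conv2 = Conv2d(c, c, 3, rng, name=f"{name}.conv2")
        self.act2 = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x, train=False):
        h = self.act1.forward(self.conv1.forward(x, train), train)
        return self.act2.forward(self.conv2.forward(h, train) + x, train)

    def backward(self, dy):
        dsum = self.act2.backward(dy)
        dx = self.conv1.backward(self.act1.backward(self.conv2.backward(dsum)))
        return dx + dsum


class _SEBlock(Layer):
    """Squeeze-and-excitation: global-average squeeze, two dense layers,
    sigmoid channel weights in (0, 1) multiplied back onto the map."""

    def __init__(self, c, rng, reduction=4, name="se"):
        hidden = max(c // reduction, 1)
        self.fc1 = Dense(c, hidden, rng, name=f"{name}.fc1")
        self.act = ReLU()
        self.fc2 = Dense(hidden, c, rng, name=f"{name}.fc2")
        self.gate = Sigmoid()

    def params(self):
        return self.fc1.params() + self.fc2.params()

    def channel_weights(self, x: np.ndarray) -> np.ndarray:
        z = x.mean(axis=(2, 3))
        return self.gate.forward(
            self.fc2.forward(self.act.forward(self.fc1.forward(z)))
        )

    def forward(self, x, train=False):
        self._x = x
        z = x.mean(axis=(2, 3))  # squeeze: B, C
        s = self.gate.forward(
            self.fc2.forward(
                self.act.forward(self.fc1.forward(z, train), train), train
            ),
            train,
        )
        self._s = s
        return x * s[:, :, None, None]

    def backward(self, dy):
        x, s = self._x, self._s
        ds = (dy * x).sum(axis=(2, 3))
        dz = self.fc1.backward(
            self.act.backward(self.fc2.backward(self.gate.backward(ds)))
        )
        _, _, H, W = x.shape
        return dy * s[:, :, None, None] + dz[:, :, None, None] / (H * W)


class _MixerBlock(Layer):
    """Token-mixing MLP across patches, then channel-mixing MLP, both with
    layer norm and residual connections."""

    def __init__(self, n_tokens, channels, token_dim, channel_dim, rng, name="mixer"):
        self.ln1 = LayerNorm(channels, name=f"{name}.ln1")
        self.tok1 = Dense(n_tokens, token_dim, rng, name=f"{name}.tok1")
        self.tact = ReLU()
        self.tok2 = Dense(token_dim, n_tokens, rng, name=f"{name}.tok2")
        self.ln2 = LayerNorm(channels, name=f"{name}.ln2")
        self.ch1 = Dense(channels, channel_dim, rng, name=f"{name}.ch1")
        self.cact = ReLU()
        self.ch2 = Dense(channel_dim, channels, rng, name=f"{name}.ch2")

    def params(self):
        return (
            self.ln1.params() + self.tok1.params() + self.tok2.params()
            + self.ln2.params() + self.ch1.params() + self.ch2.params()
        )

    def forward(self, x, train=False):  # x: B, T, C
        y = self.ln1.forward(x, train).transpose(0, 2, 1)  # B, C, T
        y = self.tok2.forward(self.tact.forward(self.tok1.forward(y, train), train), train)
        x = x + y.transpose(0, 2, 1)
        z = self.ln2.forward(x, train)
        return x + self.ch2.forward(self.cact.forward(self.ch1.forward(z, train), train), train)

    def backward(self, dy):
        dz = self.ln2.backward(
            self.ch1.backward(self.cact.backward(self.ch2.backward(dy)))
        )
        dx = dy + dz
        dyt = self.tok1.backward(
            self.tact.backward(self.tok2.backward(dx.transpose(0, 2, 1)))
        )
        return dx + self.ln1.backward(dyt.transpose(0, 2, 1))


class RAMMModel:
    """The assembled network; see the module docstring for the topology."""

    def __init__(self, cfg: RAMMConfig, seed: int = 0):
        self.cfg = cfg
        self.trained = False
        rng = np.random.default_rng(seed)
        w = cfg.residual_widths
        c_in = cfg.input_channels

        # residual branch: per stage a stride-2 conv then a residual block
        self.res_branch: list[Layer] = []
        prev = c_in
        for i, width in enumerate(w):
            self.res_branch.append(_ConvReLU(prev, width, rng, stride=2, name=f"res.down{i}"))
            self.res_branch.append(_ResidualBlock(width, rng, name=f"res.block{i}"))
            prev = width

        # attention branch: same downsampling trunk, SE gate at the end
        self.att_branch: list[Layer] = []
        prev = c_in
        for i, width in enumerate(w):
            self.att_branch.append(_ConvReLU(prev, width, rng, stride=2, name=f"att.down{i}"))
            prev = width
        self.se = _SEBlock(prev, rng, reduction=cfg.se_reduction)
        self.att_branch.append(self.se)

        merged_c = 2 * w[-1] if cfg.merge == "concat" else w[-1]
        self.reduce = Conv2d(merged_c, cfg.reduce_channels, 1, rng, pad=0, name="reduce")

        stride = 2 ** len(w)
        self._map_size = cfg.input_size // stride
        self._patch = cfg.mixer_patch // stride
        grid = self._map_size // self._patch
        self.n_tokens = grid * grid
        patch_dim = cfg.reduce_channels * self._patch * self._patch
        self.embed = Dense(patch_dim, cfg.mixer_hidden, rng, name="embed")
        self.mixers = [
            _MixerBlock(
                self.n_tokens, cfg.mixer_hidden, cfg.mixer_token_dim,
                cfg.mixer_channel_dim, rng, name=f"mixer{i}",
            )
            for i in range(cfg.mixer_depth)
        ]
        self.fc_feat = Dense(cfg.mixer_hidden, cfg.feature_dim, rng, name="fc_feat")
        self.feat_act = ReLU()
        self.fc_out = Dense(cfg.feature_dim, cfg.n_classes, rng, name="fc_out")

    # ---- plumbing -------------------------------------------------------
    def params(self) -> list[Param]:
        ps: list[Param] = []
        for m in self.res_branch + self.att_branch:
            ps += m.params()
        ps += self.reduce.params() + self.embed.params()
        for m in self.mixers:
            ps += m.params()
        ps += self.fc_feat.params() + self.fc_out.params()
        return ps

    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def _patchify(self, m: np.ndarray) -> np.ndarray:
        B, C, H, W = m.shape
        p = self._patch
        g = H // p
        v = m.reshape(B, C, g, p, g, p).transpose(0, 2, 4, 1, 3, 5)
        return v.reshape(B, g * g, C * p * p)

    def _unpatchify(self, dt: np.ndarray, shape: tuple) -> np.ndarray:
        B, C, H, W = shape
        p = self._patch
        g = H // p
        v = dt.reshape(B, g, g, C, p, p).transpose(0, 3, 1, 4, 2, 5)
        return v.reshape(B, C, H, W)

    # ---- forward / backward --------------------------------------------
    def forward(self, images: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """images (B, H, W) or (B, C, H, W) -> (features (B, D), probs (B, K))."""
        logits, feats = self._forward_logits(images, train)
        return feats, softmax(logits)

    def _forward_logits(self, images: np.ndarray, train: bool):
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} images, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        r = x
        for m in self.res_branch:
            r = m.forward(r, train)
        a = x
        for m in self.att_branch:
            a = m.forward(a, train)
        if self.cfg.merge == "concat":
            merged = np.concatenate([r, a], axis=1)
        else:
            merged = r + a
        self._r_channels = r.shape[1]
        red = self.reduce.forward(merged, train)
        self._red_shape = red.shape
        tokens = self.embed.forward(self._patchify(red), train)
        for m in self.mixers:
            tokens = m.forward(tokens, train)
        self._n_tok = tokens.shape[1]
        pooled = tokens.mean(axis=1)
        feats = self.feat_act.forward(self.fc_feat.forward(pooled, train), train)
        logits = self.fc_out.forward(feats, train)
        return logits, feats

    def _backward(self, dlogits: np.ndarray) -> None:
        d = self.fc_feat.backward(self.feat_act.backward(self.fc_out.backward(dlogits)))
        dt = np.repeat(d[:, None, :], self._n_tok, axis=1) / self._n_tok
        for m in reversed(self.mixers):
            dt = m.backward(dt)
        dred = self._unpatchify(self.embed.backward(dt), self._red_shape)
        dmerged = self.reduce.backward(dred)
        if self.cfg.merge == "concat":
            dr = dmerged[:, : self._r_channels]
            da = dmerged[:, self._r_channels :]
        else:
            dr = da = dmerged
        for m in reversed(self.res_branch):
            dr = m.backward(dr)
        for m in reversed(self.att_branch):
            da = m.backward(da)

    def loss_and_grad(self, images: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
        """Cross-entropy on a batch; accumulates parameter gradients."""
        logits, _ = self._forward_logits(images, train=True)
        loss, dlogits = softmax_cross_entropy(logits, labels)
        self._backward(dlogits)
        return loss, softmax(logits)

    # ---- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"p{i}": p.value for i, p in enumerate(self.params())}
        cfg = asdict(self.cfg)
        cfg["residual_widths"] = list(cfg["residual_widths"])
        np.savez(
            path,
            __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
            __trained__=np.array([int(self.trained)]),
            **arrays,
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RAMMModel":
        with np.load(path) as data:
            cfg_d = json.loads(bytes(data["__config__"]).decode())
            cfg_d["residual_widths"] = tuple(cfg_d["residual_widths"])
            model = cls(RAMMConfig(**cfg_d))
            model.trained = bool(data["__trained__"][0])
            for i, p in enumerate(model.params()):
                p.value[...] = data[f"p{i}"]
        return model


def build_model(cfg: RAMMConfig | None = None, seed: int = 0) -> RAMMModel:
    """Build a seeded, untrained network and log its parameter count."""
    model = RAMMModel(cfg or RAMMConfig(), seed=seed)
    logger.info("built RAMM model with %d learnable parameters", model.param_count())
    return model


LABEL_TO_INT = {"healthy": 0, "unhealthy": 1}


def encode_labels(labels: list[str]) -> np.ndarray:
    return np.array([LABEL_TO_INT[lab] for lab in labels], dtype=np.int64)


def train_model(
    model: RAMMModel,
    images: np.ndarray,
    labels: np.ndarray | list[str],
    tcfg: TrainConfig,
) -> list[dict]:
    """Train with SGD + momentum and cross-entropy; returns per-epoch history.

    A stratified ``val_fraction`` of the data is held out for the validation
    curve (none if the fraction rounds to zero per class).  Reproducible on
    one device for a fixed seed.
    """
    y = encode_labels(labels) if not isinstance(labels, np.ndarray) else labels
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training requires at least two classes")
    for c in classes:
        if (y == c).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")

    rng = np.random.default_rng(tcfg.seed)
    val_idx: list[int] = []
    train_idx: list[int] = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(tcfg.val_fraction * idx.size))
        val_idx += idx[:n_val].tolist()
        train_idx += idx[n_val:].tolist()
    train_idx = np.array(sorted(train_idx))
    val_idx = np.array(sorted(val_idx), dtype=int)

    opt = SGDMomentum(model.params(), lr=tcfg.learning_rate, momentum=tcfg.momentum)
    history: list[dict] = []
    for epoch in range(tcfg.epochs):
        order = train_idx[rng.permutation(train_idx.size)]
        losses, correct = [], 0
        for start in range(0, order.size, tcfg.batch_size):
            batch = order[start : start + tcfg.batch_size]
            opt.zero_grad()
            loss, probs = model.loss_and_grad(images[batch], y[batch])
            opt.step()
            losses.append(loss * batch.size)
            correct += int((probs.argmax(axis=1) == y[batch]).sum())
        row = {
            "epoch": epoch + 1,
            "train_loss": float(np.sum(losses) / order.size),
            "train_acc": correct / order.size,
        }
        if val_idx.size:
            vloss, vacc = evaluate(model, images[val_idx], y[val_idx], tcfg.batch_size)
            row["val_loss"], row["val_acc"] = vloss, vacc
        history.append(row)
        logger.debug("epoch %d: %s", epoch + 1, row)
    model.trained = True
    return history


def evaluate(
    model: RAMMModel, images: np.ndarray, y: np.ndarray, batch_size: int = 32
) -> tuple[float, float]:
    losses, correct = 0.0, 0
    for start in range(0, len(images), batch_size):
        sl = slice(start, start + batch_size)
        logits, _ = model._forward_logits(images[sl], train=False)
        loss, _ = softmax_cross_entropy(logits, y[sl])
        losses += loss * (logits.shape[0])
        correct += int((logits.argmax(axis=1) == y[sl]).sum())
    return losses / len(images), correct / len(images)


def extract_features(
    model: RAMMModel,
    images: np.ndarray,
    ids: list[str],
    labels: list[str],
    batch_size: int = 32,
) -> FeatureMatrix:
    """Deep features from the last ReLU layer, one row per image."""
    if not model.trained:
        logger.warning("extracting features from an untrained model")
    rows = []
    for start in range(0, len(images), batch_size):
        feats, _ = model.forward(images[start : start + batch_size], train=False)
        rows.append(feats)
    return FeatureMatrix(values=np.vstack(rows), ids=list(ids), labels=list(labels))
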