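"""The lightweight attention-augmented patch classifier (local detection stage).

A shallow network of standard convolutions, residual depthwise-separable
stages, a spatial attention gate before the first pooling stage and a channel
attention gate after the widest stage, ending in a SELU dense head with a
two-class softmax.  It maps a single-channel patch (default 32 x 32) to the
probability that the patch contains GAN-generated content.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

log = logging.getLogger(__name__)


@dataclass
class DetectorConfig:
    """Architecture hyper-parameters of the patch detector.

    ``stem`` are the widths of the standard 3x3 convolutions applied at full
    patch resolution; each entry of ``stages`` is the width of one residual
    depthwise-separable stage whose first block halves the spatial size.
    Spatial attention is inserted after the stem (before the first pooling
    stage); channel attention after the last (widest) stage.
    """

    input_size: int = 32
    stem: tuple = (32, 64)
    stages: tuple = (128, 256, 256)
    blocks_per_stage: int = 2
    dense: int = 128
    spatial_attention: bool = True
    channel_attention: bool = True
    spatial_kernel: int = 7
    bn_keep: float = 0.95

    def __post_init__(self):
        if self.input_size % (2 ** len(self.stages)) != 0:
            raise ValueError("input_size must be divisible by 2**len(stages)")
        if not self.stem or not self.stages:
            raise ValueError("stem and stages must be non-empty")

    @classmethod
    def small(cls) -> "DetectorConfig":
        """Narrow 16x16-input variant used for the 128x128 synthetic benchmark."""
        return cls(input_size=16, stem=(8, 16), stages=(16, 32, 64), dense=32)


@dataclass
class TrainConfig:
    """Optimization settings for the patch detector."""

    lr0: float = 5e-4
    decay_every: int = 600
    decay_rate: float = 0.85
    batch: int = 56
    bn_keep: float = 0.95
    l2: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    early_stop_patience: int = 3
    max_epochs: int = 30
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.early_stop_patience < self.max_epochs):
            raise ValueError("patience must be positive and below max_epochs")


class DetectorModel:
    """Assembled patch classifier with learned parameters and history."""

    def __init__(self, cfg: DetectorConfig, seed: int = 0):
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        mods: list[nn.Module] = []
        cin = 1
        for width in cfg.stem:
            mods += [nn.Conv2d(cin, width, 3, rng), nn.BatchNorm2d(width, cfg.bn_keep), nn.ReLU()]
            cin = width
        mods.append(nn.SpatialAttention(rng, cfg.spatial_kernel) if cfg.spatial_attention else nn.Identity())
        for width in cfg.stages:
            mods.append(nn.TransitionBlock(cin, width, rng, cfg.bn_keep))
            for _ in range(cfg.blocks_per_stage - 1):
                mods.append(nn.IdentityBlock(width, rng, cfg.bn_keep))
            cin = width
        mods.append(nn.ChannelAttention(cin, rng) if cfg.channel_attention else nn.Identity())
        mods.append(nn.GlobalAvgPool())
        mods.append(nn.Dense(cin, cfg.dense, rng))
        mods.append(nn.SELU())
        mods.append(nn.Dense(cfg.dense, 2, rng))
        self.modules = mods
        self.dtype = nn.DTYPE
        self.history: list[dict] = []

    # ---- parameter plumbing -------------------------------------------------
    def params(self) -> list[nn.Param]:
        return [p for m in self.modules for p in m.params()]

    def n_params(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def state(self) -> list[np.ndarray]:
        arrays = [p.value.copy() for p in self.params()]
        for m in self._bn_modules():
            arrays += [m.running_mean.copy(), m.running_var.copy()]
        return arrays

    def load_state(self, arrays: list[np.ndarray]) -> None:
        ps = self.params()
        for p, a in zip(ps, arrays[: len(ps)]):
            p.value[...] = a
        rest = arrays[len(ps) :]
        for i, m in enumerate(self._bn_modules()):
            m.running_mean = rest[2 * i]
            m.running_var = rest[2 * i + 1]

    def _bn_modules(self):
        out = []

        def walk(m):
            if isinstance(m, nn.BatchNorm2d):
                out.append(m)
            for attr in ("mods", "main", "short", "conv"):
                sub = getattr(m, attr, None)
                if isinstance(sub, nn.Module):
                    walk(sub)
                elif isinstance(sub, list):
                    for s in sub:
                        walk(s)

        for m in self.modules:
            walk(m)
        return out

    # ---- forward / backward -------------------------------------------------
    def _as_batch(self, patches: np.ndarray) -> np.ndarray:
        x = np.asarray(patches, dtype=self.dtype)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        s = self.cfg.input_size
        if x.shape[2] != s or x.shape[3] != s or x.shape[1] != 1:
            raise ValueError(f"expected single-channel {s}x{s} patches, got {x.shape}")
        return x

    def logits(self, patches: np.ndarray, train: bool = False) -> np.ndarray:
        x = self._as_batch(patches)
        for m in self.modules:
            x = m.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        dy = dlogits
        for m in reversed(self.modules):
            dy = m.backward(dy)

    def predict(self, patches: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Tamper probability (softmax coordinate of the tampered class) per patch."""
        x = self._as_batch(patches)
        out = np.empty(x.shape[0])
        for i in range(0, x.shape[0], batch_size):
            out[i : i + batch_size] = nn.softmax(self.logits(x[i : i + batch_size]))[:, 1]
        return out

    # ---- persistence --------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"a{i}": a for i, a in enumerate(self.state())}
        meta = json.dumps({"cfg": asdict(self.cfg), "seed": self.seed, "history": self.history})
        np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "DetectorModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["meta"]).decode())
            arrays = [z[f"a{i}"] for i in range(len(z.files) - 1)]
        cfg = meta["cfg"]
        cfg["stem"] = tuple(cfg["stem"])
        cfg["stages"] = tuple(cfg["stages"])
        model = cls(DetectorConfig(**cfg), seed=meta["seed"])
        model.load_state(arrays)
        model.history = meta["history"]
        return model


def build_detector(cfg: DetectorConfig | None = None, seed: int = 0) -> DetectorModel:
    """Construct the patch detector with reproducible He-style initialization."""
    return DetectorModel(cfg or DetectorConfig(), seed=seed)


def _accuracy(model: DetectorModel, patches: np.ndarray, labels: np.ndarray) -> float:
    probs = model.predict(patches)
    return float(((probs > 0.5).astype(int) == labels).mean())


def train_detector(
    model: DetectorModel,
    train_patches: np.ndarray,
    train_labels: np.ndarray,
    val_patches: np.ndarray,
    val_labels: np.ndarray,
    tc: TrainConfig | None = None,
) -> DetectorModel:
    """Train with Adam on softmax cross-entropy; early stop on validation accuracy.

    The learning rate decays by ``decay_rate`` every ``decay_every`` optimizer
    steps (staircase).  Training halts when validation accuracy has not
    improved for ``early_stop_patience`` consecutive epochs; the parameters of
    the best validation epoch are retained.
    """
    tc = tc or TrainConfig()
    train_labels = np.asarray(train_labels, dtype=int)
    val_labels = np.asarray(val_labels, dtype=int)
    if len(set(train_labels.tolist())) < 2:
        raise ValueError("training set must contain both classes")
    if val_labels.size == 0:
        raise ValueError("validation set is empty")

    opt = nn.Adam(
        model.params(), lr0=tc.lr0, decay_every=tc.decay_every, decay_rate=tc.decay_rate,
        beta1=tc.beta1, beta2=tc.beta2, eps=tc.eps, l2=tc.l2,
    )
    rng = np.random.default_rng(tc.seed)
    x = model._as_batch(train_patches)
    n = x.shape[0]
    best_val, best_state, stale = -np.inf, model.state(), 0
    for epoch in range(tc.max_epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        for i in range(0, n, tc.batch):
            idx = order[i : i + tc.batch]
            opt.zero_grad()
            logits = model.logits(x[idx], train=True)
            loss, dlogits = nn.softmax_cross_entropy(logits, train_labels[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == train_labels[idx]).sum())
        train_acc = correct / n  # running train-mode accuracy over the epoch
        val_acc = _accuracy(model, val_patches, val_labels)
        model.history.append(
            {"epoch": epoch, "lr": opt.lr, "loss": float(np.mean(losses)),
             "train_acc": train_acc, "val_acc": val_acc}
        )
        log.info("epoch %d loss %.4f train_acc %.4f val_acc %.4f", epoch, np.mean(losses), train_acc, val_acc)
        if val_acc > best_val:
            best_val, best_state, stale = val_acc, model.state(), 0
        else:
            stale += 1
            if stale >= tc.early_stop_patience:
                log.info("early stop at epoch %d (no val improvement for %d epochs)", epoch, stale)
                break
    model.load_state(best_state)
    return model


def predict_patches(model: DetectorModel, patches: np.ndarray) -> np.ndarray:
    """Order-aligned tamper probabilities for a batch of patches."""
    return model.predict(patches)
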