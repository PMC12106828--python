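"""Attention-gated U-Net nuclei segmentation, Dice metric, Otsu baseline.

The segmenter is a 5-level U-Net: encoder stages of two 3x3 convolutions
each, four 3x3/stride-2 max-pools between stages, and a decoder that mirrors
the encoder with nearest up-sampling.  Skip connections are gated by
additive spatial attention: 1x1 projections of the encoder skip and the
up-sampled decoder signal are summed, rectified, projected to one channel
and squashed to a per-pixel weight in [0, 1] that multiplies the skip
features.  A 1x1 sigmoid head yields the nuclei probability map, trained
with binary cross-entropy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from . import nnet
from .nnet import (
    Conv2D,
    MaxPool2D,
    ReLU,
    Sequential,
    UpSample2D,
    make_optimizer,
    sigmoid,
    sigmoid_bce_with_logits,
)

__all__ = [
    "UNetSAMConfig",
    "SegMask",
    "AttentionGate",
    "UNetSAM",
    "build_unet_sam",
    "dice",
    "train_segmenter",
    "predict_mask",
    "otsu_nuclei_mask",
]


@dataclass(frozen=True)
class UNetSAMConfig:
    """Architecture and training settings of the attention U-Net.

    Defaults follow the reference training setup (sigmoid head, Adam,
    binary cross-entropy, learning rate 1e-4, 50 epochs, batch size 16);
    ``width_scale`` shrinks every stage's channel count for desk-scale runs.
    """

    encoder_filters: tuple[int, ...] = (16, 32, 64, 128, 256)
    conv_kernel: int = 3
    pool_size: int = 3
    num_pool_layers: int = 4
    decoder_attention: bool = True
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 16
    optimizer: str = "adam"
    width_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.encoder_filters) != sorted(set(self.encoder_filters)):
            raise ValueError("encoder_filters must be strictly increasing")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be positive")
        if self.epochs < 0 or self.batch_size <= 0:
            raise ValueError("epochs must be >= 0 and batch_size positive")

    @property
    def scaled_filters(self) -> tuple[int, ...]:
        return tuple(max(1, round(f * self.width_scale)) for f in self.encoder_filters)

    @property
    def down_factor(self) -> int:
        return 2**self.num_pool_layers


@dataclass
class SegMask:
    """Binary nuclei mask with per-instance labels and the probability map."""

    probability: np.ndarray
    mask: np.ndarray
    instances: np.ndarray
    n_instances: int


class AttentionGate:
    """Additive spatial attention: skip features x gated by decoder signal g."""

    def __init__(self, cx: int, cg: int, inter: int, rng: np.random.Generator) -> None:
        self.theta = Conv2D(cx, inter, k=1, use_bias=False, rng=rng)
        self.phi = Conv2D(cg, inter, k=1, use_bias=True, rng=rng)
        self.relu = ReLU()
        self.psi = Conv2D(inter, 1, k=1, use_bias=True, rng=rng)
        self._convs = [self.theta, self.phi, self.psi]

    def forward(
        self, x: np.ndarray, g: np.ndarray, training: bool = False
    ) -> np.ndarray:
        if x.shape[:3] != g.shape[:3]:
            raise ValueError(f"misaligned feature maps: {x.shape} vs {g.shape}")
        a = self.relu.forward(
            self.theta.forward(x, training) + self.phi.forward(g, training), training
        )
        s = self.psi.forward(a, training)
        self._alpha = sigmoid(s)
        self._x = x
        return x * self._alpha

    def backward(self, grad: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        dx = grad * self._alpha
        dalpha = (grad * self._x).sum(axis=-1, keepdims=True)
        ds = dalpha * self._alpha * (1.0 - self._alpha)
        da = self.psi.backward(ds)
        dtp = self.relu.backward(da)
        return dx + self.theta.backward(dtp), self.phi.backward(dtp)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for c in self._convs for p in c.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for c in self._convs for g in c.grads]

    @property
    def attention_map(self) -> np.ndarray:
        """Per-pixel gate weights from the most recent forward pass."""
        return self._alpha


def _conv_block(cin: int, cout: int, k: int, rng: np.random.Generator) -> Sequential:
    return Sequential(
        [Conv2D(cin, cout, k=k, rng=rng), ReLU(), Conv2D(cout, cout, k=k, rng=rng), ReLU()]
    )


class UNetSAM:
    """5-level U-Net with attention-gated skips; head emits nuclei logits."""

    def __init__(self, config: UNetSAMConfig, in_channels: int = 3) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.scaled_filters
        k = config.conv_kernel
        self.enc = []
        cin = in_channels
        for fo in f:
            self.enc.append(_conv_block(cin, fo, k, rng))
            cin = fo
        self.pools = [
            MaxPool2D(pool=config.pool_size, stride=2) for _ in range(config.num_pool_layers)
        ]
        self.ups: list[UpSample2D] = []
        self.atts: list[AttentionGate | None] = []
        self.dec: list[Sequential] = []
        c_up = f[-1]
        for i in range(len(f) - 2, -1, -1):
            self.ups.insert(0, UpSample2D(2))
            if config.decoder_attention:
                self.atts.insert(
                    0, AttentionGate(f[i], c_up, max(1, f[i] // 2), rng)
                )
            else:
                self.atts.insert(0, None)
            self.dec.insert(0, _conv_block(f[i] + c_up, f[i], k, rng))
            c_up = f[i]
        self.head = Conv2D(f[0], 1, k=1, rng=rng)
        self._f = f

    # -- plumbing -----------------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        out = []
        for blk in self.enc + self.dec:
            out.extend(blk.params)
        for att in self.atts:
            if att is not None:
                out.extend(att.params)
        out.extend(self.head.params)
        return out

    @property
    def grads(self) -> list[np.ndarray]:
        out = []
        for blk in self.enc + self.dec:
            out.extend(blk.grads)
        for att in self.atts:
            if att is not None:
                out.extend(att.grads)
        out.extend(self.head.grads)
        return out

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))

    def describe(self) -> dict:
        """Deterministic architecture summary (pure function of config)."""
        levels = len(self._f)
        layers = []
        for i, fo in enumerate(self._f):
            layers.append(f"enc{i}: 2x conv{self.config.conv_kernel} -> {fo}ch")
            if i < levels - 1:
                layers.append(f"pool{i}: max {self.config.pool_size}x{self.config.pool_size} /2")
        for i in range(levels - 2, -1, -1):
            gate = " +attention" if self.config.decoder_attention else ""
            layers.append(f"dec{i}: up x2{gate}, 2x conv -> {self._f[i]}ch")
        layers.append("head: conv1x1 -> 1ch (sigmoid)")
        return {
            "filters": list(self._f),
            "layers": layers,
            "n_params": self.n_params(),
            "down_factor": self.config.down_factor,
        }

    # -- forward / backward --------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 4:
            raise ValueError("expected NHWC input")
        d = self.config.down_factor
        if x.shape[1] % d or x.shape[2] % d:
            raise ValueError(
                f"spatial size {x.shape[1]}x{x.shape[2]} not divisible by {d}; pad first"
            )
        skips = []
        h = np.asarray(x, dtype=float)
        for i, blk in enumerate(self.enc):
            h = blk.forward(h, training)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h, training)
        self._skip_channels = [s.shape[-1] for s in skips]
        for i in range(len(self.dec) - 1, -1, -1):
            u = self.ups[i].forward(h, training)
            if self.atts[i] is not None:
                gated = self.atts[i].forward(skips[i], u, training)
            else:
                gated = skips[i]
            h = self.dec[i].forward(np.concatenate([gated, u], axis=-1), training)
        return self.head.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        d = self.head.backward(dlogits)
        dskips: list[np.ndarray | None] = [None] * len(self.dec)
        for i in range(len(self.dec)):
            d = self.dec[i].backward(d)
            cg = self._f[i]
            dgated, du = d[..., :cg], d[..., cg:]
            if self.atts[i] is not None:
                dx_skip, dg = self.atts[i].backward(dgated)
                dskips[i] = dx_skip
                d = self.ups[i].backward(dg + du)
            else:
                dskips[i] = dgated
                d = self.ups[i].backward(du)
        d = self.enc[-1].backward(d)
        for i in range(len(self.pools) - 1, -1, -1):
            d = self.pools[i].backward(d)
            d = d + dskips[i]
            d = self.enc[i].backward(d)
        return d

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward(x, training=False))


def build_unet_sam(config: UNetSAMConfig, in_channels: int = 3) -> UNetSAM:
    """Construct the attention U-Net; weights are a pure function of the seed."""
    return UNetSAM(config, in_channels=in_channels)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); two empty masks score 1.0."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def _pixel_metrics(prob: np.ndarray, truth: np.ndarray, threshold: float = 0.5) -> dict:
    pred = prob >= threshold
    t = truth.astype(bool)
    tp = int((pred & t).sum())
    fp = int((pred & ~t).sum())
    fn = int((~pred & t).sum())
    tn = int((~pred & ~t).sum())
    return {
        "dice": dice(pred, t),
        "accuracy": (tp + tn) / max(tp + tn + fp + fn, 1),
        "precision": tp / max(tp + fp, 1),
        "recall": tp / max(tp + fn, 1),
    }


def _pad_to_factor(x: np.ndarray, d: int) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = x.shape[1], x.shape[2]
    ph, pw = (-h) % d, (-w) % d
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, ph), (0, pw), (0, 0)), mode="reflect")
    return x, (h, w)


def _as_float_patches(patches: np.ndarray) -> np.ndarray:
    x = np.asarray(patches, dtype=float)
    if x.ndim == 3:
        x = x[..., None]
    if x.max() > 1.5:
        x = x / 255.0
    return x


def train_segmenter(
    config: UNetSAMConfig,
    patches: np.ndarray,
    masks: np.ndarray,
    validation_split: float = 0.2,
    k_folds: int | None = None,
) -> tuple[UNetSAM, list[dict]] | list[dict]:
    """Train the attention U-Net with BCE/Adam per the configured settings.

    Returns ``(model, history)`` where history holds one dict per epoch with
    training loss and validation loss/dice/accuracy/precision/recall.  With
    ``k_folds`` set, runs k-fold cross-validation instead and returns one
    report per fold (final validation metrics plus the fold's history).
    """
    x = _as_float_patches(patches)
    y = np.asarray(masks, dtype=float)
    if y.ndim == 3:
        y = y[..., None]
    y = (y > 0.5).astype(float)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(x) != len(y):
        raise ValueError("patches and masks differ in length")

    if k_folds is not None:
        rng = np.random.default_rng(config.seed)
        order = rng.permutation(len(x))
        folds = np.array_split(order, k_folds)
        reports = []
        for i, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(order, test_idx)
            model, history = train_segmenter(
                replace(config, seed=config.seed + i),
                x[train_idx],
                y[train_idx],
                validation_split=0.0,
            )
            prob = model.predict_proba(x[test_idx])
            reports.append(
                {
                    "fold": i,
                    "n_train": len(train_idx),
                    "n_test": len(test_idx),
                    "history": history,
                    **_pixel_metrics(prob, y[test_idx]),
                }
            )
        return reports

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(x))
    n_val = int(round(validation_split * len(x)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    model = build_unet_sam(config, in_channels=x.shape[-1])
    opt = make_optimizer(config.optimizer, config.learning_rate)
    history: list[dict] = []
    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start : start + config.batch_size]
            logits = model.forward(x[batch], training=True)
            loss, dlogits = sigmoid_bce_with_logits(logits, y[batch])
            model.backward(dlogits)
            opt.step(model.params, model.grads)
            losses.append(loss)
        row = {"epoch": epoch, "loss": float(np.mean(losses))}
        if len(val_idx):
            logits = model.forward(x[val_idx], training=False)
            val_loss, _ = sigmoid_bce_with_logits(logits, y[val_idx])
            row.update(val_loss=val_loss, **{f"val_{k}": v for k, v in _pixel_metrics(sigmoid(logits), y[val_idx]).items()})
        history.append(row)
    return model, history


def predict_mask(model: UNetSAM, patch: np.ndarray, threshold: float = 0.5) -> SegMask:
    """Probability map, thresholded mask and connected-component instances."""
    x = _as_float_patches(patch[None] if patch.ndim in (2, 3) else patch)
    x, (h, w) = _pad_to_factor(x, model.config.down_factor)
    prob = model.predict_proba(x)[0, :h, :w, 0]
    mask = prob >= threshold
    instances = measure.label(mask, connectivity=2)
    return SegMask(
        probability=prob,
        mask=mask,
        instances=instances,
        n_instances=int(instances.max()),
    )


def otsu_nuclei_mask(
    channel: np.ndarray, nuclei_bright: bool = True, min_area: int = 0
) -> SegMask:
    """Global Otsu threshold on a single channel; nuclei become foreground.

    ``nuclei_bright`` says whether nuclei have high values (a hematoxylin
    concentration map) or low values (a stain-removed grayscale image).
    A constant image yields an empty mask with a warning.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.ndim != 2:
        raise ValueError("expected a single-channel image")
    if np.ptp(channel) == 0:
        warnings.warn("constant image: no Otsu threshold exists; returning empty mask")
        mask = np.zeros(channel.shape, dtype=bool)
    else:
        t = threshold_otsu(channel)
        mask = channel > t if nuclei_bright else channel < t
    instances = measure.label(mask, connectivity=2)
    if min_area > 0 and instances.max() > 0:
        keep = np.flatnonzero(np.bincount(instances.ravel())[1:] >= min_area) + 1
        mask = np.isin(instances, keep)
        instances = measure.label(mask, connectivity=2)
    return SegMask(
        probability=mask.astype(float),
        mask=mask,
        instances=instances,
        n_instances=int(instances.max()),
    )
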