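"""Compact trainable encoder–decoder vessel segmenter and post-processing.

One configurable U-shaped convolutional network (implemented on numpy, see
:mod:`octfundus.nn`) stands in for the family of published vessel
segmenters whose I/O contract it honors: a square patch in, a same-size
per-pixel vessel probability out, with either a 1-channel sigmoid head or
a 2-channel softmax (vessel/non-vessel) head.  Optional weight-shared
refinement passes re-process the current probability map together with
the input patch, in the spirit of iterative refinery modules.

Training presets mirror the published per-network recipes (epochs, batch
size, optimizer family and learning rate, loss, patch budget and
train/validation split):

========  ======  =====  =========================  ====================  =======
preset    epochs  batch  optimizer                  loss                  split
========  ======  =====  =========================  ====================  =======
unet      50      32     SGD lr 1e-2, momentum 0    categorical CE        90/10
iternet   50      32     Adam lr 1e-3               binary CE             100/0
bcdu      20      8      Adam lr 1e-3               binary CE             80/20
saunet    100     8      Adam lr 1e-3               binary CE             80/20
frunet    40      24     Adam lr 1e-4               binary CE             90/10
========  ======  =====  =========================  ====================  =======

Post-processing: plain thresholding, dual-threshold iterative (DTI)
refinement realized as 8-connected hysteresis region growth, and a
classical shadowgraph baseline (Gaussian smoothing + global threshold).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import FundusImage, ProbabilityMap, ValidationError, VesselMask
from .nn import Adam, Conv2d, ConvBlock, MaxPool2, Param, SGD, Upsample2, sigmoid, softmax2
from .preprocessing import AugmentConfig, PatchSet, augment, stitch_predictions


class TrainingError(RuntimeError):
    """Raised when optimization diverges (non-finite loss)."""


TRAINING_PRESETS: dict[str, dict] = {
    "unet": dict(epochs=50, batch_size=32, optimizer="sgd", lr=1e-2, momentum=0.0,
                 loss="cce", out_channels=2, in_channels=1, val_split=0.10,
                 n_patches=20000, augment_preset="none"),
    "iternet": dict(epochs=50, batch_size=32, optimizer="adam", lr=1e-3,
                    loss="bce", out_channels=1, in_channels=3, val_split=0.0,
                    n_patches=2000, refine_iters=3, augment_preset="iternet"),
    "bcdu": dict(epochs=20, batch_size=8, optimizer="adam", lr=1e-3,
                 loss="bce", out_channels=1, in_channels=1, val_split=0.20,
                 n_patches=5000, augment_preset="none"),
    "saunet": dict(epochs=100, batch_size=8, optimizer="adam", lr=1e-3,
                   loss="bce", out_channels=1, in_channels=3, val_split=0.20,
                   n_patches=180, augment_preset="saunet"),
    "frunet": dict(epochs=40, batch_size=24, optimizer="adam", lr=1e-4,
                   loss="bce", out_channels=1, in_channels=1, val_split=0.10,
                   n_patches=5120, augment_preset="frunet"),
}


@dataclass
class ModelConfig:
    """Architecture + training hyperparameters of the segmenter."""

    depth: int = 3
    base_filters: int = 8
    in_channels: int = 1
    out_channels: int = 1
    refine_iters: int = 0
    epochs: int = 10
    batch_size: int = 32
    optimizer: str = "adam"
    lr: float = 1e-3
    momentum: float = 0.0
    beta1: float = 0.9
    beta2: float = 0.999
    loss: str = "bce"
    val_split: float = 0.1
    n_patches: int = 2000
    augment_preset: str = "none"
    preset: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValidationError("depth must be >= 2")
        if self.base_filters < 4:
            raise ValidationError("base filter count must be >= 4")
        if self.epochs < 1:
            raise ValidationError("epochs must be >= 1")
        if self.out_channels not in (1, 2):
            raise ValidationError("out_channels must be 1 or 2")
        if self.loss not in ("bce", "cce"):
            raise ValidationError("loss must be 'bce' or 'cce'")
        if self.refine_iters and self.out_channels != 1:
            raise ValidationError("refinement passes require a 1-channel head")
        if self.loss == "cce" and self.out_channels != 2:
            raise ValidationError("categorical cross-entropy requires a 2-channel head")

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "ModelConfig":
        if name not in TRAINING_PRESETS:
            raise ValidationError(f"unknown preset {name!r}; have {list(TRAINING_PRESETS)}")
        kw = dict(TRAINING_PRESETS[name])
        kw.update(overrides)
        kw.setdefault("preset", name)
        return cls(**kw)


@dataclass
class TrainingHistory:
    """Per-epoch loss and pixel accuracy for training and validation."""

    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def _share_conv(conv: Conv2d) -> Conv2d:
    """A cache-independent view of a convolution sharing its parameters."""
    new = copy.copy(conv)
    new._cols = None
    new._xshape = None
    return new


def _share_block(block: ConvBlock) -> ConvBlock:
    new = object.__new__(ConvBlock)
    new.c1 = _share_conv(block.c1)
    new.c2 = _share_conv(block.c2)
    from .nn import ReLU
    new.r1, new.r2 = ReLU(), ReLU()
    return new


class SegmentationModel:
    """U-shaped patch-to-probability segmenter; see module docstring."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        f = config.base_filters
        self.enc: list[ConvBlock] = []
        self.pools: list[MaxPool2] = []
        cin = config.in_channels
        for i in range(config.depth):
            self.enc.append(ConvBlock(cin, f * 2 ** i, rng))
            self.pools.append(MaxPool2())
            cin = f * 2 ** i
        self.bottleneck = ConvBlock(cin, f * 2 ** config.depth, rng)
        self.ups: list[Upsample2] = []
        self.dec: list[ConvBlock] = []
        for i in range(config.depth - 1, -1, -1):
            self.ups.append(Upsample2())
            skip_c = f * 2 ** i
            up_c = f * 2 ** (i + 1)
            self.dec.append(ConvBlock(skip_c + up_c, skip_c, rng))
        self.head = Conv2d(f, config.out_channels, 1, rng)
        if config.refine_iters > 0:
            self.refiner_block = ConvBlock(config.in_channels + 1, f, rng)
            self.refiner_head = Conv2d(f, 1, 1, rng)
        else:
            self.refiner_block = self.refiner_head = None

    # -- parameters ---------------------------------------------------------

    def params(self) -> list[Param]:
        ps: list[Param] = []
        for b in self.enc:
            ps += b.params()
        ps += self.bottleneck.params()
        for b in self.dec:
            ps += b.params()
        ps += self.head.params()
        if self.refiner_block is not None:
            ps += self.refiner_block.params() + self.refiner_head.params()
        return ps

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.value for i, p in enumerate(self.params())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value[...] = state[f"p{i}"]

    # -- forward / backward -------------------------------------------------

    def _check_size(self, H: int, W: int) -> None:
        d = 2 ** self.config.depth
        if H % d or W % d:
            raise ValidationError(
                f"patch size {H}x{W} not divisible by 2^depth = {d}"
            )

    def _forward_base(self, x: np.ndarray, train: bool) -> np.ndarray:
        skips = []
        h = x
        for block, pool in zip(self.enc, self.pools):
            h = block.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._concat_splits = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h, train)
            self._concat_splits.append(skip.shape[1])
            h = dec.forward(np.concatenate([skip, h], axis=1), train)
        return self.head.forward(h, train)  # logits (N, out, H, W)

    def _backward_base(self, dlogits: np.ndarray) -> None:
        dh = self.head.backward(dlogits)
        dskips = []
        for dec, up, split in zip(reversed(self.dec), reversed(self.ups),
                                  reversed(self._concat_splits)):
            dcat = dec.backward(dh)
            dskip, dup = dcat[:, :split], dcat[:, split:]
            dskips.append(dskip)
            dh = up.backward(dup)
        dh = self.bottleneck.backward(dh)
        for block, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                      reversed(dskips)):
            dh = pool.backward(dh)
            dh = block.backward(dh + dskip)

    def forward(self, x: np.ndarray, train: bool = False) -> dict:
        """Run the network on a batch ``(N, C, H, W)``.

        Returns a dict with ``prob`` (N, H, W) vessel probability, plus the
        intermediate tensors needed for the backward pass when training.
        """
        N, C, H, W = x.shape
        if C != self.config.in_channels:
            raise ValidationError(
                f"expected {self.config.in_channels} input channels, got {C}"
            )
        self._check_size(H, W)
        logits = self._forward_base(x, train)
        if self.config.out_channels == 2:
            probs2 = softmax2(logits)
            return {"prob": probs2[:, 1], "probs2": probs2, "logits": logits, "x": x}
        p = sigmoid(logits[:, 0])
        stages = [(logits, p)]
        refiners = []
        for _ in range(self.config.refine_iters):
            rb = _share_block(self.refiner_block)
            rh = _share_conv(self.refiner_head)
            inp = np.concatenate([x, p[:, None].astype(x.dtype)], axis=1)
            rl = rh.forward(rb.forward(inp, train), train)
            p = sigmoid(rl[:, 0])
            stages.append((rl, p))
            refiners.append((rb, rh))
        return {"prob": p, "stages": stages, "refiners": refiners, "x": x}

    def backward_from_prob_grad(self, fwd: dict, dloss_dlogit_final: np.ndarray) -> None:
        """Backpropagate given dL/d(final logits)."""
        if self.config.out_channels == 2:
            self._backward_base(dloss_dlogit_final)
            return
        dlogit = dloss_dlogit_final  # (N, 1, H, W)
        for (rb, rh), (_, p_prev) in zip(
            reversed(fwd["refiners"]), reversed(fwd["stages"][:-1])
        ):
            dinp = rb.backward(rh.backward(dlogit))
            dp_prev = dinp[:, -1]  # gradient w.r.t. the probability channel
            dlogit = (dp_prev * p_prev * (1.0 - p_prev))[:, None]
        self._backward_base(dlogit)

    def predict_patches(self, patches: np.ndarray, batch: int = 64) -> np.ndarray:
        """Vessel probabilities for a stack of patches (N, H, W) or (N, C, H, W)."""
        x = np.asarray(patches, dtype=np.float32)
        if x.ndim == 3:
            x = x[:, None]
        if x.shape[1] == 1 and self.config.in_channels == 3:
            x = np.repeat(x, 3, axis=1)
        out = np.empty((x.shape[0],) + x.shape[2:], dtype=np.float64)
        for i in range(0, x.shape[0], batch):
            out[i:i + batch] = self.forward(x[i:i + batch], train=False)["prob"]
        return out


def build_model(config: ModelConfig) -> SegmentationModel:
    """Construct a (deterministically initialized) segmentation model."""
    return SegmentationModel(config)


def _loss_and_grad(fwd: dict, targets: np.ndarray, loss: str) -> tuple[float, np.ndarray]:
    """Loss value and dL/d(final logits) for a batch; targets (N, H, W) in {0,1}."""
    t = targets.astype(np.float64)
    n = t.size
    eps = 1e-12
    if loss == "bce":
        p = fwd["prob"]
        value = -np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps))
        dlogit = ((p - t) / n)[:, None].astype(np.float32)
        return float(value), dlogit
    probs2 = fwd["probs2"]
    value = -np.mean(t * np.log(probs2[:, 1] + eps) + (1 - t) * np.log(probs2[:, 0] + eps))
    onehot = np.stack([1 - t, t], axis=1)
    dlogits = ((probs2 - onehot) / n).astype(np.float32)
    return float(value), dlogits


def _make_optimizer(model: SegmentationModel, config: ModelConfig):
    if config.optimizer == "sgd":
        return SGD(model.params(), lr=config.lr, momentum=config.momentum)
    if config.optimizer == "adam":
        return Adam(model.params(), lr=config.lr, beta1=config.beta1, beta2=config.beta2)
    raise ValidationError(f"unknown optimizer {config.optimizer!r}")


def _epoch_eval(model: SegmentationModel, images: np.ndarray, masks: np.ndarray,
                loss_name: str, batch: int = 64) -> tuple[float, float]:
    losses, accs, weights = [], [], []
    for i in range(0, len(images), batch):
        x = images[i:i + batch][:, None].astype(np.float32)
        if model.config.in_channels == 3:
            x = np.repeat(x, 3, axis=1)
        fwd = model.forward(x, train=False)
        value, _ = _loss_and_grad(fwd, masks[i:i + batch], loss_name)
        losses.append(value)
        accs.append(np.mean((fwd["prob"] >= 0.5) == masks[i:i + batch].astype(bool)))
        weights.append(len(x))
    w = np.asarray(weights, dtype=float)
    return float(np.average(losses, weights=w)), float(np.average(accs, weights=w))


def train(model: SegmentationModel, patchset: PatchSet,
          config: ModelConfig | None = None,
          augment_config: AugmentConfig | None = None) -> tuple[SegmentationModel, TrainingHistory]:
    """Train by mini-batch gradient descent on the configured loss.

    The patch set is split into training and validation parts according to
    ``config.val_split``; validation loss/accuracy are computed from the
    vessel probability channel.  Fully deterministic for fixed seeds.
    """
    config = config or model.config
    if len(patchset) == 0:
        raise ValidationError("empty patch set")
    if augment_config is None:
        augment_config = AugmentConfig(preset=config.augment_preset)
    rng = np.random.default_rng(config.seed + 1)
    n = len(patchset)
    order = rng.permutation(n)
    n_val = int(round(n * config.val_split))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValidationError("validation split leaves no training patches")
    imgs, msks = patchset.images, patchset.masks

    opt = _make_optimizer(model, config)
    history = TrainingHistory()
    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        ep_losses, ep_accs, ep_w = [], [], []
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i:i + config.batch_size]
            xb = np.empty((len(idx), patchset.size, patchset.size), dtype=np.float32)
            yb = np.empty((len(idx), patchset.size, patchset.size), dtype=np.uint8)
            for j, k in enumerate(idx):
                if augment_config.preset == "none":
                    xb[j], yb[j] = imgs[k], msks[k]
                else:
                    xi, yi = augment(imgs[k], msks[k], augment_config, rng)
                    xb[j], yb[j] = xi, yi
            x = xb[:, None]
            if config.in_channels == 3:
                x = np.repeat(x, 3, axis=1)
            fwd = model.forward(x, train=True)
            value, dlogits = _loss_and_grad(fwd, yb, config.loss)
            if not np.isfinite(value):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward_from_prob_grad(fwd, dlogits)
            opt.step()
            ep_losses.append(value)
            ep_accs.append(np.mean((fwd["prob"] >= 0.5) == yb.astype(bool)))
            ep_w.append(len(idx))
        w = np.asarray(ep_w, dtype=float)
        history.train_loss.append(float(np.average(ep_losses, weights=w)))
        history.train_accuracy.append(float(np.average(ep_accs, weights=w)))
        if len(val_idx):
            vl, va = _epoch_eval(model, imgs[val_idx], msks[val_idx], config.loss)
        else:
            vl, va = float("nan"), float("nan")
        history.val_loss.append(vl)
        history.val_accuracy.append(va)
    return model, history


def predict_image(model: SegmentationModel, image: FundusImage,
                  patch_size: int = 48, stride: int | None = None) -> ProbabilityMap:
    """Sliding-window inference stitched by per-pixel averaging."""
    stride = stride or patch_size // 2
    if stride > patch_size:
        raise ValidationError("stride must be <= patch size")
    px = image.pixels
    H, W = px.shape[:2]
    if patch_size > H or patch_size > W:
        raise ValidationError(f"patch size {patch_size} exceeds image {px.shape}")

    def starts(limit: int) -> list[int]:
        s = list(range(0, limit - patch_size + 1, stride))
        if s[-1] != limit - patch_size:
            s.append(limit - patch_size)
        return s

    coords = [(r, c) for r in starts(H) for c in starts(W)]
    patches = np.stack([px[r:r + patch_size, c:c + patch_size] for r, c in coords])
    probs = model.predict_patches(patches)
    return stitch_predictions(list(probs), np.array(coords), (H, W))


# -- thresholding and post-processing ---------------------------------------

_CONN8 = np.ones((3, 3), dtype=bool)


def binarize(prob: ProbabilityMap, threshold: float = 0.5) -> VesselMask:
    """Pixel = vessel iff probability >= threshold."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("threshold must lie in [0, 1]")
    return VesselMask((prob.pixels >= threshold).astype(np.uint8))


def dti_refine(prob: ProbabilityMap, high: float = 0.6, low: float = 0.3,
               max_iter: int = 100) -> VesselMask:
    """Dual-threshold iterative refinement (8-connected hysteresis growth).

    Seeds the mask at ``prob >= high`` and repeatedly annexes 8-connected
    neighbours with ``prob >= low`` until a fixpoint (or ``max_iter``).
    The result always nests between the high- and low-threshold masks.
    """
    if not (0.0 <= low < high <= 1.0):
        raise ValidationError(f"need 0 <= low < high <= 1, got low={low}, high={high}")
    p = prob.pixels
    grown = p >= high
    low_mask = p >= low
    for _ in range(max_iter):
        nxt = ndimage.binary_dilation(grown, structure=_CONN8) & low_mask
        if (nxt == grown).all():
            break
        grown = nxt
    return VesselMask(grown.astype(np.uint8))


def baseline_shadowgraph(image: FundusImage, sigma: float = 1.0,
                         method: str = "otsu", threshold: float = 0.5,
                         polarity: str = "dark") -> VesselMask:
    """Classical shadowgraph detector: Gaussian smoothing + global threshold.

    ``polarity='dark'`` marks pixels *below* threshold as vessels (the
    shadow convention of outer-retina projections); ``'bright'`` the
    opposite.  A constant image yields an empty mask.
    """
    if method not in ("otsu", "fixed"):
        raise ValidationError("threshold method must be 'otsu' or 'fixed'")
    if polarity not in ("dark", "bright"):
        raise ValidationError("polarity must be 'dark' or 'bright'")
    px = image.pixels
    smooth = ndimage.gaussian_filter(px, sigma) if sigma > 0 else px
    if smooth.max() == smooth.min():
        return VesselMask(np.zeros(px.shape, dtype=np.uint8))
    thr = threshold_otsu(smooth) if method == "otsu" else threshold
    mask = smooth < thr if polarity == "dark" else smooth > thr
    return VesselMask(mask.astype(np.uint8))


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(model: SegmentationModel, path: str | Path) -> None:
    """Write model weights + config echo as a single .npz archive."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __config__=np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    ), **model.state_dict())


def load_checkpoint(path: str | Path) -> SegmentationModel:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        model = SegmentationModel(ModelConfig(**cfg))
        model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
    return model
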