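"""The learned inverse model: an scSE-UNet that de-scatters patterned stacks.

Architecture: 9 convolution blocks — 4 encoder blocks, a bottleneck, and 4
decoder blocks — each block two [conv 3x3 -> batchnorm -> ReLU] layers; 2x2
max pooling between encoder blocks; bilinear 2x upsampling (plus a 1x1
channel-halving convolution) before each decoder block; skip connections
concatenate encoder features into the decoder.  Every decoder block is
followed by a concurrent spatial-and-channel squeeze-and-excitation (scSE)
gate: a channel gate (global average pool -> bottleneck MLP -> sigmoid) and a
spatial gate (1x1 conv -> sigmoid) recalibrate the features and are combined
by elementwise max.  A terminal conv + ReLU reconstruction block maps to one
non-negative output channel.

Four selectable training losses: MSE, RMSLE (on log1p of the images),
elementwise Smooth-L1 (Huber, quadratic below unit error), and KL divergence
between the images renormalized to probability maps.  Training uses Adam
with (lr, beta1, beta2, batch) = (1e-3, 0.9, 0.999, 10) for 100 epochs by
default, tracks validation loss / SSIM / PSNR per epoch, and keeps the
best-validation-loss parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np

from . import nn
from .io import get_logger, substream
from .metrics import psnr, ssim

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "ScSEUNet",
    "build_network",
    "loss_value",
    "loss_and_grad",
    "train",
    "reconstruct",
    "save_model",
    "load_model",
]

logger = get_logger(__name__)

LOSSES = ("mse", "rmsle", "smooth_l1", "kl")


@dataclass
class NetworkConfig:
    in_channels: int = 32
    base_width: int = 64
    depth_levels: int = 4
    scse_reduction: int = 2
    loss: str = "kl"
    include_pattern_channels: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if self.loss not in LOSSES:
            raise ValueError(f"loss must be one of {LOSSES}")
        if self.scse_reduction < 1:
            raise ValueError("scse_reduction must be >= 1")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    batch_size: int = 10
    epochs: int = 100
    seed: int = 0
    patience: int | None = None  # early stop after this many non-improving epochs

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class _ConvBlock(nn.Module):
    def __init__(self, c_in, c_out, rng):
        self.conv1 = nn.Conv2d(c_in, c_out, 3, rng, bias=False)
        self.bn1 = nn.BatchNorm2d(c_out)
        self.conv2 = nn.Conv2d(c_out, c_out, 3, rng, bias=False)
        self.bn2 = nn.BatchNorm2d(c_out)

    def __call__(self, x):
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


class _SCSE(nn.Module):
    """Concurrent channel and spatial squeeze-and-excitation, max-combined.

    With ``identity=True`` both gates are forced to 1, reducing the block to
    a pass-through (the vanilla-UNet ablation hook).
    """

    def __init__(self, channels, reduction, rng):
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)
        self.spatial = nn.Conv2d(channels, 1, 1, rng)
        self.identity = False

    def __call__(self, x):
        if self.identity:
            return x
        gate_c = nn.sigmoid(self.fc2(nn.relu(self.fc1(nn.global_avg_pool(x)))))
        cse = nn.scale_channels(x, gate_c)
        gate_s = nn.sigmoid(self.spatial(x))
        sse = nn.scale_spatial(x, gate_s)
        return nn.elementwise_max(cse, sse)


class ScSEUNet(nn.Module):
    """UNet encoder/decoder with scSE attention on the expanding path."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(substream(cfg.seed, "net-init"))
        w, L = cfg.base_width, cfg.depth_levels
        c_in = cfg.in_channels * (2 if cfg.include_pattern_channels else 1)
        widths = [w * 2 ** i for i in range(L)]

        self.encoders = []
        c = c_in
        for wi in widths:
            self.encoders.append(_ConvBlock(c, wi, rng))
            c = wi
        self.bottleneck = _ConvBlock(c, c * 2, rng)
        c = c * 2
        self.up_convs = []
        self.decoders = []
        self.scse = []
        for wi in reversed(widths):
            self.up_convs.append(nn.Conv2d(c, wi, 1, rng))
            self.decoders.append(_ConvBlock(wi * 2, wi, rng))
            self.scse.append(_SCSE(wi, cfg.scse_reduction, rng))
            c = wi
        self.final = nn.Conv2d(c, 1, 3, rng)
        self.training = True

    # -- plumbing -----------------------------------------------------------
    @property
    def n_blocks(self) -> int:
        return len(self.encoders) + 1 + len(self.decoders)

    def param_count(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def set_scse_identity(self, flag: bool) -> None:
        for block in self.scse:
            block.identity = flag

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4:
            raise ValueError("input must be (N, C, H, W)")
        c_expected = self.cfg.in_channels * (2 if self.cfg.include_pattern_channels else 1)
        if x.shape[1] != c_expected:
            raise ValueError(
                f"input has {x.shape[1]} channels, model expects {c_expected}"
            )
        div = 2 ** self.cfg.depth_levels
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input H and W must be divisible by 2^{self.cfg.depth_levels} = {div}; "
                f"got {x.shape[2]}x{x.shape[3]} — pad or crop the stacks"
            )

    # -- forward ------------------------------------------------------------
    def __call__(self, x: np.ndarray | nn.Tensor) -> nn.Tensor:
        if not isinstance(x, nn.Tensor):
            self._check_input(np.asarray(x))
            x = nn.Tensor(x)
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = nn.maxpool2(h)
        h = self.bottleneck(h)
        for up, dec, att, skip in zip(self.up_convs, self.decoders, self.scse, reversed(skips)):
            h = up(nn.upsample_bilinear2(h))
            h = dec(nn.concat_channels(skip, h))
            h = att(h)
        return nn.relu(self.final(h))

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference-mode forward pass returning a plain array (N, 1, H, W)."""
        was_training = self.training
        self.set_training(False)
        out = self(np.asarray(x, dtype=np.float32)).data
        self.set_training(was_training)
        return out


def build_network(cfg: NetworkConfig) -> ScSEUNet:
    return ScSEUNet(cfg)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

_EPS_KL = 1e-8


def loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str):
    """Loss value and its gradient with respect to ``pred``.

    Shapes must match.  KL renormalizes each image (last two axes) of both
    prediction and target to a probability map after an epsilon shift; RMSLE
    operates on log(1 + x) of zero-clipped images.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("pred and target must have the same shape")
    n = pred.size
    if kind == "mse":
        d = pred - target
        return float(np.mean(d * d)), (2.0 * d / n)
    if kind == "smooth_l1":
        d = pred - target
        a = np.abs(d)
        quad = a < 1.0
        value = float(np.mean(np.where(quad, 0.5 * d * d, a - 0.5)))
        return value, np.clip(d, -1.0, 1.0) / n
    if kind == "rmsle":
        p = np.clip(pred, 0.0, None)
        t = np.clip(target, 0.0, None)
        d = np.log1p(p) - np.log1p(t)
        msle = float(np.mean(d * d))
        value = float(np.sqrt(msle))
        if value == 0.0:
            return 0.0, np.zeros_like(pred)
        # clip treated as identity (network output is >= 0)
        grad = d / ((1.0 + p) * n * value)
        return value, grad
    if kind == "kl":
        # per-image probability maps over the spatial axes
        axes = tuple(range(pred.ndim - 2, pred.ndim))
        q_raw = np.clip(pred, 0.0, None) + _EPS_KL
        p_raw = np.clip(target, 0.0, None) + _EPS_KL
        Q = q_raw.sum(axis=axes, keepdims=True)
        P = p_raw.sum(axis=axes, keepdims=True)
        q = q_raw / Q
        p = p_raw / P
        n_images = int(np.prod(pred.shape[:-2])) if pred.ndim > 2 else 1
        value = float((p * np.log(p / q)).sum() / n_images)
        # d/dpred of sum_i p_i log(p_i / q_i) with q = (pred + eps)/Q; the
        # clip at zero is treated as identity (the network output is >= 0)
        grad = (-p / q_raw + 1.0 / Q) / n_images
        return value, grad
    raise ValueError(f"unknown loss kind {kind!r}")


def loss_value(pred: np.ndarray, target: np.ndarray, kind: str) -> float:
    """Scalar loss of one of the four training criteria."""
    return loss_and_grad(pred, target, kind)[0]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _epoch_metrics(net: ScSEUNet, X: np.ndarray, Y: np.ndarray, kind: str,
                   batch: int = 10):
    losses, ssims, psnrs = [], [], []
    for i in range(0, len(X), batch):
        pred = net.predict(X[i:i + batch])
        tgt = Y[i:i + batch]
        losses.append(loss_value(pred, tgt, kind) * len(pred))
        for p, t in zip(pred[:, 0], tgt[:, 0]):
            rng_val = float(t.max()) or 1.0
            ssims.append(ssim(t, p, data_range=rng_val))
            psnrs.append(psnr(t, p, data_range=rng_val))
    n = max(len(X), 1)
    finite_psnrs = [v for v in psnrs if np.isfinite(v)]
    return (
        float(np.sum(losses) / n),
        float(np.mean(ssims)) if ssims else float("nan"),
        float(np.mean(finite_psnrs)) if finite_psnrs else float("inf"),
    )


def train(
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    net_cfg: NetworkConfig,
    train_cfg: TrainConfig | None = None,
    net: ScSEUNet | None = None,
) -> tuple[ScSEUNet, list[dict]]:
    """Train the inverse model; returns (best model, per-epoch history).

    ``train_data``/``val_data`` are (X, Y) arrays of shape (n, T, H, W) and
    (n, 1, H, W) as produced by :func:`deeptfm.forward.load_dataset`.  Fully
    seeded: the parameter initialization comes from ``net_cfg.seed`` and the
    batch shuffling from ``train_cfg.seed``.  Divergence (non-finite loss)
    aborts with a diagnostic.
    """
    train_cfg = train_cfg or TrainConfig()
    Xtr, Ytr = train_data
    Xva, Yva = val_data
    if len(Xva) == 0:
        raise ValueError("validation split must be non-empty")
    net = net or build_network(net_cfg)
    opt = nn.Adam(net.parameters(), lr=train_cfg.lr,
                  beta1=train_cfg.beta1, beta2=train_cfg.beta2)
    rng = np.random.default_rng(substream(train_cfg.seed, "train-shuffle"))
    history: list[dict] = []
    best_val = np.inf
    best_params = [p.data.copy() for p in net.parameters()]
    stale = 0
    for epoch in range(train_cfg.epochs):
        net.set_training(True)
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for i in range(0, len(order), train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            opt.zero_grad()
            out = net(Xtr[idx])
            value, grad = loss_and_grad(out.data, Ytr[idx], net_cfg.loss)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss = {value}"
                )
            out.backward(grad.astype(np.float32))
            opt.step()
            epoch_loss += value * len(idx)
        train_loss = epoch_loss / max(len(Xtr), 1)
        val_loss, val_ssim, val_psnr = _epoch_metrics(
            net, Xva, Yva, net_cfg.loss, train_cfg.batch_size
        )
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "val_loss": val_loss,
                "val_ssim": val_ssim,
                "val_psnr": val_psnr,
            }
        )
        logger.info(
            "epoch %d: train %s=%.5g val=%.5g ssim=%.4f psnr=%.2f",
            epoch, net_cfg.loss, train_loss, val_loss, val_ssim, val_psnr,
        )
        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.data.copy() for p in net.parameters()]
            stale = 0
        else:
            stale += 1
            if train_cfg.patience is not None and stale > train_cfg.patience:
                logger.info("early stop at epoch %d", epoch)
                break
    for p, best in zip(net.parameters(), best_params):
        p.data = best
    net.set_training(False)
    return net, history


def reconstruct(
    net: ScSEUNet,
    measurements: np.ndarray,
    normalize: bool = True,
    percentile: float = 99.9,
) -> tuple[np.ndarray, float]:
    """De-scatter one measurement stack (T, H, W).

    Applies the same per-stack normalization used to build training data
    (division by the stack's high percentile) unless the stack is already
    normalized, runs the network, and returns (image, norm_factor): multiply
    the image by ``norm_factor`` to return to input units.
    """
    m = np.asarray(measurements, dtype=np.float32)
    if m.ndim != 3:
        raise ValueError("measurement stack must be (T, H, W)")
    factor = 1.0
    if normalize:
        factor = float(np.percentile(m, percentile))
        if factor <= 0:
            factor = 1.0
        m = m / factor
    out = net.predict(m[None])[0, 0]
    return out, factor


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_model(path: str | Path, net: ScSEUNet, extra: dict | None = None) -> Path:
    """Save parameters + running stats (npz) and the config (json sidecar)."""
    path = Path(path)
    arrays: dict[str, np.ndarray] = {}
    for i, p in enumerate(net.parameters()):
        arrays[f"param_{i}"] = p.data
    for i, bn in enumerate(_iter_batchnorms(net)):
        arrays[f"bn_mean_{i}"] = bn.running_mean
        arrays[f"bn_var_{i}"] = bn.running_var
    np.savez(path.with_suffix(".npz"), **arrays)
    meta = {"config": asdict(net.cfg), "extra": extra or {}}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path.with_suffix(".npz")


def load_model(path: str | Path) -> tuple[ScSEUNet, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg = NetworkConfig(**meta["config"])
    net = build_network(cfg)
    data = np.load(path.with_suffix(".npz"))
    for i, p in enumerate(net.parameters()):
        p.data = data[f"param_{i}"].astype(np.float32)
    for i, bn in enumerate(_iter_batchnorms(net)):
        bn.running_mean = data[f"bn_mean_{i}"].astype(np.float32)
        bn.running_var = data[f"bn_var_{i}"].astype(np.float32)
    net.set_training(False)
    return net, meta.get("extra", {})


def _iter_batchnorms(module: nn.Module):
    for value in module.__dict__.values():
        if isinstance(value, nn.BatchNorm2d):
            yield value
        elif isinstance(value, nn.Module):
            yield from _iter_batchnorms(value)
        elif isinstance(value, (list, tuple)):
            for item in value:
                if isinstance(item, nn.Module):
                    yield from _iter_batchnorms(item)
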