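"""1D-UNet for binary semantic segmentation of orientation signals.

The network maps a (batch, 3, L) window of head-orientation samples to a
(batch, 1, L) track of movement probabilities.  Architecture: an encoder of
five blocks (two kernel-9 'same' convolutions, each followed by batch
normalisation and ReLU, then a size-2 max-pool), a two-convolution
bottleneck, and a mirrored decoder of five blocks (x2 upsampling,
concatenation with the matching encoder features, two convolutions with
batch norm and ReLU), closed by a kernel-1 convolution to one channel and a
sigmoid.  Level widths default to 16/32/64/128/256; five pools mean the
window length must be divisible by 32.

Weights use Kaiming initialisation where a ReLU follows and Xavier for the
sigmoid head, drawn from a seeded generator so builds are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np

from .errors import ConfigurationError, ShapeError
from .nn import (
    Adadelta,  # noqa: F401  (re-exported for training code)
    BatchNorm1d,
    Conv1d,
    ConvTranspose1d2x,
    MaxPool1d,
    Param,
    ReLU,
    Sigmoid,
    UpsampleNearest2,
)

_CHECKPOINT_VERSION = 1
_PROB_EPS = 1e-7


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``conv_padding`` must equal ``(conv_kernel - 1) / 2`` so convolutions
    preserve length; ``level_channels`` are the five encoder widths, and the
    bottleneck doubles the deepest width.
    """

    in_channels: int = 3
    level_channels: tuple[int, ...] = (16, 32, 64, 128, 256)
    conv_kernel: int = 9
    conv_stride: int = 1
    conv_padding: int = 4
    pool_size: int = 2
    out_channels: int = 1
    upsample_mode: str = "fixed_upsample"

    def __post_init__(self) -> None:
        if self.conv_kernel % 2 != 1 or self.conv_padding != (self.conv_kernel - 1) // 2:
            raise ConfigurationError(
                f"conv_padding must be (conv_kernel-1)/2 = {(self.conv_kernel - 1) // 2} "
                f"to preserve length, got {self.conv_padding}"
            )
        if self.conv_stride != 1:
            raise ConfigurationError("only stride-1 convolutions are supported")
        if self.pool_size != 2:
            raise ConfigurationError("only pool size 2 is supported")
        if len(self.level_channels) != 5:
            raise ConfigurationError(f"exactly 5 encoder levels required, got {len(self.level_channels)}")
        if any(a >= b for a, b in zip(self.level_channels, self.level_channels[1:])):
            raise ConfigurationError(f"level_channels must be strictly increasing: {self.level_channels}")
        if self.out_channels != 1:
            raise ConfigurationError("binary segmentation requires out_channels = 1")
        if self.upsample_mode not in ("fixed_upsample", "transposed_conv"):
            raise ConfigurationError(f"unknown upsample_mode {self.upsample_mode!r}")

    @property
    def length_divisor(self) -> int:
        """Input windows must be a multiple of this (2^5 = 32)."""
        return self.pool_size ** len(self.level_channels)

    @property
    def bottleneck_channels(self) -> int:
        return 2 * self.level_channels[-1]


def dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1e-6) -> float:
    """Soft dice loss: 1 - (2*sum(p*t) + s) / (sum(p) + sum(t) + s).

    Lies in [0, 1) for ``smooth > 0``; 0 at perfect overlap, approaching 1 at
    a total miss.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ShapeError(f"pred shape {pred.shape} != target shape {target.shape}")
    num = 2.0 * float((pred * target).sum()) + smooth
    den = float(pred.sum()) + float(target.sum()) + smooth
    if den == 0.0:
        return 0.0  # both empty, smooth 0: treat as perfect agreement
    return 1.0 - num / den


def dice_loss_grad(
    pred: np.ndarray, target: np.ndarray, smooth: float = 1e-6
) -> tuple[float, np.ndarray]:
    """Dice loss and its gradient with respect to ``pred``."""
    if pred.shape != target.shape:
        raise ShapeError(f"pred shape {pred.shape} != target shape {target.shape}")
    num = 2.0 * (pred * target).sum() + smooth
    den = pred.sum() + target.sum() + smooth
    loss = 1.0 - num / den
    grad = (num - 2.0 * target * den) / den**2
    return float(loss), grad.astype(pred.dtype)


class UNet1D:
    """The segmentation model: parameter state plus its :class:`UNetConfig`.

    Calling the model runs inference (batch norm in evaluation mode, outputs
    clipped into the open interval (0, 1)); training code uses
    :meth:`forward` / :meth:`backward` directly.
    """

    def __init__(self, cfg: UNetConfig, seed: int = 0, dtype=np.float32) -> None:
        self.cfg = cfg
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        k, p = cfg.conv_kernel, cfg.conv_padding
        ch = cfg.level_channels
        mk = lambda cin, cout: _ConvBlock(cin, cout, k, p, rng, dtype)  # noqa: E731

        enc_in = (cfg.in_channels,) + ch[:-1]
        self.enc = [(mk(enc_in[i], ch[i]), mk(ch[i], ch[i]), MaxPool1d()) for i in range(5)]
        bch = cfg.bottleneck_channels
        self.bottleneck = (mk(ch[-1], bch), mk(bch, bch))
        up_ch = (bch,) + tuple(reversed(ch))[:-1]  # input widths to each upsample
        dec_out = tuple(reversed(ch))
        self.ups = []
        self.dec = []
        for i in range(5):
            if cfg.upsample_mode == "transposed_conv":
                self.ups.append(ConvTranspose1d2x(up_ch[i], rng, dtype))
            else:
                self.ups.append(UpsampleNearest2())
            skip_ch = ch[4 - i]
            cat_ch = skip_ch + up_ch[i]
            self.dec.append((mk(cat_ch, dec_out[i]), mk(dec_out[i], dec_out[i])))
        self.head = Conv1d(ch[0], 1, 1, 0, rng, init="xavier", dtype=dtype)
        self.sigmoid = Sigmoid()
        self._skip_ch = tuple(ch[4 - i] for i in range(5))

    # -- parameter plumbing -------------------------------------------------
    @property
    def in_channels(self) -> int:
        return self.cfg.in_channels

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for c1, c2, _ in self.enc:
            out += c1.params + c2.params
        out += self.bottleneck[0].params + self.bottleneck[1].params
        for up, (c1, c2) in zip(self.ups, self.dec):
            out += getattr(up, "params", []) + c1.params + c2.params
        out += self.head.params
        return out

    def _batchnorms(self) -> list[BatchNorm1d]:
        bns = []
        for c1, c2, _ in self.enc:
            bns += [c1.bn, c2.bn]
        bns += [self.bottleneck[0].bn, self.bottleneck[1].bn]
        for c1, c2 in self.dec:
            bns += [c1.bn, c2.bn]
        return bns

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 3 or x.shape[1] != self.cfg.in_channels:
            raise ShapeError(
                f"expected input of shape (B, {self.cfg.in_channels}, L), got {x.shape}"
            )
        d = self.cfg.length_divisor
        if x.shape[2] % d != 0 or x.shape[2] == 0:
            raise ShapeError(
                f"window length {x.shape[2]} must be a positive multiple of {d} "
                f"(five size-{self.cfg.pool_size} poolings)"
            )

    def forward(
        self, x: np.ndarray, training: bool = True, drop_skip: int | None = None
    ) -> np.ndarray:
        """Movement probabilities of shape (B, 1, L), strictly inside (0, 1).

        ``drop_skip`` zeroes the contribution of encoder level ``i``'s skip
        connection; used by ablation tests only.
        """
        self._check_input(x)
        h = np.ascontiguousarray(x, dtype=self.dtype)
        skips = []
        for c1, c2, pool in self.enc:
            h = c2.forward(c1.forward(h, training), training)
            skips.append(h)
            h = pool.forward(h, training)
        h = self.bottleneck[1].forward(self.bottleneck[0].forward(h, training), training)
        for i, (up, (c1, c2)) in enumerate(zip(self.ups, self.dec)):
            h = up.forward(h, training)
            skip = skips[4 - i]
            if drop_skip == 4 - i:
                skip = np.zeros_like(skip)
            h = np.concatenate([skip, h], axis=1)
            h = c2.forward(c1.forward(h, training), training)
        probs = self.sigmoid.forward(self.head.forward(h, training), training)
        return np.clip(probs, _PROB_EPS, 1.0 - _PROB_EPS)

    def backward(self, dprobs: np.ndarray) -> np.ndarray:
        """Backpropagate through the whole network; accumulates parameter grads."""
        dh = self.head.backward(self.sigmoid.backward(dprobs.astype(self.dtype)))
        pending: dict[int, np.ndarray] = {}
        for i in range(4, -1, -1):
            up, (c1, c2) = self.ups[i], self.dec[i]
            dcat = c1.backward(c2.backward(dh))
            s = self._skip_ch[i]
            pending[4 - i] = dcat[:, :s]
            dh = up.backward(np.ascontiguousarray(dcat[:, s:]))
        dh = self.bottleneck[0].backward(self.bottleneck[1].backward(dh))
        for j in range(4, -1, -1):
            c1, c2, pool = self.enc[j]
            dh = pool.backward(dh) + pending[j]
            dh = c1.backward(c2.backward(dh))
        return dh

    def __call__(self, x: np.ndarray) -> np.ndarray:
        """Inference: evaluation-mode forward pass."""
        return self.forward(x, training=False)

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p.data for p in self.parameters()]
        for bn in self._batchnorms():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def load_state_arrays(self, arrs: list[np.ndarray]) -> None:
        params = self.parameters()
        n = len(params)
        if len(arrs) != n + 2 * len(self._batchnorms()):
            raise ConfigurationError("checkpoint parameter count does not match architecture")
        for p, a in zip(params, arrs[:n]):
            if p.data.shape != a.shape:
                raise ConfigurationError(
                    f"checkpoint shape {a.shape} does not match parameter shape {p.data.shape}"
                )
            p.data = a.astype(self.dtype)
            p.grad = np.zeros_like(p.data)
        rest = arrs[n:]
        for bn, mean, var in zip(self._batchnorms(), rest[0::2], rest[1::2]):
            bn.running_mean = mean.astype(self.dtype)
            bn.running_var = var.astype(self.dtype)


class _ConvBlock:
    """conv -> batchnorm -> ReLU, the repeated unit of every level."""

    def __init__(self, cin: int, cout: int, k: int, pad: int, rng, dtype) -> None:
        self.conv = Conv1d(cin, cout, k, pad, rng, init="kaiming", dtype=dtype)
        self.bn = BatchNorm1d(cout, dtype=dtype)
        self.relu = ReLU()

    @property
    def params(self) -> list[Param]:
        return self.conv.params + self.bn.params

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        return self.relu.forward(self.bn.forward(self.conv.forward(x, training), training), training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))


def build_model(cfg: UNetConfig | None = None, seed: int = 0, dtype=np.float32) -> UNet1D:
    """Construct a seeded, reproducibly initialised model."""
    return UNet1D(cfg or UNetConfig(), seed=seed, dtype=dtype)


@dataclass
class CheckpointMeta:
    """Training provenance stored inside a checkpoint."""

    seed: int | None = None
    epochs: int | None = None
    loss_history: list[float] = field(default_factory=list)
    normalized_input: bool = True
    extra: dict = field(default_factory=dict)


def save_checkpoint(model: UNet1D, path, meta: CheckpointMeta | None = None) -> None:
    """Write a single-file checkpoint: config + weights + training metadata."""
    meta = meta or CheckpointMeta()
    header = {
        "format_version": _CHECKPOINT_VERSION,
        "config": {**asdict(model.cfg), "level_channels": list(model.cfg.level_channels)},
        "meta": asdict(meta),
    }
    arrays = {f"arr_{i:04d}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path, dtype=np.float32) -> tuple[UNet1D, CheckpointMeta]:
    """Version-checked checkpoint reader; rebuilds the model from its config."""
    with np.load(path) as data:
        header = json.loads(bytes(data["header"]).decode())
        if header.get("format_version") != _CHECKPOINT_VERSION:
            raise ConfigurationError(
                f"unsupported checkpoint version {header.get('format_version')}"
            )
        cfg_d = dict(header["config"])
        cfg_d["level_channels"] = tuple(cfg_d["level_channels"])
        cfg = UNetConfig(**cfg_d)
        model = UNet1D(cfg, seed=0, dtype=dtype)
        arrs = [data[k] for k in sorted(k for k in data.files if k.startswith("arr_"))]
        model.load_state_arrays(arrs)
    meta = CheckpointMeta(**header["meta"])
    return model, meta
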