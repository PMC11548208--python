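"""Training loop: windowing, dice-loss optimisation with Adadelta.

The reference recipe is Adadelta at learning rate 0.1, dice loss, batch size
64, 1000 epochs.  Full-scale training on real cohorts uses those defaults;
the synthetic experiments in this package run reduced presets (fewer epochs,
a subsample of windows per session) chosen for the easier synthetic task —
see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, EmptyInputError
from .pose import normalize_signal
from .synth import SessionRecord
from .unet import UNet1D, Adadelta, dice_loss_grad

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the reference recipe)."""

    optimizer: str = "adadelta"
    learning_rate: float = 0.1
    batch_size: int = 64
    epochs: int = 1000
    loss: str = "dice"
    seed: int = 0
    window_len: int = 320
    window_overlap: float = 0.5
    windows_per_session: int | None = None
    normalize: bool = True
    dice_smooth: float = 1e-6
    device: str = "cpu"

    def __post_init__(self) -> None:
        if self.optimizer != "adadelta":
            raise ConfigurationError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "dice":
            raise ConfigurationError(f"unsupported loss {self.loss!r}")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.window_len % 32 != 0 or self.window_len <= 0:
            raise ConfigurationError(
                f"window_len must be a positive multiple of 32, got {self.window_len}"
            )
        if not 0.0 <= self.window_overlap < 1.0:
            raise ConfigurationError("window_overlap must lie in [0, 1)")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")


def session_windows(
    session: SessionRecord,
    window_len: int,
    overlap: float = 0.5,
    normalize: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Tile one session into training windows.

    Returns ``(x, y)`` with x of shape (n, 3, window_len) and y of shape
    (n, 1, window_len); the final window is aligned to the session end so no
    samples are dropped.  ``normalize`` applies the robust per-session
    standardisation also used at inference.
    """
    sig = normalize_signal(session.signal)[0] if normalize else session.signal
    values = sig.values.T.astype(np.float32)  # (3, T)
    mask = session.mask.astype(np.float32)
    t = values.shape[1]
    if t < window_len:
        raise EmptyInputError(
            f"session {session.participant_id} ({t} samples) is shorter than one "
            f"window ({window_len}); use predict-style padding instead"
        )
    step = max(1, int(round(window_len * (1.0 - overlap))))
    starts = list(range(0, t - window_len + 1, step))
    if starts[-1] != t - window_len:
        starts.append(t - window_len)
    x = np.stack([values[:, s:s + window_len] for s in starts])
    y = np.stack([mask[None, s:s + window_len] for s in starts])
    return x, y


def cohort_windows(
    sessions: list[SessionRecord],
    cfg: TrainConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Windows for a whole cohort, optionally subsampled per session.

    With ``cfg.windows_per_session`` set, that many windows are drawn per
    session without replacement (seeded), trading training-set size for time.
    """
    if not sessions:
        raise EmptyInputError("no training sessions given")
    rng = rng or np.random.default_rng(cfg.seed)
    xs, ys = [], []
    for session in sessions:
        x, y = session_windows(session, cfg.window_len, cfg.window_overlap, cfg.normalize)
        if cfg.windows_per_session is not None and cfg.windows_per_session < len(x):
            keep = np.sort(rng.choice(len(x), cfg.windows_per_session, replace=False))
            x, y = x[keep], y[keep]
        xs.append(x)
        ys.append(y)
    return np.concatenate(xs), np.concatenate(ys)


@dataclass
class TrainResult:
    """Per-epoch mean dice loss plus its running minimum (monotone envelope)."""

    loss_history: list[float] = field(default_factory=list)

    @property
    def smoothed(self) -> np.ndarray:
        return np.minimum.accumulate(np.asarray(self.loss_history))

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]


def train_on_windows(
    model: UNet1D, x: np.ndarray, y: np.ndarray, cfg: TrainConfig
) -> TrainResult:
    """Optimise ``model`` in place on pre-built windows; returns loss history.

    Epoch shuffling is driven by ``cfg.seed`` so identical inputs and seed
    give identical histories (single-threaded determinism).
    """
    if len(x) == 0:
        raise EmptyInputError("empty training set")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adadelta(model.parameters(), lr=cfg.learning_rate)
    result = TrainResult()
    n = len(x)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            probs = model.forward(x[idx], training=True)
            loss, grad = dice_loss_grad(probs, y[idx], cfg.dice_smooth)
            model.backward(grad)
            opt.step()
            opt.zero_grad()
            losses.append(loss)
        result.loss_history.append(float(np.mean(losses)))
        if epoch % 10 == 0 or epoch == cfg.epochs - 1:
            logger.info("epoch %d/%d dice loss %.4f", epoch + 1, cfg.epochs, result.loss_history[-1])
    return result


def train(
    model: UNet1D, sessions: list[SessionRecord], cfg: TrainConfig | None = None
) -> tuple[UNet1D, TrainResult]:
    """Train on a cohort of annotated sessions (windowing included)."""
    cfg = cfg or TrainConfig()
    x, y = cohort_windows(sessions, cfg)
    logger.info(
        "training on %d windows of %d samples from %d sessions",
        len(x), cfg.window_len, len(sessions),
    )
    result = train_on_windows(model, x, y, cfg)
    return model, result
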