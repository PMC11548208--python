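"""Head-orientation signals and the pluggable pose-estimation backend.

A session video is reduced, frame by frame, to three head-rotation angles
(pitch-like up/down, yaw-like left/right, roll-like lateral bend), giving a
3-channel time series sampled at the camera frame rate.  The package never
decodes video itself: any per-frame pose estimator (e.g. a pre-trained 3D
face-alignment network) can be plugged in through :class:`PoseBackend`, and
everything downstream sees only the resulting :class:`OrientationSignal`.

Failed frames (no face detected, estimator exception) are kept in place as
invalid samples so video time and annotation time stay aligned; short gaps are
repaired by interpolation, long ones stay flagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Protocol, runtime_checkable

import numpy as np

from .errors import DataError, EmptyInputError, ShapeError

logger = logging.getLogger(__name__)

#: Channel order of every orientation signal: rotation axes named after the
#: instructed movement axes (up/down ~ pitch, left/right ~ yaw, bend ~ roll).
AXES: tuple[str, str, str] = ("updown", "leftright", "bend")

#: Physical plausibility bound for head rotation, degrees.
MAX_ANGLE_DEG = 90.0


@dataclass
class OrientationSignal:
    """3-channel head-orientation time series in degrees.

    Parameters
    ----------
    values
        Array of shape (T, 3), one row per frame, columns ordered as
        :data:`AXES`, in degrees.
    fs
        Sampling rate in Hz (the camera frame rate).
    valid
        Boolean array of shape (T,); False where the pose estimate failed.
    t0
        Offset of the first sample from session start, seconds.
    """

    values: np.ndarray
    fs: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ShapeError(
                f"orientation values must have shape (T, 3), got {self.values.shape}"
            )
        if self.fs <= 0:
            raise DataError(f"sampling rate must be positive, got {self.fs}")
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (len(self.values),):
            raise ShapeError(
                f"valid has shape {self.valid.shape}, expected ({len(self.values)},)"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return len(self.values) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds from session start."""
        return self.t0 + np.arange(len(self.values)) / self.fs

    def copy(self) -> "OrientationSignal":
        return OrientationSignal(self.values.copy(), self.fs, self.valid.copy(), self.t0)


@runtime_checkable
class PoseBackend(Protocol):
    """Contract for per-frame head-pose estimators.

    Implementations must be stateless across frames (or document otherwise)
    and return finite angles when they succeed.
    """

    def estimate(self, frame) -> tuple[float, float, float] | None:
        """Return (updown, leftright, bend) in degrees, or None on failure."""
        ...


def extract_signal(
    frames: Iterable,
    backend: PoseBackend,
    fs: float,
    channel_order: tuple[str, str, str] = AXES,
) -> OrientationSignal:
    """Run a pose backend over an ordered frame source.

    One output sample per input frame, in order.  A frame on which the backend
    returns ``None`` or raises is marked invalid (values NaN) and processing
    continues; the failure count is logged.  Use :func:`clean_signal` to repair
    the gaps before segmentation.

    ``channel_order`` names the axes of the backend's output triple (Euler
    conventions differ between estimators); columns are reordered to the
    package convention :data:`AXES`.

    Raises
    ------
    EmptyInputError
        If the frame source yields no frames.
    """
    if sorted(channel_order) != sorted(AXES):
        raise DataError(f"channel_order must be a permutation of {AXES}")
    perm = [channel_order.index(a) for a in AXES]
    rows: list[tuple[float, float, float]] = []
    valid: list[bool] = []
    n_failed = 0
    for frame in frames:
        try:
            est = backend.estimate(frame)
        except Exception:  # noqa: BLE001 - backend failures degrade to invalid samples
            est = None
        if est is None or not np.all(np.isfinite(est)):
            rows.append((np.nan, np.nan, np.nan))
            valid.append(False)
            n_failed += 1
        else:
            rows.append((float(est[0]), float(est[1]), float(est[2])))
            valid.append(True)
    if not rows:
        raise EmptyInputError("frame source yielded no frames")
    if n_failed:
        logger.warning("pose backend failed on %d of %d frames", n_failed, len(rows))
    return OrientationSignal(np.array(rows)[:, perm], fs, np.array(valid))


def clean_signal(sig: OrientationSignal, max_gap_s: float = 0.5) -> OrientationSignal:
    """Repair invalid samples by interpolation.

    Invalid runs no longer than ``max_gap_s`` are linearly interpolated from
    the flanking valid samples and marked valid.  Leading/trailing runs are
    filled with the nearest valid value.  Runs longer than ``max_gap_s`` get
    interpolated *values* (so no non-finite numbers remain) but stay flagged
    invalid, and their count is logged.

    Raises
    ------
    DataError
        If the signal has no valid sample at all.
    """
    valid = sig.valid
    if not valid.any():
        raise DataError("cannot clean a signal with zero valid samples")
    if valid.all():
        return sig.copy()

    idx = np.arange(len(sig))
    values = sig.values.copy()
    for ch in range(values.shape[1]):
        values[~valid, ch] = np.interp(idx[~valid], idx[valid], values[valid, ch])

    max_gap = int(round(max_gap_s * sig.fs))
    new_valid = valid.copy()
    n_long = 0
    for start, stop in _runs(~valid):
        run_len = stop - start
        interior = start > 0 and stop < len(sig)
        if run_len <= max_gap:
            new_valid[start:stop] = True
        else:
            n_long += 1
            if not interior:
                # edge fill is nearest-value; still treated as unreliable
                pass
    if n_long:
        logger.warning("%d invalid run(s) exceed max_gap_s=%.3g and stay flagged", n_long, max_gap_s)
    return OrientationSignal(values, sig.fs, new_valid, sig.t0)


def normalize_signal(
    sig: OrientationSignal,
) -> tuple[OrientationSignal, tuple[np.ndarray, np.ndarray]]:
    """Robust per-channel standardisation.

    Subtracts the per-channel median and divides by the normalised median
    absolute deviation (MAD x 1.4826, a consistent robust sigma).  Channels
    with zero spread keep scale 1 so constants map to zeros.  Returns the
    normalised signal and ``(center, scale)`` for inversion with
    :func:`denormalize_signal`.
    """
    center = np.median(sig.values, axis=0)
    mad = np.median(np.abs(sig.values - center), axis=0)
    scale = mad * 1.4826
    scale = np.where(scale > 0, scale, 1.0)
    out = replace(sig.copy(), values=(sig.values - center) / scale)
    return out, (center, scale)


def denormalize_signal(
    sig: OrientationSignal, params: tuple[np.ndarray, np.ndarray]
) -> OrientationSignal:
    """Invert :func:`normalize_signal`."""
    center, scale = params
    return replace(sig.copy(), values=sig.values * scale + center)


def lowpass_signal(sig: OrientationSignal, cutoff_hz: float, order: int = 4) -> OrientationSignal:
    """Optional zero-phase Butterworth low-pass (off by default in pipelines)."""
    from scipy.signal import butter, filtfilt

    if not 0 < cutoff_hz < sig.fs / 2:
        raise DataError(f"cutoff must lie in (0, fs/2)=(0, {sig.fs / 2}), got {cutoff_hz}")
    b, a = butter(order, cutoff_hz, fs=sig.fs)
    return replace(sig.copy(), values=filtfilt(b, a, sig.values, axis=0))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open (start, stop)."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), stops.tolist()))
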