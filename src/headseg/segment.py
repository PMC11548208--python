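"""Apply a trained model to whole sessions and turn masks into timed events.

A full recording is longer than one network window, so inference tiles
windows across the signal (stride = one window by default), averages
probabilities where windows overlap, binarises at a threshold, and optionally
converts the binary track into an annotation table of movement intervals.
Annotations can be resampled onto a different timebase (e.g. the ~10.17 Hz
fNIRS sampling grid) with an overlap rule that never loses short events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, ShapeError
from .pose import OrientationSignal, normalize_signal
from .synth import MovementEvent, events_to_mask  # noqa: F401  (round-trip partner)

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class PredictionTrack:
    """Per-sample movement probabilities and their binarisation."""

    probs: np.ndarray
    mask: np.ndarray
    threshold: float
    fs: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.probs.shape != self.mask.shape:
            raise ShapeError("probs and mask must have equal length")


def predict_session(
    model,
    sig: OrientationSignal,
    window_len: int = 320,
    threshold: float = 0.5,
    stride: int | None = None,
    normalize: bool = True,
    batch_size: int = 16,
) -> PredictionTrack:
    """Segment one session with a trained model.

    Windows are tiled over the signal (``stride`` defaults to ``window_len``,
    i.e. no overlap); where windows do overlap, probabilities are combined by
    arithmetic mean.  Signals shorter than one window are right-padded by edge
    replication and the output cropped back; a warning is logged.

    ``model`` only needs to be callable on a (batch, channels, window) array
    and return (batch, 1, window) probabilities, so mock predictors can stand
    in for a real network.
    """
    if normalize:
        sig = normalize_signal(sig)[0]
    values = sig.values.T.astype(np.float32)  # (C, T)
    t = values.shape[1]
    if t == 0:
        raise DataError("cannot predict on an empty signal")
    stride = stride or window_len
    if not 1 <= stride <= window_len:
        raise DataError(f"stride must lie in [1, window_len], got {stride}")

    if t < window_len:
        logger.warning(
            "signal (%d samples) shorter than one window (%d); padding and cropping",
            t, window_len,
        )
    n_win = max(1, int(np.ceil((t - window_len) / stride)) + 1)
    t_pad = (n_win - 1) * stride + window_len
    if t_pad > t:
        values = np.pad(values, ((0, 0), (0, t_pad - t)), mode="edge")

    starts = [i * stride for i in range(n_win)]
    prob_sum = np.zeros(t_pad)
    counts = np.zeros(t_pad)
    for lo in range(0, n_win, batch_size):
        batch_starts = starts[lo:lo + batch_size]
        batch = np.stack([values[:, s:s + window_len] for s in batch_starts])
        probs = np.asarray(model(batch))
        if probs.shape != (len(batch_starts), 1, window_len):
            raise ShapeError(
                f"model returned shape {probs.shape}, expected "
                f"({len(batch_starts)}, 1, {window_len})"
            )
        for s, p in zip(batch_starts, probs[:, 0, :]):
            prob_sum[s:s + window_len] += p
            counts[s:s + window_len] += 1
    probs = (prob_sum / counts)[:t]
    mask = (probs >= threshold).astype(np.uint8)
    return PredictionTrack(probs, mask, threshold, sig.fs)


def mask_to_events(
    mask: np.ndarray,
    fs: float,
    min_duration_s: float = 0.0,
    merge_gap_s: float = 0.0,
) -> list[MovementEvent]:
    """Convert a binary mask into (unlabelled) movement intervals.

    Maximal runs of ones become half-open events ``[first/fs, (last+1)/fs)``.
    Runs separated by gaps shorter than ``merge_gap_s`` are merged first, then
    events shorter than ``min_duration_s`` are dropped.  With both filters at
    0 this is the exact inverse of :func:`headseg.synth.events_to_mask`.
    """
    if fs <= 0:
        raise DataError(f"fs must be positive, got {fs}")
    mask = np.asarray(mask).astype(bool)
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1)
    intervals = [(s / fs, e / fs) for s, e in zip(starts, stops)]

    if merge_gap_s > 0 and len(intervals) > 1:
        merged = [intervals[0]]
        for onset, offset in intervals[1:]:
            if onset - merged[-1][1] < merge_gap_s - _EPS:
                merged[-1] = (merged[-1][0], offset)
            else:
                merged.append((onset, offset))
        intervals = merged
    if min_duration_s > 0:
        intervals = [iv for iv in intervals if iv[1] - iv[0] >= min_duration_s - _EPS]
    return [MovementEvent(onset, offset) for onset, offset in intervals]


def resample_mask(
    mask: np.ndarray, fs_in: float, fs_out: float, conservative: bool = False
) -> np.ndarray:
    """Project a binary mask onto a different sampling grid.

    By default each masked interval's ends are rounded to the nearest output
    sample boundary (keeping at least one sample per event), so no event at
    least one output sample long is lost and total masked duration is
    preserved to within one output sample per event.  ``conservative=True``
    instead marks every output sample whose interval overlaps a masked input
    interval at all — never misses contamination, but can over-mark up to one
    extra sample at each event end.
    """
    if fs_in <= 0 or fs_out <= 0:
        raise DataError("sampling rates must be positive")
    mask = np.asarray(mask).astype(bool)
    n_in = len(mask)
    n_out = int(np.ceil(n_in * fs_out / fs_in - _EPS))
    out = np.zeros(n_out, dtype=np.uint8)
    padded = np.diff(np.concatenate(([0], mask.astype(np.int8), [0])))
    for s, e in zip(np.flatnonzero(padded == 1), np.flatnonzero(padded == -1)):
        onset, offset = s / fs_in, e / fs_in
        if conservative:
            j_lo = int(np.floor(onset * fs_out + _EPS))
            j_hi = int(np.ceil(offset * fs_out - _EPS)) - 1
        else:
            j_lo = int(np.round(onset * fs_out))
            j_hi = int(np.round(offset * fs_out)) - 1
            if j_hi < j_lo:  # event shorter than one output sample: keep one
                mid = 0.5 * (onset + offset) * fs_out
                j_lo = j_hi = min(int(mid), n_out - 1)
        out[max(j_lo, 0):min(j_hi, n_out - 1) + 1] = 1
    return out
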