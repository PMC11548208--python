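"""Synthetic head-movement sessions with the structure of the instructed-movement study.

The emulated protocol: a participant watches an avatar demonstrate a head
movement, gets a 3 s countdown, then has a 7 s response window to perform it.
Movements span 3 rotation axes (up/down, left/right, lateral bend), 2 speeds
(slow, fast) and 3 types (half: excursion that holds; complete: there-and-back;
repeated: several oscillations).  The 18-condition grid is cycled over
3 blocks for 60 movements per session.

Each generated session carries the ground-truth event table and its
rasterised binary movement mask, so the segmentation model can be trained and
scored without any recorded data.  Waveforms are raised-cosine (smooth,
band-limited, endpoint-exact); realism terms are i.i.d. Gaussian sample noise
(pose-estimator jitter) and one slow sinusoidal drift per channel (posture
drift).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DataError, OverlappingEventsError, UnknownLabelError
from .pose import AXES, MAX_ANGLE_DEG, OrientationSignal

SPEEDS: tuple[str, str] = ("slow", "fast")
MTYPES: tuple[str, str, str] = ("half", "complete", "repeated")

#: Movement durations in seconds at slow speed, per movement type.  Fast
#: movements use these times scaled by ``SessionDesign.fast_duration_factor``.
SLOW_DURATIONS_S: dict[str, float] = {"half": 3.0, "complete": 4.0, "repeated": 5.0}

_EPS = 1e-9


@dataclass(frozen=True)
class MovementEvent:
    """A movement interval in seconds from session start.

    Labels are None for unlabelled (model-derived) events; when present they
    must come from the study vocabulary.
    """

    onset: float
    offset: float
    axis: str | None = None
    speed: str | None = None
    mtype: str | None = None

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise DataError(f"event offset {self.offset} must exceed onset {self.onset}")
        if self.axis is not None:
            _check_label("axis", self.axis, AXES)
        if self.speed is not None:
            _check_label("speed", self.speed, SPEEDS)
        if self.mtype is not None:
            _check_label("mtype", self.mtype, MTYPES)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SessionDesign:
    """Timing and condition structure of one session.

    Defaults encode the study protocol: 60 movements over 3 blocks, each trial
    a 3 s countdown plus a 7 s response window; the 2 s inter-trial gap,
    onset jitter and fast/slow ratio are generator choices (see docs).
    """

    n_blocks: int = 3
    movements_per_session: int = 60
    countdown_s: float = 3.0
    response_window_s: float = 7.0
    inter_trial_gap_s: float = 2.0
    sampling_rate_hz: float = 30.0
    onset_jitter_s: float = 1.5
    amplitude_deg: float = 30.0
    fast_duration_factor: float = 0.5
    fast_rise_factor: float = 0.5
    drift_period_s: float = 120.0

    def __post_init__(self) -> None:
        for name in ("countdown_s", "response_window_s", "inter_trial_gap_s",
                     "sampling_rate_hz", "amplitude_deg"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_blocks < 1 or self.movements_per_session < 1:
            raise ConfigurationError("n_blocks and movements_per_session must be >= 1")
        if self.movements_per_session % self.n_blocks != 0:
            raise ConfigurationError(
                f"movements_per_session={self.movements_per_session} is not attainable: "
                f"not divisible into {self.n_blocks} equal blocks"
            )
        longest = max(SLOW_DURATIONS_S.values())
        if longest + self.onset_jitter_s > self.response_window_s + _EPS:
            raise ConfigurationError(
                f"longest movement ({longest} s) plus jitter ({self.onset_jitter_s} s) "
                f"does not fit the {self.response_window_s} s response window"
            )

    @property
    def trial_duration_s(self) -> float:
        """Countdown + response window + inter-trial gap."""
        return self.countdown_s + self.response_window_s + self.inter_trial_gap_s

    @property
    def session_duration_s(self) -> float:
        return self.movements_per_session * self.trial_duration_s

    @property
    def n_samples(self) -> int:
        return int(round(self.session_duration_s * self.sampling_rate_hz))


@dataclass
class SessionRecord:
    """One participant session: signal, ground-truth events, rasterised mask."""

    participant_id: str
    signal: OrientationSignal
    events: list[MovementEvent]
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = events_to_mask(self.events, len(self.signal), self.signal.fs)
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        if self.mask.shape != (len(self.signal),):
            raise DataError(
                f"mask length {self.mask.shape} does not match signal length {len(self.signal)}"
            )


def condition_grid() -> list[tuple[str, str, str]]:
    """The 18 (axis, speed, mtype) conditions in deterministic order."""
    return list(itertools.product(AXES, SPEEDS, MTYPES))


def movement_duration_s(mtype: str, speed: str, design: SessionDesign) -> float:
    """Scheduled duration of one movement for the given type and speed."""
    _check_label("mtype", mtype, MTYPES)
    _check_label("speed", speed, SPEEDS)
    dur = SLOW_DURATIONS_S[mtype]
    return dur * design.fast_duration_factor if speed == "fast" else dur


def movement_waveform(
    mtype: str,
    speed: str,
    axis: str,
    duration_s: float,
    amplitude_deg: float,
    fs: float,
    *,
    direction: int = 1,
    fast_rise_factor: float = 0.5,
    n_cycles: int = 3,
) -> np.ndarray:
    """Raised-cosine orientation increment for one movement.

    Returns an array of shape (n, 3), n = round(duration_s * fs), nonzero only
    on the channel mapped to ``axis``.  Shapes by type:

    * ``half`` — monotone raised-cosine rise from 0 to the amplitude, then hold
      (net posture change; the session generator alternates direction so the
      baseline stays bounded).
    * ``complete`` — rise to the amplitude and return to 0.
    * ``repeated`` — ``n_cycles`` tapered sinusoidal oscillations, net 0.

    Fast movements use a rise time ``fast_rise_factor`` (default one half)
    times the slow rise time, relative to the movement duration.
    """
    _check_label("mtype", mtype, MTYPES)
    _check_label("speed", speed, SPEEDS)
    _check_label("axis", axis, AXES)
    if amplitude_deg <= 0:
        raise DataError(f"amplitude must be positive, got {amplitude_deg}")
    if duration_s <= 0:
        raise DataError(f"duration must be positive, got {duration_s}")
    n = int(round(duration_s * fs))
    if n < 4:
        raise DataError(f"duration {duration_s} s at {fs} Hz gives only {n} samples")

    t = np.linspace(0.0, 1.0, n)
    rise = 0.5 * (fast_rise_factor if speed == "fast" else 1.0)

    if mtype == "half":
        y = np.where(t < rise, 0.5 * (1.0 - np.cos(np.pi * np.minimum(t, rise) / rise)), 1.0)
    elif mtype == "complete":
        # raised-cosine rise over [0, r], hold at peak, fall over [1-r, 1];
        # the plateau guarantees the amplitude is attained on the sample grid
        r = min(rise, 0.45)
        y = np.ones(n)
        up = t < r
        down = t > 1.0 - r
        y[up] = 0.5 * (1.0 - np.cos(np.pi * t[up] / r))
        y[down] = 0.5 * (1.0 - np.cos(np.pi * (1.0 - t[down]) / r))
    else:  # repeated
        taper = np.minimum(1.0, np.minimum(t, 1.0 - t) / rise)
        taper = 0.5 * (1.0 - np.cos(np.pi * taper))
        y = np.sin(2.0 * np.pi * n_cycles * t) * taper

    seg = np.zeros((n, 3))
    seg[:, AXES.index(axis)] = direction * amplitude_deg * y
    return seg


def events_to_mask(events: list[MovementEvent], n_samples: int, fs: float) -> np.ndarray:
    """Rasterise events onto the sample grid.

    Sample ``i`` is 1 iff ``i / fs`` lies in some half-open ``[onset, offset)``
    interval, so abutting events tile without double counting.

    Raises
    ------
    OverlappingEventsError
        If any two events overlap.
    DataError
        If an event extends past the signal end.
    """
    mask = np.zeros(n_samples, dtype=np.uint8)
    prev_offset, prev = -np.inf, None
    for ev in sorted(events, key=lambda e: e.onset):
        if ev.onset < prev_offset - _EPS:
            raise OverlappingEventsError(
                f"event at {ev.onset:.3f}s overlaps previous event ending {prev_offset:.3f}s"
            )
        if ev.offset > n_samples / fs + _EPS:
            raise DataError(
                f"event offset {ev.offset:.3f}s exceeds signal end {n_samples / fs:.3f}s"
            )
        i0 = int(np.ceil(ev.onset * fs - _EPS))
        i1 = int(np.ceil(ev.offset * fs - _EPS))
        mask[max(i0, 0):min(i1, n_samples)] = 1
        prev_offset, prev = ev.offset, ev
    return mask


def generate_session(
    design: SessionDesign | None = None,
    noise_sd: float = 0.5,
    drift_amp: float = 2.0,
    participant_id: str = "p00",
    seed: int = 0,
) -> SessionRecord:
    """Simulate one participant session.

    One trial per condition (the 18-condition grid cycled across the session,
    so 60 movements cover each condition 3 or 4 times), each movement placed in
    its response window at a uniformly jittered onset with a per-trial
    amplitude factor in [0.8, 1.2].  Gaussian noise (sd ``noise_sd`` degrees)
    and one slow sinusoidal drift per channel (peak ``drift_amp`` degrees) are
    superimposed; values are clipped to +/-90 degrees with a warning.
    Identical arguments reproduce the session bit for bit.
    """
    design = design or SessionDesign()
    if noise_sd < 0 or drift_amp < 0:
        raise ConfigurationError("noise_sd and drift_amp must be non-negative")
    rng = np.random.default_rng(seed)
    fs = design.sampling_rate_hz
    n_samples = design.n_samples
    grid = condition_grid()

    values = np.zeros((n_samples, 3))
    baseline = np.zeros(3)
    events: list[MovementEvent] = []
    cursor = 0
    for t_idx in range(design.movements_per_session):
        axis, speed, mtype = grid[t_idx % len(grid)]
        jitter = rng.uniform(0.0, design.onset_jitter_s)
        amp = design.amplitude_deg * rng.uniform(0.8, 1.2)
        if mtype == "half":
            ch = AXES.index(axis)
            direction = -1 if baseline[ch] > 0 else 1
            rng.integers(0, 2)  # keep the per-trial draw count fixed across types
        else:
            direction = int(rng.integers(0, 2)) * 2 - 1
        dur = movement_duration_s(mtype, speed, design)
        onset = t_idx * design.trial_duration_s + design.countdown_s + jitter
        wave = movement_waveform(
            mtype, speed, axis, dur, amp, fs,
            direction=direction, fast_rise_factor=design.fast_rise_factor,
        )
        i0 = int(round(onset * fs))
        i1 = i0 + len(wave)
        events.append(MovementEvent(i0 / fs, i1 / fs, axis, speed, mtype))
        values[cursor:i0] = baseline
        values[i0:i1] = baseline + wave
        baseline = baseline + wave[-1]
        cursor = i1
    values[cursor:] = baseline

    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, values.shape)
    if drift_amp > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi, 3)
        tgrid = np.arange(n_samples)[:, None] / fs
        values = values + drift_amp * np.sin(
            2.0 * np.pi * tgrid / design.drift_period_s + phase[None, :]
        )
    if np.any(np.abs(values) > MAX_ANGLE_DEG):
        warnings.warn(
            f"session {participant_id}: orientation exceeded +/-{MAX_ANGLE_DEG} deg; clipped",
            stacklevel=2,
        )
        values = np.clip(values, -MAX_ANGLE_DEG, MAX_ANGLE_DEG)

    signal = OrientationSignal(values, fs)
    return SessionRecord(participant_id, signal, events)


def make_cohort(
    n_train: int = 10,
    n_test: int = 5,
    design: SessionDesign | None = None,
    noise_sd: float = 0.5,
    drift_amp: float = 2.0,
    seed: int = 0,
) -> tuple[list[SessionRecord], list[SessionRecord]]:
    """Generate disjoint train/test participant cohorts (defaults 10 / 5).

    Per-participant seeds are derived from ``seed`` so the whole cohort is
    reproducible while sessions differ from one another.
    """
    if n_train < 1 or n_test < 1:
        raise ConfigurationError("n_train and n_test must both be >= 1")
    design = design or SessionDesign()
    base = np.random.default_rng(seed)
    child_seeds = base.integers(0, 2**31 - 1, size=n_train + n_test)
    sessions = [
        generate_session(design, noise_sd, drift_amp, f"p{i + 1:02d}", int(child_seeds[i]))
        for i in range(n_train + n_test)
    ]
    return sessions[:n_train], sessions[n_train:]


def _check_label(kind: str, value: str, allowed: tuple[str, ...]) -> None:
    if value not in allowed:
        raise UnknownLabelError(f"unknown {kind} label {value!r}; expected one of {allowed}")
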