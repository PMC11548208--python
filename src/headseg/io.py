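"""Tabular session and annotation files.

One session is two plain-text files: ``<id>.csv`` with the sampled signal
(time_s, ax_updown_deg, ax_leftright_deg, ax_bend_deg, valid and, when
annotated, mask) and a sidecar ``<id>_events.csv`` with the event table
(onset_s, offset_s, axis, speed, mtype).  Floats are written with 17
significant digits so a read-back reproduces the arrays bit for bit; the
sampling rate and start offset travel in ``#``-comment header lines.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .pose import AXES, OrientationSignal
from .synth import MovementEvent, SessionRecord

_FLOAT_FMT = "%.17g"
_SIGNAL_COLS = ["time_s"] + [f"ax_{a}_deg" for a in AXES] + ["valid"]


def write_signal(sig: OrientationSignal, path, mask: np.ndarray | None = None) -> None:
    """Write a signal table; include a mask column when one is given."""
    df = pd.DataFrame({"time_s": sig.times})
    for i, a in enumerate(AXES):
        df[f"ax_{a}_deg"] = sig.values[:, i]
    df["valid"] = sig.valid.astype(int)
    if mask is not None:
        df["mask"] = np.asarray(mask, dtype=int)
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={sig.fs!r}\n# t0={sig.t0!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_signal(path) -> tuple[OrientationSignal, np.ndarray | None]:
    """Read a signal table back; returns (signal, mask or None)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].strip().partition("=")
            header[key.strip()] = float(val)
    if "fs_hz" not in header:
        raise DataError(f"{path}: missing '# fs_hz=' header line")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in _SIGNAL_COLS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing columns {missing}")
    values = df[[f"ax_{a}_deg" for a in AXES]].to_numpy(dtype=np.float64)
    sig = OrientationSignal(
        values, header["fs_hz"], df["valid"].to_numpy(dtype=bool), header.get("t0", 0.0)
    )
    mask = df["mask"].to_numpy(dtype=np.uint8) if "mask" in df.columns else None
    return sig, mask


def write_events(events: list[MovementEvent], path) -> None:
    df = pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "offset_s": [e.offset for e in events],
            "axis": [e.axis or "" for e in events],
            "speed": [e.speed or "" for e in events],
            "mtype": [e.mtype or "" for e in events],
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_events(path) -> list[MovementEvent]:
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    events = []
    for row in df.itertuples(index=False):
        events.append(
            MovementEvent(
                float(row.onset_s),
                float(row.offset_s),
                str(row.axis) or None,
                str(row.speed) or None,
                str(row.mtype) or None,
            )
        )
    return events


def session_paths(directory, participant_id: str) -> tuple[Path, Path]:
    d = Path(directory)
    return d / f"{participant_id}.csv", d / f"{participant_id}_events.csv"


def write_session(record: SessionRecord, directory) -> tuple[Path, Path]:
    """Write one session as signal + events sidecar; returns the two paths."""
    Path(directory).mkdir(parents=True, exist_ok=True)
    sig_path, ev_path = session_paths(directory, record.participant_id)
    write_signal(record.signal, sig_path, record.mask)
    write_events(record.events, ev_path)
    return sig_path, ev_path


def read_session(directory, participant_id: str) -> SessionRecord:
    sig_path, ev_path = session_paths(directory, participant_id)
    sig, mask = read_signal(sig_path)
    events = read_events(ev_path) if ev_path.exists() else []
    if mask is None:
        if not events:
            raise DataError(f"{sig_path}: session has neither mask nor events")
        mask = None  # SessionRecord rasterises from events
    return SessionRecord(participant_id, sig, events, mask)


def list_sessions(directory) -> list[str]:
    """Participant ids present in a session directory."""
    d = Path(directory)
    return sorted(
        p.stem for p in d.glob("*.csv")
        if not p.stem.endswith("_events")
    )
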