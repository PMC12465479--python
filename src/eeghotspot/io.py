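"""Recording container and on-disk formats.

Two interchange formats are supported for recordings:

* ``matrix`` — a ``.npy`` channel x sample matrix with a JSON sidecar header
  (labels, sampling rate, events, subject metadata).  This is the native
  format; it round-trips exactly.
* ``edf`` — read-only EDF support through MNE, for recordings exported from
  clinical systems.

Hotspot ground-truth tables are plain CSV with columns
``subject_id, hand, x_mm, y_mm, z_mm``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import HotspotLocation, HotspotSource

logger = logging.getLogger(__name__)

EVENT_TYPES = ("keypress", "cue")


@dataclass
class EEGRecording:
    """Continuous multi-channel EEG (µV) with event markers."""

    signal: np.ndarray  # channels x samples
    fs: float
    labels: tuple[str, ...]
    events: tuple[tuple[int, str], ...] = ()
    subject_id: str = ""
    hand: str = ""
    cohort: str = "healthy"

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        self.labels = tuple(self.labels)
        if len(self.labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.signal.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.events = tuple((int(s), str(t)) for s, t in self.events)
        if any(t not in EVENT_TYPES for _, t in self.events):
            bad = sorted({t for _, t in self.events} - set(EVENT_TYPES))
            raise ValueError(f"unknown event types {bad}; expected {EVENT_TYPES}")
        if any(s < 0 or s >= self.n_samples for s, _ in self.events):
            raise ValueError("event sample index outside the recording")
        if list(self.events) != sorted(self.events, key=lambda e: e[0]):
            raise ValueError("events must be sorted by sample index")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def event_samples(self, event_type: str | None = None) -> np.ndarray:
        return np.array(
            [s for s, t in self.events if event_type is None or t == event_type],
            dtype=int,
        )

    def copy_with(self, **kw) -> "EEGRecording":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# matrix + JSON header dialect


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write the matrix+header dialect; `path` is the .npy file."""
    path = Path(path).with_suffix(".npy")
    np.save(path, rec.signal)
    header = {
        "fs": rec.fs,
        "labels": list(rec.labels),
        "events": [[s, t] for s, t in rec.events],
        "subject_id": rec.subject_id,
        "hand": rec.hand,
        "cohort": rec.cohort,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))
    return path


def read_recording(path: str | Path, format: str = "matrix") -> EEGRecording:
    path = Path(path)
    if format == "matrix":
        return _read_matrix(path)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}; expected 'matrix' or 'edf'")


def _read_matrix(path: Path) -> EEGRecording:
    sidecar = path.with_suffix(".json")
    if not path.exists():
        raise FileNotFoundError(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar header {sidecar}")
    header = json.loads(sidecar.read_text())
    for key in ("fs", "labels"):
        if key not in header:
            raise ValueError(f"malformed header {sidecar}: missing field {key!r}")
    events = header.get("events")
    if events is None:
        logger.warning("%s: no event list in header; recording has no events", path)
        events = []
    return EEGRecording(
        signal=np.load(path),
        fs=header["fs"],
        labels=header["labels"],
        events=[(int(s), t) for s, t in events],
        subject_id=header.get("subject_id", ""),
        hand=header.get("hand", ""),
        cohort=header.get("cohort", "healthy"),
    )


def _read_edf(path: Path) -> EEGRecording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    events = []
    for onset, _, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        etype = desc.lower()
        if etype in EVENT_TYPES:
            events.append((int(round(onset * raw.info["sfreq"])), etype))
    if not events:
        logger.warning("%s: no keypress/cue annotations found", path)
    return EEGRecording(
        signal=raw.get_data() * 1e6,  # MNE stores volts
        fs=raw.info["sfreq"],
        labels=tuple(raw.ch_names),
        events=sorted(events),
    )


# ---------------------------------------------------------------------------
# hotspot tables

HOTSPOT_COLUMNS = ["subject_id", "hand", "x_mm", "y_mm", "z_mm"]


def read_hotspot_table(path: str | Path) -> list[tuple[str, str, HotspotLocation]]:
    """Read a ground-truth CSV; hemisphere is inferred from the sign of x."""
    df = pd.read_csv(path, dtype={"subject_id": str, "hand": str})
    missing = [c for c in HOTSPOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = []
    for i, row in df.iterrows():
        coords = []
        for c in ("x_mm", "y_mm", "z_mm"):
            try:
                coords.append(float(row[c]))
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-numeric coordinate {row[c]!r} in column {c}, row {i}"
                ) from None
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"{path}: non-finite coordinate in row {i}")
        loc = HotspotLocation.from_array(coords, HotspotSource.TMS_GROUND_TRUTH)
        out.append((str(row["subject_id"]), str(row["hand"]), loc))
    return out


def write_hotspot_table(
    rows: list[tuple[str, str, HotspotLocation]], path: str | Path
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {"subject_id": sid, "hand": hand, "x_mm": loc.x, "y_mm": loc.y,
             "z_mm": loc.z}
            for sid, hand, loc in rows
        ],
        columns=HOTSPOT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f")
    return path
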