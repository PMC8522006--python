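"""Readers and writers for every on-disk representation the pipeline touches.

Signals travel as EDF (the lingua franca of sleep tooling) or as a
human-inspectable wide CSV; hypnograms, grapho-element event lists and
confusion matrices are plain CSV. The canonical sleep-stage alphabet is
``Art, W, N1, N2, N3, REM`` (AASM stages plus an artifact category) and every
confusion matrix is reordered into that order on read so matrices from
different sources are comparable cell by cell.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import _edf

#: Canonical stage order used everywhere (hypnograms, confusion matrices).
STAGES: tuple[str, ...] = ("Art", "W", "N1", "N2", "N3", "REM")

#: Grapho-element labels the annotation format accepts.
EVENT_LABELS: tuple[str, ...] = ("k_complex", "spindle")

#: Names of the published confusion-matrix fixtures bundled with the package.
BUNDLED_CONFUSIONS: tuple[str, ...] = (
    "fpz_eog_test_retest",
    "fpz_eog_vs_ceegrid",
    "fpz_eog_vs_ceegrid_eog",
)


class FormatError(ValueError):
    """A file does not parse under the named standard."""


class IntegrityError(ValueError):
    """Parsed content violates a structural invariant."""


@dataclass
class Recording:
    """A multi-channel EEG/EOG recording in microvolts.

    ``data`` has shape (n_channels, n_samples); channel ``channel_labels[i]``
    is row ``i``.
    """

    channel_labels: tuple[str, ...]
    data: np.ndarray
    fs: float
    start_time: _dt.datetime | None = None

    def __post_init__(self):
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise IntegrityError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise IntegrityError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise IntegrityError("channel labels must be unique")
        if not self.fs > 0:
            raise IntegrityError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None
        return self.data[idx]


@dataclass
class Hypnogram:
    """Sleep-stage labels for consecutive fixed-length epochs (default 30 s)."""

    stages: list[str]
    epoch_length: float = 30.0

    def __post_init__(self):
        self.stages = list(self.stages)
        bad = sorted({s for s in self.stages if s not in STAGES})
        if bad:
            raise IntegrityError(f"unknown stage label(s): {bad}; alphabet is {STAGES}")
        if not self.epoch_length > 0:
            raise IntegrityError("epoch_length must be positive")

    def __len__(self) -> int:
        return len(self.stages)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Hypnogram)
            and self.stages == other.stages
            and self.epoch_length == other.epoch_length
        )


@dataclass(frozen=True)
class EventAnnotation:
    """One annotated grapho-element interval (K-complex or sleep spindle)."""

    onset: float
    duration: float
    label: str
    channel: str = "Fpz"

    def __post_init__(self):
        if self.onset < 0:
            raise IntegrityError(f"event onset {self.onset} < 0")
        if not self.duration > 0:
            raise IntegrityError(f"event duration {self.duration} must be > 0")
        if self.label not in EVENT_LABELS:
            raise IntegrityError(
                f"unknown event label {self.label!r}; expected one of {EVENT_LABELS}"
            )


# ---------------------------------------------------------------------------
# recordings


def read_recording(path, format: str | None = None) -> Recording:
    """Read a Recording from EDF or wide CSV (format inferred from suffix)."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        try:
            data, labels, fs, start = _edf.read_edf(path)
        except ValueError as exc:
            raise FormatError(str(exc)) from exc
        return Recording(tuple(labels), data, fs, start)
    if fmt == "csv":
        df = pd.read_csv(path)
        if df.shape[1] < 2 or df.columns[0] != "time_s":
            raise FormatError(f"{path}: recording CSV must start with a time_s column")
        t = df["time_s"].to_numpy(float)
        if len(t) < 2:
            raise FormatError(f"{path}: need at least two samples to infer fs")
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise IntegrityError(f"{path}: time column is not uniformly sampled")
        fs = 1.0 / dt[0]
        labels = tuple(df.columns[1:])
        return Recording(labels, df[list(labels)].to_numpy(float).T, fs)
    raise FormatError(f"unknown recording format {fmt!r}")


def write_recording(rec: Recording, path, format: str | None = None) -> None:
    """Write a Recording as EDF (physical dimension uV) or wide CSV."""
    path = Path(path)
    fmt = format or ("edf" if path.suffix.lower() == ".edf" else "csv")
    if fmt == "edf":
        _edf.write_edf(path, rec.data, list(rec.channel_labels), rec.fs, rec.start_time)
    elif fmt == "csv":
        t = np.arange(rec.n_samples) / rec.fs
        df = pd.DataFrame({"time_s": t})
        for i, lb in enumerate(rec.channel_labels):
            df[lb] = rec.data[i]
        df.to_csv(path, index=False)
    else:
        raise FormatError(f"unknown recording format {fmt!r}")


# ---------------------------------------------------------------------------
# hypnograms


def read_hypnogram(path, epoch_length: float = 30.0) -> Hypnogram:
    df = pd.read_csv(path)
    for col in ("epoch_index", "stage"):
        if col not in df.columns:
            raise FormatError(f"{path}: hypnogram CSV needs column {col!r}")
    stages = [str(s) for s in df["stage"]]
    return Hypnogram(stages, epoch_length)


def write_hypnogram(h: Hypnogram, path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(len(h)), "stage": h.stages}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# grapho-element event lists


def read_events(path) -> list[EventAnnotation]:
    """Read event annotations; returned sorted by onset."""
    df = pd.read_csv(path)
    for col in ("onset_s", "duration_s", "label", "channel"):
        if col not in df.columns:
            raise FormatError(f"{path}: events CSV needs column {col!r}")
    events = [
        EventAnnotation(float(r.onset_s), float(r.duration_s), str(r.label), str(r.channel))
        for r in df.itertuples()
    ]
    return sorted(events, key=lambda e: e.onset)


def write_events(events: list[EventAnnotation], path) -> None:
    pd.DataFrame(
        {
            "onset_s": [e.onset for e in events],
            "duration_s": [e.duration for e in events],
            "label": [e.label for e in events],
            "channel": [e.channel for e in events],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# confusion matrices


def read_confusion_csv(path):
    """Read a label-indexed square count table into a ConfusionMatrix.

    Rows and columns are reordered into the canonical stage order, so a file
    with permuted (but complete) labels yields the same matrix.
    """
    from .agreement import ConfusionMatrix  # local import: avoid cycle at import time

    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise IntegrityError(f"{path}: confusion matrix must be square, got {df.shape}")
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    if sorted(row_labels) != sorted(col_labels):
        raise IntegrityError(f"{path}: row and column labels differ")
    if not set(row_labels).issubset(STAGES):
        raise IntegrityError(
            f"{path}: labels {sorted(set(row_labels) - set(STAGES))} outside stage alphabet"
        )
    order = [s for s in STAGES if s in row_labels]
    df = df.loc[order, order]
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number) or np.any(counts < 0):
        raise IntegrityError(f"{path}: counts must be non-negative numbers")
    if np.any(counts != np.rint(counts)):
        raise IntegrityError(f"{path}: counts must be integers")
    return ConfusionMatrix(counts.astype(int), tuple(order))


def write_confusion_csv(m, path) -> None:
    pd.DataFrame(m.counts, index=list(m.labels), columns=list(m.labels)).to_csv(
        path, index_label="stage"
    )


def bundled_confusion(name: str):
    """Load one of the published confusion-matrix fixtures shipped in-package.

    ``name`` is one of :data:`BUNDLED_CONFUSIONS`: the expert scorer's
    test-retest matrix and the two ear-EEG comparison matrices.
    """
    if name not in BUNDLED_CONFUSIONS:
        raise KeyError(f"unknown fixture {name!r}; available: {BUNDLED_CONFUSIONS}")
    ref = resources.files("earsleep.data").joinpath(f"confusion_{name}.csv")
    with resources.as_file(ref) as p:
        return read_confusion_csv(p)
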