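"""Domain types, file I/O and trial segmentation.

A :class:`Recording` is a channels x samples voltage matrix sampled at
``fs`` (30 kHz by default, the rate of the neural recorder used in the
study protocol).  Trials are described by a :class:`TrialTable`: each row
is one attempted phantom movement, a 2 s movement window (1 s flexion
immediately followed by 1 s extension) followed by 2 s of rest.

Time convention: seconds from recording start, half-open intervals
``[start, end)``; the sample index of time ``t`` is ``floor(t * fs)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ChannelInfo",
    "Recording",
    "TrialTable",
    "LabeledSegment",
    "default_channel_layout",
    "load_recording",
    "save_recording",
    "segment_trials",
    "qc_flags",
    "PHASES",
    "JOINTS",
    "DIRECTIONS",
]

JOINTS = ("knee", "ankle", "toes")
DIRECTIONS = ("flexion", "extension")
PHASES = ("flexion", "extension", "movement", "rest")

#: CSV columns of the trial annotation table.
TRIAL_COLUMNS = [
    "class",
    "joint",
    "direction",
    "block",
    "repetition",
    "movement_start",
    "movement_end",
]


def sample_index(t: float, fs: float) -> int:
    """Sample index of time ``t`` under the floor convention.

    A tiny epsilon absorbs float representation error so that e.g.
    ``0.1 * 30000`` lands on 3000 rather than 2999.
    """
    return int(np.floor(t * fs + 1e-6))


@dataclass(frozen=True)
class ChannelInfo:
    """One recording contact (active site) of an intrafascicular electrode."""

    electrode_index: int  # TIME number, 1-4
    site_index: int  # active site within the electrode, 1-14
    side: str = "L"
    is_ground: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.electrode_index <= 4:
            raise ValueError(f"electrode_index out of range: {self.electrode_index}")
        if not 1 <= self.site_index <= 14:
            raise ValueError(f"site_index out of range: {self.site_index}")
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")

    @property
    def name(self) -> str:
        return f"T{self.electrode_index}S{self.site_index:02d}"


def default_channel_layout(n_channels: int = 56, side: str = "L") -> list[ChannelInfo]:
    """Up to 4 electrodes x 14 active sites, in recording order."""
    if not 1 <= n_channels <= 56:
        raise ValueError("channel layout supports 1-56 sites (4 electrodes x 14)")
    return [
        ChannelInfo(electrode_index=i // 14 + 1, site_index=i % 14 + 1, side=side)
        for i in range(n_channels)
    ]


@dataclass
class Recording:
    """Multichannel extracellular recording.

    data : (n_channels, n_samples) float array, volts or normalised units
    fs : sampling rate in Hz
    channels : per-channel electrode metadata, same order as rows of data
    """

    data: np.ndarray
    fs: float = 30000.0
    channels: list[ChannelInfo] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channels:
            self.channels = default_channel_layout(self.data.shape[0])
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def validate_finite(self) -> None:
        """Hard-error on non-finite samples, naming the offending channel."""
        bad = ~np.isfinite(self.data)
        if bad.any():
            ch = int(np.flatnonzero(bad.any(axis=1))[0])
            raise ValueError(
                f"non-finite samples in channel {self.channels[ch].name} (row {ch})"
            )

    def decoding_channels(self) -> np.ndarray:
        """Row indices of non-ground channels (grounds are metadata only)."""
        return np.array(
            [i for i, c in enumerate(self.channels) if not c.is_ground], dtype=int
        )


class TrialTable:
    """Labelled movement events anchoring segmentation.

    Wraps a pandas DataFrame with columns ``class, joint, direction, block,
    repetition, movement_start, movement_end``.  Derived windows:

    - flexion   = [movement_start, movement_start + 1)
    - extension = [movement_start + 1, movement_end)
    - rest      = [movement_end, movement_end + rest_s)
    """

    MOVEMENT_S = 2.0
    REST_S = 2.0

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"trial table missing columns: {missing}")
        self.df = df.reset_index(drop=True)
        if validate and len(df):
            self._validate()

    def _validate(self) -> None:
        dur = self.df["movement_end"] - self.df["movement_start"]
        if not np.allclose(dur, self.MOVEMENT_S, atol=1e-6):
            bad = self.df.index[~np.isclose(dur, self.MOVEMENT_S, atol=1e-6)].tolist()
            raise ValueError(f"movement windows must be {self.MOVEMENT_S} s; bad rows {bad}")
        starts = np.sort(self.df["movement_start"].to_numpy())
        ends = np.sort(self.df["movement_end"].to_numpy() + self.REST_S)
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("trial windows (movement + rest) overlap")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, TrialTable) and self.df.equals(other.df)

    @property
    def class_labels(self) -> list[str]:
        return sorted(self.df["class"].unique().tolist())

    def windows(self, phase: str) -> pd.DataFrame:
        """Half-open (t0, t1) window per trial for the given phase."""
        if phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        ms, me = self.df["movement_start"], self.df["movement_end"]
        if phase == "flexion":
            t0, t1 = ms, ms + 1.0
        elif phase == "extension":
            t0, t1 = ms + 1.0, me
        elif phase == "movement":
            t0, t1 = ms, me
        else:  # rest
            t0, t1 = me, me + self.REST_S
        out = self.df[["class", "joint", "direction", "block", "repetition"]].copy()
        out["t0"] = t0.to_numpy()
        out["t1"] = t1.to_numpy()
        return out

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrialTable":
        df = pd.read_csv(path)
        if len(df) == 0:
            df = pd.DataFrame(columns=TRIAL_COLUMNS)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def empty(cls) -> "TrialTable":
        return cls(pd.DataFrame(columns=TRIAL_COLUMNS), validate=False)


@dataclass
class LabeledSegment:
    """A channels x samples slice with its movement label and phase."""

    data: np.ndarray
    label: str
    phase: str
    t0: float
    fs: float = 30000.0

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


# ---------------------------------------------------------------------------
# container I/O


def save_recording(path: str | Path, recording: Recording) -> None:
    """Write the recording to an HDF5 container.

    Datasets: ``data`` (float32, channels x samples); attributes ``fs`` and
    ``subject_id``; channel metadata in a ``channels`` group.
    """
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data.astype(np.float32))
        f.attrs["fs"] = float(recording.fs)
        f.attrs["subject_id"] = recording.subject_id
        g = f.create_group("channels")
        g.create_dataset(
            "electrode_index",
            data=np.array([c.electrode_index for c in recording.channels]),
        )
        g.create_dataset(
            "site_index", data=np.array([c.site_index for c in recording.channels])
        )
        g.create_dataset(
            "side",
            data=np.array([c.side for c in recording.channels], dtype="S1"),
        )
        g.create_dataset(
            "is_ground",
            data=np.array([c.is_ground for c in recording.channels], dtype=bool),
        )


def load_recording(
    container_path: str | Path,
    annotation_path: str | Path | None = None,
) -> tuple[Recording, TrialTable]:
    """Load an HDF5 recording container and its CSV trial annotation.

    Raises on a missing ``fs`` attribute, on non-finite samples (naming the
    channel) and on annotation windows extending beyond the recording
    (listing the offending rows).
    """
    with h5py.File(container_path, "r") as f:
        if "data" not in f:
            raise ValueError(f"{container_path}: no 'data' dataset")
        if "fs" not in f.attrs:
            raise ValueError(f"{container_path}: missing required attribute 'fs'")
        data = f["data"][...]
        fs = float(f.attrs["fs"])
        subject = str(f.attrs.get("subject_id", ""))
        channels: list[ChannelInfo] = []
        if "channels" in f:
            g = f["channels"]
            for e, s, side, gr in zip(
                g["electrode_index"][...],
                g["site_index"][...],
                g["side"][...],
                g["is_ground"][...],
            ):
                channels.append(
                    ChannelInfo(int(e), int(s), side.decode(), bool(gr))
                )
    rec = Recording(data=data, fs=fs, channels=channels, subject_id=subject)
    rec.validate_finite()

    if annotation_path is None:
        return rec, TrialTable.empty()
    trials = TrialTable.from_csv(annotation_path)
    if len(trials):
        t_end = trials.df["movement_end"] + TrialTable.REST_S
        bad = trials.df.index[t_end > rec.duration + 1e-9].tolist()
        if bad:
            raise ValueError(
                f"annotation rows extend beyond the {rec.duration:.3f} s recording: rows {bad}"
            )
    return rec, trials


def qc_flags(recording: Recording, nonfinite_frac: float = 0.01) -> list[dict]:
    """Automated quality-control gate replacing manual corrupted-file removal.

    A channel is flagged when more than ``nonfinite_frac`` of its samples are
    non-finite or when the signal is constant.  Returns one record per
    flagged channel; callers exclude flagged channels and log the records.
    """
    flags = []
    for i, ch in enumerate(recording.channels):
        row = recording.data[i]
        frac_bad = float(np.mean(~np.isfinite(row)))
        finite = row[np.isfinite(row)]
        constant = finite.size == 0 or bool(np.all(finite == finite[0]))
        if frac_bad > nonfinite_frac or constant:
            flags.append(
                {
                    "channel": ch.name,
                    "row": i,
                    "nonfinite_frac": frac_bad,
                    "constant": constant,
                }
            )
    return flags


# ---------------------------------------------------------------------------
# segmentation


def segment_trials(
    recording: Recording,
    trials: TrialTable,
    phase: str,
    window_s: float,
) -> list[LabeledSegment]:
    """Cut each trial's phase window into contiguous non-overlapping segments.

    ``window_s`` must divide the phase duration; for each trial,
    ``phase_duration / window_s`` segments are emitted, covering the phase
    window exactly once.
    """
    wins = trials.windows(phase)
    segments: list[LabeledSegment] = []
    fs = recording.fs
    for _, row in wins.iterrows():
        dur = row.t1 - row.t0
        n_win = dur / window_s
        if abs(n_win - round(n_win)) > 1e-6:
            raise ValueError(
                f"window_s={window_s} does not divide the {dur:.3f} s {phase} phase"
            )
        n_win = int(round(n_win))
        for w in range(n_win):
            t0 = row.t0 + w * window_s
            i0 = sample_index(t0, fs)
            i1 = i0 + sample_index(window_s, fs)
            if i1 > recording.n_samples:
                raise ValueError(
                    f"segment [{t0:.3f}, {t0 + window_s:.3f}) s beyond recording end"
                )
            segments.append(
                LabeledSegment(
                    data=recording.data[:, i0:i1],
                    label="rest" if phase == "rest" else str(row["class"]),
                    phase=phase,
                    t0=t0,
                    fs=fs,
                )
            )
    return segments
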