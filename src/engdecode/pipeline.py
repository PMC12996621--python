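"""End-to-end assembly: recording -> preprocessed bands -> event tensors /
feature vectors ready for the decoders.

Decoding samples are non-overlapping 100 ms windows cut from the 2 s
movement window of every trial, labelled with the trial's movement class.
Event tensors are binned at 2.5 ms (40 steps per sample); conventional
features use two 50 ms sub-windows per channel (56 -> 112 dimensions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .baselines import build_feature_matrix
from .encoding import (
    EncoderParams,
    lif_events_recording,
    threshold_events_recording,
)
from .io import Recording, TrialTable, sample_index, segment_trials
from .preprocess import FilterSpec, preprocess_recording

__all__ = ["EncodedDataset", "build_event_dataset", "build_feature_dataset",
           "electrode_groups", "SAMPLE_S"]

SAMPLE_S = 0.1  # decoding sample length


@dataclass
class EncodedDataset:
    """Stacked decoding samples: X (n, steps, width), string labels."""

    X: np.ndarray
    labels: list[str]
    bin_s: float
    encoding: str
    class_names: list[str]

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def y(self) -> np.ndarray:
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels])


def _sample_windows(trials: TrialTable, window_s: float = SAMPLE_S):
    wins = trials.windows("movement")
    out = []
    for _, row in wins.iterrows():
        n = int(round((row.t1 - row.t0) / window_s))
        for w in range(n):
            out.append((row.t0 + w * window_s, str(row["class"])))
    return out


def build_event_dataset(
    recording: Recording,
    trials: TrialTable,
    encoding: str = "double",
    k: float = 3.5,
    params: EncoderParams | None = None,
    band: str = "eng",
    preprocessed: bool = False,
    notch: bool = True,
    filter_spec: FilterSpec | None = None,
) -> EncodedDataset:
    """Preprocess, encode the whole recording, and cut 100 ms samples.

    ``encoding`` is ``"thr"``, ``"lif"`` or ``"double"`` (threshold
    channels then LIF channels, width doubled).  Detection thresholds and
    LIF normalisation statistics are computed over the full trace.
    """
    if encoding not in ("thr", "lif", "double"):
        raise ValueError(f"unknown encoding {encoding!r}")
    params = params or EncoderParams()
    rec = (
        recording
        if preprocessed
        else preprocess_recording(recording, band=band, spec=filter_spec, notch=notch)
    )
    per_channel: list[np.ndarray] = []
    if encoding in ("thr", "double"):
        per_channel += threshold_events_recording(rec, k=k)
    if encoding in ("lif", "double"):
        per_channel += lif_events_recording(rec, params)

    samples = _sample_windows(trials)
    n_bins = int(round(SAMPLE_S / params.bin_s))
    t0s = np.array([t0 for t0, _ in samples])
    labels = [label for _, label in samples]
    edges = (t0s[:, None] + params.bin_s * np.arange(n_bins + 1)[None, :]).ravel()
    X = np.zeros((len(samples), n_bins, len(per_channel)), dtype=np.int64)
    for ci, times in enumerate(per_channel):
        idx = np.searchsorted(times, edges).reshape(len(samples), n_bins + 1)
        X[:, :, ci] = np.diff(idx, axis=1)
    return EncodedDataset(
        X=X,
        labels=labels,
        bin_s=params.bin_s,
        encoding=encoding,
        class_names=sorted(set(labels)),
    )


def build_feature_dataset(
    recording: Recording,
    trials: TrialTable,
    kind: str = "rms",
    k: float = 3.5,
    band: str = "eng",
    preprocessed: bool = False,
    notch: bool = True,
    filter_spec: FilterSpec | None = None,
):
    """100 ms samples as 112-dim conventional feature vectors.

    Returns (features (n, 2 * n_channels), labels list).
    """
    rec = (
        recording
        if preprocessed
        else preprocess_recording(recording, band=band, spec=filter_spec, notch=notch)
    )
    segments = segment_trials(rec, trials, "movement", SAMPLE_S)
    X = build_feature_matrix(segments, kind=kind, k=k)
    labels = [s.label for s in segments]
    return X, labels


def electrode_groups(recording: Recording) -> dict[int, np.ndarray]:
    """Electrode id -> base-channel row indices (14 sites per electrode)."""
    groups: dict[int, list[int]] = {}
    for i, ch in enumerate(recording.channels):
        groups.setdefault(ch.electrode_index, []).append(i)
    return {g: np.asarray(v) for g, v in groups.items()}
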