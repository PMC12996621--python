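"""Powerline notch and Butterworth band filtering of intraneural recordings.

Four signal variants are produced by 4th-order Butterworth band-pass
filters applied zero-phase (forward-backward):

====== =============== =========================================
name    band (Hz)       content
====== =============== =========================================
eng      250 - 7500     neural multi-unit band (default path)
imemg     50 -  350     inter-muscular EMG residual
eng_only 350 - 7500     neural band with the EMG range excluded
hybrid    50 - 7500     neural + muscular content
====== =============== =========================================

Powerline interference is removed beforehand by a cascade of IIR notch
biquads at every multiple of 50 Hz up to ``notch_max_hz`` (10 kHz by
default), each with quality factor Q = 100 (Q = centre / bandwidth).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import Recording

__all__ = ["FilterSpec", "BANDS", "notch_powerline", "bandpass", "preprocess_recording"]

#: named band-pass variants (low, high) in Hz
BANDS: dict[str, tuple[float, float]] = {
    "eng": (250.0, 7500.0),
    "imemg": (50.0, 350.0),
    "eng_only": (350.0, 7500.0),
    "hybrid": (50.0, 7500.0),
}


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass + powerline-notch specification."""

    band_name: str = "eng"
    low_hz: float | None = None
    high_hz: float | None = None
    order: int = 4
    notch_base_hz: float = 50.0
    notch_q: float = 100.0
    notch_max_hz: float = 10000.0

    def __post_init__(self):
        if self.band_name not in BANDS and (self.low_hz is None or self.high_hz is None):
            raise ValueError(
                f"unknown band {self.band_name!r}; known: {sorted(BANDS)}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"need 0 < low < high, got ({lo}, {hi})")

    @property
    def band(self) -> tuple[float, float]:
        if self.low_hz is not None and self.high_hz is not None:
            return (self.low_hz, self.high_hz)
        return BANDS[self.band_name]

    def with_band(self, name: str) -> "FilterSpec":
        return replace(self, band_name=name, low_hz=None, high_hz=None)


def _notch_sos(fs: float, spec: FilterSpec) -> np.ndarray | None:
    """Stack of second-order notch sections at powerline harmonics < fs/2."""
    top = min(spec.notch_max_hz, fs / 2 * (1 - 1e-6))
    freqs = np.arange(spec.notch_base_hz, top, spec.notch_base_hz)
    freqs = freqs[freqs < fs / 2]
    if freqs.size == 0:
        return None
    sections = []
    for f0 in freqs:
        b, a = signal.iirnotch(f0, spec.notch_q, fs=fs)
        sections.append(signal.tf2sos(b, a))
    return np.vstack(sections)


def _padlen(order: int) -> int:
    # reflect-padding of 3x the (effective) filter order
    return 3 * max(order, 8)


def notch_powerline(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Suppress 50 Hz powerline interference and its harmonics.

    Cascaded IIR notch biquads at 50, 100, ... Hz up to
    ``min(notch_max_hz, fs/2)``, Q = 100, applied zero-phase along the last
    axis.  If ``fs`` leaves no applicable harmonic a warning is emitted and
    the signal is returned unchanged.
    """
    spec = spec or FilterSpec()
    sos = _notch_sos(fs, spec)
    if sos is None:
        warnings.warn(f"fs={fs} Hz leaves no powerline harmonic to notch; identity")
        return np.asarray(x, dtype=float).copy()
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1,
                              padlen=min(_padlen(2 * len(sos)), np.shape(x)[-1] - 1))


def bandpass(x: np.ndarray, fs: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    The effective magnitude response of the forward-backward pass is the
    squared 4th-order Butterworth response (8th-order roll-off).
    """
    spec = spec or FilterSpec()
    lo, hi = spec.band
    if hi >= fs / 2:
        raise ValueError(f"high cutoff {hi} Hz >= Nyquist {fs / 2} Hz")
    sos = signal.butter(spec.order, [lo, hi], btype="band", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1,
                              padlen=min(_padlen(spec.order), np.shape(x)[-1] - 1))


def preprocess_recording(
    recording: Recording,
    band: str = "eng",
    spec: FilterSpec | None = None,
    notch: bool = True,
) -> Recording:
    """Notch (first) then band-pass every channel; returns a new Recording."""
    spec = (spec or FilterSpec()).with_band(band)
    # float32 output, per-channel float64 intermediates: bounded memory
    out = np.empty(recording.data.shape, dtype=np.float32)
    for i in range(recording.n_channels):
        x = recording.data[i]
        if notch:
            x = notch_powerline(x, recording.fs, spec)
        out[i] = bandpass(x, recording.fs, spec)
    return Recording(
        data=out,
        fs=recording.fs,
        channels=list(recording.channels),
        subject_id=recording.subject_id,
    )
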