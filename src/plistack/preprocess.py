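"""Preprocessing: broadband filtering, baseline correction, down-sampling,
non-overlapping windowing and rhythm-band extraction.

The fixed stage order is::

    bandpass(4-30 Hz) -> baseline_correct -> downsample(125 Hz)
        -> segment(window_length) -> extract_band(per rhythm)

All filters are 4th-order Butterworth applied forward-backward
(zero-phase), so filtering introduces no phase shift that could masquerade
as a phase lag downstream.  Band extraction runs per window, after
segmentation, keeping windows fully independent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal as sps

from .montage import BandDefinition, CANONICAL_BANDS
from .recording import EEGRecording

DEFAULT_BROADBAND = (4.0, 30.0)
DEFAULT_TARGET_RATE = 125.0
DEFAULT_WINDOW_LENGTHS = (2, 4, 6, 8, 10, 12, 14, 16)
FILTER_ORDER = 4

#: Optional artifact-removal hook applied after down-sampling; identity by
#: default (synthetic recordings are artifact-free).  A real-data pipeline
#: can install e.g. an ICA-based cleaner here.
ArtifactHook = Callable[[EEGRecording], EEGRecording]


@dataclass
class Window:
    """One non-overlapping window of a (down-sampled, broadband) recording."""

    samples: np.ndarray  # channels x time
    rate: float
    window_length: float
    window_index: int
    subject_id: str
    group: str
    montage: tuple[str, ...]


@dataclass
class BandEpoch:
    """A window narrowband-filtered to one rhythm."""

    samples: np.ndarray
    rate: float
    band: BandDefinition
    window_length: float
    window_index: int
    subject_id: str
    group: str
    montage: tuple[str, ...]


def bandpass(recording: EEGRecording, low: float, high: float,
             order: int = FILTER_ORDER) -> EEGRecording:
    """Zero-phase Butterworth band-pass, per channel, length preserved."""
    nyq = recording.rate / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band ({low}, {high}) Hz outside (0, {nyq}) Hz")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=recording.rate,
                     output="sos")
    filtered = sps.sosfiltfilt(sos, recording.samples, axis=1)
    return recording.copy_with(filtered)


def baseline_correct(recording: EEGRecording) -> EEGRecording:
    """Remove per-channel linear trend and mean (baseline drift)."""
    corrected = sps.detrend(recording.samples, axis=1, type="linear")
    return recording.copy_with(corrected)


def downsample(recording: EEGRecording, target_rate: float = DEFAULT_TARGET_RATE
               ) -> EEGRecording:
    """Anti-alias low-pass then decimate to ``target_rate``.

    The decimation factor must be an integer (250 -> 125 Hz is factor 2).
    """
    factor = recording.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"rate {recording.rate} not an integer multiple of {target_rate}"
        )
    q = int(round(factor))
    if q == 1:
        return recording.copy_with(recording.samples.copy())
    out = sps.decimate(recording.samples, q, axis=1, zero_phase=True)
    return recording.copy_with(out, rate=target_rate)


def segment(recording: EEGRecording, window_length: float) -> list[Window]:
    """Split into floor(duration/window_length) non-overlapping windows.

    The trailing remainder that does not fill a whole window is dropped.
    """
    per_window = int(round(window_length * recording.rate))
    if per_window > recording.n_times:
        raise ValueError(
            f"window of {window_length} s longer than recording "
            f"({recording.duration:.1f} s)"
        )
    n_windows = recording.n_times // per_window
    return [
        Window(
            samples=recording.samples[:, i * per_window:(i + 1) * per_window].copy(),
            rate=recording.rate,
            window_length=window_length,
            window_index=i,
            subject_id=recording.subject_id,
            group=recording.group,
            montage=recording.montage,
        )
        for i in range(n_windows)
    ]


def extract_band(window: Window, band: BandDefinition,
                 order: int = FILTER_ORDER) -> BandEpoch:
    """Narrowband-filter one window to one rhythm (zero-phase)."""
    nyq = window.rate / 2.0
    if not (0 < band.low < band.high < nyq):
        raise ValueError(f"band {band.name} outside (0, {nyq}) Hz at rate "
                         f"{window.rate}")
    sos = sps.butter(order, [band.low, band.high], btype="bandpass",
                     fs=window.rate, output="sos")
    filtered = sps.sosfiltfilt(sos, window.samples, axis=1)
    return BandEpoch(
        samples=filtered,
        rate=window.rate,
        band=band,
        window_length=window.window_length,
        window_index=window.window_index,
        subject_id=window.subject_id,
        group=window.group,
        montage=window.montage,
    )


def preprocess_recording(
    recording: EEGRecording,
    window_length: float,
    bands: Sequence[BandDefinition] = CANONICAL_BANDS,
    broadband: tuple[float, float] = DEFAULT_BROADBAND,
    target_rate: float = DEFAULT_TARGET_RATE,
    artifact_hook: ArtifactHook | None = None,
) -> list[dict[str, BandEpoch]]:
    """Run the full fixed-order preprocessing chain on one recording.

    Returns one dict per window mapping band name -> :class:`BandEpoch`.
    """
    rec = bandpass(recording, *broadband)
    rec = baseline_correct(rec)
    rec = downsample(rec, target_rate)
    if artifact_hook is not None:
        rec = artifact_hook(rec)
    windows = segment(rec, window_length)
    return [{b.name: extract_band(w, b) for b in bands} for w in windows]
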