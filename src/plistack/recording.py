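"""Continuous multichannel EEG recording container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .montage import DEFAULT_MONTAGE


@dataclass
class EEGRecording:
    """A continuous multichannel scalp recording.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    rate : float
        Sampling frequency in Hz.
    montage : tuple of str
        Ordered channel names; length must equal ``samples.shape[0]``.
    subject_id : str
    group : str
        Cohort label ("HC", "GAD" or "DD" for the default templates).
    """

    samples: np.ndarray
    rate: float
    montage: tuple[str, ...] = DEFAULT_MONTAGE
    subject_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.shape[0] != len(self.montage):
            raise ValueError(
                f"channel count {self.samples.shape[0]} does not match montage "
                f"length {len(self.montage)}"
            )
        if self.samples.shape[1] == 0:
            raise ValueError("recording has zero duration")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_times / self.rate

    def copy_with(self, samples: np.ndarray, rate: float | None = None) -> "EEGRecording":
        return EEGRecording(
            samples=samples,
            rate=self.rate if rate is None else rate,
            montage=self.montage,
            subject_id=self.subject_id,
            group=self.group,
            meta=dict(self.meta),
        )
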