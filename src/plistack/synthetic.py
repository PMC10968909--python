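"""Synthetic three-group EEG cohort generator with planted phase coupling.

Each subject is simulated as a 16-channel 10-20 recording containing, per
rhythm band, a narrowband Gaussian oscillation per channel plus pink
broadband noise.  A :class:`CouplingEdge` plants a *shared* narrowband
oscillator into two channels: channel B receives the same analytic signal
rotated by a constant phase lag plus slowly varying Gaussian phase jitter.
With zero jitter and full mixing strength the phase difference between the
two channels is exactly the configured lag, so the downstream phase lag
index is analytically controlled (1 for any lag other than 0 or π);
increasing jitter or lowering strength degrades it smoothly.

Group templates differ in which edges exist and how strong they are; the
defaults plant the strongest group differences in beta-band frontal edges,
with milder alpha-band perturbations, so that feature selection and
classification have a known ground truth.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .montage import BAND_NAMES, DEFAULT_MONTAGE, band_by_name
from .recording import EEGRecording

DEFAULT_RATE = 250.0
DEFAULT_DURATION = 600.0

#: Per-band background oscillation amplitudes (µV), eyes-closed-like:
#: alpha dominant, beta weakest.
DEFAULT_BAND_AMPLITUDES: dict[str, float] = {
    "theta": 4.0,
    "alpha1": 6.0,
    "alpha2": 5.0,
    "beta": 3.0,
}


@dataclass(frozen=True)
class CouplingEdge:
    """A planted phase-coupled channel pair in one rhythm band.

    ``lag`` is the constant phase offset (radians, channel A leading) and
    ``jitter_sd`` the standard deviation of slowly varying Gaussian phase
    noise added on top of it.  ``strength`` in [0, 1] mixes the shared
    oscillator against each channel's independent band background.
    """

    channel_a: str
    channel_b: str
    band: str
    lag: float
    strength: float
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.channel_a == self.channel_b:
            raise ValueError("coupling edge endpoints must differ")
        if self.band not in BAND_NAMES:
            raise ValueError(f"unknown band {self.band!r}")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")
        if not (-np.pi < self.lag <= np.pi):
            raise ValueError("lag must lie in (-pi, pi]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.channel_a, self.channel_b)))


@dataclass
class CohortTemplate:
    """Ground-truth generating conditions for one subject group."""

    group: str
    edges: tuple[CouplingEdge, ...] = ()
    n_subjects: int = 1
    noise_sd: float = 2.0
    band_amplitudes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BAND_AMPLITUDES)
    )
    duration: float = DEFAULT_DURATION
    rate: float = DEFAULT_RATE
    montage: tuple[str, ...] = DEFAULT_MONTAGE

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        seen: set[tuple[tuple[str, str], str]] = set()
        for e in self.edges:
            key = (e.pair, e.band)
            if key in seen:
                raise ValueError(
                    f"duplicate coupling edge for pair {e.pair} in band {e.band}"
                )
            seen.add(key)
            for ch in (e.channel_a, e.channel_b):
                if ch not in self.montage:
                    raise ValueError(f"edge channel {ch!r} not in montage")

    def to_json(self) -> str:
        d = asdict(self)
        d["edges"] = [asdict(e) for e in self.edges]
        d["montage"] = list(self.montage)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortTemplate":
        d = json.loads(text)
        d["edges"] = tuple(CouplingEdge(**e) for e in d["edges"])
        d["montage"] = tuple(d["montage"])
        return cls(**d)


# ---------------------------------------------------------------------------
# signal building blocks


def _narrowband_analytic(rng: np.random.Generator, band_name: str, n: int,
                         rate: float) -> np.ndarray:
    """Unit-RMS analytic narrowband Gaussian process (background content)."""
    band = band_by_name(band_name)
    white = rng.standard_normal(n)
    sos = sps.butter(4, [band.low, band.high], btype="bandpass", fs=rate, output="sos")
    narrow = sps.sosfiltfilt(sos, white)
    rms = np.sqrt(np.mean(narrow**2))
    if rms > 0:
        narrow = narrow / rms
    return sps.hilbert(narrow)


def _smooth_unit_noise(rng: np.random.Generator, n: int, rate: float,
                       cutoff: float) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = sps.butter(2, cutoff, btype="lowpass", fs=rate, output="sos")
    slow = sps.sosfiltfilt(sos, white)
    s = slow.std()
    return slow / s if s > 0 else slow


def _shared_oscillator(rng: np.random.Generator, band_name: str, n: int,
                       rate: float) -> np.ndarray:
    """Unit-RMS analytic oscillator for a coupled edge.

    A narrowband random-FM process: instantaneous frequency wanders slowly
    inside the band around its center, and the envelope is modulated but
    bounded away from zero.  Unlike a filtered-Gaussian process, the
    envelope never fades to zero, so the instantaneous phase stays
    well defined throughout and a constant planted lag survives windowed
    analytic-phase extraction exactly.
    """
    band = band_by_name(band_name)
    width = band.high - band.low
    f_dev = _smooth_unit_noise(rng, n, rate, cutoff=max(0.5, width / 8.0))
    f_inst = band.center + (width / 6.0) * f_dev
    phase = 2.0 * np.pi * (np.cumsum(f_inst) / rate + rng.uniform())
    envelope = 1.0 + 0.35 * _smooth_unit_noise(rng, n, rate, cutoff=1.0)
    envelope = np.clip(envelope, 0.3, None)
    z = envelope * np.exp(1j * phase)
    return z / np.sqrt(np.mean(z.real**2))


def _slow_phase_jitter(rng: np.random.Generator, sd: float, n: int,
                       rate: float, cutoff: float = 0.5) -> np.ndarray:
    """Slowly varying Gaussian phase noise with marginal standard deviation sd."""
    if sd == 0.0:
        return np.zeros(n)
    return sd * _smooth_unit_noise(rng, n, rate, cutoff)


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1]  # avoid division by zero at DC
    spec = spec / np.sqrt(freqs)
    x = np.fft.irfft(spec, n=n)
    return (x - x.mean()) / x.std()


def _subject_rng(template: CohortTemplate, subject_index: int, seed: int
                 ) -> np.random.Generator:
    group_code = zlib.crc32(template.group.encode()) % (2**31)
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), group_code, int(subject_index)])
    )


# ---------------------------------------------------------------------------
# generation


def generate_subject(template: CohortTemplate, subject_index: int, seed: int
                     ) -> EEGRecording:
    """Simulate one subject's recording from a cohort template.

    Deterministic given ``(template, subject_index, seed)``: the random
    stream is keyed on the seed, group name and subject index.
    """
    rng = _subject_rng(template, subject_index, seed)
    n = int(round(template.duration * template.rate))
    montage = template.montage
    ch_index = {ch: i for i, ch in enumerate(montage)}
    data = np.zeros((len(montage), n))

    # total shared-power fraction per (channel, band), to scale independent
    # background so band power stays comparable across channels
    strength_sq: dict[tuple[str, str], float] = {}
    for e in template.edges:
        for ch in (e.channel_a, e.channel_b):
            key = (ch, e.band)
            strength_sq[key] = strength_sq.get(key, 0.0) + e.strength**2

    for band_name in BAND_NAMES:
        amp = template.band_amplitudes.get(band_name, 0.0)
        if amp == 0.0:
            continue
        for ch in montage:
            w = np.sqrt(max(0.0, 1.0 - strength_sq.get((ch, band_name), 0.0)))
            if w == 0.0:
                continue
            z = _narrowband_analytic(rng, band_name, n, template.rate)
            data[ch_index[ch]] += amp * w * z.real

    for e in template.edges:
        amp = template.band_amplitudes.get(e.band, 0.0)
        z = _shared_oscillator(rng, e.band, n, template.rate)
        jitter = _slow_phase_jitter(rng, e.jitter_sd, n, template.rate)
        data[ch_index[e.channel_a]] += amp * e.strength * z.real
        # channel B lags channel A by `lag` (plus jitter): phase_b = phase_a - lag + jitter
        rotated = z * np.exp(1j * (jitter - e.lag))
        data[ch_index[e.channel_b]] += amp * e.strength * rotated.real

    if template.noise_sd > 0:
        for i in range(len(montage)):
            data[i] += template.noise_sd * _pink_noise(rng, n)

    return EEGRecording(
        samples=data,
        rate=template.rate,
        montage=montage,
        subject_id=f"{template.group}{subject_index:03d}",
        group=template.group,
    )


def generate_cohort(templates: Sequence[CohortTemplate], seed: int
                    ) -> list[EEGRecording]:
    """Simulate all subjects of all group templates, deterministically.

    Per-subject random streams are derived from the master seed, the group
    name and the subject index, so cohorts are reproducible and individual
    subjects can be regenerated in isolation.
    """
    if len(templates) == 0:
        raise ValueError("no cohort templates given")
    if len({t.group for t in templates}) < 2:
        raise ValueError("cohort generation requires at least two distinct groups")
    recordings = []
    for template in templates:
        for i in range(template.n_subjects):
            recordings.append(generate_subject(template, i, seed))
    return recordings


# ---------------------------------------------------------------------------
# default study templates


def default_templates(
    n_subjects: tuple[int, int, int] = (38, 45, 42),
    duration: float = DEFAULT_DURATION,
    noise_sd: float = 2.0,
    jitter_sd: float = 0.9,
) -> tuple[CohortTemplate, CohortTemplate, CohortTemplate]:
    """Default HC / GAD / DD templates.

    HC carries a baseline edge set; GAD strengthens and adds beta-band
    frontal edges; DD adds a distinct set of beta frontal edges; both
    patient groups also perturb one alpha edge.  Group sizes default to
    38 / 45 / 42 subjects.
    """

    def edge(a: str, b: str, band: str, lag: float, strength: float,
             jit: float | None = None) -> CouplingEdge:
        return CouplingEdge(a, b, band, lag=lag, strength=strength,
                            jitter_sd=jitter_sd if jit is None else jit)

    hc_edges = (
        edge("Fp1", "Fp2", "theta", 0.9, 0.50),
        edge("O1", "O2", "alpha1", 1.1, 0.60),
        edge("P3", "P4", "alpha2", 1.0, 0.60),
        edge("F3", "F4", "beta", 1.2, 0.30),
        edge("C3", "C4", "beta", 0.8, 0.30),
    )
    gad_edges = (
        edge("Fp1", "Fp2", "theta", 0.9, 0.50),
        edge("O1", "O2", "alpha1", 1.1, 0.35),   # weakened occipital alpha
        edge("P3", "P4", "alpha2", 1.0, 0.60),
        edge("F3", "F4", "beta", 1.2, 0.80),     # strengthened frontal beta
        edge("C3", "C4", "beta", 0.8, 0.30),
        edge("Fp1", "F7", "beta", 1.0, 0.70),    # added frontal beta edges
        edge("Fp2", "F8", "beta", 1.0, 0.70),
    )
    dd_edges = (
        edge("Fp1", "Fp2", "theta", 0.9, 0.50),
        edge("O1", "O2", "alpha1", 1.1, 0.60),
        edge("P3", "P4", "alpha2", 1.0, 0.35),   # weakened parietal alpha
        edge("F3", "F4", "beta", 1.2, 0.55),
        edge("C3", "C4", "beta", 0.8, 0.30),
        edge("Fp1", "F3", "beta", 1.0, 0.70),    # distinct frontal beta edges
        edge("F7", "F8", "beta", 1.3, 0.70),
    )
    mk = lambda group, edges, ns: CohortTemplate(
        group=group, edges=edges, n_subjects=ns,
        noise_sd=noise_sd, duration=duration,
    )
    return (
        mk("HC", hc_edges, n_subjects[0]),
        mk("GAD", gad_edges, n_subjects[1]),
        mk("DD", dd_edges, n_subjects[2]),
    )
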