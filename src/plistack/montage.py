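"""Electrode montage, rhythm bands and brain-region segmentation.

The recordings use a 16-channel subset of the international 10-20 system
referenced to the earlobes.  Channels are grouped into the five classical
scalp regions (frontal, central, temporal, parietal, occipital) for the
network-level summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Ordered 16-channel 10-20 montage used throughout the package.
DEFAULT_MONTAGE: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8",
    "C3", "C4", "T3", "T4", "T5", "T6",
    "P3", "P4", "O1", "O2",
)

#: Scalp-region assignment for every montage channel.
DEFAULT_REGION_MAP: dict[str, str] = {
    "Fp1": "frontal", "Fp2": "frontal", "F3": "frontal", "F4": "frontal",
    "F7": "frontal", "F8": "frontal",
    "C3": "central", "C4": "central",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "P3": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
}

REGIONS: tuple[str, ...] = ("frontal", "temporal", "parietal", "occipital", "central")


@dataclass(frozen=True)
class BandDefinition:
    """A named rhythm band with its frequency range in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low < self.high):
            raise ValueError(f"invalid band {self.name}: ({self.low}, {self.high}) Hz")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: Canonical rhythm bands, in feature-vector order.
CANONICAL_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha1", 8.0, 10.0),
    BandDefinition("alpha2", 10.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in CANONICAL_BANDS)

GROUPS: tuple[str, ...] = ("HC", "GAD", "DD")


def band_by_name(name: str) -> BandDefinition:
    for band in CANONICAL_BANDS:
        if band.name == name:
            return band
    raise KeyError(f"unknown rhythm band: {name!r}")


def validate_region_map(region_map: dict[str, str], montage: tuple[str, ...]) -> None:
    """Every montage channel must map to exactly one known region."""
    missing = [ch for ch in montage if ch not in region_map]
    if missing:
        raise ValueError(f"channels without region assignment: {missing}")
    bad = {ch: r for ch, r in region_map.items() if r not in REGIONS}
    if bad:
        raise ValueError(f"unknown regions in map: {bad}")
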