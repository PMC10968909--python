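"""European Data Format (EDF) input/output.

Writing uses a minimal EDF encoder (16-bit samples, one-second data
records) sufficient for continuous resting-state recordings; reading goes
through MNE's EDF reader so that files written here interoperate with the
wider EEG toolchain.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable

import numpy as np

from .recording import EEGRecording

_HEADER_FIELDS = 256  # bytes in the fixed part of an EDF header


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a 16-bit EDF file.

    Samples are stored in one-second data records; a trailing partial
    second is zero-padded (the true length in samples is recoverable from
    the physical signal, and the generator always produces whole seconds).
    """
    path = Path(path)
    rate = recording.rate
    if abs(rate - round(rate)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(rate))  # samples per one-second record
    n_ch = recording.n_channels
    n_records = int(np.ceil(recording.n_times / spr))

    data = np.zeros((n_ch, n_records * spr), dtype=np.float64)
    data[:, : recording.n_times] = recording.samples

    # per-channel symmetric physical range covering the data
    phys_max = np.maximum(np.abs(data).max(axis=1), 1.0)
    dig_min, dig_max = -32768, 32767
    scale = phys_max / dig_max
    digital = np.clip(np.round(data / scale[:, None]), dig_min, dig_max).astype("<i2")

    header_bytes = _HEADER_FIELDS * (1 + n_ch)
    with open(path, "wb") as fh:
        fh.write(_ascii("0", 8))
        fh.write(_ascii(f"{recording.subject_id} {recording.group}".strip() or "X", 80))
        fh.write(_ascii("Startdate 01-JAN-2000 synthetic resting-state", 80))
        fh.write(_ascii("01.01.00", 8))
        fh.write(_ascii("00.00.00", 8))
        fh.write(_ascii(str(header_bytes), 8))
        fh.write(_ascii("", 44))
        fh.write(_ascii(str(n_records), 8))
        fh.write(_ascii("1", 8))  # record duration: 1 s
        fh.write(_ascii(str(n_ch), 4))

        for ch in recording.montage:
            fh.write(_ascii(f"EEG {ch}", 16))
        for _ in range(n_ch):
            fh.write(_ascii("AgAgCl electrode", 80))
        for _ in range(n_ch):
            fh.write(_ascii("uV", 8))
        for pm in phys_max:
            fh.write(_ascii(f"{-pm:.6g}"[:8], 8))
        for pm in phys_max:
            fh.write(_ascii(f"{pm:.6g}"[:8], 8))
        for _ in range(n_ch):
            fh.write(_ascii(str(dig_min), 8))
        for _ in range(n_ch):
            fh.write(_ascii(str(dig_max), 8))
        for _ in range(n_ch):
            fh.write(_ascii("", 80))
        for _ in range(n_ch):
            fh.write(_ascii(str(spr), 8))
        for _ in range(n_ch):
            fh.write(_ascii("", 32))

        # data records: per record, all channels consecutively
        for rec in range(n_records):
            block = digital[:, rec * spr : (rec + 1) * spr]
            fh.write(block.tobytes())
    return path


def read_edf(path: str | Path, subject_id: str = "", group: str = "") -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (samples in µV)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    montage = tuple(ch.removeprefix("EEG ").strip() for ch in raw.ch_names)
    samples = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EEGRecording(
        samples=samples,
        rate=float(raw.info["sfreq"]),
        montage=montage,
        subject_id=subject_id or Path(path).stem,
        group=group,
    )


def write_cohort(
    recordings: Iterable[EEGRecording], out_dir: str | Path
) -> tuple[list[Path], Path]:
    """Write one EDF per subject plus a tab-separated labels manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    manifest = out_dir / "labels.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", "group"])
        for rec in recordings:
            p = write_edf(rec, out_dir / f"{rec.subject_id}.edf")
            paths.append(p)
            writer.writerow([rec.subject_id, rec.group])
    return paths, manifest


def read_cohort(edf_dir: str | Path) -> list[EEGRecording]:
    """Read every EDF listed in the ``labels.tsv`` manifest of a directory."""
    edf_dir = Path(edf_dir)
    manifest = edf_dir / "labels.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"labels manifest not found: {manifest}")
    recordings = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rec = read_edf(
                edf_dir / f"{row['subject_id']}.edf",
                subject_id=row["subject_id"],
                group=row["group"],
            )
            recordings.append(rec)
    return recordings
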