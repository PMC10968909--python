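"""Phase lag index (PLI) connectivity features.

For two narrowband signals the analytic signal Z(t) = S(t) + j·HT(S(t))
yields the instantaneous phase; the per-sample phase difference is the
argument of Z1·Z2* and the PLI is

    PLI = | mean_t sign(Δφ(t)) |  ∈ [0, 1]

A PLI of 1 indicates a perfectly consistent non-zero phase lag; 0 means no
consistent lag.  Exact zero phase differences (sign 0) contribute nothing,
so a channel against itself has PLI 0, and zero-lag (volume-conduction-
like) coupling is discounted by construction.

A 16-channel window yields 16·15/2 = 120 pair features per rhythm band and
4·120 = 480 features per window, ordered band-major (theta, alpha1,
alpha2, beta) and, within a band, by upper-triangle row-major montage
index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .montage import BAND_NAMES, DEFAULT_MONTAGE
from .preprocess import BandEpoch


def analytic_phase(signal: np.ndarray) -> np.ndarray:
    """Instantaneous phase (radians, in (-π, π]) of a narrowband signal.

    An all-zero signal has undefined phase; it is flagged with a warning
    and returns NaN phases, which downstream PLI maps to 0.
    """
    x = np.asarray(signal, dtype=np.float64)
    if x.shape[-1] < 2:
        raise ValueError("signal too short for analytic phase")
    if not np.any(x):
        warnings.warn("all-zero signal: instantaneous phase undefined",
                      RuntimeWarning, stacklevel=2)
        return np.full(x.shape, np.nan)
    return np.angle(hilbert(x, axis=-1))


def phase_difference(pa: np.ndarray, pb: np.ndarray) -> np.ndarray:
    """Per-sample phase difference pa - pb wrapped into (-π, π]."""
    pa = np.asarray(pa)
    pb = np.asarray(pb)
    if pa.shape != pb.shape:
        raise ValueError("phase series length mismatch")
    d = pa - pb
    # wrap into (-pi, pi]
    return np.pi - np.mod(np.pi - d, 2.0 * np.pi)


def _trim_slice(n: int, edge_trim: float) -> slice:
    t = int(n * edge_trim)
    return slice(t, n - t) if t > 0 else slice(None)


def pli_signed(sa: np.ndarray, sb: np.ndarray, edge_trim: float = 0.0) -> float:
    """Signed mean of sign(Δφ): diagnostic companion of :func:`pli`.

    ``edge_trim`` drops that fraction of samples at each window end before
    averaging (the analytic signal of a finite window is least reliable at
    its first/last few samples); 0 keeps everything.
    """
    pa = analytic_phase(sa)
    pb = analytic_phase(sb)
    if np.isnan(pa).any() or np.isnan(pb).any():
        return 0.0
    d = phase_difference(pa, pb)[_trim_slice(len(pa), edge_trim)]
    return float(np.mean(np.sign(d)))


def pli(sa: np.ndarray, sb: np.ndarray, edge_trim: float = 0.0) -> float:
    """Phase lag index between two equal-length narrowband epochs."""
    return abs(pli_signed(sa, sb, edge_trim))


@dataclass
class ConnectivityMatrix:
    """Symmetric 16x16 PLI matrix for one band epoch."""

    band: str
    values: np.ndarray
    montage: tuple[str, ...]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.montage):
            raise ValueError("matrix shape does not match montage")


def _epoch_phases(epoch_samples: np.ndarray) -> np.ndarray:
    """Analytic phases for all channels at once; NaN rows for zero channels."""
    x = np.asarray(epoch_samples, dtype=np.float64)
    phases = np.angle(hilbert(x, axis=-1))
    zero_rows = ~np.any(x, axis=-1)
    if zero_rows.any():
        warnings.warn("all-zero channel(s): PLI set to 0 for their pairs",
                      RuntimeWarning, stacklevel=2)
        phases[zero_rows] = np.nan
    return phases


def connectivity_matrix(epoch: BandEpoch, edge_trim: float = 0.0
                        ) -> ConnectivityMatrix:
    """All-pairs PLI for one band epoch (vectorized over channel pairs)."""
    x = epoch.samples
    if x.shape[0] < 2:
        raise ValueError("need at least two channels")
    z = hilbert(np.asarray(x, dtype=np.float64), axis=-1)
    z = z[:, _trim_slice(z.shape[1], edge_trim)]
    zero_rows = ~np.any(x, axis=-1)
    # sign(Δφ) == sign(Im(Z_a Z_b*)) — avoids explicit angle computation
    cross_im = np.einsum("it,jt->ijt", z.imag, z.real) - np.einsum(
        "it,jt->ijt", z.real, z.imag)
    out = np.abs(np.mean(np.sign(cross_im), axis=-1))
    np.fill_diagonal(out, 0.0)
    if zero_rows.any():
        warnings.warn("all-zero channel(s): PLI set to 0 for their pairs",
                      RuntimeWarning, stacklevel=2)
        out[zero_rows, :] = 0.0
        out[:, zero_rows] = 0.0
    return ConnectivityMatrix(band=epoch.band.name, values=out,
                              montage=epoch.montage)


# ---------------------------------------------------------------------------
# canonical feature ordering


def feature_names(montage: Sequence[str] = DEFAULT_MONTAGE,
                  bands: Sequence[str] = BAND_NAMES) -> list[str]:
    """Canonical 480 feature names ``band__chA__chB``, band-major, pairs
    upper-triangle row-major by montage index."""
    names = []
    for band in bands:
        for i in range(len(montage)):
            for j in range(i + 1, len(montage)):
                names.append(f"{band}__{montage[i]}__{montage[j]}")
    return names


def feature_vector(epochs: Mapping[str, BandEpoch], edge_trim: float = 0.0
                   ) -> np.ndarray:
    """Assemble the 480-dimensional PLI vector for one window.

    ``epochs`` must contain exactly the four canonical bands.
    """
    if set(epochs) != set(BAND_NAMES):
        missing = set(BAND_NAMES) - set(epochs)
        extra = set(epochs) - set(BAND_NAMES)
        raise ValueError(f"need exactly bands {BAND_NAMES}; missing={missing}, "
                         f"unexpected={extra}")
    parts = []
    for band in BAND_NAMES:
        mat = connectivity_matrix(epochs[band], edge_trim).values
        iu = np.triu_indices(mat.shape[0], k=1)
        parts.append(mat[iu])
    return np.concatenate(parts)


def feature_table(per_window_epochs: Iterable[Mapping[str, BandEpoch]]
                  ) -> pd.DataFrame:
    """PLI feature table: one row per window, 480 named feature columns
    plus subject_id / group / window_length / window_index metadata."""
    rows = []
    meta = []
    names = None
    for epochs in per_window_epochs:
        any_epoch = next(iter(epochs.values()))
        if names is None:
            names = feature_names(any_epoch.montage)
        rows.append(feature_vector(epochs))
        meta.append(
            (any_epoch.subject_id, any_epoch.group, any_epoch.window_length,
             any_epoch.window_index)
        )
    if not rows:
        raise ValueError("no windows given")
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "window_index", [m[3] for m in meta])
    df.insert(0, "window_length", [m[2] for m in meta])
    df.insert(0, "group", [m[1] for m in meta])
    df.insert(0, "subject_id", [m[0] for m in meta])
    return df


META_COLUMNS = ("subject_id", "group", "window_length", "window_index")


def split_feature_table(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, feature_names)."""
    cols = [c for c in df.columns if c not in META_COLUMNS]
    return df[cols].to_numpy(dtype=np.float64), df["group"].to_numpy(), cols
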