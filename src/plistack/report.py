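"""Network-level reporting: decode selected features back to electrode-pair
edges, count key edges per rhythm, and summarize mean connection strength
per brain region and group."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .montage import BAND_NAMES, DEFAULT_MONTAGE, DEFAULT_REGION_MAP, \
    validate_region_map
from .connectivity import feature_names


@dataclass(frozen=True)
class Edge:
    band: str
    channel_a: str
    channel_b: str


def decode_feature(feature_id: int,
                   montage: Sequence[str] = DEFAULT_MONTAGE) -> Edge:
    """Inverse of the canonical (band-major, upper-triangle row-major)
    feature ordering: id -> (band, channel_a, channel_b)."""
    n_ch = len(montage)
    n_pairs = n_ch * (n_ch - 1) // 2
    d = n_pairs * len(BAND_NAMES)
    if not 0 <= feature_id < d:
        raise ValueError(f"feature id {feature_id} out of range [0, {d})")
    band = BAND_NAMES[feature_id // n_pairs]
    k = feature_id % n_pairs
    # walk the upper-triangle row lengths
    i = 0
    row_len = n_ch - 1
    while k >= row_len:
        k -= row_len
        i += 1
        row_len -= 1
    j = i + 1 + k
    return Edge(band, montage[i], montage[j])


def decode_features(feature_ids: Iterable[int],
                    montage: Sequence[str] = DEFAULT_MONTAGE) -> list[Edge]:
    return [decode_feature(int(f), montage) for f in feature_ids]


def count_per_rhythm(feature_ids: Iterable[int],
                     montage: Sequence[str] = DEFAULT_MONTAGE
                     ) -> dict[str, int]:
    """How many selected features fall in each rhythm band."""
    counts = {b: 0 for b in BAND_NAMES}
    for edge in decode_features(feature_ids, montage):
        counts[edge.band] += 1
    return counts


def region_strength(
    feature_ids: Iterable[int],
    feature_table: pd.DataFrame,
    region_map: Mapping[str, str] | None = None,
    montage: Sequence[str] = DEFAULT_MONTAGE,
) -> pd.DataFrame:
    """Mean PLI of the selected (key) edges per (region, rhythm, group).

    Each selected edge's group-mean PLI contributes to the regions of both
    endpoints (once only, if both endpoints share a region).  Regions with
    no contributing edge in a rhythm are absent from the table rather than
    reported as zero.
    """
    region_map = dict(region_map or DEFAULT_REGION_MAP)
    validate_region_map(region_map, tuple(montage))
    names = feature_names(montage)
    groups = sorted(feature_table["group"].unique())
    if not groups:
        raise ValueError("empty feature table")
    edges = decode_features(feature_ids, montage)

    acc: dict[tuple[str, str, str], list[float]] = {}
    group_tables = {g: feature_table[feature_table["group"] == g] for g in groups}
    for fid, edge in zip(feature_ids, edges):
        col = names[int(fid)]
        regions = {region_map[edge.channel_a], region_map[edge.channel_b]}
        for g in groups:
            mean_pli = float(group_tables[g][col].mean())
            for region in regions:
                acc.setdefault((region, edge.band, g), []).append(mean_pli)

    rows = [
        {"region": r, "rhythm": b, "group": g,
         "mean_pli": float(np.mean(vals)), "n_edges": len(vals)}
        for (r, b, g), vals in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["region", "rhythm", "group",
                                       "mean_pli", "n_edges"])


def edge_list(feature_ids: Iterable[int], feature_table: pd.DataFrame,
              montage: Sequence[str] = DEFAULT_MONTAGE) -> pd.DataFrame:
    """Plain-text edge list: rhythm, chA, chB and per-group mean PLI."""
    names = feature_names(montage)
    groups = sorted(feature_table["group"].unique())
    rows = []
    for fid in feature_ids:
        edge = decode_feature(int(fid), montage)
        row = {"rhythm": edge.band, "channel_a": edge.channel_a,
               "channel_b": edge.channel_b}
        for g in groups:
            sub = feature_table[feature_table["group"] == g]
            row[f"mean_pli_{g}"] = float(sub[names[int(fid)]].mean())
        rows.append(row)
    return pd.DataFrame(rows)
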