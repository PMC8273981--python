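"""Fixed-size window tracks on chromosome coordinates.

Windows tile each chromosome at a fixed size (0-based half-open); the ragged
last window is kept. A track carries one numeric value per window plus the
number of variants (or other items) that informed it; ``NaN`` marks missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def tile_windows(chrom_lengths: dict[str, int], size: int) -> pd.DataFrame:
    """Tile every chromosome with windows of ``size`` bp (ragged last window kept)."""
    if size <= 0:
        raise ValueError("window size must be positive")
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, size, dtype=np.int64)
        ends = np.minimum(starts + size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class WindowTrack:
    """Per-window values over tiling windows.

    ``df`` columns: chrom, start, end, value, n_variants.
    """

    df: pd.DataFrame
    window_size: int = 0

    def __post_init__(self):
        required = {"chrom", "start", "end", "value"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"WindowTrack missing columns: {sorted(missing)}")
        if "n_variants" not in self.df.columns:
            self.df = self.df.assign(n_variants=0)

    def on(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df.chrom == chrom].reset_index(drop=True)

    def values_in(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Windows overlapping [start, end) on ``chrom``."""
        d = self.df
        m = (d.chrom == chrom) & (d.end > start) & (d.start < end)
        return d[m].reset_index(drop=True)

    def to_bedgraph(self, path) -> None:
        d = self.df.dropna(subset=["value"])
        d[["chrom", "start", "end", "value"]].to_csv(
            path, sep="\t", header=False, index=False, float_format="%.6g"
        )


def windowed_counts(
    chrom_lengths: dict[str, int],
    positions: pd.DataFrame,
    size: int,
) -> WindowTrack:
    """Count items (columns chrom, pos; 0-based) per tiling window."""
    win = tile_windows(chrom_lengths, size)
    counts = np.zeros(len(win), dtype=np.int64)
    offsets = {}
    cursor = 0
    for chrom, length in chrom_lengths.items():
        n = int(np.ceil(length / size)) if length else 0
        offsets[chrom] = cursor
        cursor += n
    for chrom, grp in positions.groupby("chrom"):
        if chrom not in offsets:
            continue
        idx = (grp["pos"].to_numpy() // size).astype(np.int64) + offsets[chrom]
        np.add.at(counts, idx, 1)
    win["value"] = counts.astype(float)
    win["n_variants"] = counts
    return WindowTrack(win, window_size=size)
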