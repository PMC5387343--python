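"""Light interval utilities shared across modules (BED I/O, membership tests).

All intervals are 0-based, half-open [start, end).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path, n_cols: int | None = None) -> pd.DataFrame:
    """Read a BED3..BED6 file; missing optional columns are filled."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"malformed BED (fewer than 3 columns): {path}")
    df = df.iloc[:, :6]
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0), ("strand", "+")):
        if col not in df.columns:
            df[col] = default
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    if (df["end"] < df["start"]).any():
        raise ValueError(f"malformed BED (end < start): {path}")
    if n_cols is not None:
        df = df.iloc[:, :n_cols]
    return df


def write_bed(df: pd.DataFrame, path, columns=None) -> None:
    cols = columns or [c for c in BED6_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as sorted, disjoint (starts, ends)."""
    if len(starts) == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [s[0]], [e[0]]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], b)
        else:
            out_s.append(a)
            out_e.append(b)
    return np.asarray(out_s, dtype=np.int64), np.asarray(out_e, dtype=np.int64)


class IntervalIndex:
    """Per-chromosome merged-interval index supporting point membership."""

    def __init__(self, bed: pd.DataFrame):
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, grp in bed.groupby("chrom", sort=False):
            self._merged[str(chrom)] = merge_intervals(
                grp["start"].to_numpy(), grp["end"].to_numpy()
            )

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: position inside the interval union (half-open)."""
        positions = np.asarray(positions)
        if chrom not in self._merged:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = self._merged[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        inside = np.zeros(len(positions), dtype=bool)
        inside[ok] = positions[ok] < ends[idx[ok]]
        return inside
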