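"""Nucleosome midpoints from MNase-seq reads, with MNase-bias control weighting.

MNase digestion leaves ~147 bp of nucleosome-protected DNA, so the dyad
(midpoint) of the wrapped segment sits 73 bp inside the fragment: a
plus-strand read's midpoint is its 5' end + 73, a minus-strand read's is its
5' end - 73. Naked-DNA control libraries carry the enzyme's sequence
preference; midpoints are down-weighted where the control is locally
enriched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_context import GenomeAssembly
from .intervals import read_bed, write_bed

MIDPOINT_OFFSET = 73  # bp from fragment 5' end to the dyad

MIDPOINT_COLUMNS = ["chrom", "pos", "weight"]


@dataclass
class MidpointSet:
    """Weighted dyad positions plus bookkeeping of dropped reads."""

    table: pd.DataFrame  # columns: chrom, pos, weight
    n_dropped: int = 0
    log: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.table)

    def per_chrom(self):
        for chrom, grp in self.table.groupby("chrom", sort=False):
            yield str(chrom), grp["pos"].to_numpy(), grp["weight"].to_numpy()


def reads_from_bed(path_or_df) -> pd.DataFrame:
    """BED6 reads; the 5' end is start on '+' and end-1 on '-'."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else read_bed(path_or_df)
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{int(bad.sum())} reads with strand not in +/-")
    five = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return pd.DataFrame(
        {"chrom": df["chrom"].to_numpy(), "five_prime": five, "strand": df["strand"].to_numpy()}
    )


def derive_midpoints(reads: pd.DataFrame, genome: GenomeAssembly) -> MidpointSet:
    """Apply the 5' +/- 73 bp rule; out-of-bounds midpoints are dropped and counted.

    ``reads`` needs columns chrom, five_prime, strand (see :func:`reads_from_bed`).
    """
    lengths = genome.lengths
    unknown = set(reads["chrom"].unique()) - set(lengths)
    if unknown:
        raise KeyError(f"reads on unknown chromosomes: {sorted(unknown)}")
    pos = np.where(
        reads["strand"] == "+",
        reads["five_prime"] + MIDPOINT_OFFSET,
        reads["five_prime"] - MIDPOINT_OFFSET,
    ).astype(np.int64)
    chrom_len = reads["chrom"].map(lengths).to_numpy()
    ok = (pos >= 0) & (pos < chrom_len)
    table = pd.DataFrame(
        {
            "chrom": reads["chrom"].to_numpy()[ok],
            "pos": pos[ok],
            "weight": np.ones(int(ok.sum())),
        }
    )
    return MidpointSet(table.reset_index(drop=True), n_dropped=int((~ok).sum()))


def reconstruct_reads(midpoints: MidpointSet, strand: str) -> pd.DataFrame:
    """Inverse of the midpoint rule (used for invariance checks)."""
    sign = -1 if strand == "+" else 1
    return pd.DataFrame(
        {
            "chrom": midpoints.table["chrom"],
            "five_prime": midpoints.table["pos"] + sign * MIDPOINT_OFFSET,
            "strand": strand,
        }
    )


def _window_counts(
    mid_pos: np.ndarray, n_windows: int, window: int
) -> np.ndarray:
    return np.bincount(mid_pos // window, minlength=n_windows)[:n_windows]


def control_normalize(
    midpoints: MidpointSet,
    ctrl_midpoints: MidpointSet,
    genome: GenomeAssembly,
    window: int = 147,
    clamp: tuple[float, float] = (0.1, 10.0),
    invert: bool = False,
) -> MidpointSet:
    """Weight midpoints by inverse relative control enrichment in tiled windows.

    The genome is tiled in non-overlapping ``window``-bp windows anchored at
    coordinate 0. Each window's enrichment e_w is its control midpoint count
    divided by the genome-wide mean count per window; midpoints in the window
    receive weight 1/e_w (or e_w with ``invert=True``), clamped to ``clamp``.
    Windows with zero control coverage fall back to weight 1.
    """
    if len(ctrl_midpoints) == 0:
        raise ValueError("empty control library")
    lengths = genome.lengths
    n_win = {c: -(-L // window) for c, L in lengths.items()}
    total_windows = sum(n_win.values())

    ctrl_counts = {
        chrom: np.zeros(n_win[chrom], dtype=np.int64) for chrom in lengths
    }
    for chrom, pos, _w in ctrl_midpoints.per_chrom():
        if chrom not in ctrl_counts:
            raise KeyError(f"control reads on unknown chromosome {chrom!r}")
        ctrl_counts[chrom] = _window_counts(pos, n_win[chrom], window)
    genome_mean = len(ctrl_midpoints) / total_windows

    out = midpoints.table.copy()
    log = []
    for chrom, grp in out.groupby("chrom", sort=False):
        counts = ctrl_counts[str(chrom)]
        win = grp["pos"].to_numpy() // window
        e_w = counts[win] / genome_mean
        with np.errstate(divide="ignore"):
            w = e_w.astype(float) if invert else 1.0 / e_w
        zero = counts[win] == 0
        w = np.clip(w, clamp[0], clamp[1])
        w[zero] = 1.0
        if zero.any():
            log.append(f"{chrom}: {int(zero.sum())} midpoints in zero-control windows")
        out.loc[grp.index, "weight"] = grp["weight"].to_numpy() * w
    return MidpointSet(out, n_dropped=midpoints.n_dropped, log=log)


def write_midpoints_bed(midpoints: MidpointSet, path) -> None:
    """BED4 with the weight in the score column."""
    df = pd.DataFrame(
        {
            "chrom": midpoints.table["chrom"],
            "start": midpoints.table["pos"],
            "end": midpoints.table["pos"] + 1,
            "name": midpoints.table["weight"],
        }
    )
    write_bed(df, path, columns=["chrom", "start", "end", "name"])


def read_midpoints_bed(path) -> MidpointSet:
    df = pd.read_csv(path, sep="\t", header=None, dtype={0: str})
    table = pd.DataFrame(
        {"chrom": df[0], "pos": df[1].astype(np.int64), "weight": df[3].astype(float)}
    )
    return MidpointSet(table)
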