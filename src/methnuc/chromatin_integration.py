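"""ChIP-seq Z-score tracks and Z-weighted nucleosome summaries.

Histone-modification enrichment is standardized genome-wide: per fixed-width
bin, d_i = ChIP RPM - input RPM, then z_i = (d_i - mean(d)) / sd(d) with the
population standard deviation. Nucleosome-level quantities (occupancy proxy,
methylated-CpG count, methylation fraction) are then averaged with weights
proportional to the positive part of a mark's Z-score:

    xbar(h)      = sum_i x_i z(h)_i / sum_i z(h)_i          over i with z(h)_i > 0
    xbar(hA, hB) = min-weighted mean, weight_i = min(zA_i, zB_i),
                   over i with both zA_i > 0 and zB_i > 0

The pair form follows the rule that each nucleosome is weighted by the
modification with the smaller Z-score.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

DEFAULT_BIN = 200


def _binned_means(track: pd.DataFrame, chrom_lengths: dict[str, int], bin_width: int):
    """Mean bedGraph value per bin; uncovered base pairs count as zero."""
    out = {}
    for chrom, L in chrom_lengths.items():
        n_bins = -(-L // bin_width)
        sums = np.zeros(n_bins)
        grp = track[track["chrom"] == chrom]
        for s, e, v in zip(grp["start"], grp["end"], grp["value"]):
            e = min(e, L)
            if e <= s:
                continue
            b0, b1 = s // bin_width, (e - 1) // bin_width
            if b0 == b1:
                sums[b0] += v * (e - s)
            else:
                sums[b0] += v * ((b0 + 1) * bin_width - s)
                sums[b0 + 1 : b1] += v * bin_width
                sums[b1] += v * (e - b1 * bin_width)
        widths = np.full(n_bins, bin_width, dtype=float)
        widths[-1] = L - (n_bins - 1) * bin_width
        out[chrom] = sums / widths
    return out


@dataclass
class ZScoreTrack:
    """Genome-binned Z-scores for one modification."""

    bins: dict[str, np.ndarray]
    bin_width: int
    mean: float
    sd: float

    def at(self, chrom: str, positions) -> np.ndarray:
        """Z-score of the bin containing each position."""
        positions = np.asarray(positions)
        if chrom not in self.bins:
            raise KeyError(f"no Z-scores for chromosome {chrom!r}")
        return self.bins[chrom][positions // self.bin_width]

    def footprint_mean(self, chrom: str, positions, half: int = 73) -> np.ndarray:
        """Mean Z over the bins overlapped by a +/-half footprint."""
        positions = np.asarray(positions)
        z = self.bins[chrom]
        lo = np.maximum((positions - half) // self.bin_width, 0)
        hi = np.minimum((positions + half) // self.bin_width, len(z) - 1)
        cum = np.concatenate([[0.0], np.cumsum(z)])
        return (cum[hi + 1] - cum[lo]) / (hi - lo + 1)


def genome_zscores(
    chip_track: pd.DataFrame,
    input_track: pd.DataFrame,
    chrom_lengths: dict[str, int],
    bin_width: int = DEFAULT_BIN,
) -> ZScoreTrack:
    """Standardize ChIP-minus-input signal over all genome bins."""
    chip = _binned_means(chip_track, chrom_lengths, bin_width)
    inp = _binned_means(input_track, chrom_lengths, bin_width)
    diffs = {c: chip[c] - inp[c] for c in chrom_lengths}
    flat = np.concatenate(list(diffs.values()))
    mean, sd = float(flat.mean()), float(flat.std())  # population sd
    if sd == 0:
        raise ValueError("ChIP - input signal has zero variance; Z-scores undefined")
    return ZScoreTrack(
        {c: (d - mean) / sd for c, d in diffs.items()}, bin_width, mean, sd
    )


def weighted_mean_single(x, z) -> float:
    """Z-weighted mean over entries with z > 0."""
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if x.shape != z.shape:
        raise ValueError("x and z must have equal length")
    pos = z > 0
    if not pos.any():
        raise ValueError("no entries with positive Z-score")
    return float(np.sum(x[pos] * z[pos]) / np.sum(z[pos]))


def weighted_mean_pair(x, z_a, z_b) -> float:
    """min(zA, zB)-weighted mean over entries where both Z-scores are positive."""
    x = np.asarray(x, dtype=float)
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    if not (x.shape == z_a.shape == z_b.shape):
        raise ValueError("x, zA, zB must have equal length")
    both = (z_a > 0) & (z_b > 0)
    if not both.any():
        raise ValueError("no entries with both Z-scores positive")
    w = np.minimum(z_a[both], z_b[both])
    return float(np.sum(x[both] * w) / np.sum(w))


SUMMARY_X_COLUMNS = {
    "occupancy": "u_gch_core",
    "mcpg": "mcpg_int",
    "m_fraction": "m_hcg_core",
}


def modification_summary_table(
    features: pd.DataFrame,
    ztracks: dict[str, ZScoreTrack],
    pairs: str | list[tuple[str, str]] = "all",
) -> pd.DataFrame:
    """One Z-weighted summary row per modification and per unordered pair.

    Excluded nucleosomes are omitted. A modification with no positive Z at
    any retained nucleosome contributes no row.
    """
    feats = features[~features["excluded"]].reset_index(drop=True)
    zmat = {}
    for name, zt in ztracks.items():
        parts = [
            pd.Series(zt.at(str(chrom), grp["pos"].to_numpy()), index=grp.index)
            for chrom, grp in feats.groupby("chrom", sort=False)
        ]
        zmat[name] = pd.concat(parts).reindex(feats.index).to_numpy()

    xcols = {label: feats[col].to_numpy(dtype=float) for label, col in SUMMARY_X_COLUMNS.items()}
    rows = []

    def _row(name, kind, weights, mask):
        entry = {"name": name, "kind": kind, "n": int(mask.sum())}
        for label, x in xcols.items():
            entry[f"w_{label}"] = float(np.sum(x[mask] * weights[mask]) / np.sum(weights[mask]))
        return entry

    for name, z in zmat.items():
        mask = z > 0
        if mask.any():
            rows.append(_row(name, "single", z, mask))
    if pairs == "all":
        pair_list = list(combinations(sorted(zmat), 2))
    else:
        pair_list = list(pairs or [])
    for a, b in pair_list:
        za, zb = zmat[a], zmat[b]
        mask = (za > 0) & (zb > 0)
        if mask.any():
            rows.append(_row(f"{a}+{b}", "pair", np.minimum(za, zb), mask))
    return pd.DataFrame(rows)


def occupancy_mcpg_correlation(table: pd.DataFrame) -> float:
    """Pearson correlation of weighted occupancy vs weighted mCpG across rows."""
    if len(table) < 3:
        raise ValueError("need at least 3 summary rows for a correlation")
    r, _ = stats.pearsonr(table["w_mcpg"], table["w_occupancy"])
    return float(r)


def regression_outliers(
    table: pd.DataFrame,
    x: str = "w_mcpg",
    y: str = "w_occupancy",
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Flag rows far off the occupancy-vs-mCpG regression line.

    Ordinary least squares of y on x; a row is an outlier when the absolute
    externally studentized residual exceeds ``threshold``.
    """
    X = sm.add_constant(table[x].to_numpy(dtype=float))
    fit = sm.OLS(table[y].to_numpy(dtype=float), X).fit()
    resid = fit.get_influence().resid_studentized_external
    out = table.copy()
    out["studentized_residual"] = resid
    out["outlier"] = np.abs(resid) > threshold
    return out
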