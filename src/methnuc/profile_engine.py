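"""Midpoint-anchored, orientation-symmetrized occurrence and methylation
profiles.

Every anchor (a weighted nucleosome dyad) contributes in both orientations
with half weight, exactly as if the profile had been computed from forward
and reverse-complement sequences aligned to the midpoints: a k-mer at
forward offset ``o`` (offset of its first base from the dyad) also appears at
``-o-(k-1)`` on the reverse complement, and a single-base methylation site at
``o`` reflects to ``-o``. Methylation profiles are pooled-count ratios per
offset, not means of per-site fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .genome_context import GenomeAssembly, HCG, GCH, CG
from .intervals import IntervalIndex
from .read_midpoints import MidpointSet

DEFAULT_FLANK = 1000


@dataclass
class Profile:
    """Per-offset numerator/denominator sums around nucleosome midpoints."""

    flank: int
    num: np.ndarray
    den: np.ndarray
    n_anchors: int

    @classmethod
    def empty(cls, flank: int, n_anchors: int = 0) -> "Profile":
        size = 2 * flank + 1
        return cls(flank, np.zeros(size), np.zeros(size), n_anchors)

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.flank, self.flank + 1)

    @property
    def values(self) -> np.ndarray:
        """numerator / denominator; NaN where the denominator is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.num / self.den
        v[self.den == 0] = np.nan
        return v

    def value_at(self, offset: int) -> float:
        return float(self.values[offset + self.flank])

    def merge(self, other: "Profile") -> "Profile":
        """Denominator-weighted pooling of two profiles (same flank)."""
        if other.flank != self.flank:
            raise ValueError("profiles have different flanks")
        return Profile(
            self.flank,
            self.num + other.num,
            self.den + other.den,
            self.n_anchors + other.n_anchors,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.offsets,
                "value": self.values,
                "numerator": self.num,
                "denominator": self.den,
                "n_anchors": self.n_anchors,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _expand_pairs(lo: np.ndarray, hi: np.ndarray):
    """Index pairs for per-anchor ranges [lo_j, hi_j) over a sorted array."""
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    anchor_idx = np.repeat(np.arange(len(lo)), counts)
    offsets_within = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    item_idx = offsets_within + np.repeat(lo, counts)
    return anchor_idx, item_idx


def _range_add(acc: np.ndarray, lo: np.ndarray, hi: np.ndarray, w: np.ndarray) -> None:
    """acc[lo:hi+1] += w for each row, via a difference-array accumulation.

    ``acc`` must have one spare trailing slot; ranges are inclusive indices.
    """
    valid = hi >= lo
    np.add.at(acc, lo[valid], w[valid])
    np.add.at(acc, hi[valid] + 1, -w[valid])


def _mirror(arr: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement image of a per-offset array: offset o -> -o-(k-1).

    Offsets whose mirror falls outside the profile are dropped. Adding the
    mirror to the forward array makes the symmetry value(o) = value(-o-(k-1))
    hold bitwise, since each offset pair sums the same two terms.
    """
    out = np.zeros_like(arr)
    keep = len(arr) - (k - 1)  # offsets whose mirror stays inside the profile
    out[:keep] = arr[:keep][::-1]
    return out


def occurrence_profile(
    midpoints: MidpointSet,
    positions: dict[str, np.ndarray],
    k: int,
    genome: GenomeAssembly,
    flank: int = DEFAULT_FLANK,
) -> Profile:
    """Weighted per-anchor frequency of a k-mer around midpoints.

    ``positions`` maps chromosome to sorted forward-strand start positions of
    the k-mer (e.g. from :func:`methnuc.genome_context.find_dinucleotides`).
    Each midpoint contributes an indicator at forward offset
    ``o = start - midpoint`` and a reverse-complement contribution at
    ``-o-(k-1)``, each with half its weight; per-offset denominators count
    only offsets whose k-mer window lies inside the chromosome.
    """
    F = flank
    size = 2 * F + 1
    num_fwd = np.zeros(size)
    den_diff = np.zeros(size + 1)
    n_anchors = 0
    lengths = genome.lengths
    for chrom, mids, weights in midpoints.per_chrom():
        L = lengths[chrom]
        feats = positions.get(chrom, np.empty(0, dtype=np.int64))
        n_anchors += len(mids)
        # forward-orientation numerator from actual occurrences
        lo = np.searchsorted(feats, mids - F)
        hi = np.searchsorted(feats, mids + F, side="right")
        mi, fi = _expand_pairs(lo, hi)
        o = feats[fi] - mids[mi]
        np.add.at(num_fwd, o + F, weights[mi] / 2.0)
        # forward coverage (contiguous per-anchor offset ranges)
        o_lo = np.maximum(-F, -mids)
        o_hi = np.minimum(F, L - k - mids)
        _range_add(den_diff, o_lo + F, o_hi + F, weights / 2.0)
    den_fwd = np.cumsum(den_diff)[:size]
    # the reverse-complement orientation is the mirror image of the forward one
    num = num_fwd + _mirror(num_fwd, k)
    den = den_fwd + _mirror(den_fwd, k)
    return Profile(F, num, den, n_anchors)


def _context_mask(records: pd.DataFrame, context: str) -> pd.Series:
    if context == HCG or context == GCH:
        return records["context"] == context
    if context == CG:
        # plain CpG channel: HCG plus GCG-ambiguous CG sites
        return records["context"].isin([HCG, CG])
    raise ValueError(f"unknown context {context!r}")


def fraction_profile(
    midpoints: MidpointSet,
    records: pd.DataFrame,
    context: str,
    mode: str = "methylated",
    flank: int = DEFAULT_FLANK,
) -> Profile:
    """Pooled methylated (or unmethylated) fraction per offset around midpoints.

    Per offset, numerator = sum of methylated (or unmethylated) read counts
    and denominator = sum of total read counts over all anchors; each site
    also contributes at the reflected offset ``-o`` for the reverse
    orientation. Value per offset is numerator/denominator.
    """
    if mode not in ("methylated", "unmethylated"):
        raise ValueError(f"mode must be methylated|unmethylated, got {mode!r}")
    F = flank
    size = 2 * F + 1
    num_fwd = np.zeros(size)
    den_fwd = np.zeros(size)
    n_anchors = 0
    recs = records[_context_mask(records, context)]
    by_chrom = {
        str(chrom): grp.sort_values("pos")
        for chrom, grp in recs.groupby("chrom", sort=False)
    }
    for chrom, mids, weights in midpoints.per_chrom():
        n_anchors += len(mids)
        grp = by_chrom.get(chrom)
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        meth = grp["meth"].to_numpy(dtype=float)
        total = grp["total"].to_numpy(dtype=float)
        top = meth if mode == "methylated" else total - meth
        lo = np.searchsorted(pos, mids - F)
        hi = np.searchsorted(pos, mids + F, side="right")
        mi, ri = _expand_pairs(lo, hi)
        o = pos[ri] - mids[mi]
        w_half = weights[mi] / 2.0
        np.add.at(num_fwd, o + F, w_half * top[ri])
        np.add.at(den_fwd, o + F, w_half * total[ri])
    # single-base sites reflect o -> -o on the reverse orientation
    prof = Profile(F, num_fwd + num_fwd[::-1], den_fwd + den_fwd[::-1], n_anchors)
    if prof.den.sum() == 0:
        import warnings

        warnings.warn("fraction profile has no methylation evidence in range")
    return prof


def restrict_anchors(
    midpoints: MidpointSet, regions: pd.DataFrame, keep: str = "inside"
) -> MidpointSet:
    """Keep midpoints whose position falls inside (or outside) a region union."""
    if keep not in ("inside", "outside"):
        raise ValueError(f"keep must be inside|outside, got {keep!r}")
    index = IntervalIndex(regions)
    masks = []
    for chrom, grp in midpoints.table.groupby("chrom", sort=False):
        inside = index.contains(str(chrom), grp["pos"].to_numpy())
        masks.append(pd.Series(inside, index=grp.index))
    if masks:
        inside_all = pd.concat(masks).reindex(midpoints.table.index)
        mask = inside_all if keep == "inside" else ~inside_all
        table = midpoints.table[mask.to_numpy(dtype=bool)]
    else:
        table = midpoints.table
    return MidpointSet(table.reset_index(drop=True), n_dropped=midpoints.n_dropped)


@dataclass
class PeriodicityResult:
    dominant_period: float
    power_fraction_10: float
    periods: np.ndarray
    power: np.ndarray


def periodicity_power(
    profile: Profile,
    period: float = 10.0,
    band: tuple[int, int] = (-70, 70),
    period_range: tuple[float, float] = (5.0, 25.0),
    grid_step: float = 0.05,
) -> PeriodicityResult:
    """Dominant period and normalized spectral power near ``period`` bp.

    Mean-subtracted Lomb-Scargle periodogram over the offset band (missing
    offsets are simply omitted); normalized power is the fraction of the
    band's variance explained by a sinusoid at each trial period. Returns the
    argmax period over ``period_range`` and the peak power within
    ``period`` +/- 0.5 bp.
    """
    values = profile.values
    offsets = profile.offsets
    in_band = (offsets >= band[0]) & (offsets <= band[1])
    y = values[in_band]
    t = offsets[in_band].astype(float)
    good = ~np.isnan(y)
    if not good.any():
        raise ValueError("profile has no data in the requested band")
    t, y = t[good], y[good]
    if t.max() - t.min() < 2 * period:
        raise ValueError("band holds fewer than two full periods of data")
    y = y - y.mean()
    periods = np.arange(period_range[0], period_range[1] + grid_step / 2, grid_step)
    if np.allclose(y, 0.0):
        return PeriodicityResult(float("nan"), 0.0, periods, np.zeros_like(periods))
    freqs = 2.0 * np.pi / periods
    power = lombscargle(t, y, freqs, normalize=True)
    dominant = float(periods[int(np.argmax(power))])
    near = np.abs(periods - period) <= 0.5
    return PeriodicityResult(dominant, float(power[near].max()), periods, power)
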