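"""Per-nucleosome core and linker statistics.

The analysis window for a nucleosome core is the central 123 bp of the
147-bp footprint, positions -61..+61 (inclusive) around the dyad; linker DNA
is taken as the two 31-bp windows at positions +/-85..+/-115. For each
nucleosome the module computes CpG counts, G+C composition, pooled
methylated-HCG and unmethylated-GCH fractions (the latter serving as the
nucleosome-occupancy proxy), integer methylated/unmethylated CpG counts, and
the core-versus-linker methylated-CpG density ratio

    (m_core * nCpG_core / 123) / (m_linker * nCpG_linker / 62).

A nucleosome needs methylation evidence for at least 2 HCG and 2 GCH
cytosines (either strand) in the core to enter the analysis, and at least 2
HCG cytosines plus one CpG in the linker for the density ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_context import GenomeAssembly, HCG, GCH
from .read_midpoints import MidpointSet

CORE_HALF = 61          # core window = [dyad-61, dyad+61], 123 bp
CORE_BP = 2 * CORE_HALF + 1
LINKER_NEAR, LINKER_FAR = 85, 115   # linker windows = dyad +/- [85, 115]
LINKER_BP = 2 * (LINKER_FAR - LINKER_NEAR + 1)

MIN_INFORMATIVE = 2     # covered cytosines required per channel

FEATURE_COLUMNS = [
    "chrom", "pos", "weight",
    "n_cpg_core", "gc_core", "gc_minus_cpg_core",
    "m_hcg_core", "u_gch_core", "informative_hcg_core", "informative_gch_core",
    "n_cpg_linker", "m_hcg_linker", "informative_hcg_linker",
    "mcpg_int", "ucpg_int", "density_ratio",
    "excluded", "ratio_excluded",
]


def round_half_away(x):
    """Round to nearest integer with ties going away from zero."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def integer_mcpg(n_cpg, m_fraction):
    """Integer methylated/unmethylated CpG counts from a pooled fraction.

    Both counts are rounded independently, so their sum may differ from
    n_cpg by one.
    """
    m = round_half_away(np.asarray(n_cpg) * np.asarray(m_fraction))
    u = round_half_away(np.asarray(n_cpg) * (1.0 - np.asarray(m_fraction)))
    return m, u


class _CumulativeCounts:
    """Prefix sums over one chromosome for O(1) window aggregation."""

    def __init__(self, pos: np.ndarray, values: dict[str, np.ndarray]):
        order = np.argsort(pos, kind="stable")
        self.pos = pos[order]
        self.cum = {
            name: np.concatenate([[0], np.cumsum(vals[order])])
            for name, vals in values.items()
        }

    def window_sum(self, name: str, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        """Sum of a value over sites with lo <= pos <= hi (inclusive)."""
        i = np.searchsorted(self.pos, lo, side="left")
        j = np.searchsorted(self.pos, hi, side="right")
        return self.cum[name][j] - self.cum[name][i]


def _composition_tables(genome: GenomeAssembly):
    """Per-chromosome prefix structures for CpG starts and G+C content."""
    tables = {}
    for chrom, seq in genome.chromosomes.items():
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = codes == ord("C")
        is_g = codes == ord("G")
        gc = (is_c | is_g).astype(np.int64)
        cg_start = np.zeros(len(codes), dtype=bool)
        cg_start[:-1] = is_c[:-1] & is_g[1:]
        # a base participates in a CpG if it is the C of one or the G of one
        in_cpg = np.zeros(len(codes), dtype=bool)
        in_cpg |= cg_start
        in_cpg[1:] |= cg_start[:-1]
        gc_free = (gc.astype(bool) & ~in_cpg).astype(np.int64)
        all_pos = np.arange(len(codes))
        tables[chrom] = {
            "bases": _CumulativeCounts(all_pos, {"gc": gc, "gc_free": gc_free}),
            "cpg_starts": np.nonzero(cg_start)[0],
            "length": len(codes),
        }
    return tables


def _count_in(starts: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """CpG starts with both bases inside [lo, hi] (start in [lo, hi-1])."""
    return (
        np.searchsorted(starts, hi - 1, side="right")
        - np.searchsorted(starts, lo, side="left")
    )


def _meth_tables(records: pd.DataFrame, context: str):
    recs = records[records["context"] == context]
    tables = {}
    for chrom, grp in recs.groupby("chrom", sort=False):
        tables[str(chrom)] = _CumulativeCounts(
            grp["pos"].to_numpy(),
            {
                "meth": grp["meth"].to_numpy(dtype=float),
                "total": grp["total"].to_numpy(dtype=float),
                "n": np.ones(len(grp)),
            },
        )
    return tables


def _pooled(tab, lo, hi, n_mid):
    if tab is None:
        z = np.zeros(n_mid)
        return z.copy(), z.copy(), z.copy()
    meth = tab.window_sum("meth", lo, hi)
    total = tab.window_sum("total", lo, hi)
    n = tab.window_sum("n", lo, hi)
    return meth, total, n


def compute_features(
    midpoints: MidpointSet,
    genome: GenomeAssembly,
    records: pd.DataFrame,
    gc_within_window_only: bool = False,
) -> pd.DataFrame:
    """Core/linker statistics for every midpoint with a full +/-61 bp window.

    ``records`` holds context-joined methylation evidence for both channels
    (HCG rows feed the endogenous methylation fields, GCH rows the occupancy
    proxy). Midpoints whose core window is truncated by a chromosome edge are
    skipped (their count is reported via the returned frame's ``attrs``).
    ``gc_within_window_only`` switches the CpG-free G+C definition to
    gc_core - 2 * n_cpg_core (CpGs fully inside the window only) instead of
    excluding every base participating in any genomic CpG.
    """
    comp = _composition_tables(genome)
    hcg = _meth_tables(records, HCG)
    gch = _meth_tables(records, GCH)

    frames = []
    n_skipped = 0
    for chrom, mids, weights in midpoints.per_chrom():
        tabs = comp[chrom]
        ok = (mids - LINKER_FAR >= 0) & (mids + LINKER_FAR < tabs["length"])
        core_ok = (mids - CORE_HALF >= 0) & (mids + CORE_HALF < tabs["length"])
        n_skipped += int((~core_ok).sum())
        # require the full +/-115 span so linker fields are always defined
        keep = ok
        n_skipped += int((core_ok & ~ok).sum())
        mids, weights = mids[keep], weights[keep]
        if len(mids) == 0:
            continue
        c_lo, c_hi = mids - CORE_HALF, mids + CORE_HALF
        starts = tabs["cpg_starts"]
        n_cpg_core = _count_in(starts, c_lo, c_hi)
        gc_core = tabs["bases"].window_sum("gc", c_lo, c_hi)
        if gc_within_window_only:
            gc_free = gc_core - 2 * n_cpg_core
        else:
            gc_free = tabs["bases"].window_sum("gc_free", c_lo, c_hi)
        n_cpg_linker = _count_in(starts, mids - LINKER_FAR, mids - LINKER_NEAR) + \
            _count_in(starts, mids + LINKER_NEAR, mids + LINKER_FAR)

        hm, ht, hn = _pooled(hcg.get(chrom), c_lo, c_hi, len(mids))
        gm, gt, gn = _pooled(gch.get(chrom), c_lo, c_hi, len(mids))
        lm = lt = ln = np.zeros(len(mids))
        if hcg.get(chrom) is not None:
            lm1, lt1, ln1 = _pooled(hcg[chrom], mids - LINKER_FAR, mids - LINKER_NEAR, len(mids))
            lm2, lt2, ln2 = _pooled(hcg[chrom], mids + LINKER_NEAR, mids + LINKER_FAR, len(mids))
            lm, lt, ln = lm1 + lm2, lt1 + lt2, ln1 + ln2

        with np.errstate(invalid="ignore", divide="ignore"):
            m_hcg_core = np.where(ht > 0, hm / ht, np.nan)
            u_gch_core = np.where(gt > 0, (gt - gm) / gt, np.nan)
            m_hcg_linker = np.where(lt > 0, lm / lt, np.nan)

        excluded = (hn < MIN_INFORMATIVE) | (gn < MIN_INFORMATIVE)
        mcpg, ucpg = integer_mcpg(n_cpg_core, np.nan_to_num(m_hcg_core))
        mcpg = np.where(np.isnan(m_hcg_core), -1, mcpg)
        ucpg = np.where(np.isnan(m_hcg_core), -1, ucpg)

        core_density = m_hcg_core * n_cpg_core / CORE_BP
        linker_density = m_hcg_linker * n_cpg_linker / LINKER_BP
        ratio_excluded = (
            excluded
            | (ln < MIN_INFORMATIVE)
            | (n_cpg_linker < 1)
            | ~(linker_density > 0)
            | ~(core_density > 0)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            density_ratio = np.where(ratio_excluded, np.nan, core_density / linker_density)

        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom, "pos": mids, "weight": weights,
                    "n_cpg_core": n_cpg_core, "gc_core": gc_core,
                    "gc_minus_cpg_core": gc_free,
                    "m_hcg_core": m_hcg_core, "u_gch_core": u_gch_core,
                    "informative_hcg_core": hn.astype(np.int64),
                    "informative_gch_core": gn.astype(np.int64),
                    "n_cpg_linker": n_cpg_linker,
                    "m_hcg_linker": m_hcg_linker,
                    "informative_hcg_linker": ln.astype(np.int64),
                    "mcpg_int": mcpg.astype(np.int64),
                    "ucpg_int": ucpg.astype(np.int64),
                    "density_ratio": density_ratio,
                    "excluded": excluded,
                    "ratio_excluded": ratio_excluded,
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=FEATURE_COLUMNS)
    out.attrs["n_skipped_edge"] = n_skipped
    return out


def core_composition(midpoint_pos: int, chrom: str, genome: GenomeAssembly):
    """(n_cpg_core, gc_core, gc_minus_cpg_core) for a single dyad position."""
    seq = genome.sequence(chrom)
    lo, hi = midpoint_pos - CORE_HALF, midpoint_pos + CORE_HALF
    if lo < 0 or hi >= len(seq):
        raise ValueError("core window truncated by chromosome edge")
    window = seq[lo : hi + 1]
    n_cpg = sum(1 for i in range(len(window) - 1) if window[i : i + 2] == "CG")
    gc = sum(1 for b in window if b in "GC")
    # CpGs straddling the window edge still claim their in-window base
    in_cpg = set()
    for i in range(max(lo - 1, 0), min(hi + 1, len(seq) - 1)):
        if seq[i : i + 2] == "CG":
            in_cpg.update((i, i + 1))
    gc_free = sum(1 for p in range(lo, hi + 1) if seq[p] in "GC" and p not in in_cpg)
    return n_cpg, gc, gc_free


def density_ratio(m_core: float, n_cpg_core: int, m_linker: float, n_cpg_linker: int) -> float:
    """Core/linker methylated-CpG density per bp; NaN when the linker density is 0."""
    link = m_linker * n_cpg_linker / LINKER_BP
    if not link > 0:
        return float("nan")
    return (m_core * n_cpg_core / CORE_BP) / link


def partition_by_core_cpg(
    features: pd.DataFrame, max_bin: int = 10
) -> dict[str, pd.DataFrame]:
    """Disjoint, exhaustive sublibraries keyed by core CpG count (overflow bin >=max)."""
    bins: dict[str, pd.DataFrame] = {}
    n = features["n_cpg_core"]
    for b in range(max_bin):
        bins[str(b)] = features[n == b]
    bins[f">={max_bin}"] = features[n >= max_bin]
    return bins


def sublibrary_midpoints(features: pd.DataFrame) -> MidpointSet:
    """Use a feature subset as an anchor set for the profile engine."""
    return MidpointSet(features[["chrom", "pos", "weight"]].reset_index(drop=True))


@dataclass
class FiveNumberSummary:
    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n_outliers: int
    n: int


def distribution_summary(values) -> FiveNumberSummary:
    """Tukey boxplot summary: quartiles (linear interpolation), whiskers at the
    most extreme points within 1.5*IQR of the box, and the outlier count."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) == 0:
        raise ValueError("empty input")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return FiveNumberSummary(
        float(q1), float(med), float(q3),
        float(inside.min()), float(inside.max()),
        int(len(v) - len(inside)), int(len(v)),
    )


def write_features_tsv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, sep="\t", index=False, columns=FEATURE_COLUMNS)


def read_features_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
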