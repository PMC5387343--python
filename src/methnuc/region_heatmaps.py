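"""Anchor-binned signal matrices, occupancy sorting, the methylation split of
CpG-containing TF binding sites, and CpG-island nucleosome classification.

Heatmap rows are anchors (TSSs, CpG-island centers, TFBSs); columns are an
odd number of fixed-width bins (21 bp by default) centered on the anchor,
with minus-strand anchors' columns reversed so that downstream is always to
the right. Rows are conventionally sorted by decreasing mean occupancy, and
the same permutation can be applied to companion matrices so rows stay
aligned across signals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genome_context import HCG, CG
from .intervals import IntervalIndex

ANCHOR_COLUMNS = ["chrom", "pos", "strand", "label"]


@dataclass
class AnchorMatrix:
    anchors: pd.DataFrame       # chrom, pos, strand, label (row order = matrix order)
    values: np.ndarray          # anchors x n_bins, NaN where uncovered
    bin_width: int
    sort_key: str = "input"

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_offsets(self) -> np.ndarray:
        half = (self.n_bins - 1) // 2
        return (np.arange(self.n_bins) - half) * self.bin_width

    def row_means(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=[str(o) for o in self.bin_offsets])
        return pd.concat([self.anchors.reset_index(drop=True), df], axis=1)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def bin_signal(
    anchors: pd.DataFrame,
    track: dict[str, np.ndarray],
    n_bins: int = 101,
    bin_width: int = 21,
) -> AnchorMatrix:
    """Average a per-bp signal in ``n_bins`` bins of ``bin_width`` bp per anchor.

    ``track`` maps chromosome to a per-bp array (NaN allowed for uncovered
    positions). ``n_bins`` must be odd; the center bin spans the anchor
    +/-(bin_width-1)/2. Anchors near a chromosome edge keep their row, with
    out-of-range bins left missing. Minus-strand anchor rows are reversed.
    """
    if n_bins % 2 == 0:
        raise ValueError("n_bins must be odd")
    half_bins = (n_bins - 1) // 2
    half_bp = (bin_width - 1) // 2
    span = n_bins * bin_width
    values = np.full((len(anchors), n_bins), np.nan)
    for i, (chrom, pos, strand) in enumerate(
        zip(anchors["chrom"], anchors["pos"], anchors["strand"])
    ):
        sig = track.get(str(chrom))
        if sig is None:
            continue
        start = int(pos) - half_bins * bin_width - half_bp
        window = np.full(span, np.nan)
        lo, hi = max(start, 0), min(start + span, len(sig))
        if hi > lo:
            window[lo - start : hi - start] = sig[lo:hi]
        grid = window.reshape(n_bins, bin_width)
        good = ~np.isnan(grid)
        counts = good.sum(axis=1)
        with np.errstate(invalid="ignore"):
            row = np.where(counts > 0, np.nansum(grid, axis=1), np.nan) / counts
        if strand == "-":
            row = row[::-1]
        values[i] = row
    return AnchorMatrix(anchors.reset_index(drop=True), values, bin_width)


def sort_rows(matrix: AnchorMatrix, direction: str = "decreasing") -> AnchorMatrix:
    """Sort rows by mean signal across bins (missing bins ignored).

    Stable; ties are broken by anchor coordinate. Returns a new matrix; apply
    :func:`apply_order` with ``matrix.anchors.index`` semantics to companions.
    """
    means = matrix.row_means()
    key = -means if direction == "decreasing" else means
    key = np.where(np.isnan(key), np.inf, key)
    anchors = matrix.anchors.reset_index(drop=True)
    chrom_codes = pd.factorize(anchors["chrom"], sort=True)[0]
    order = np.lexsort((anchors["pos"].to_numpy(), chrom_codes, key))
    return apply_order(matrix, order, sort_key="mean_" + direction)


def apply_order(matrix: AnchorMatrix, order: np.ndarray, sort_key: str = "shared") -> AnchorMatrix:
    """Apply a row permutation (e.g. one matrix's occupancy order) to a matrix."""
    order = np.asarray(order)
    return replace(
        matrix,
        anchors=matrix.anchors.reset_index(drop=True).iloc[order].reset_index(drop=True),
        values=matrix.values[order],
        sort_key=sort_key,
    )


def collapse_cpg_units(records: pd.DataFrame) -> pd.DataFrame:
    """Pool strand-resolved CpG-context evidence into duplex CpG units.

    A forward-strand CpG cytosine at position p and the minus-strand cytosine
    at p+1 report on the same duplex CpG; both are assigned unit position p
    (the C of the forward-strand CG) and their counts are summed.
    """
    cg = records[records["context"].isin([HCG, CG])].copy()
    unit = np.where(cg["strand"] == "+", cg["pos"], cg["pos"] - 1)
    cg["unit"] = unit
    pooled = (
        cg.groupby(["chrom", "unit"], sort=True)[["meth", "total"]]
        .sum()
        .reset_index()
        .rename(columns={"unit": "pos"})
    )
    return pooled


def split_tfbs(
    tfbs: pd.DataFrame, records: pd.DataFrame, threshold: float = 0.5
) -> pd.DataFrame:
    """Classify CpG-containing TF binding sites by duplex CpG methylation.

    Per site, the pooled methylated fraction over CpG units fully inside
    [start, end) decides the class: >= ``threshold`` -> ``methylated``,
    < threshold -> ``unmethylated``; sites with no covered CpG -> ``excluded``.
    Returns the input with ``cpg_fraction``, ``n_cpg_covered`` and
    ``meth_class`` columns appended.
    """
    units = collapse_cpg_units(records)
    out = tfbs.reset_index(drop=True).copy()
    fractions = np.full(len(out), np.nan)
    n_covered = np.zeros(len(out), dtype=np.int64)
    for chrom, grp in out.groupby("chrom", sort=False):
        u = units[units["chrom"] == chrom]
        pos = u["pos"].to_numpy()
        meth = u["meth"].to_numpy(dtype=float)
        total = u["total"].to_numpy(dtype=float)
        cm = np.concatenate([[0.0], np.cumsum(meth)])
        ct = np.concatenate([[0.0], np.cumsum(total)])
        cn = np.concatenate([[0], np.arange(1, len(pos) + 1)])
        # unit fully inside the site: C at p, G at p+1, both < end
        i = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        j = np.searchsorted(pos, grp["end"].to_numpy() - 1, side="left")
        tot = ct[j] - ct[i]
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = (cm[j] - cm[i]) / tot
        fractions[grp.index] = np.where(tot > 0, frac, np.nan)
        n_covered[grp.index] = cn[j] - cn[i]
    out["cpg_fraction"] = fractions
    out["n_cpg_covered"] = n_covered
    out["meth_class"] = np.select(
        [np.isnan(fractions), fractions >= threshold],
        ["excluded", "methylated"],
        default="unmethylated",
    )
    return out


def classify_cgi_nucleosomes(
    midpoints: pd.DataFrame,
    tss: pd.DataFrame,
    gene_bodies: pd.DataFrame,
    window: int = 500,
) -> pd.Series:
    """TSS / intragenic / intergenic class per CpG-island midpoint.

    A midpoint within ``window`` bp (inclusive) of the nearest TSS is class
    ``TSS``; otherwise ``intragenic`` if it lies inside a gene body, else
    ``intergenic``. ``midpoints`` is a frame with chrom/pos (e.g.
    ``MidpointSet.table`` already restricted to CpG islands); ``tss`` needs
    chrom/pos or chrom/start columns.
    """
    tss_pos_col = "pos" if "pos" in tss.columns else "start"
    tss_by_chrom = {
        str(c): np.sort(g[tss_pos_col].to_numpy()) for c, g in tss.groupby("chrom")
    }
    genes = IntervalIndex(gene_bodies)
    labels = pd.Series("intergenic", index=midpoints.index, dtype=object)
    for chrom, grp in midpoints.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        t = tss_by_chrom.get(str(chrom), np.empty(0, dtype=np.int64))
        if len(t):
            i = np.clip(np.searchsorted(t, pos), 0, len(t) - 1)
            d1 = np.abs(t[i] - pos)
            d0 = np.abs(t[np.maximum(i - 1, 0)] - pos)
            near = np.minimum(d0, d1) <= window
        else:
            near = np.zeros(len(pos), dtype=bool)
        in_gene = genes.contains(str(chrom), pos)
        lab = np.where(near, "TSS", np.where(in_gene, "intragenic", "intergenic"))
        labels.loc[grp.index] = lab
    return labels


def cgi_scatter_table(features: pd.DataFrame, classes: pd.Series) -> pd.DataFrame:
    """(occupancy, methylation, class) triples for 2D scatter export."""
    return pd.DataFrame(
        {
            "occupancy": features["u_gch_core"],
            "methylation": features["m_hcg_core"],
            "class": classes,
        }
    )


def track_from_bedgraph(
    bedgraph: pd.DataFrame, chrom_lengths: dict[str, int], fill=np.nan
) -> dict[str, np.ndarray]:
    """Expand a bedGraph into per-bp arrays for :func:`bin_signal`."""
    out = {}
    for chrom, L in chrom_lengths.items():
        arr = np.full(L, fill, dtype=float)
        grp = bedgraph[bedgraph["chrom"] == chrom]
        for s, e, v in zip(grp["start"], grp["end"], grp["value"]):
            arr[max(s, 0) : min(e, L)] = v
        out[chrom] = arr
    return out
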