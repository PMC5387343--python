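"""Per-cytosine methylation tables for the HCG (endogenous) and GCH
(accessibility) channels.

The canonical on-disk dialect is a headered TSV::

    chrom<TAB>pos<TAB>strand<TAB>context<TAB>meth<TAB>total

with 0-based forward coordinates (minus-strand cytosines at the coordinate
of the complementary G) and integer read counts. A ``fraction+coverage``
dialect (columns ``fraction`` and ``coverage``) is converted to counts by
rounding fraction x coverage to the nearest integer.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

METH_COLUMNS = ["chrom", "pos", "strand", "context", "meth", "total"]

_DIALECTS = ("counts", "fraction+coverage")


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValueError(f"{int(bad_strand.sum())} records with invalid strand")
    if (df["total"] < df["meth"]).any():
        raise ValueError("total < meth in methylation table")
    if (df["meth"] < 0).any():
        raise ValueError("negative meth count")
    return df[df["total"] >= 1].reset_index(drop=True)


def read_methylation_table(path, dialect: str = "counts") -> pd.DataFrame:
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if dialect == "counts":
        try:
            df["meth"] = df["meth"].astype(np.int64)
            df["total"] = df["total"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric counts in {path}") from exc
    else:
        cov = df["coverage"].astype(np.int64)
        meth = np.rint(df["fraction"].astype(float) * cov).astype(np.int64)
        df = df.drop(columns=["fraction", "coverage"])
        df["meth"], df["total"] = meth, cov
    df["pos"] = df["pos"].astype(np.int64)
    return _validate(df[METH_COLUMNS])


def write_methylation_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False, columns=METH_COLUMNS)


def records_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an in-memory frame against the table contract."""
    return _validate(df[METH_COLUMNS].copy())


def join_contexts(records: pd.DataFrame, sites: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Verify record contexts against genome-derived cytosine sites.

    Records at positions/strands that are not cytosines in the genome are
    dropped; records whose claimed context disagrees with the genome are
    dropped; records with a missing context inherit the genome's label.
    Returns (kept records, number dropped).
    """
    merged = records.merge(
        sites.rename(columns={"context": "genome_context"}),
        on=["chrom", "pos", "strand"],
        how="left",
    )
    at_cytosine = merged["genome_context"].notna()
    claimed = merged["context"].astype(object)
    missing = claimed.isna() | (claimed == ".")
    agree = missing | (claimed == merged["genome_context"])
    keep = at_cytosine & agree
    out = merged[keep].copy()
    out["context"] = out["genome_context"]
    out = out.drop(columns=["genome_context"]).reset_index(drop=True)
    return out, int((~keep).sum())


def pooled_fraction(records: pd.DataFrame) -> float:
    """Genome-wide pooled methylated fraction, (sum meth) / (sum total)."""
    total = records["total"].sum()
    if total == 0:
        raise ValueError("no methylation evidence")
    return float(records["meth"].sum() / total)


def read_bedgraph(path) -> pd.DataFrame:
    """bedGraph import for pre-binned signal tracks."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype={0: str},
        names=["chrom", "start", "end", "value"],
    )
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(float)
    return df


def write_bedgraph(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])
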