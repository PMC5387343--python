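"""Genome sequence handling and NOMe-seq cytosine context classification.

NOMe-seq reads out two methylation channels from the same molecules: the
endogenous CpG channel at HCG trinucleotides (H = A, C or T) and the
exogenous GpC-methyltransferase accessibility channel at GCH trinucleotides.
Cytosines inside a GCG trinucleotide are ambiguous between the two channels
and are excluded from both; they keep the plain ``CG`` label when they sit in
a CpG dinucleotide.

Coordinates are 0-based throughout; a minus-strand cytosine (the complement
of a forward-strand G) is reported at the forward coordinate of that G with
``strand == "-"``, and its context is evaluated on the reverse-complement
read-through.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeAssembly",
    "load_fasta",
    "classify_cytosines",
    "find_dinucleotides",
    "write_sites_tsv",
    "read_sites_tsv",
]

_VALID = frozenset("ACGT")

# cytosine context labels
HCG = "HCG"
GCH = "GCH"
CG = "CG"  # CpG dinucleotide that is neither HCG nor GCH (GCG-ambiguous or edge)
OTHER = "OTHER"

SITE_COLUMNS = ["chrom", "pos", "strand", "context"]


@dataclass
class GenomeAssembly:
    """Uppercase nucleotide sequences keyed by chromosome name."""

    chromosomes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"empty sequence for chromosome {name!r}")
            self.chromosomes[name] = seq.upper()

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chromosomes.items()}

    def sequence(self, chrom: str) -> str:
        if chrom not in self.chromosomes:
            raise KeyError(f"unknown chromosome {chrom!r}")
        return self.chromosomes[chrom]

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Half-open slice [start, end); out-of-bounds lookups are rejected."""
        seq = self.sequence(chrom)
        if start < 0 or end > len(seq) or start > end:
            raise IndexError(
                f"[{start}, {end}) outside {chrom} of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chromosomes


def load_fasta(path) -> GenomeAssembly:
    """Load a (possibly multi-record, line-wrapped) FASTA into memory.

    Lowercase bases are uppercased. Duplicate record names and empty records
    are errors.
    """
    chroms: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chroms:
            raise ValueError(f"duplicate chromosome name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        chroms[rec.id] = seq
    if not chroms:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeAssembly(chroms)


def _seq_to_codes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def classify_cytosines(genome: GenomeAssembly) -> pd.DataFrame:
    """Assign a NOMe-seq context to every cytosine on both strands.

    Returns a DataFrame with columns ``chrom, pos, strand, context`` where
    context is one of HCG, GCH, CG, OTHER. Rules, evaluated on the strand
    the cytosine is read on (H = A/C/T):

    * followed by G and preceded by H  -> HCG (a CpG site)
    * followed by G and preceded by G  -> CG  (GCG-ambiguous CpG)
    * preceded by G and followed by H  -> GCH
    * anything else (incl. N neighbours or a missing neighbour at a
      sequence edge next to a G) -> OTHER; edge CpGs with no upstream base
      keep the plain CG label.
    """
    frames = []
    A, C, G, T = (ord(b) for b in "ACGT")
    for chrom, seq in genome.chromosomes.items():
        codes = _seq_to_codes(seq)
        n = len(codes)
        # neighbours padded with 0 (an invalid base) at the edges
        prev = np.empty(n, dtype=np.uint8)
        nxt = np.empty(n, dtype=np.uint8)
        prev[0], prev[1:] = 0, codes[:-1]
        nxt[-1], nxt[:-1] = 0, codes[1:]

        is_h_prev = (prev == A) | (prev == C) | (prev == T)
        is_h_next = (nxt == A) | (nxt == C) | (nxt == T)

        # forward strand: site is a C; read-through is prev, C, next
        fwd = codes == C
        fwd_ctx = np.full(n, OTHER, dtype=object)
        fwd_ctx[fwd & (nxt == G) & is_h_prev] = HCG
        fwd_ctx[fwd & (nxt == G) & ~is_h_prev] = CG
        fwd_ctx[fwd & (prev == G) & is_h_next] = GCH

        # minus strand: site is the complement of a forward G at pos j.
        # On the minus read-through, 5' neighbour = complement(codes[j+1]),
        # 3' neighbour = complement(codes[j-1]); complement(x) == G iff
        # x == C, complement(x) in H iff x in {A, G, T}.
        rev = codes == G
        comp_prev_is_g = nxt == C
        comp_next_is_g = prev == C
        comp_prev_is_h = (nxt == A) | (nxt == G) | (nxt == T)
        comp_next_is_h = (prev == A) | (prev == G) | (prev == T)
        rev_ctx = np.full(n, OTHER, dtype=object)
        rev_ctx[rev & comp_next_is_g & comp_prev_is_h] = HCG
        rev_ctx[rev & comp_next_is_g & ~comp_prev_is_h] = CG
        rev_ctx[rev & comp_prev_is_g & comp_next_is_h] = GCH

        fpos = np.nonzero(fwd)[0]
        rpos = np.nonzero(rev)[0]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.concatenate([fpos, rpos]),
                    "strand": np.concatenate(
                        [np.full(len(fpos), "+"), np.full(len(rpos), "-")]
                    ),
                    "context": np.concatenate([fwd_ctx[fpos], rev_ctx[rpos]]),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["chrom", "pos", "strand"], kind="stable")
    return out.reset_index(drop=True)


def cpg_sites(sites: pd.DataFrame, include_ambiguous: bool = True) -> pd.DataFrame:
    """Subset of sites lying in a CpG dinucleotide on their strand.

    ``include_ambiguous`` keeps GCG-ambiguous cytosines (plain ``CG`` label);
    set False for analyses restricted to the clean HCG channel.
    """
    wanted = {HCG, CG} if include_ambiguous else {HCG}
    return sites[sites["context"].isin(wanted)]


def find_dinucleotides(genome: GenomeAssembly, dinuc: str) -> dict[str, np.ndarray]:
    """0-based forward-strand start positions of a dinucleotide, per chromosome.

    Positions are sorted and unique; overlapping occurrences are all reported.
    """
    dinuc = dinuc.upper()
    if len(dinuc) != 2 or any(b not in _VALID for b in dinuc):
        raise ValueError(f"dinucleotide must be a 2-mer over ACGT, got {dinuc!r}")
    b0, b1 = (ord(b) for b in dinuc)
    out = {}
    for chrom, seq in genome.chromosomes.items():
        codes = _seq_to_codes(seq)
        hits = np.nonzero((codes[:-1] == b0) & (codes[1:] == b1))[0]
        out[chrom] = hits.astype(np.int64)
    return out


def write_sites_tsv(sites: pd.DataFrame, path) -> None:
    sites.to_csv(path, sep="\t", index=False, columns=SITE_COLUMNS)


def read_sites_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "pos": np.int64})
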