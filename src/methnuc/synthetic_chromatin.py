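"""Synthetic chromatin generator.

Emits a toy genome plus every input the pipeline consumes — MNase-seq
nucleosome and naked-DNA control reads, per-cytosine HCG and GCH methylation
tables, region annotations and ChIP-like mark tracks — with the statistical
structure the analysis assumes:

* phased nucleosome arrays (fixed spacing plus Gaussian jitter);
* CpG-density strata (intergenic/intron/exon/CGI-like segments) whose
  endogenous methylation prefers linker DNA at low CpG density and core DNA
  at high density;
* 10-bp rotational modulation of methylated-CpG placement inside cores;
* nucleosome occupancy following a logistic link on the true methylated-CpG
  count of the core, encoded in the GCH channel exactly as NOMe-seq logic
  dictates (protected GCH sites stay unmethylated, so the unmethylated GCH
  fraction recovers occupancy);
* MNase sequence bias in the control library (a smooth positional field);
* a heterochromatin-like subpopulation (low CpG, high occupancy) carrying a
  dedicated mark, plus a panel of marks painted on methylated-CpG bands;
* planted methylated/unmethylated TF binding sites centered on dyads.

Every quantity is drawn from one seeded generator, so identical parameters
give byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genome_context import GenomeAssembly, classify_cytosines, HCG, GCH
from .intervals import merge_intervals
from .methylation_io import METH_COLUMNS

NUCLEOSOME_BP = 147
PROTECT_HALF = 73


@dataclass
class Stratum:
    name: str
    weight: float
    cpg_per_kb: float
    m_core: float   # endogenous methylation probability, core CpGs
    m_link: float   # endogenous methylation probability, linker/other CpGs


def default_strata() -> list[Stratum]:
    return [
        Stratum("intergenic", 0.45, 8.0, 0.25, 0.55),
        Stratum("intron", 0.30, 16.0, 0.30, 0.60),
        Stratum("exon", 0.15, 35.0, 0.70, 0.35),
        Stratum("cgi", 0.10, 65.0, 0.75, 0.30),
    ]


@dataclass
class SimParams:
    """Study conditions for the generator (see docs/methods.md for rationale)."""

    seed: int                       # mandatory
    genome_length: int = 2_000_000
    chrom_name: str = "chr1"
    segment_length: int = 10_000
    strata: list[Stratum] = field(default_factory=default_strata)
    spacing: int = 190              # nucleosome repeat length, bp
    phasing_jitter_sd: float = 8.0  # dyad placement jitter, bp
    read_jitter_sd: float = 2.0     # per-read dyad jitter, bp
    occ_a: float = -1.0             # occupancy link intercept
    occ_b: float = 0.35             # occupancy link slope per methylated CpG
    rot_amplitude: float = 0.5      # rotational modulation of core mCpG placement
    rot_phase: float = 0.0          # bp
    rot_period: float = 10.0        # bp
    read_depth: float = 12.0        # expected reads/nucleosome at full occupancy
    read_length: int = 50
    control_reads_per_bp: float = 0.2   # deep enough for stable 147-bp window counts
    mnase_bias_amplitude: float = 0.4
    mnase_bias_period: float = 5_000.0
    coverage: float = 10.0          # Poisson mean reads per cytosine
    meth_error: float = 0.0         # per-read miscall probability
    gpc_efficiency: float = 0.9     # GpC methyltransferase conversion on open DNA
    heterochromatin_fraction: float = 0.08
    heterochromatin_occupancy: float = 0.85
    n_tfbs: int = 300
    tfbs_halfwidth: int = 10
    n_marks: int = 8                # correlated mark bands (mCpG = 0 .. n-1)
    mark_bin: int = 200
    mark_amplitude: float = 3.0
    mark_noise_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.spacing <= NUCLEOSOME_BP:
            raise ValueError(f"spacing must exceed {NUCLEOSOME_BP} bp")
        for s in self.strata:
            for p in (s.m_core, s.m_link):
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"methylation probability {p} outside [0, 1]")

    @classmethod
    def from_yaml(cls, path, seed: int) -> "SimParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata" in raw:
            raw["strata"] = [Stratum(**s) for s in raw["strata"]]
        raw["seed"] = seed
        return cls(**raw)


@dataclass
class SimResult:
    params: SimParams
    genome: GenomeAssembly
    sites: pd.DataFrame             # classified cytosines
    nuc_reads: pd.DataFrame         # BED6
    ctrl_reads: pd.DataFrame        # BED6
    hcg: pd.DataFrame               # methylation table, endogenous channel
    gch: pd.DataFrame               # methylation table, accessibility channel
    annotations: dict[str, pd.DataFrame]
    marks: dict[str, tuple[pd.DataFrame, pd.DataFrame]]  # name -> (chip, input)
    truth: dict

    def write(self, outdir) -> None:
        from .intervals import write_bed
        from .methylation_io import write_methylation_table, write_bedgraph

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for name, seq in self.genome.chromosomes.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        write_bed(self.nuc_reads, out / "nuc_reads.bed")
        write_bed(self.ctrl_reads, out / "ctrl_reads.bed")
        write_methylation_table(self.hcg, out / "hcg.tsv")
        write_methylation_table(self.gch, out / "gch.tsv")
        ann = out / "annotations"
        ann.mkdir(exist_ok=True)
        for name, bed in self.annotations.items():
            write_bed(bed, ann / f"{name}.bed")
        marks = out / "marks"
        marks.mkdir(exist_ok=True)
        for name, (chip, inp) in self.marks.items():
            write_bedgraph(chip, marks / f"{name}.chip.bedgraph")
            write_bedgraph(inp, marks / f"{name}.input.bedgraph")
        with open(out / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def _logistic(x):
    return 1.0 / (1.0 + np.exp(-x))


def _build_genome(params: SimParams, rng: np.random.Generator):
    """Sequence with stratum segments and exactly the planted CpGs."""
    L = params.genome_length
    n_seg = -(-L // params.segment_length)
    weights = np.array([s.weight for s in params.strata], dtype=float)
    weights = weights / weights.sum()
    seg_stratum = rng.choice(len(params.strata), size=n_seg, p=weights)

    # CpG-free background: accidental CGs are repaired after planting
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    codes = rng.choice(bases, size=L, p=[0.3, 0.2, 0.2, 0.3])

    rate_per_bp = np.array([s.cpg_per_kb / 1000.0 for s in params.strata])
    bp_stratum = seg_stratum[np.minimum(np.arange(L) // params.segment_length, n_seg - 1)]
    cand = np.nonzero(rng.random(L) < rate_per_bp[bp_stratum])[0]
    cand = cand[(cand >= 1) & (cand <= L - 3)]
    if len(cand):
        keep = np.concatenate([[True], np.diff(cand) >= 2])
        planted = cand[keep]
    else:
        planted = cand
    codes[planted] = ord("C")
    codes[planted + 1] = ord("G")

    # repair accidental CGs (mutate the G; cannot create new CGs or touch planted pairs)
    is_cg = np.zeros(L, dtype=bool)
    is_cg[:-1] = (codes[:-1] == ord("C")) & (codes[1:] == ord("G"))
    planted_mask = np.zeros(L, dtype=bool)
    planted_mask[planted] = True
    accidental = np.nonzero(is_cg & ~planted_mask)[0]
    codes[accidental + 1] = rng.choice(
        np.frombuffer(b"AT", dtype=np.uint8), size=len(accidental)
    )

    seq = codes.tobytes().decode("ascii")
    genome = GenomeAssembly({params.chrom_name: seq})
    return genome, planted, seg_stratum, bp_stratum


def _nearest(sorted_anchors: np.ndarray, pos: np.ndarray):
    """Index of and signed offset to the nearest anchor for each position."""
    i = np.searchsorted(sorted_anchors, pos)
    left = np.maximum(i - 1, 0)
    right = np.minimum(i, len(sorted_anchors) - 1)
    pick_right = np.abs(sorted_anchors[right] - pos) < np.abs(sorted_anchors[left] - pos)
    idx = np.where(pick_right, right, left)
    return idx, pos - sorted_anchors[idx]


def _reads_from_dyads(dyads, strands, read_length, L, chrom):
    start = np.where(
        strands == "+", dyads - PROTECT_HALF, dyads + PROTECT_HALF + 1 - read_length
    )
    end = start + read_length
    ok = (start >= 0) & (end <= L)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": start[ok],
            "end": end[ok],
            "name": ".",
            "score": 0,
            "strand": strands[ok],
        }
    )


def _methylation_table(sites, context, p_meth_by_site, coverage, rng, chrom):
    sub = sites[sites["context"].isin(context)].reset_index(drop=True)
    cov = rng.poisson(coverage, size=len(sub))
    keep = cov > 0
    sub, cov = sub[keep].reset_index(drop=True), cov[keep]
    p = p_meth_by_site(sub)
    meth = rng.binomial(cov, p)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": sub["pos"].to_numpy(),
            "strand": sub["strand"].to_numpy(),
            "context": sub["context"].to_numpy(),
            "meth": meth,
            "total": cov,
        }
    )[METH_COLUMNS]


def simulate(params: SimParams) -> SimResult:
    rng = np.random.default_rng(params.seed)
    chrom = params.chrom_name
    L = params.genome_length
    genome, units, seg_stratum, bp_stratum = _build_genome(params, rng)
    strata = params.strata

    # --- phased nucleosome array ---
    margin = 130
    grid = np.arange(margin, L - margin, params.spacing)
    dyads = grid + np.rint(rng.normal(0, params.phasing_jitter_sd, len(grid))).astype(int)
    dyads = np.sort(np.clip(dyads, margin, L - margin - 1))
    n_nuc = len(dyads)
    nuc_stratum = bp_stratum[dyads]

    # --- true methylation state per duplex CpG unit ---
    unit_stratum = bp_stratum[units]
    nearest_idx, offset = _nearest(dyads, units)
    in_core = np.abs(offset) <= 61
    m_core = np.array([s.m_core for s in strata])[unit_stratum]
    m_link = np.array([s.m_link for s in strata])[unit_stratum]
    rot = 1.0 + params.rot_amplitude * np.cos(
        2.0 * np.pi * (offset - params.rot_phase) / params.rot_period
    )
    p_state = np.where(in_core, np.clip(m_core * rot, 0.0, 1.0), m_link)
    state = rng.random(len(units)) < p_state

    # --- heterochromatin-like subpopulation (low CpG, occupancy decoupled) ---
    hetero = np.zeros(n_nuc, dtype=bool)
    low_cpg = nuc_stratum == 0
    hetero[low_cpg] = rng.random(int(low_cpg.sum())) < params.heterochromatin_fraction

    # --- planted TF binding sites centered on dyads ---
    # units fully inside a [dyad-th, dyad+th+1) site: C at dyad+o, G at dyad+o+1
    th = params.tfbs_halfwidth
    unit_ok = (offset >= -th) & (offset <= th - 1)
    cand = np.unique(nearest_idx[unit_ok])
    cand = cand[~hetero[cand]]
    n_tfbs = min(params.n_tfbs, len(cand))
    chosen = np.sort(rng.choice(cand, size=n_tfbs, replace=False))
    tfbs_meth = np.zeros(n_tfbs, dtype=bool)
    tfbs_meth[: n_tfbs // 2] = True
    rng.shuffle(tfbs_meth)
    tfbs_class = {int(i): bool(m) for i, m in zip(chosen, tfbs_meth)}
    override = unit_ok & np.isin(nearest_idx, chosen)
    state[override] = np.array(
        [tfbs_class[int(i)] for i in nearest_idx[override]], dtype=bool
    )

    # --- occupancy link and read sampling ---
    mcpg_true = np.bincount(nearest_idx[in_core], weights=state[in_core], minlength=n_nuc)
    mcpg_true = mcpg_true.astype(int)
    p_occ = _logistic(params.occ_a + params.occ_b * mcpg_true)
    p_occ[hetero] = params.heterochromatin_occupancy

    # MNase cutting bias: smooth positional field shared by both libraries
    x = np.arange(L, dtype=float)
    bias = 1.0 + params.mnase_bias_amplitude * np.sin(
        2.0 * np.pi * x / params.mnase_bias_period
    )

    n_reads = rng.poisson(params.read_depth * p_occ * bias[dyads])
    read_nuc = np.repeat(np.arange(n_nuc), n_reads)
    read_dyads = dyads[read_nuc] + np.rint(
        rng.normal(0, params.read_jitter_sd, len(read_nuc))
    ).astype(int)
    read_strand = np.where(rng.random(len(read_nuc)) < 0.5, "+", "-")
    nuc_reads = _reads_from_dyads(read_dyads, read_strand, params.read_length, L, chrom)

    # --- control reads from the MNase-bias field only ---
    cdf = np.cumsum(bias)
    n_ctrl = int(round(L * params.control_reads_per_bp))
    ctrl_mid = np.searchsorted(cdf, rng.random(n_ctrl) * cdf[-1])
    ctrl_mid = np.clip(ctrl_mid, PROTECT_HALF + 1, L - PROTECT_HALF - 2)
    ctrl_strand = np.where(rng.random(n_ctrl) < 0.5, "+", "-")
    ctrl_reads = _reads_from_dyads(ctrl_mid, ctrl_strand, params.read_length, L, chrom)

    # --- methylation tables ---
    sites = classify_cytosines(genome)
    eps = params.meth_error

    unit_state = dict(zip(units.tolist(), state.tolist()))

    def hcg_p(sub: pd.DataFrame) -> np.ndarray:
        unit_pos = np.where(sub["strand"] == "+", sub["pos"], sub["pos"] - 1)
        st = np.array([unit_state.get(int(u), False) for u in unit_pos])
        return np.where(st, 1.0 - eps, eps)

    def gch_p(sub: pd.DataFrame) -> np.ndarray:
        idx, off = _nearest(dyads, sub["pos"].to_numpy())
        protected = np.abs(off) <= PROTECT_HALF
        access = np.where(protected, 1.0 - p_occ[idx], 1.0)
        return params.gpc_efficiency * access

    hcg = _methylation_table(sites, [HCG, "CG"], hcg_p, params.coverage, rng, chrom)
    gch = _methylation_table(sites, [GCH], gch_p, params.coverage, rng, chrom)

    # --- annotations ---
    seg_starts = np.arange(len(seg_stratum)) * params.segment_length
    seg_ends = np.minimum(seg_starts + params.segment_length, L)

    def _seg_bed(mask):
        s, e = merge_intervals(seg_starts[mask], seg_ends[mask])
        return pd.DataFrame(
            {"chrom": chrom, "start": s, "end": e, "name": ".", "score": 0, "strand": "+"}
        )

    names = np.array([s.name for s in strata])
    cgi_bed = _seg_bed(names[seg_stratum] == "cgi")
    exon_bed = _seg_bed(names[seg_stratum] == "exon")
    gene_bed = _seg_bed(np.isin(names[seg_stratum], ["exon", "intron"]))
    tss_bed = pd.DataFrame(
        {
            "chrom": chrom,
            "start": gene_bed["start"],
            "end": gene_bed["start"] + 1,
            "name": ".",
            "score": 0,
            "strand": "+",
        }
    )
    tfbs_bed = pd.DataFrame(
        {
            "chrom": chrom,
            "start": dyads[chosen] - th,
            "end": dyads[chosen] + th + 1,
            "name": [f"tfbs_{i}" for i in range(n_tfbs)],
            "score": 0,
            "strand": "+",
        }
    )

    # --- ChIP-like mark tracks ---
    n_bins = -(-L // params.mark_bin)
    bin_edges = np.arange(n_bins + 1) * params.mark_bin
    marks: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    peak_beds = {}

    def _mark(name: str, on_nucs: np.ndarray):
        on_bins = np.zeros(n_bins, dtype=bool)
        on_bins[dyads[on_nucs] // params.mark_bin] = True
        d = on_bins * params.mark_amplitude + rng.normal(0, params.mark_noise_sd, n_bins)
        chip = pd.DataFrame(
            {"chrom": chrom, "start": bin_edges[:-1], "end": bin_edges[1:],
             "value": 1.0 + d}
        )
        inp = chip.copy()
        inp["value"] = 1.0
        marks[name] = (chip, inp)
        s, e = merge_intervals(bin_edges[:-1][on_bins], bin_edges[1:][on_bins])
        peak_beds[name] = pd.DataFrame(
            {"chrom": chrom, "start": s, "end": e, "name": name, "score": 0, "strand": "+"}
        )

    for k in range(params.n_marks):
        _mark(f"mark_mcpg{k}", np.nonzero((mcpg_true == k) & ~hetero)[0])
    _mark("k9like", np.nonzero(hetero)[0])

    annotations = {
        "cgi": cgi_bed,
        "exon": exon_bed,
        "gene_bodies": gene_bed,
        "tss": tss_bed,
        "tfbs": tfbs_bed,
    }
    annotations.update({f"peaks_{n}": b for n, b in peak_beds.items()})

    truth = {
        "params": _params_dict(params),
        "dyads": dyads.tolist(),
        "stratum": names[nuc_stratum].tolist(),
        "mcpg_true": mcpg_true.tolist(),
        "p_occ": p_occ.tolist(),
        "heterochromatin": hetero.tolist(),
        "tfbs": [
            {"start": int(dyads[i] - th), "end": int(dyads[i] + th + 1),
             "name": f"tfbs_{j}", "methylated": bool(tfbs_class[int(i)])}
            for j, i in enumerate(chosen)
        ],
        "rot_phase": params.rot_phase,
        "rot_period": params.rot_period,
    }
    return SimResult(
        params, genome, sites, nuc_reads, ctrl_reads, hcg, gch,
        annotations, marks, truth,
    )


def _params_dict(params: SimParams) -> dict:
    d = dataclasses.asdict(params)
    d["strata"] = [dataclasses.asdict(s) for s in params.strata]
    return d


# ---------------------------------------------------------------------------
# parameter-recovery metrics against planted truth


def occupancy_recovery(features: pd.DataFrame, min_bin_n: int = 10):
    """Spearman rho of per-bin mean occupancy proxy vs integer mCpG count."""
    from scipy import stats

    ok = features[~features["excluded"] & (features["mcpg_int"] >= 0)]
    means = ok.groupby("mcpg_int")["u_gch_core"].agg(["mean", "size"])
    means = means[means["size"] >= min_bin_n]
    if len(means) < 3:
        raise ValueError("too few populated mCpG bins")
    rho, _ = stats.spearmanr(means.index.to_numpy(), means["mean"].to_numpy())
    return float(rho), means


def ratio_medians_by_bin(features: pd.DataFrame, min_bin_n: int = 5) -> pd.Series:
    """Median core/linker mCpG density ratio per core CpG-count bin."""
    ok = features[~features["ratio_excluded"]]
    med = ok.groupby("n_cpg_core")["density_ratio"].agg(["median", "size"])
    return med[med["size"] >= min_bin_n]["median"]


def tfbs_confusion(split: pd.DataFrame, truth: dict) -> dict[str, int]:
    """Planted-vs-recovered TFBS class counts (excluded sites reported apart)."""
    planted = {t["name"]: t["methylated"] for t in truth["tfbs"]}
    counts = {"tp": 0, "tn": 0, "fp": 0, "fn": 0, "excluded": 0}
    for name, cls in zip(split["name"], split["meth_class"]):
        want = planted[name]
        if cls == "excluded":
            counts["excluded"] += 1
        elif cls == "methylated":
            counts["tp" if want else "fp"] += 1
        else:
            counts["tn" if not want else "fn"] += 1
    return counts


def truth_report(sim: SimResult, features: pd.DataFrame, split=None, profile=None) -> dict:
    """Deterministic recovery-metric table for a simulated dataset."""
    report: dict = {}
    rho, _ = occupancy_recovery(features)
    report["occupancy_mcpg_spearman"] = rho
    med = ratio_medians_by_bin(features)
    report["ratio_medians"] = {int(k): float(v) for k, v in med.items()}
    crossing = [int(k) for k, v in med.items() if v > 1]
    report["ratio_crossing_bin"] = min(crossing) if crossing else None
    if split is not None:
        report["tfbs_confusion"] = tfbs_confusion(split, sim.truth)
    if profile is not None:
        from .profile_engine import periodicity_power

        res = periodicity_power(profile)
        report["rotational_period"] = res.dominant_period
        report["rotational_power_10bp"] = res.power_fraction_10
    return report
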