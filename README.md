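# methnuc

Integrated MNase-seq + NOMe-seq analysis of the relationship between CpG
methylation density and nucleosome occupancy.

## The problem

Whether DNA methylation stabilizes or evicts nucleosomes has been argued both
ways. Combining two assays on the same genome resolves much of the apparent
contradiction: MNase-seq locates nucleosome dyads (midpoint = read 5' end
± 73 bp), and NOMe-seq reads two methylation channels off the same
molecules — endogenous CpG methylation at **HCG** trinucleotides (mHCG/HCG)
and exogenous GpC-methyltransferase accessibility at **GCH** trinucleotides,
whose *unmethylated* fraction (uGCH/GCH) is a nucleosome-occupancy proxy
(H = A/C/T; ambiguous GCG sites are excluded from both channels). Anchoring
both channels on dyads shows that occupancy rises with methylated-CpG density,
that methylation prefers linker DNA where CpGs are sparse but the 123-bp core
(dyad ±61 bp) where CpGs are dense, and that core methylated CpGs sit with
~10-bp rotational periodicity.

`methnuc` is a tested re-implementation of that analysis stack for anyone who
wants to run it on their own midpoint/methylation tables or to study its
statistical behavior: dyad derivation with naked-DNA control weighting,
orientation-symmetrized anchored profiles, per-nucleosome core/linker
statistics and the core-vs-linker methylated-CpG density ratio

    (m_core · nCpG_core / 123) / (m_linker · nCpG_linker / 62),

ChIP Z-score-weighted summaries (x̄(h) = Σ xᵢz(h)ᵢ / Σ z(h)ᵢ over z(h)ᵢ > 0;
pairs weighted by min(z_A, z_B)), anchor-binned heatmap matrices, and the
methylated/unmethylated split of CpG-containing TF binding sites. A seeded
synthetic-chromatin generator with planted truth (phased arrays, CpG-density
strata, logistic occupancy link, rotational methylation placement, MNase
bias, decoupled heterochromatin-like marks) makes every stage testable
without downloads. See `docs/methods.md` for the full model.

## Worked example

```python
import pandas as pd
from methnuc import (synthetic_chromatin as sc, read_midpoints as rm,
                     nucleosome_features as nf, profile_engine as pe,
                     region_heatmaps as rh)

params = sc.SimParams(seed=7, genome_length=500_000, segment_length=5_000)
sim = sc.simulate(params)

mids = rm.derive_midpoints(rm.reads_from_bed(sim.nuc_reads), sim.genome)
mids = pe.restrict_anchors(mids, sim.annotations["cgi"], keep="outside")
records = pd.concat([sim.hcg, sim.gch], ignore_index=True)
feats = nf.compute_features(mids, sim.genome, records)

rho, bin_means = sc.occupancy_recovery(feats)
print(f"nucleosomes analyzed: {len(feats)} ({int(feats['excluded'].sum())} excluded)")
print(f"occupancy vs mCpG Spearman rho: {rho:.3f}")

ok = feats[~feats["ratio_excluded"]]
for label, sel in [("1-3 CpG", ok["n_cpg_core"].between(1, 3)),
                   (">=5 CpG", ok["n_cpg_core"] >= 5)]:
    print(f"median core/linker mCpG density ratio, {label}: "
          f"{ok.loc[sel, 'density_ratio'].median():.2f}")

prof = pe.fraction_profile(mids, sim.hcg, context="HCG", flank=80)
res = pe.periodicity_power(prof)
print(f"dominant methylation period: {res.dominant_period:.1f} bp "
      f"(power fraction at 10 bp: {res.power_fraction_10:.2f})")

split = rh.split_tfbs(sim.annotations["tfbs"], records)
print("TFBS split:", split["meth_class"].value_counts().to_dict())
```

prints

```
nucleosomes analyzed: 10284 (3343 excluded)
occupancy vs mCpG Spearman rho: 1.000
median core/linker mCpG density ratio, 1-3 CpG: 0.52
median core/linker mCpG density ratio, >=5 CpG: 1.55
dominant methylation period: 10.1 bp (power fraction at 10 bp: 0.71)
TFBS split: {'unmethylated': 150, 'methylated': 150}
```

Reading the numbers: mean occupancy (uGCH/GCH) increases monotonically with
the integer methylated-CpG count of the core (Spearman ρ = 1 across bins);
nucleosomes with 1–3 core CpGs are methylated preferentially in their linkers
(median density ratio < 1) while CpG-rich cores flip the preference
(ratio > 1); the planted 10-bp rotational placement of core methylated CpGs
is recovered from the dyad-anchored mHCG/HCG profile; and all 300 planted TF
binding sites are classified into the correct methylation class.

A command-line interface mirrors the library
(`methnuc simulate | midpoints | profile | features | integrate | heatmap`);
run `methnuc --help`.

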