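# Methods

## The measurement model

`methnuc` analyzes two sequencing readouts of the same chromatin:

* **MNase-seq** fragments mark nucleosome-protected DNA. The dyad (midpoint)
  of the canonical 147-bp protected segment lies 73 bp inside the fragment,
  so a plus-strand read maps to dyad = 5' end + 73 and a minus-strand read to
  5' end − 73. No positioning or peak calling is attempted: every read yields
  one (possibly fractionally weighted) dyad.
* **NOMe-seq** treats nuclei with an exogenous GpC methyltransferase before
  bisulfite conversion. Cytosines in **GCH** trinucleotides (H = A/C/T)
  become methylated only where chromatin is accessible, so the
  *unmethylated* GCH fraction (uGCH/GCH) is a nucleosome-occupancy proxy.
  Cytosines in **HCG** trinucleotides report endogenous CpG methylation
  (mHCG/HCG) from the same molecules. GCG trinucleotides are ambiguous
  between the two channels and are excluded from both; they keep a plain
  `CG` label so that plain-CpG (BS-seq style) analyses can still use them
  (that inclusion is the default for the `CG` context and switchable).

All coordinates are 0-based, intervals half-open; minus-strand cytosines are
stored at the forward coordinate of the complementary G, with context
evaluated on the reverse-complement read-through.

## Core procedures

**Control weighting.** MNase prefers some sequence environments; a naked-DNA
control library carries that preference alone. The genome is tiled in
non-overlapping 147-bp windows anchored at coordinate 0, each window's
relative control enrichment e_w is its control midpoint count divided by the
genome-mean count per window, and nucleosome midpoints falling in the window
receive weight 1/e_w, clamped to [0.1, 10] for stability (zero-control
windows fall back to weight 1). The opposite ratio orientation is available
as a flag. Weighting only the relative control enrichment — never the
nucleosome library's own coverage — avoids normalizing the signal against
itself.

**Anchored profiles.** A profile accumulates per-offset numerator and
denominator sums over all weighted dyads within a flank (default ±1000 bp)
and reports their ratio, exactly as if forward and reverse-complement
sequences had been stacked on the midpoints: a k-mer at forward offset o
(offset of its first base) contributes again at −o−(k−1) with half weight,
and a single-base methylation site at o reflects to −o. Methylation values
are pooled-count ratios per offset (Σ meth / Σ total), not means of per-site
fractions — robust at low coverage. Both symmetries hold bitwise because the
reverse-orientation half is constructed as the mirror image of the forward
half. No smoothing is applied.

**Rotational periodicity.** The ~10-bp positioning signal is quantified by a
normalized Lomb–Scargle periodogram of the mean-subtracted profile over
offsets −70..+70 (missing offsets simply drop out). Normalized power at a
trial period is the fraction of band variance explained by a sinusoid at
that period, so a pure tone scores 1, a constant profile 0, and two tones
score in proportion to amplitude². The dominant period is the argmax over a
5–25 bp grid (0.05 bp step); the headline statistic is the peak power within
10 ± 0.5 bp.

**Per-nucleosome features.** For each dyad with a complete ±115 bp span:
CpG count, G+C content and CpG-free G+C content over the 123-bp core
(positions −61..+61); pooled mHCG/HCG and uGCH/GCH fractions over the core;
the same HCG quantities over the linker (two 31-bp windows at ±85..±115,
62 bp total). Inclusion requires methylation evidence at ≥2 HCG and ≥2 GCH
cytosines in the core (either strand), and additionally ≥2 linker HCG
cytosines plus ≥1 linker CpG for the density ratio. Integer methylated and
unmethylated CpG counts are the core fraction (and its complement) times the
CpG count, each rounded independently to the nearest integer, ties away from
zero. The methylated-CpG density ratio is

    (m_core · nCpG_core / 123) / (m_linker · nCpG_linker / 62)

and is left undefined (nucleosome excluded from ratio analyses) when either
density is zero. "CpG-free G+C" counts G+C bases not participating in any
genomic CpG; the window-local alternative (gc − 2·nCpG) differs only for
window-straddling CpGs and is exposed as a flag.

**Z-weighted mark summaries.** ChIP signal minus input is averaged in 200-bp
bins and standardized genome-wide (population SD). A nucleosome's Z for a
mark is the value of the bin containing its midpoint (a footprint-mean
alternative is provided). Single-mark summaries weight nucleosome-level
quantities by Z over nucleosomes with Z > 0; pair summaries use
min(z_A, z_B) over nucleosomes where both are positive — the algebraic form
of "weight by the modification with the smaller Z-score". Marks decoupled
from the occupancy–mCpG trend are flagged by externally studentized
residuals (>2) of an OLS fit of weighted occupancy on weighted mCpG count.

**Region matrices and classifications.** Heatmap rows average a signal in an
odd number of 21-bp bins centered on each anchor, reverse minus-strand rows,
and sort by decreasing row mean (stable, coordinate tie-break). TF binding
sites are split on the pooled duplex-CpG methylated fraction over CpGs fully
inside the site: ≥0.5 → methylated, <0.5 → unmethylated, no covered CpG →
excluded. The TFBS split pools both strands per CpG (duplex units) since
motif methylation is a property of the duplex; all other analyses keep
strand-resolved cytosines as atoms. CpG-island nucleosomes are classed TSS
(within 500 bp of a TSS, inclusive), intragenic, or intergenic.

## The synthetic generator

`synthetic_chromatin.simulate` emits every pipeline input from one seeded
`numpy` generator (identical seeds give byte-identical files). Defaults are
the package's study conditions:

* **Genome**: 2 Mb, one chromosome, 10-kb segments drawn from four strata
  with distinct planted CpG rates and methylation preferences —
  intergenic-like (8 CpG/kb, core 0.25 / linker 0.55), intron-like (16,
  0.30/0.60), exon-like (35, 0.70/0.35), CGI-like (65, 0.75/0.30). The
  background sequence is CpG-free by construction (accidental CGs are
  repaired), so the planted CpGs are exactly the genome's CpGs. The low-CpG
  strata prefer linker methylation and the high-CpG strata prefer core
  methylation, encoding the linker-to-core transition with increasing CpG
  density.
* **Nucleosomes**: phased arrays with 190-bp spacing, placement jitter
  SD 8 bp, per-read dyad jitter SD 2 bp, 12 expected reads per nucleosome at
  full occupancy (read length 50).
* **Methylation states**: one Bernoulli state per duplex CpG; core CpGs
  (|offset| ≤ 61) use the stratum core rate modulated by
  1 + 0.5·cos(2π(o − φ)/10) (rotational placement, phase φ = 0), all other
  CpGs the stratum linker rate.
* **Occupancy**: p_occ = logistic(−1.0 + 0.35 · true core methylated-CpG
  count), spanning ≈0.27 (0 mCpG) to ≈0.86 (8 mCpG). 8% of intergenic
  nucleosomes form a heterochromatin-like subpopulation with occupancy
  fixed at 0.85 regardless of methylation — the planted exception carrying
  the `k9like` mark.
* **Readout**: per-cytosine coverage Poisson(10); HCG reads report the CpG
  state exactly (call-error probability 0 by default — these emulate
  processed methylation calls, not raw reads); GCH reads are methylated with
  probability 0.9 × accessibility, where accessibility is 1 − p_occ inside a
  ±73-bp footprint and 1 elsewhere. uGCH/GCH therefore recovers
  0.1 + 0.9·p_occ.
* **MNase bias**: a smooth sinusoidal field (amplitude 0.4, period 5 kb)
  multiplies the nucleosome read rate and is the sole density of the control
  library (0.2 reads/bp, ≈30 control midpoints per 147-bp window, enough
  for stable window enrichment estimates).
* **Marks**: eight "correlated" marks paint 200-bp bins containing dyads
  with true mCpG = 0..7 (chip−input amplitude 3, Gaussian bin noise 0.25);
  `k9like` paints the heterochromatin subpopulation.
* **TFBSs**: 300 21-bp sites centered on dyads with a core CpG; half have
  all their CpGs forced methylated, half unmethylated, feeding both the
  split check and (through the occupancy link) the methylated-high /
  unmethylated-low occupancy contrast.

**What the generator does not emulate**: sequencing errors and incomplete
bisulfite conversion, fragment-length variation, copy-number and mapping
artifacts, realistic human base composition beyond CpG-density strata,
per-molecule phasing of the two NOMe channels, and biological coupling
between marks and methylation beyond the painted bands. Passing tests show
the estimators recover what they are defined to recover under the stated
generative model; they are not evidence about artifact regimes absent from
that model.

## Numerical choices and problem sizes

Quartiles use linear interpolation; whiskers are the most extreme points
within 1.5×IQR (Tukey). Rounding ties go away from zero. Degenerate cases
are explicit: zero-variance ChIP tracks and all-nonpositive Z sets raise;
zero-control windows and empty profiles fall back with a logged warning;
edge-truncated cores are skipped and counted. Sorting ties break on anchor
coordinate, keeping repeated sorts idempotent.

Tests and the acceptance script run the same generative rules at smaller
genome sizes chosen for minute-scale wall time: 150–600 kb for unit and
property tests, 1 Mb (≈5,200 nucleosomes) for the occupancy-link and
acceptance runs, and twenty 250-kb replicates for the density-ratio
transition check. Statistical thresholds (Spearman ρ ≥ 0.9 on bin means with
≥10 nucleosomes per bin, medians on the correct side of 1 in ≥18/20 runs,
|studentized residual| > 2) follow the property definitions, not the
realized values.

## Known limitations

* Single-end 5'±73 midpoints only; paired-end fragment midpoints are out of
  scope.
* Control weighting assumes the bias is shared between libraries and smooth
  at the 147-bp window scale; very sparse control libraries make 1/e_w
  noisy (hence the clamp).
* The occupancy proxy pools GCH evidence across molecules, so it estimates
  mean occupancy, not single-molecule configurations.
* `periodicity_power` needs ≥2 full periods of covered offsets in the band
  and reports NaN for flat profiles.
* Feature annotation (island/exon/TFBS discovery) and peak calling are
  consumed as BED inputs, never computed.
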