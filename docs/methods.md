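# Methods

## Scope and coordinate conventions

The package quantifies three layers of the osmostress response in yeast-like
synthetic data: RNA Pol II and Hog1 chromatin association (ChIP-Seq),
nucleosome occupancy around transcription start sites (MNase-Seq), and
expression-based gene classes. All coordinates are 0-based, half-open (BED
convention) internally; 1-based gene tables are converted at the reader.
The promoter is the 500 bp immediately upstream of the annotated TSS; the
TSS is always an input column, never inferred from the ORF.

## Synthetic experiment

The generator emulates the statistical structure of a genome-wide
ChIP-Seq/MNase-Seq/microarray study of the osmostress response, not any
particular dataset. Everything is an exact function of `(config, seed)`.

**Genome.** `n` genes (default 100 per class, 5 classes) tiled on one
chromosome with fixed 4-kb spacing, 2-kb ORFs, alternating strands, TSS
50 bp upstream of the ORF start. Class labels are a seed-determined
permutation of the tiling so class and position are not confounded.

**ChIP reads.** Fragment centres are drawn from a mixture: uniform genomic
background (per-base weight 1) plus per-gene foreground over promoter ∪ ORF
with per-base weight equal to the gene's class multiplier for that factor,
strain and condition; the expected read share of a region with multiplier m
is `m·L / Σ w·L`. Exactly `chip_depth` fragments (default 5×10⁵) are
emitted per sample as 36-nt reads anchored at a random fragment end, so the
pipeline's extension step reconstructs the 250-bp fragment. Default Pol II
multipliers: strong stress recruitment at Hog1-dependent genes in wild type
only (8 vs 1 in the *hog1* strain), intermediate Hog1-independent
recruitment in both strains (4), and a twofold stress drop at housekeeping
and down-regulated genes in both strains. Hog1 ChIP enrichment (multiplier
8) is confined to the truly Hog1-bound genes — exactly 85% of dependent and
30% of independent genes, a fixed condition of the scenario — and is zero in
the deletion strain. An optional PCR-duplication step (off by default)
resamples a configured read fraction with geometric multiplicity to exercise
deduplication.

**MNase fragments.** 147-bp fragments centred on a phased nucleosome grid at
TSS-relative offsets −200, +50, +215, +380, +545 (canonical yeast spacing;
+1 at +50) with Gaussian jitter (sd 20 bp), plus a 5% uniform background.
Under stress each nucleosome's sampling weight is thinned by the class- and
strain-specific eviction fraction: 0.51 at Hog1-dependent genes in wild type
and 0 in the *hog1* strain; 0.25 at Hog1-independent genes in both strains;
0 elsewhere. By default eviction hits all of a gene's nucleosomes
(remodeling spans promoter and ORF); `evicted_offsets` can restrict it, e.g.
to the +1 nucleosome only. `plus1_shift_dependent` can displace the +1 of
dependent genes to emulate the slightly shifted +1 of stress genes.

**Expression.** Linear fold changes drawn lognormally around class means
chosen so the classifier's thresholds hold exactly at zero noise:
dependent (8, 2), independent (2, 2), housekeeping (1.05), down-regulated
(0.4), unchanged (1.3); log-noise sd 0.1 (typical microarray spread).

What the generator does *not* model: sequence content and mappability,
MNase digestion bias, replicate structure, chromatin domains, and real
inter-gene variability of induction. Passing recovery tests therefore shows
the estimators are correct under the stated sampling model, not that they
are robust to every artifact of real libraries.

## Quantification

**Dedup / extension / counting.** At most 10 reads are kept per
(chrom, start, strand) (first-seen; idempotent). Reads are extended 3'-ward
from their 5' end to 250 bp — the usual fragment-size proxy; "extend to" was
chosen over "extend by" as the standard reading, and the length is
configurable. Fragments are assigned to regions by midpoint (unambiguous
single assignment); coverage tracks use full-interval pileup and conserve
mass exactly.

**TMM / TRPK.** The scaling factor between a sample and its reference
(the factor's unstressed wild-type sample) is `2^mean(M)` over regions
surviving a double trim: zero regions excluded, then the most extreme 30%
by |M − median(M)| and 5% by |A − median(A)| dropped (the method's canonical
trim fractions). The mean is unweighted: uniform weights make the factor
exactly scale-equivariant — multiplying one sample's counts by c multiplies
its factor by c — so TRPK is exactly invariant to sequencing depth, which is
the property the normalization exists to provide. TRPK = RPK / factor.

**MA Z-scores.** M and A are computed on TRPK with a pseudocount of 0.5.
Regions are split into up to 20 equal-count A-strata (merged below 25 points
per stratum). Three standardization modes:

- `technical-null` (default): the stratum scale is the standard deviation of
  null M values obtained by a binomial split of each region's pooled raw
  count at the samples' depth ratio — under Poisson sampling this is exactly
  the distribution of M between technical replicates at that intensity. M is
  centred at its global median, which cancels residual normalization offset
  and is robust when up to half the regions are truly changed. This keeps
  calling power when a large gene fraction responds (as in a stress
  experiment, where self-standardization would absorb the signal into the
  stratum spread).
- `empirical`: stratum mean/sd of the observed M (ddof 1).
- `robust`: stratum median and scaled MAD.

Strata with zero spread yield Z = 0 with a warning. Calls use strict
inequality (Z = 4.00 is not significant at threshold 4); a two-sided mode
exists for down-regulation analyses. A gene is "Hog1-bound" when either its
promoter or its ORF region passes the threshold, enabling the
promoter-vs-ORF breakdown. The nominal normal-tail p of a given Z is not
asserted anywhere; the null calibration test measures the empirical
false-call rate instead.

**Nucleosome profiles and peaks.** TSS-aligned matrices span ±1 kb with
minus-strand rows reversed; genes without full flanks are dropped with a
warning. The peak caller smooths with a 75-bp moving average (edge-padded to
avoid boundary damping), takes local maxima whose height above the profile
minimum exceeds 25% of the relief (max − min), and merges maxima closer than
120 bp keeping the higher. A profile whose relief is below 25% of its
maximum is treated as flat (or noise-only) and yields no calls — an explicit
guard, since a pure height rule would call maxima of flat noise. Width is
the half-height span capped midway to neighbouring calls, so calls never
overlap. This caller is a deliberately simple positioning tool; the
occupancy statistics below do not depend on it.

**Occupancy / eviction.** Per gene, the mean coverage in [TSS, TSS+200)
(strand-aware) of the stressed sample is divided by the strain's unstressed
sample (≡ 100%). Because total depth is fixed, large-scale eviction at
responsive genes would inflate the apparent occupancy of untouched genes
under naive per-million scaling; the model therefore first rescales the
stressed sample by a TMM factor computed across all gene windows
(`normalize="tmm"`, default). Genes with zero unstressed signal are excluded
with a warning. Group values average per gene and then per group — the same
pairing the paired t-test uses. Eviction = 100 − occupancy exactly. The
wt-vs-*hog1* comparison is a two-sided paired Student t-test on per-gene
eviction over the shared gene set; identical vectors return (t = 0, p = 1).

**Classification.** "Depends at least 25% on the kinase" is read as a
residual induction ratio fc_hog1/fc_wt ≤ 0.75 on the linear scale, and "at
least 90% similar" as ratio ≥ 0.90 (a log2-scale mode is provided). Genes in
the 0.75–0.90 gap are "neither" and are excluded from dependent/independent
comparisons. Thresholds: strict > for 1.75 and 3; inclusive bounds for
[1, 1.1] and ≤ 0.5. The optional override that counts ORF-Hog1-enriched but
expression-independent genes as independent is off by default.

## Numerical choices and degenerate inputs

- Pseudocount 0.5 on TRPK before logs keeps zero regions finite (M = 0,
  A = −1 for a double zero).
- A stratum sd within 1e-12 (relative) of zero is treated as zero spread.
- TMM requires ≥ 10 regions positive in both samples; zero-length regions,
  mismatched region sets, empty gene groups and < 3 paired genes raise
  errors.
- Promoters are clipped at chromosome edges; a fully clipped promoter
  degrades to a 1-bp window rather than an invalid interval.
- Deduplication and trimming use stable orderings, and every random draw
  flows from named child generators of the scenario seed, so whole-pipeline
  runs are byte-reproducible.

## Problem sizes

The default scenario used by the tests and the acceptance script is 500
genes (100 per class) at 5×10⁵ reads per sample — large enough that the
recovery targets (differential-recruitment sensitivity, ±5-point eviction
recovery, ±20-bp nucleosome centres) are limited by the estimators rather
than by sampling noise, while a full simulate-plus-analysis run takes
seconds. Null calibration uses 2 000 genes × 10 seed pairs at the same
depth.

## Known limitations

- The enrichment caller assumes Poisson-level technical noise; overdispersed
  biological replicates would need a wider null (no replicate structure is
  simulated).
- TMM over gene windows can retain a small residual offset when >30% of
  regions change in one direction; in the default scenario this appears as a
  few points of apparent negative eviction at unchanged genes.
- The peak caller reports maxima of the class-mean profile; it is not a
  per-gene dyad-resolution positioning method and carries no fuzziness
  statistics.
- BED is the only read format (SAM/BAM ingestion is out of scope), and the
  simulator emits protein-coding gene models only.
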