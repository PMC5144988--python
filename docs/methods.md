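# Methods

This note records the models, parameter choices, numerical conventions, and
known limitations behind musmosaic's four analysis stages and its
synthetic-data generator.

## Coordinates and genome model

All interval arithmetic is 0-based half-open (the BED convention); VCF
positions (1-based) are converted at the I/O boundary only. Windows tile
each chromosome as [0, w), [w, 2w), … with the final partial window
retained and truncated at the chromosome end; its statistics use its true
length. Retaining the partial window keeps chromosome ends covered; the
length-weighted ancestry summary treats it correctly and the unweighted
summary differs only by that one window per chromosome.

Mouse chromosomes are acrocentric, so "centromere-proximal" means the
low-coordinate end. The default centromere-proximal interval is the first
5 Mb of each nuclear chromosome, configurable per chromosome via a BED
file; no cytogenetic band definitions are used.

Masks (intersubspecific introgression / contamination) are normalized to
sorted, disjoint intervals; adjacent half-open intervals merge. A window is
excluded from ancestry analysis when its mask-overlap fraction exceeds 0.5
(configurable). The threshold is a genuine free choice: windowing a
region-level mask necessarily leaves partially masked windows, and 0.5
treats a window as analyzable while most of its sequence is unmasked.

## Variant I/O

The supported VCF v4.2 subset is CHROM POS REF ALT FILTER
INFO{DP, MQ, DP4 or AD} FORMAT{GT}, read and written through pysam.
Alt-supporting reads are the sum of the two alt-strand DP4 counts when DP4
is present, else the focal sample's alt AD. MQ is taken as the site-level
INFO value, not recomputed. Indel alleles are normalized only by
left-trimming the shared prefix; with no reference FASTA in scope, full
left-alignment is not attempted. Heterozygous genotypes in inbred samples
are retained at parse time — rejecting them is the homozygosity filter's
job, keeping I/O policy-free. pysam aborts on a structurally malformed
record; the reader reports the failing record index rather than silently
skipping, so no record is ever dropped without notice.

## Hard filters

Every threshold comparison is strict (DP = 5 fails "> 5"); the
mitochondrial rule is a minimum only, since mtDNA is high-copy and a
nuclear-style maximum would reject everything. Homozygosity is evaluated on
the focal sample alone — each strain is filtered independently, and the
joint panel enters only at privacy classification. Homozygous-reference
focal genotypes pass the homozygosity rule (the site may still be a variant
of the other strain). Indel proximity is the absolute difference of VCF
anchor positions with no allele-span expansion — the simplest defensible
reading, configurable. Sites missing DP, MQ, or alt support fail with
MISSING_STAT rather than passing: the pipeline's contract is "variants
passing all filters", and an unevaluable filter is not passed.
`filter_all` is vectorized over numpy arrays; the scalar `filter_site` is
the same rules stated once per site, and the tests hold the two (plus an
independent straight-line reference) verdict-for-verdict equal.

## Privacy classification

Classification is per alternate allele (privacy is an allele property, so
multiallelic sites get one call per alt). Precedence: any panel strain
carrying the allele (het or hom) decides *known* outright; otherwise a
missing panel genotype makes the call *unclassifiable*, because absence
from the panel cannot be established; otherwise the focal homozygous
carriers decide private_A / private_B / shared_exclusive. A configuration
where neither focal strain is a homozygous carrier is also unclassifiable —
the category set has no bucket for "not a variant of either focal strain",
and the pipeline's pre-condition (site passed filters for a focal strain)
keeps such sites out of the real flow; the total function exists so the
classifier can be enumerated exhaustively in tests. The panel is
quantifier-based ("absent from all"), not count-based, so its size is
arbitrary. Ts:Tv is computed over the novel (non-known, non-unclassifiable)
biallelic SNVs.

## Ancestry painting

Polarization uses the outgroup's homozygous allele as ancestral; the
reference allele can be derived. Excluded sites (het/missing outgroup,
multiallelic, non-SNV) and sites with any missing representative genotype
are tallied per window but carry no signal; "exactly one representative
carries the derived allele" is undecidable under missing data, so such
sites are excluded rather than imputed. Only focal-homozygous-derived sites
contribute — these are inbred genomes, and homozygosity is already a filter
requirement.

The window label is the argmax of the per-representative exclusive-sharing
counts, with two guards: fewer than 10 informative sites → *uninformative*
(at the default density of 1/500 bp a 25-kb window carries ~50 candidate
sites, so ~20+ informative sites are typical and the floor only catches
genuinely depleted windows), and a tied argmax → *ambiguous*. Both knobs
and the window width are config-exposed. Genome fractions are reported
both as unweighted window fractions and length-weighted; the two differ
only through truncated final windows. Per window the bookkeeping identity
counts + non-exclusive + focal-not-derived + excluded = total biallelic
SNVs holds exactly and is asserted in tests.

No HMM or probabilistic smoothing is applied: the method is deliberately
the plain windowed statistic, so single-window noise is visible rather
than absorbed into a model.

## Depth analytics

Depth enters as windowed means (25-kb default, sharing the ancestry grid);
no per-base pileups or BAMs are touched. Normalization divides by the
autosome-wide median MQ>20 depth, making the autosomal median ratio 1 and
the operation idempotent. Sex calls use the median normalized X ratio with
a 0.75 threshold (XY male ≈ 0.5, XX female ≈ 1.0; the boundary goes to
female); only XX/XY karyotypes are modeled. The callable fraction uses the
inclusive boundary (exactly 10× is callable) and weights windows by
length.

The CNV screen calls runs of ≥ 3 windows with normalized depth < 0.25 or
> 1.5; a call is private when every control track's mean over the span
stays in [0.75, 1.25]. These four numbers are not derived from any external
source — they are declared screen definitions, config-exposed, chosen so a
homozygous deletion (ratio ≈ 0) or full duplication (ratio ≈ 1.5+) is
unmissable while typical window noise (CV ≈ 14% at the generator's default
dispersion) never produces a 3-window excursion. Runs never cross
chromosome boundaries. The centromere screen reports, for every
Robertsonian-fusion chromosome, the private calls overlapping its
centromere-proximal interval; an all-zero table is an explicit negative
finding, not an empty result.

## Synthetic-data generator

The generator emulates the statistical structure the pipeline consumes,
not the biology that produces it:

- **Mosaic.** Segment lengths are exponential (mean 1 Mb default);
  each new segment's ancestry is drawn with weights proportional to each
  ancestry's remaining base-pair deficit against its target fraction. This
  self-correcting scheme keeps realized fractions within a fraction of a
  point of targets once a genome holds ~100 segments, where iid sampling
  would wander by several points. Defaults target 92% dom / 8% mus — the
  ancestry composition typical of a *M. m. domesticus* wild-derived strain
  with minority introgression.
- **Sharing.** Within a segment of ancestry s, a site's derived allele is
  shared exclusively with representative s with probability 0.8, with a
  single wrong representative with probability 0.05 (standing in for
  incomplete lineage sorting and homoplasy, and making recovery
  non-trivial), and otherwise non-exclusively (zero, two, or three
  carriers). Each representative genotype is independently missing with
  probability 0.02. No coalescent is simulated: the painting statistic
  consumes only sharing patterns, and generating them directly keeps the
  truth exact at desk scale.
- **Polarity.** The outgroup is homozygous ancestral (= reference) at
  polarizable sites (90% default) and het/missing otherwise. The
  polarity-flip case (outgroup homozygous alt) is exercised in unit tests
  rather than generated, keeping the generator's truth alt-centric and
  consistent with the privacy channel.
- **Privacy.** Categories are drawn per site (defaults 33% private-A, 33%
  private-B, 14% shared, 20% known) and realized directly in the focal and
  panel genotypes. The recorded truth is then re-derived from the emitted
  genotypes by a straight-line rule inside the generator, so truth and data
  cannot disagree even at sites whose genotypes were perturbed by the
  filter-failure channel.
- **Site statistics.** 90% of sites draw DP/MQ/alt-support strictly inside
  all filter bounds; the rest violate one randomly chosen filter.
  Transitions are drawn with probability 2.14/3.14 so the expected Ts:Tv
  is 2.14, the value typical of mouse germline SNVs. Indels (10% of sites)
  have length differences of 1–9 bp.
- **Depth.** Each window's MQ>20 depth is the mean per-base depth implied
  by an overdispersed read count: reads per window follow the continuous
  gamma analog of a negative binomial with variance n + 0.02 n², converted
  back to depth via the 100-bp read length. Modeling the count (≈ 4,500
  reads per 25-kb window at 18×) rather than the window mean keeps the
  window-mean coefficient of variation at the realistic ~14% — applying
  count-level dispersion to the mean itself would inflate sampling noise
  by the window/read length ratio. Males get a 0.5 factor on X; CNV
  intervals scale the local mean by their copy ratio (overlap-weighted at
  window edges); depth_total adds a 12% low-MQ excess. Default depth is
  18× (the deeper of the two strains that motivated the pipeline; the
  other was 14×).
- **Mask.** Random intervals (exponential lengths, mean 500 kb, capped at
  the remaining deficit) accumulate until 19% of the nuclear genome is
  masked — the masked share of the real analysis.
- **Determinism.** One `numpy` SeedSequence is split into named child
  streams (mosaic, variants, mask, one per depth track), so adding a
  component never perturbs earlier streams, and identical configs produce
  byte-identical output files.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: alignment artifacts and mappability structure
(the real uncallable fraction is dominated by repeats and segmental
duplications; synthetic callable fractions are near 100% at 18×), GC bias,
linkage between nearby sites, realistic indel length spectra beyond the
<10 bp bound, population history behind the sharing probabilities, and
sample contamination. Recovery results on synthetic data bound the
statistical behavior of the estimators, not the quality of an upstream
caller.

## Problem sizes

Default end-to-end runs use a 60-Mb genome (5 × 10-Mb autosomes + 10-Mb X
+ chrM) with ~120k candidate sites and 2,400 25-kb windows — large enough
that ancestry fractions, Ts:Tv, and false-call rates are measured with
sub-point precision, while a full pipeline run stays under half a minute.
Repeated-seed checks (sex inference, CNV false-call rate) use 100 seeds on
a 20-Mb layout.

## Numerical conventions and degenerate inputs

- Ts:Tv with zero transversions reports NaN, not an error.
- `summarize_ancestry` with every window masked is an error (there is no
  denominator); a single analyzed window is fine.
- Normalizing an all-zero-depth track is an error; a zero-depth window in
  an otherwise covered track is a ratio of 0.
- An empty VCF writes a valid header-only file and reads back as an empty
  stream.
- A genome shorter than one expected mosaic segment warns and emits
  single-segment chromosomes.
- Exit codes of the CLI: 0 success, 2 validation error (before any stage
  runs), 3 stage failure.
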