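# Methods

This note documents the statistical procedures, their assumptions, the
numerical and design choices that were genuinely open, and what the
synthetic-data generator does and does not emulate.

## Data model

All analyses consume *condition tables*: per-position duplex depths and
per-allele alternate duplex depths summed over the replicate animals of one
strain × tissue × age condition, on a circular mt-genome with 1-based
inclusive coordinates (position L+1 ≡ 1).  Frequencies are always ratios of
summed counts, never averages of per-sample frequencies.  A position's
mutation frequency is the sum of all alternate-allele depths over its duplex
depth (multi-allelic sites sum, they do not take the max).  Indels are
left-aligned to their minimal anchor-base representation at the reader.

The standard filter removes every allele at positions whose total mutation
frequency exceeds 1×10⁻³ (such positions are dominated by inherited or
early-developmental heteroplasmies rather than somatic mutations); the
de-novo event filter keeps alleles with alternate depth < 100 and frequency
< 0.01 and scores each surviving (position, ref, alt) once.  The reversion
analysis deliberately uses the *unfiltered* table.  Depth normalisation
across conditions rescales counts by the deterministic binomial-downsampling
expectation to the per-position minimum depth (count × min_depth / depth);
this is reproducible where stochastic downsampling is not, and leaves
frequencies unchanged in expectation.

## Consequences and site counting

Consequences use the vertebrate mitochondrial genetic code (AGA/AGG stop,
ATA Met, TGA Trp; table 2 via Biopython).  Positions are attributed to the
first annotated protein-coding region that contains them; minus-strand
genes are handled by complementing into the coding frame.  Genes whose
length is not a multiple of three (incomplete stop codons are common in
mtDNA) have the trailing partial codon excluded from consequence calls and
site counting, with a log warning.

Synonymous/nonsynonymous site counts are equal-weight (Nei–Gojobori-style):
each of the three possible substitutions at a codon position contributes
1/3 site to the class of its consequence, stop gains counting as
nonsynonymous, so the two totals sum exactly to the counted coding length.
No transition/transversion weighting mode is provided.

## Burden

The condition mutation frequency is Σ alt / Σ depth with the exact Garwood
interval [½χ²(α/2, 2k), ½χ²(1−α/2, 2k+2)] / Σ depth.  Region mutation
probability is count / (length × mean regional depth).  "Percent bp
mutated" counts unique mutated positions, not allele multiplicity.
Age and strain rate effects are Poisson GLMs with a log total-depth offset
("log-link regression"); because alternate-read counts cluster into
heteroplasmic events, they are overdispersed relative to Poisson, so the
Pearson dispersion is reported as a diagnostic and Wald intervals should be
read accordingly.  Per-condition age tests are Bonferroni-adjusted.

## Hotspot scans

Sliding windows (default 150 bp, step 1) wrap the circular origin; a
window's frequency is Σ counts / Σ depth over the window, which makes the
depth-weighted track mean equal the global frequency and the scan exactly
equivariant under genome rotation.  Hotspot calling (maximal runs of
windows above a fold-over-background threshold, merged across the origin)
is a convenience for testability; thresholds are free parameters, not a
claim about significance.

## Mutation spectra

SNVs collapse across strands into six classes named by their
purine-reference representative (G>A/C>T, G>T/C>A, G>C/C>G, T>C/A>G,
T>A/A>T, T>G/A>C); insertions and deletions complete the 8-class spectrum.
Class frequencies divide by the duplex depth summed over positions whose
reference base matches the class's strand pair (G:C or T:A); indel
frequencies divide by total depth.  Trinucleotide contexts collapse to the
pyrimidine-centred representative (ACG stands for ACG with C>T and CGT with
G>A).  Age association per class is a two-sided Fisher exact test on
[count, denominator − count] × [young, aged], BH-adjusted across the eight
classes; the count-versus-depth construction is one of two defensible 2×2
layouts and is the one implemented.  The Fisher p is computed by direct
hypergeometric summation (every table probability not exceeding the
observed one), which matches R's two-sided convention.

The null consequence spectrum enumerates all three substitutions at every
coding position once and reports the class composition of all possible
missense and of all possible synonymous changes — the reference against
which observed missense/synonymous spectra are compared.

## Selection: hN/hS against a simulated null

The statistic per gene is hN/hS with counts weighted by duplex
alternate-allele depth.  The null redraws the observed mutations and places
each uniformly at random (with replacement) among the positions whose
reference nucleotide admits its strand-collapsed type, then re-scores every
gene; 10,000 simulations is the default (the bundled scenario studies use
2,000, which already resolves the BH threshold at the scales involved).
Statistics with hN = 0 or hS = 0 are reported as undefined and excluded,
never silently dropped; simulations that leave a gene undefined are
excluded for that gene only.

Empirical p-values are two-tailed: the more extreme tail fraction doubled,
ties counted as extreme, clipped at 1; a p of 0 means "below 2/n_sims".
BH runs across genes and conditions within a mode, and within each
frequency bin for the binned scan (which keeps the number of corrected
tests comparable between modes).  Verdicts at BH-adjusted p < 0.01:
positive when the ratio exceeds 1, negative below 1.

Two structural choices deserve emphasis:

- **Placement unit.**  Placing every *read* independently (the literal
  multinomial over summed alt depths) ignores that duplex reads cluster
  into heteroplasmic events; under alt-depth weighting such a null is far
  too narrow and mis-calibrated.  The default therefore relocates observed
  *events* carrying their alt-depth weights.  In aggregated modes the event
  unit is the per-replicate record — heteroplasmies private to different
  animals are independent origins.  The binned scan instead relocates the
  aggregated (position, ref, alt) records, because bin membership is a
  condition on the aggregated record's frequency: relocating its
  constituents independently would break the exchangeability the empirical
  p-value relies on.  The read-level multinomial remains available as
  `placement_unit="read"`.
- **Type/position reconciliation.**  "Uniform placement" is uniform over
  the positions admitting the drawn type's reference pair.  Placement
  intensity differences between regions cancel inside the per-gene ratio;
  what moves the null is the *type mix*, which is exactly how pooling
  frequencies induces the spurious positive-selection artifact that the
  binned, D-loop-excluded mode removes.

The aggregated modes apply the 1×10⁻³ frequency cap; the binned mode keeps
all frequencies and excludes D-loop positions from both observed counts and
null placement.  Default bin edges are {4×10⁻⁶, 10⁻⁵, 5×10⁻⁵, 10⁻⁴,
5×10⁻⁴, 10⁻³, 1}: the lowest edge is the detection floor of a ~2.5×10⁵×
aggregated duplex experiment, and the interior edges bracket the
intermediate-frequency band where selection is expected to act; they are
fully configurable.  Indels carry no synonymous/nonsynonymous status and
are excluded from hN/hS; type proportions renormalise over the six SNV
classes.

## Reversions and NUMT correction

Haplotype sites are positions where the conplastic mt-genome differs from
B6; a reversion is a somatic mutation reintroducing the B6 allele.  Because
the chr1 NUMT carries B6 alleles, nuclear reads inflate apparent reversion
frequencies inside the NUMT-homologous interval.  The contamination
fraction is estimated per junction as mean chr1-supporting depth over the
mean mitochondrial depth (computed outside the interval), taking the
maximum junction estimate as a conservative headline; optional SNV-cluster
counts give a median cross-check.  Correction subtracts the estimated chr1
depth from both the reversion allele depth (floored at zero, with a
warning) and the duplex depth.  Corrected frequency is monotone
non-increasing in the contamination fraction.  Note the correction removes
the *expected* contamination; the binomial fluctuation of the realised
contamination at a site is an irreducible noise floor of order √(cD) reads.

Site significance is empirical and one-sided: the fraction of non-haplotype
background positions (same condition, unfiltered, zero-coverage positions
excluded) whose frequency is at least the site's corrected frequency,
BH-adjusted across sites; strains with many sites also get a Wilcoxon
rank-sum test.  Age deltas compare depth-normalised young and aged tables;
"more extreme" defaults to magnitude (|background delta| ≥ |site delta|),
configurable to signed.  The reversion-allele test contrasts B6-versus-other
alternate reads at the site with the genome-wide share of the matching
substitution class by Fisher's exact test.  Thresholds (BH 0.01) are config
values.

## Synthetic-data generator

The generator emulates the *statistical structure* of an aggregated duplex
experiment on a small circular genome (default 5.4 kb: a 900 bp D-loop,
eight 450 bp genes — one on the minus strand — OriL, two tRNAs, two rRNAs),
with per-sample depths ~2×10⁴ (NB dispersion giving ~2% positional spread,
matching the smoothness of real duplex coverage) and four replicates, i.e.
~8×10⁴ per condition, the scale of a well-covered condition.

Event frequencies are parameterised on the aggregated condition scale
(log-uniform on [10⁻⁶, 10⁻³] by default, the observed heteroplasmy range);
an event private to one replicate gets per-sample frequency n·f so the
aggregated table shows it near f.  Events arise Poisson per position at a
base rate times region multipliers, draw a class from the 8-class spectrum
restricted to the classes admissible at their reference base, and realise
Binomial(depth, n·f) alternate reads.  Optional machinery: a second
spectrum above a frequency threshold (frequency-dependent spectra),
per-region frequency ranges (hotspots of high-frequency mutations),
thinning of amino-acid-changing SNVs inside a frequency band (negative
selection), B6-reversion alleles present in all replicates at fold ×
background mean frequency, and NUMT contamination that adds Poisson(c·depth)
reads (B6-carrying at haplotype sites) inside the homologous interval plus
matching junction counts.

Canonical scenarios fix these knobs: `neutral` (calibration), `hotspot`
(focal 5× segment), `dloop_artifact` (6× D-loop of 5–8×10⁻⁵ transition-heavy
mutations over a transversion-heavy low-frequency background — the
frequency-pooling artifact), `missense_thinning` (2× thinning above 5×10⁻⁵),
and `reversion` (fold 7 at four sites, 0.5% contamination).  The reversion
scenario runs at an NZB-like elevated heteroplasmy scale (background mean
~3×10⁻⁴): a 0.5% contamination correction is only materially testable when
the contamination depth is comparable to the site counts, and the
background's frequency range is kept below ~4×10⁻⁴ so that site enrichment
is separable from background stacking.

What the generator does **not** emulate: read-level errors and duplex
consensus artefacts (end-repair damage, trimming), strand bias, true
trinucleotide context preferences (classes are context-independent),
mutational signatures beyond the 8-class mix, realistic gene order or
codon usage, cell-type heterogeneity, and linkage between events on the
same molecule.  Passing the recovery suites therefore demonstrates that the
*estimators and tests* behave correctly under the assumed generative
structure, not that real libraries are free of upstream artefacts.

## Problem sizes in the bundled studies

The recovery studies simulate the 5.4 kb genome rather than a full 16.3 kb
mt-genome, with 50 seeds for the calibration/artifact/thinning studies
(three conditions per seed for the artifact, mirroring pooled BH across
conditions) and 100 seeds for reversion recovery, at 2,000 null simulations
per test.  These sizes resolve the BH-0.01 threshold (2/2000 < 0.01/8)
while keeping a full run in minutes.

## Known limitations

- The hN/hS null conditions on the observed event set; it does not model
  uncertainty in the event frequencies themselves.
- The Poisson GLMs ignore event-level clustering (dispersion is reported,
  not modelled); a per-animal mixed model is out of scope.
- Overlapping genes use first-annotation attribution for consequences.
- The NUMT correction assumes all chr1 reads carry the B6 allele and a
  spatially uniform contamination depth across the homologous interval.
- `percent bp mutated` depends on depth through detectability; it is
  intended for depth-normalised pairs only.
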