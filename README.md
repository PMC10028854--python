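# mitosoma

Somatic mitochondrial mutation analysis from duplex-sequencing variant
tables.

Duplex sequencing reads both strands of each mtDNA fragment and calls a
consensus, pushing error rates below ~1 in 10⁷ and exposing heteroplasmies
at frequencies of 10⁻⁶–10⁻³.  `mitosoma` takes the per-sample, per-position
output of such an experiment — alternate-allele duplex depths and total
duplex depths over a circular mitochondrial genome — and implements the
downstream population-genetic analysis for researchers studying somatic
mtDNA evolution across tissues, ages and mitochondrial haplotypes:

- **Burden** — condition-level mutation frequencies with exact Poisson
  (Garwood) confidence intervals, region-wise mutation probabilities, and
  Poisson log-link regressions of age- and strain-associated rates.
- **Hotspots** — circular sliding-window frequency scans (150 bp default),
  repeat-tract frequencies, and hotspot interval calling.
- **Spectra** — strand-collapsed 8-class mutation spectra (6 SNV classes +
  INS + DEL) with reference-nucleotide-restricted denominators,
  pyrimidine-centred trinucleotide spectra of de-novo events, and exact
  Fisher tests of age association.
- **Selection** — the heteroplasmy analogue of dN/dS,

  hN/hS = (nonsynonymous counts / nonsynonymous sites) /
  (synonymous counts / synonymous sites),

  with counts weighted by duplex alternate-allele depth, sites counted by
  equal-weight (Nei–Gojobori-style) enumeration under the vertebrate
  mitochondrial code, and significance from a simulated null that redraws
  the observed mutations and places them uniformly at random among
  admissible positions.  Empirical p-values are two-tailed and BH-adjusted;
  the scan runs frequency-aggregated or binned by mutation frequency with
  the D-loop excluded — the comparison that separates genuine purifying
  selection from the artifact created by pooling frequency-dependent
  mutation spectra.
- **Reversions** — at haplotype sites (positions where a conplastic
  mt-genome differs from the B6 nuclear-matched genome), enrichment of
  somatic reversions to the B6 allele, corrected for nuclear-embedded
  mitochondrial (NUMT) read contamination estimated from chr1 junction
  depths, with empirical significance against the background per-position
  frequency distribution and age-delta tests.
- **Synthetic data** — a ground-truth generator that emulates the whole
  data structure (depths, low-frequency events, hotspots, spectra shifts,
  selection thinning, reversions, contamination), so every stage is
  testable without any sequencing data.

## Worked example

Simulate a conplastic condition with fold-7 reversion enrichment at four
haplotype sites and 0.5% NUMT contamination, then recover both:

```python
import numpy as np
from mitosoma.simulate import (GenomeSpec, generate_genome, reversion_truth,
                               condition_table)
from mitosoma import (mean_mutation_frequency, apply_site_filters,
                      estimate_numt_contamination, haplotype_site_test)

genome, sites = generate_genome(
    GenomeSpec(n_haplotype_sites=4, haplotype_interval=(1000, 3000)), seed=1)
truth = reversion_truth(seed=1)            # fold-7 reversions, 0.5% NUMT reads
table, extras = condition_table(truth, genome, sites, ("CONP", "liver", "young"))

freq, ci = mean_mutation_frequency(apply_site_filters(table))
print(f"mean somatic mutation frequency: {freq:.3e}  (95% CI {ci[0]:.3e} - {ci[1]:.3e})")

lo, hi = truth.numt_interval
outside = np.ones(genome.L, bool); outside[lo - 1:hi] = False
est = estimate_numt_contamination(extras["junction_counts"], table.depth[outside].mean())
print(f"estimated NUMT contamination: {100 * est.contamination_fraction:.2f}%")

result, _ = haplotype_site_test(table, sites, est, numt_interval=truth.numt_interval)
print(result[["position", "raw_freq", "corrected_freq", "empirical_p", "adjusted_p"]]
      .round(6).to_string(index=False))
```

prints

```
mean somatic mutation frequency: 2.782e-04  (95% CI 2.766e-04 - 2.797e-04)
estimated NUMT contamination: 0.51%
 position  raw_freq  corrected_freq  empirical_p  adjusted_p
     1523  0.006816        0.001770          0.0         0.0
     2341  0.006798        0.001718          0.0         0.0
     2681  0.007233        0.002201          0.0         0.0
     2689  0.006951        0.001842          0.0         0.0
```

The raw haplotype-site frequencies (~7×10⁻³) are dominated by contaminating
nuclear reads carrying the B6 allele; after subtracting the estimated chr1
read depth the corrected frequencies sit near 7× the background mean
(2.8×10⁻⁴), and every site beats all background positions (empirical p = 0,
i.e. below 1/number of background positions).

The same analyses run from the shell on on-disk datasets:

```bash
mitosoma simulate -o fixtures --seed 1      # write synthetic scenarios
mitosoma run -c config.yaml -o results     # burden/hotspots/spectra/selection/reversions
```

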