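# dgrpld

Genome-wide linkage-disequilibrium (LD) cataloguing and inversion
karyotyping for panels of sequenced inbred lines, built around the
*Drosophila* Genome Reference Panel (DGRP) design: ~200 inbred lines, a
rare-skewed site-frequency spectrum, a handful of polymorphic chromosomal
inversions at low frequency, and residual heterozygosity left over from
inbreeding.

## Who this is for

Association studies on inbred panels are confounded by LD: a variant with no
phenotypic effect can show a significant association simply because it is
correlated with a causal variant — possibly one hundreds of kilobases away or
on another chromosome, since rare alleles in a small panel are frequently
correlated by chance ("rarity disequilibrium") and inversions carry diverged
haplotypes across megabases.  This package finds every highly correlated pair
of sites, summarises where a SNP's correlated partners lie, types inversion
karyotypes directly from genotypes, and quantifies the false-positive risk
that correlated partners pose to multivariate association tests.

## The statistics

* **LD measure.** For two biallelic sites with minor-allele-coded genotypes
  over the jointly called lines, LD is the squared product-moment correlation
  r². Heterozygous calls are treated as missing for LD; a pair with
  r² ≥ 0.5 is "highly correlated", and sites more than 100 kb apart are
  "distant". Focal sites require minor allele count (MAC) ≥ 5; partners may
  have MAC ≥ 3; sites with more than 85 missing calls are excluded, and
  genotypes with phred quality < 20 are set missing.
* **Fast all-pairs search.** Two sites can only reach r² ≥ c if their minor
  allele frequencies are similar: for focal MAF p, a partner must satisfy
  c·p < MAF < p/c. Sites are binned by MAF to the nearest 0.01 and each bin
  is correlated only against partners inside an admissible MAF window (the
  theoretical bound, or the wider of it and an empirically fitted quadratic
  limit 0.01 + 1.875·p_b − 1.17·p_b²). On complete data with theoretical
  windows the scan provably returns exactly the brute-force set.
* **Inversion karyotyping.** SNPs inside an inversion's breakpoints that are
  in high LD with ≥ 200 distant sites (scaled down for small panels) are
  diagnostic of arrangement class. A PCA of a random 5000-SNP subset of their
  dosage matrix (missing imputed to the common allele) separates Standard and
  Inverted lines on PC1, with heterozygotes midway; the region
  heterozygosity H (proportion of calls that are heterozygous; H > 0.15 is
  "highly heterozygous") flags lines whose sequence contradicts the call.
* **False-positive profile.** A focal SNP receives an effect explaining 1% of
  the variance of a multivariate trait; every partner at r² > 0.25 (its "SNP
  family") is tested by one-way MANOVA with the chi-square (Bartlett)
  approximation of Wilks' Λ: χ² = −(n − 1 − (d+2)/2)·ln Λ on d degrees of
  freedom. Rejection rates per r² bin show how far down the r² scale false
  positives reach.

A synthetic-panel generator (`dgrpld.synthetic_data`) reproduces all of this
structure with a ground-truth manifest, and everything is exercised against
it.

## Worked example

```bash
cd analysis
python 01_simulate_panel.py
python 02_scan_ld.py
python 03_summarize_ld.py
python 04_karyotype.py
```

prints (abridged):

```
panel: 205 lines x 3000 sites (2 inversions)
focal sites (MAC>=5): 1905; partner-eligible (MAC>=3): 2200
median MAF of focal sites: 0.075
high-LD pairs (r^2 >= 0.5): 32727
scan vs all-pairs enumeration: 0 missed, 0 spurious
focal SNPs with >=1 high-LD partner: 29.6%
  with >=1 distant partner:          19.1%
mean partners per focal SNP: 34.6 (median 0)
mean partners, MAF<0.1: 45.9 vs MAF>=0.3: 0.3 (rarity disequilibrium)
In(2L)sim: {'Std': 186, 'Inv': 13, 'Het': 6} (11 lines H-flagged)
concordance with truth manifest: 408 of 410 (99.5%)
```

Reading this: on a desk-scale panel nearly a third of testable SNPs already
have at least one interchangeable partner at r² ≥ 0.5, the burden falls
almost entirely on rare variants (mean 45.9 partners below MAF 0.1 versus
0.3 above 0.3 — while the median is 0, the degree distribution being
strongly right-skewed), and genotype-based karyotype calls recover the
planted inversion status of 99.5% of line × region combinations.  Drivers
05–06 add the heterozygosity-correlation structure and the MANOVA
false-positive profile.

The same stages are available as a CLI for real VCFs
(`dgrpld simulate | filter | scan | summarize | karyotype | hetcorr | fpsim`);
run any subcommand with `--help`.

## Layout

```
src/dgrpld/        library: synthetic_data, genotype_io, ld_scan,
                   ld_summary, inversion_typing, het_structure,
                   fp_simulation, cli
analysis/          numbered narrative drivers (01 simulate ... 06 fp sim)
scripts/           acceptance.py
tests/             pytest suite (unit, property and end-to-end checks)
docs/methods.md    model, assumptions, parameter choices, limitations
```
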