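# Methods

## Scope and data model

The package operates on a lines × sites call matrix with four codes (REF and
ALT homozygote, heterozygote, missing) read from a multi-sample VCF with GT
and GQ fields.  Inbred lines are treated as (nearly) homozygous: two
encodings are derived from the same matrix — an *LD encoding* in which
heterozygous calls become missing, used for every correlation, and a
*karyotyping encoding* that retains heterozygotes as dosage 1.  Only
biallelic records are used; indel records, if present, are treated as
generic biallelic variants.  Genotypes with phred-scale quality below 20 are
set missing on input.

## Site filters

Per-site statistics (minor allele count MAC, minor allele frequency MAF,
called/missing/het tallies) are computed on the LD encoding, i.e. after
heterozygote-to-missing conversion; the karyotyping path recomputes its own
counts from the het-retained matrix.  Focal sites require MAC ≥ 5, partner
sites MAC ≥ 3, and both exclude sites with more than 85 missing calls — an
absolute count calibrated to a 205-line panel; `max_missing_frac`
(85/205 ≈ 0.415) is provided for other panel sizes.  At an exact frequency
tie the ALT allele is designated minor so the 0/1 coding is deterministic;
r² is invariant to the choice.

## The high-LD scan

r² between two sites is the squared Pearson correlation of their 0/1 vectors
over the jointly called lines, computed for whole blocks of site pairs with
three masked matrix products (for 0/1 data the pairwise-complete sums of x,
x² and xy are all inner products of the genotype and mask matrices).  A pair
is undefined — and silently not a pair — when fewer than 2 lines are jointly
called or either restricted vector is constant.

Two sites with folded MAFs p ≤ q ≤ 0.5 satisfy, on complete data,
r² ≤ p(1−q)/(q(1−p)); consequently a partner of a focal site with MAF p can
reach the cutoff c only if c·p < MAF < p/c.  The scan bins sites by MAF
rounded to the nearest 0.01 (round-half-up; the tie rule is configurable)
and, per bin at frequency p_b, correlates the bin's focal members against
all partner-eligible sites with MAF in [c·(p_b − 0.005), hi]:

* `window="theoretical"`: hi = (p_b + 0.005)/c.  Widening both window edges
  to the bin's extreme frequencies makes the scan provably equivalent to
  brute-force enumeration on complete data — every attainable pair has both
  members inside some bin's window (verified by set equality against an
  independent pandas pairwise-complete correlation in the tests).
* `window="empirical"` (default): hi is the larger of the theoretical limit
  and a quadratic empirical limit 0.01 + 1.875·p_b − 1.17·p_b², plus an
  ε = 0.005 margin.  With missing data the MAF realised on a pair's
  jointly-called subset can drift outside the nominal window, so a small
  fraction of qualifying pairs can be missed; the margin keeps the missed
  fraction below 1% at 10% missingness on synthetic panels (measured
  against brute force in the acceptance checks).  `fit_empirical_limit`
  re-estimates the quadratic on any panel by per-bin maxima of the partner
  MAF attaining the cutoff.

The lower window edge extends *below* the bin (rather than starting at
p_b + 0.005) so that same-bin pairs and pairs whose lower-MAF member is
partner-only (MAC 3–4, hence never focal) are examined too.  Each unordered
pair is emitted exactly once — focal–focal pairs from the lower bin with
(chrom, pos) tie-breaking, focal–nonfocal pairs from the focal member's bin —
and the catalogue (sites, r², joint call count, distance, class) is sorted
and fully deterministic; the comparison is `r2 >= cutoff`, with the cutoff a
flag.  Pairs are classed *local* (same chromosome, ≤ 100 kb), *distant*
(same chromosome, > 100 kb) or *interchromosomal*.

## Catalogue summaries

Per-site partner degrees count every catalogue pair toward both members
(partners below the focal MAC threshold are counted as partners; only focal
sites are reported).  "Distant" degrees include interchromosomal partners by
default — a different chromosome is "more than 100 kb away" in the ordinary
sense — with a flag to restrict to same-chromosome pairs, since either
reading of the convention is defensible.  Summaries: fractions of sites with
≥ 1 partner (overall / distant / other-chromosome), optionally stratified;
mean and median degrees per MAF class (default width 0.02); mean distant
degree per non-overlapping 100-kb window (half-open on pos − 1; windows with
no focal site are reported missing); and the r² distribution of seeded
uniform random focal pairs (sampled with replacement).

## Inversion karyotyping

Sites with fewer than 5 missing calls are kept, remaining missing calls are
imputed to the common allele *before* the PCA subsample is drawn, and calls
are dosage-coded 0 (common homozygote) / 1 (het) / 2 (minor homozygote).
Diagnostic SNPs for a region are those inside its breakpoints whose distant
partner degree is at least `min_distant_partners` (default 200, the
full-panel scale; scale it roughly with the number of catalogued sites in
the region — the analysis drivers use 20 for a panel ~50× smaller).  Regions
are 1-based inclusive; rows of a region table sharing a name are unioned for
karyotyping, which is how a flanking segment (role `flanking-merged`) is
merged into its inversion, while heterozygosity summaries keep rows
separate.

PCA (full SVD, column-centred) of a seeded random subset of up to 5000
diagnostic SNPs yields PC1 scores; the sign is oriented so the minority
(inverted) cluster is positive, operationalised as positive skewness of the
score distribution.  Scores are clustered in 1-D: k-means with k = 3 and a
deterministic geometric initialisation at the score minimum, midpoint and
maximum — heterozygotes must score midway between the homozygote clusters
because dosage 1 is the average of 0 and 2 — followed by a merge of adjacent
clusters separated by less than 5% of the score range, so an unstructured
cloud is not forced into three groups.  Lowest cluster → Std, highest → Inv,
middle → Het; if only two clusters survive, the minority is Het when its
mean region heterozygosity exceeds the threshold and Inv otherwise; a single
cluster is all Std.  Region heterozygosity H is the proportion of a line's
called in-region sites scored heterozygous; H > 0.15 with a homozygous call
(or ≤ 0.15 with a Het call) sets an independent flag rather than changing
the call, and raw PC1 and H are always reported so users can re-threshold.
The clustering rule is this package's formalisation of what is usually an
eyeball decision; the thresholds are parameters, not estimates.

Concordance with an external assignment table (labels Std/Inv/Het/NA) is a
per-region cross-tabulation plus a discordance list carrying both labels,
PC1 and H.

## Heterozygosity structure and interval accounting

The lines × regions H matrix uses the same per-line H over a set of
non-overlapping regions (typically arm segments split at inversion
breakpoints).  Pairwise Pearson correlations over lines
(pairwise-complete — whether to drop lines with any undefined H is not
standardised, and pairwise-complete wastes nothing) get two-sided p-values
from the t transform with n − 2 df, classed `b` (P < 10⁻⁴), `a`
(10⁻⁴ ≤ P < 0.05) or `ns`.  Ancestry-interval accounting merges a line's
overlapping intervals before summing the intersection with a region;
coordinates are 1-based inclusive throughout, so an overlap of [a, b]
contributes b − a + 1 bases — conventions differ between sources, so this is
stated explicitly.

## False-positive simulation

A SNP family is a focal SNP plus all partners with catalogue r² above 0.25.
Focal SNPs are sampled per decile of the eligible-focal MAF distribution (10
per decile, 100 total; short deciles contribute what they have) and families
with more than 100 partners are down-sampled, all seeded.  Phenotypes are
multivariate: Y = g·β + E with E standard normal (unit isotropic
covariance), β a uniformly random direction scaled so the focal genotype
explains a set fraction (default 1%) of the total phenotypic variance
(trace), computed from the realised genotype variance.  The trait dimension
(default 10), the noise covariance and the effect construction are
simulation choices exposed as configuration — they are not estimates of any
particular study, and results should be read per trait dimension.

Each test is a one-predictor MANOVA: Λ = det(E)/det(E+H) from the residual
and hypothesis cross-product matrices, referred to chi-square via Bartlett's
approximation χ² = −(n − 1 − (d + q + 1)/2)·ln Λ with q = 1 and d·q df.
Against an exact-F implementation (statsmodels) our Λ agrees to machine
precision, and the chi-square tail is mildly conservative at small α — the
type-I calibration run (no effect, 165 lines, 10 traits, 2000 tests) stays
within 3 binomial SEs of α at 10⁻² and 10⁻³.  The profile reports, per r²
bin (default width 0.05 over (0.25, 1], midpoints as bin labels) and per α,
the rejection proportion of non-causal partners with its Monte-Carlo SE,
plus the focal SNP's own power.  A partner with r² = 1 rejects exactly when
the focal SNP does.

## The synthetic generator

The generator is the package's study-condition definition, not a fixture.
Defaults: 205 lines; two 2-Mb chromosome arms with 1500 sites each (desk
scale — large enough for thousands of catalogue pairs and stable PCA, small
enough that every end-to-end check runs in seconds); folded site-frequency
weights ∝ 1/k; 10-kb haplotype blocks with 8 founder haplotypes; two
inversions at frequencies 0.07 (5 heterozygous lines) and 0.05 (3), each
with 30% of in-region sites fixed differently between arrangements;
residual-het block rate 0.2 per line and region with incidence correlation
0.6 across regions and block length up to 20% of the region; 1% missing
calls and 2% low-quality (phred < 20) calls.

Mechanics and what they emulate:

* **Exact spectrum.** Each site draws its minor allele count k from the
  configured folded spectrum and exactly k lines carry the minor allele, so
  the realised spectrum matches the configuration up to multinomial noise
  (chi-square checked in the tests).
* **Founder blocks.** Within a block, lines are assigned one of the founder
  haplotypes and carriers are filled founder-first along a per-block
  priority order; carrier sets of same-block sites are therefore nested,
  giving strong local LD that decays with frequency difference and stops at
  block boundaries.  Sites rarer than the first whole founder fall through
  to individually random carriers — private-mutation behaviour, which is
  exactly what produces rarity disequilibrium among rare variants.
* **Inversions.** round(frequency × n) lines (seeded shuffle — deterministic,
  so small-panel tests are not at the mercy of binomial noise) are inverted
  homozygotes and a configured number heterozygous; a divergence fraction of
  in-region sites is overwritten to separate the classes (Het lines coded
  heterozygous).  Diagnostic sites therefore depart from the configured
  spectrum; spectrum checks use inversion-free configurations.
* **Heterozygosity blocks.** Each line draws one shared latent block
  (incidence Bernoulli plus length fraction); each region copies the shared
  latent with probability √ρ or draws independently, so the correlation of
  region heterozygosities equals the configured ρ by construction — sharing
  the length as well as the incidence is what prevents the attenuation that
  independent block lengths would cause.  Block length is capped at 20% of
  the region, which puts the mean region H near 0.02–0.04, the level
  observed in real inbred panels, and keeps partial het blocks from mimicking
  inversion heterozygotes.
* **Noise.** Missing calls are uniform at the configured rate; genotype
  qualities are 20 + Exponential(30) with a configured fraction uniform in
  [0, 20) to exercise the quality filter.  Same seed → byte-identical VCF.

What the generator does *not* emulate: coalescent genealogy, recombination
maps, gene conversion, population structure or relatedness between lines,
realistic indels, or reference bias in calling.  Passing tests therefore
demonstrate algorithmic correctness and statistical behaviour under the
stated structure, not performance on any real panel; in particular
interchromosomal high LD is much rarer here than in a multi-million-site
panel, simply because far fewer rare-variant carrier coincidences exist at
desk scale.

## Numerical and design notes

* Undefined correlations are non-pairs logged at debug level, never NaNs in
  output.
* The catalogue, summaries and karyotype calls contain no randomness beyond
  the documented seeds (PCA subsample, random pairs, simulations); reruns
  are bit-identical.
* Degenerate inputs fail loudly: empty panels, overlapping regions,
  malformed intervals, constant genotype predictors, all-identical PCA
  input, fewer lines than the trait dimension.
* Karyotype PC1 sign and cluster labels are stable across PCA subsample
  seeds on the reference panel (the minority-positive orientation is
  determined by the data, not the seed).
* Problem sizes in the analysis drivers and acceptance script (panels of
  200–205 lines × 1200–3000 sites, 10–20 seeds per recovery experiment,
  2000 null MANOVA tests, 10 replicates per SNP family) were chosen as the
  package's desk-scale study conditions; every experiment completes in
  seconds on one CPU.

## Known limitations

* The scan's miss rate under missingness is bounded empirically, not
  analytically; pathological missingness patterns (strongly structured by
  site pairs) could exceed the synthetic bound.
* K-means-with-merge on PC1 assumes at most three arrangement classes per
  region; multiple segregating inversions on one arm would need the
  `Anomalous`/flag route and manual review.
* MANOVA p-values use the chi-square approximation throughout (as is
  conventional for this design); exact-F or permutation p-values are out of
  scope.
* The ancestry-overlap step consumes interval tables; it does not infer
  ancestry.
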