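# Methods

`mosaicma` estimates per-base-pair, per-generation SNP mutation rates from
mutation-accumulation (MA) lines of clonally propagating organisms — the
motivating system is duckweed (*Spirodela polyrhiza*, *Lemna minor*) — in
which a daughter individual is founded by several parental cell lineages.
This note records the models, the parameter choices, the numerical
conventions, and the limits of what the synthetic tests demonstrate.

## The multi-cell descent model

Clonal reproduction is modelled as `n` parental cells founding each diploid
offspring. A new mutation occurs in one founder cell and is therefore
heterozygous in `1/n` of the offspring's cell lineages, i.e. at within-plant
allele frequency `1/(2n)`. Assuming all lineages grow at equal rates and
each generation's `n` founders are drawn at random from one exchangeable
pool, the mutant-lineage count performs neutral Wright–Fisher drift on a
population of `n` lineages ("somatic drift"):

* a single mutant lineage eventually fixes within the clone with
  probability `1/n` and is lost with probability `(n-1)/n`;
* the unconditional mean lineage frequency is conserved (martingale);
* all lineages coalesce in roughly `2n` generations in the large-`n`
  (coalescent) limit, with variance growing like `n²`.

On the last point the discrete chain is measurably below the asymptote at
small `n`: first-step analysis of the ancestral process gives an exact mean
time to the MRCA of 2.00, 5.78, **13.57** and 29.34 generations for
`n = 2, 4, 8, 16` — i.e. 84.8% of `2n` at `n = 8` and 91.7% at `n = 16`.
The test suite therefore checks the simulator against the exact values at
small `n` and against the `2n` law at `n = 16`, where the approximation is
good. `n = 1` recovers conventional single-cell descent (a new mutation is
an ordinary 50% heterozygote, fixed immediately).

The key practical consequence is that observed mutant-read fractions at de
novo sites center well below 50% whenever `n > 1`, which both motivates and
calibrates the power correction below. Cell-lineage selection (differential
lineage growth) and realistic meristem geometry are out of scope; founder
cells are drawn from a single exchangeable pool rather than per meristem
pouch, since nothing in the data model distinguishes the pouches.

## Pipeline

The analysis consumes a per-site, per-line table of read depths and base
counts (an mpileup-derived "pileup TSV", or an allelic-depth-bearing VCF)
plus line metadata; read alignment and genotype calling are upstream of the
package. Stages, per genotype group:

1. **Coverage filter.** Sites with depth summed across lines outside
   `median ± delta` are removed (`delta` = 200 reads by default; 100 is
   appropriate for lower-quality assemblies).
2. **Heterozygosity windows.** A consensus genotype marks a site
   heterozygous when ≥ 2 lines call it het. Sliding windows (1000 bp,
   100 bp step, anchored at position 1) containing more than `max_het`
   consensus hets (10 by default; 5 for noisier assemblies) mask every site
   they overlap. A site is masked if *any* overlapping window exceeds the
   threshold — the conservative reading, matching the filter's purpose of
   excluding variant-rich collapsed-duplication artifacts. Terminal partial
   windows use the same absolute count. Coordinates are 1-based inclusive
   internally, BED 0-based half-open on disk.
3. **Candidate calling.** A SNP candidate is a callable site where exactly
   one line is heterozygous with ≥ 5 reads supporting a single non-reference
   base and every other line is called homozygous (missing calls
   disqualify). Two pileup-level vetoes follow: any read of the mutant base
   in another line (`cross_line_support`), and more than two reads of
   *third* alleles — neither reference nor the focal mutant base — summed
   over all lines (`error_rich_site`). The third-allele reading is
   deliberate: counting *all* non-reference reads would contradict the
   ≥ 5-mutant-read requirement; the filter targets sequencing-error-prone
   sites. Short indels (≤ 10 bp) follow the same one-line logic plus a
   2000 bp exclusion radius around any other line's indel call (exactly
   2000 bp away is retained). A count-level linkage flag stands in for
   visual read inspection; read-level linkage is outside the input
   contract.
4. **Power.** Eligible sites (all lines hom-ref, ≤ 1 stray alternate read)
   are resampled — 500,000 draws by default, without replacement when
   enough sites exist — a line is chosen uniformly per site, sites with one
   stray alternate read are discarded with probability 1/3 (a coincidental
   error matching the mutant base would have vetoed a real mutation), and
   mutant reads are drawn from Binomial(depth, assumed fraction). Power is
   the fraction of the *original* sample reaching 5 reads, so the discard
   loss is absorbed into power — the only accounting under which
   multiplying callable sites by power corrects the rate for that veto.
   The assumed fraction defaults to the grid 0.50/0.34/0.28/0.20/0.10, with
   0.28 as the headline value (the observed mean mutant-read fraction in
   the motivating data); the true frequency distribution is unknown and the
   single-fraction correction is knowingly crude.
5. **Rates.** With `TP = n_validated / (n_validated + n_failed)` estimated
   once from all Sanger-tested candidates (TP = 1 when no validation data
   are supplied), the rate per group × treatment is
   `(n_validated_in_lines + TP · n_not_checked_in_lines) /
   (Σ_lines(callable × generations) · power · 2)`; candidates that failed
   validation are excluded outright. Intervals are Agresti–Coull at 95%,
   treating each site-generation copy as a Bernoulli trial; the fractional
   numerator is used as-is. Contrasts are 1-df Pearson chi-square tests on
   the 2×2 table `[mutations, exposure − mutations]` with effective counts
   rounded to integers only for the table (not for rates); no continuity
   correction is applied — at exposures of ~10¹⁰ site-generations the Yates
   correction is numerically irrelevant. A species-level contrast pools
   conspecific genotypes by summing numerators and power-scaled exposures
   per treatment. Spectra are strand-collapsed to the six pyrimidine
   classes; ti = C>T + T>C; a C>T is CpG when the mutated C is immediately
   followed by G on its strand.

## Synthetic data

The generator emulates the experiment end to end with known ground truth:
a random reference with ancestral heterozygosity (Bernoulli per site),
dense in-phase "collapsed duplication" regions with reference-biased
allelic coverage, per-line de novo mutations arising at `2μ` per
homozygous site per generation whose frequencies drift under the lineage
model until sequencing, Poisson read depth per line and site, binomial
allele sampling, uniform sequencing errors over the three non-reference
bases (matching the 1/3 coincidental-match probability the power model
assumes), and a threshold genotype caller (het at ≥ 2 alt reads and ≥ 10%
of depth).

Defaults follow the study conditions: 60 generations per line, 14 lines
per genotype, mean depth 26, `n = 8` founder lineages, mutation rate
8.4 × 10⁻¹¹ /bp/gen. Values the source experiment does not print were fixed
once at field-typical levels: sequencing error 10⁻³ per base (post-filter
Illumina), ancestral heterozygosity 5 × 10⁻⁵ /bp (duckweed populations are
depauperate in diversity), duplication regions of 1 kb at 20 hets/kb with
alt-read fraction 0.2 (the reference bias of such artifacts is not
quantified upstream, so it is a parameter). The genome length defaults to
1 Mb so that a full experiment generates in seconds; rate-recovery tests
inflate `μ` rather than the genome, which preserves all per-site
distributions.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: mapping artifacts beyond the stylized
duplication regions, base-quality structure and PCR duplicates, indel
simulation, GC-dependent coverage, and cross-line contamination. Depth is
Poisson (the experiment reports only means/medians); real depth is
over-dispersed, which would lower power at fixed mean.

## Parameter recovery and its limits

With `n = 1` the prescribed assumed fraction (the truth mean, 0.5) makes
the power correction exactly unbiased, and the pipeline's 95% CI covers the
true `μ` in ≥ 90% of replicates (the acceptance script measures this at 50
replicates on a 0.4 Mb × 10-line genome). With `n = 8` the single-fraction
correction inherits the documented crudeness: detection conditions on ≥ 5
reads, so recovered sites over-represent high-frequency (often
within-clone-fixed) mutations — after 60 generations at `n = 8` most
surviving mutations have fixed, and the recovered-site mean read fraction
sits near 45%, significantly below both 50% and the `n = 1` condition,
while the mean over *all* surviving truth mutations is ~35%. Recovery-set
equality (candidates ≡ detectable truth) is checked in the mosaic case.

## Numerical conventions

* All stochastic entry points take an integer seed or a
  `numpy.random.Generator`; the pipeline derives per-stage child streams
  from one seed, and identical configurations reproduce byte-identical
  reports (no timestamps in provenance).
* Depth is stored densely as `uint16` per site and line; non-reference
  counts and non-hom-ref genotypes are sparse long-format frames, keeping a
  10 Mb, 14-line table well under 1 GB.
* The chi-square contrast returns (0, 1) for the degenerate
  no-mutations-anywhere table rather than failing.
* Agresti–Coull bounds are truncated to [0, 1]; zero-candidate groups
  report rate 0 with a positive upper bound.
* Ties for the focal line's best-supported alternate base break toward the
  first base in A<C<G<T order; sequencing errors exceeding depth at a site
  (possible when error draws stack on structural alleles) are trimmed from
  the error component, never from the mutation or ancestral-het reads.
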