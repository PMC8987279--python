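# Methods

## Scope and data model

The package operates on phased (for haplotype statistics) or unphased
multi-sample biallelic SNV panels with a sample→population map. Internally
all coordinates are 0-based half-open; VCF (1-based) and GTF (1-based
inclusive) convert at the I/O boundary. Multi-allelic and non-SNV records
are dropped at load, not split — every downstream statistic is defined on
biallelic SNVs only. A genotype with any missing allele is treated as fully
missing, so allele counts are always twice the fully-called diploid count;
this keeps allele frequencies, diploid sample sizes and observed
heterozygosities mutually consistent for the variance-component estimator.

Site filters follow common resequencing practice: pooled MAF > 0.01, site
call rate ≥ 0.3, QUAL > 30 where present. The call-rate reading of the
"coverage" filter is a deliberate choice (a per-site fraction of genotyped
samples); the cutoff is configurable.

## Statistics

**Weir–Cockerham F_ST.** Per site, the r = 2 variance components

    a (among populations), b (among individuals within populations),
    c (within individuals)

are computed from diploid sample sizes, alternate-allele frequencies and
*observed* heterozygote counts. Window F_ST is the ratio-of-sums estimator
Σa / Σ(a+b+c) over sites in the window (the "weighted" estimator used by
vcftools), not the mean of per-site ratios. Negative values are reported
as-is; clamping would distort the estimator's distribution and the empirical
tail is unaffected either way. Sites where a population has no data, or
where the mean sample size is ≤ 1, carry a defined-flag of false and are
excluded from window sums and SNP counts.

**Nucleotide diversity.** Site π = 2·c_ref·c_alt / (n(n−1)) with n the
non-missing allele count; window π divides the site sum by the full window
length in bp (vcftools `--window-pi` semantics), so sparse windows are not
inflated. The contrast statistic is log₂(π_ref/π_target): right tail =
diversity deficit in the target. Windows where either π is zero are
unscored for the ratio rather than ±infinite.

**XP-EHH.** EHH at extension j is Σ_g C(n_g,2)/C(n,2) over haplotype groups
identical from the core to j inclusive; at the core the groups are the two
core alleles (the whole-sample variant appropriate for cross-population
comparison, not the allele-specific iHS variant). iHH integrates the decay
curve trapezoidally over physical distance (no genetic map is assumed), arm
by arm, stopping after including the first point below the EHH cutoff
(default 0.05); a fixed convention, since edge handling varies between
implementations. Arms cut off by a chromosome end, missing data, or an
inter-SNP gap above 200 kb (a guard against integrating across SNP deserts)
are integrated to the truncation point and flagged. Raw XP-EHH =
ln(iHH_A/iHH_B) with A fixed to the scan's target population, so sweeps in
the target are positive; scores are z-normalized genome-wide (population
standard deviation) rather than within frequency bins. Cores with pooled
MAF < 0.05 are unscored. Window-level XP-EHH is the mean of normalized
per-SNP scores in the window (max is available via configuration); the mean
is the less noisy aggregator for 100 kb windows holding ~100 SNPs.

The genome scan path and the readable per-core path share one definition;
a test checks the numba kernel against the curve-based route point for
point, and both against a brute-force prefix-hashing oracle.

**Consensus calling.** Per method and contrast, the cutoff is the (1−tail)
empirical quantile of scored windows with linear interpolation between order
statistics; windows with value ≥ cutoff are flagged (ties included), so the
flagged fraction is at most tail + 1/n_scored. Windows with fewer than
min_snps (default 10) contributing sites are unscored and excluded from both
the quantile and flagging; the floor avoids windows whose score rests on a
handful of SNPs. Windows flagged by ≥ min_methods (default 2) methods merge
when they overlap or abut (no gap bridging); cross-contrast "overlap" is
≥ 1 bp and the reported interval is the intersection, the conservative
choice when overlap extent is otherwise unspecified.

**ΔAF.** ΔAF = |AF_target − mean(AF_ref1, AF_ref2)| — the mean of the two
reference frequencies, the only reading under which the statistic stays in
[0,1]. High-ΔAF enrichment is reported as the ratio of the high-ΔAF fraction
among SNVs inside regions to the genome-wide fraction; no significance test
is attached. Breed-specific SNVs use strict inequalities (target AF > 0.95
and every reference < 0.05); the mirrored pattern is off by default.

**ROH.** Sliding windows of 50 SNPs are homozygosity-compatible with ≤ 1
heterozygous and ≤ 5 missing calls; a SNP seeds a run when ≥ 5% of the
windows containing it are compatible; runs are split at inter-SNP gaps
> 1 Mb and kept when they have ≥ 50 SNPs, span ≥ 100 kb and average at most
50 kb per SNP. These are the PLINK `--homozyg` defaults except the 100 kb
length floor, chosen because the smallest reported length class starts at
100 kb; all parameters are configurable. Segment length is the SNP-span
(last − first SNP position + 1). The seven length bins are half-open, so a
segment of exactly 200 kb falls in the 200–300 kb bin. F_ROH divides total
ROH length by the autosome length, default 2.27 Gb (pig autosomes). The
seed rule implies detected boundaries sit within about one inter-SNP gap of
a planted tract's edge (the outermost tract SNPs can fall just under the 5%
hit fraction, and one flanking SNP can fall just over it).

**Structure.** IBS similarity per pair is the mean over co-genotyped sites
of shared alleles / 2; distance = 1 − similarity (pairwise-complete
treatment of missing data, mirroring PLINK). Neighbor joining is the
standard Saitou–Nei Q-criterion algorithm with a deterministic lexicographic
tie-break; negative branch lengths are clamped to zero with the deficit
moved to the sister branch so the pair distance is preserved (a divergence
from PHYLIP, which prints negative lengths). On additive matrices the
implementation reproduces path distances to 1e-9 and the generating
topology exactly. The GRM follows the GCTA estimator with mean-imputed
missing dosages and monomorphic sites excluded; PCA coordinates are
eigenvectors scaled by √eigenvalue and variance fractions are
eigenvalue/trace.

**Annotation.** Region-to-gene and region-to-QTL joins use interval trees
with a ≥ 1 bp overlap rule on half-open intervals (containment is
subsumed); a QTL overlapping several regions is tallied once, and trait
classes are taken verbatim from the QTL BED payload.

## The simulator

`synthetic_data` emulates the downstream form of a multi-breed resequencing
study. Per SNP, an ancestral frequency p ~ Uniform(0.05, 0.95) and
per-population frequencies q ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–
Nichols with differentiation F). Each population carries n_founders founder
haplotypes drawn Bernoulli(q); each sample haplotype is a founder mosaic
switching founders between adjacent SNPs with probability
1 − exp(−switch_rate · gap). The mosaic produces the haplotype-length
structure XP-EHH needs at a fraction of a coalescent simulator's cost.
Sweeps are planted by replacing, in a chosen fraction of the target
population's haplotypes, the alleles over an interval with one donor
haplotype's segment — instantaneous near-fixation with exact ground truth.

Default preset: 3 populations (1 target, 2 references) × 25 diploids,
F = 0.05, two 10 Mb chromosomes with 20,000 SNPs total, 30 founders,
switch_rate 1e-6/bp (mean segment ~1 Mb), five 300 kb sweeps at haplotype
frequency 0.95. With 30 founders the finite founder pool adds
founder-sampling drift of roughly (1−F)/n_founders to the realized
differentiation — a property of the mosaic model, not of the estimator —
so F_ST *parameter-recovery* checks use n_founders = 1000, where haplotypes
are effectively independent Balding–Nichols draws and windowed F_ST
recovers F to well within 0.02.

What the simulator does **not** emulate: demography (bottlenecks,
admixture, growth), recombination/mutation rate heterogeneity, selection
dynamics (partial sweeps have sharp edges rather than decaying shoulders),
genotyping error and missingness, and reference bias. Passing tests
therefore demonstrate correctness of the statistics and of the consensus
machinery under a clean, known model — not calibration of thresholds on
real livestock data, where demography alone can move empirical tails.

## Numerical conventions and degenerate inputs

- Quantiles: linear interpolation between order statistics; ≥ 20 scored
  values required for a 5% tail.
- Unscored values propagate as NaN and are excluded from quantiles,
  normalization, and window means; they are never silently zeroed.
- z-normalization uses the population standard deviation (denominator n);
  an all-equal score vector leaves every site unscored with a warning.
- EHH at a core already below the cutoff gives iHH = 0 (flagged);
  ln(iHH_A/iHH_B) is unscored when either side is 0.
- An empty filtered panel is returned with a warning, not an error; a
  popmap missing a VCF sample is a hard error naming the sample.
- All simulator randomness flows from a single integer seed through
  NumPy SeedSequence spawning (panel first, then one child per sweep), so
  identical configuration and seed reproduce output bundles byte for byte
  (the run manifest contains no timestamps).

## Problem sizes

The test suite and the acceptance script run the default preset (75
diploids, 20k SNPs, 20 Mb) and smaller fixtures; a full scan of one
simulated study completes in a few seconds on one CPU, dominated by the
XP-EHH kernel. These sizes were chosen so every stage — including the
brute-force oracles — runs comfortably at desk scale while leaving the
statistics in their intended operating regime (~1 SNP/kb, ~100 SNPs per
window).

## Known limitations

- Only two-population F_ST is implemented (the scan is pairwise by design);
  Hudson/Nei variants are not offered.
- XP-EHH integrates over physical distance; genetic-map weighting and
  within-frequency-bin normalization are not implemented.
- The NJ negative-branch convention differs from PHYLIP (see above).
- ROH parameters are a stated convention, not a fit: the detector's
  defaults plus the 100 kb floor.
- The ΔAF enrichment ratio is descriptive; no null distribution is derived.
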