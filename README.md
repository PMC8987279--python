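# sweepscan

Selection-signature scanning and population-diversity analysis for
multi-population SNV panels, built for resequencing studies that contrast a
target livestock breed against reference breeds (the motivating case is a
black pig breed scanned against two commercial breeds). The package detects
genomic regions under recent positive selection by combining three
complementary window statistics, and ships the surrounding population-genetic
toolkit: runs of homozygosity and genomic inbreeding, IBS/NJ/PCA structure
analysis, highly differentiated and breed-specific SNVs, and region-to-gene /
region-to-QTL annotation. A synthetic haplotype simulator with injected
sweeps and exact ground truth makes every stage verifiable at desk scale.

## The scan

Windows of 100 kb sliding by 10 kb are scored, per breed contrast, by:

* **F_ST** — Weir–Cockerham (1984) variance components *a*, *b*, *c*;
  per window the weighted estimator Σa / Σ(a+b+c);
* **log₂ π-ratio** — nucleotide diversity π = Σ_sites 2·c_ref·c_alt/(n(n−1))
  per window length, oriented as log₂(π_ref/π_target) so reduced diversity in
  the target falls in the right tail;
* **XP-EHH** — per SNP, ln(iHH_target/iHH_ref), where iHH is the trapezoidal
  integral of the EHH decay curve over physical distance; z-normalized
  genome-wide and averaged per window.

For each method and contrast the top 5% of scored windows (empirical
right-tail quantile) are flagged; windows flagged by at least two methods are
merged into candidate regions; regions are intersected across contrasts; and
each final region is annotated with the number of highly differentiated SNVs,
ΔAF = |AF_target − mean(AF_ref1, AF_ref2)| > 0.8, together with an enrichment
ratio against the genome-wide high-ΔAF density.

Also included: PLINK-style sliding-window ROH detection with a seven-bin
length spectrum and F_ROH = ΣROH length / autosome length (2.27 Gb pig
autosome default); IBS distances, Saitou–Nei neighbor joining with Newick
output, GCTA-style GRM PCA; breed-specific SNVs (target AF > 95%, others
< 5%); and a Balding–Nichols founder-mosaic simulator with segment-replacement
sweeps.

## Worked example

Simulate the default study (3 populations × 25 diploids, two 10 Mb
chromosomes, 20,000 SNPs, F_ST 0.05, five 300 kb sweeps at haplotype
frequency 0.95 injected into the target population) and scan it:

```python
from sweepscan.synthetic_data import default_study_params, simulate_study
from sweepscan.pipeline import ScanConfig, run_scan, evaluate_recovery

panel, truths = simulate_study(default_study_params(seed=1))
result = run_scan(ScanConfig(outdir="scan_out", seed=1), panel=panel)
metrics = evaluate_recovery(result, truths, panel.chrom_lengths)
print(f"final regions: {len(result.regions)}")
print(f"sensitivity: {metrics['sensitivity']:.2f}")
print(f"genome fraction covered: {metrics['genome_fraction']:.3f}")
print(f"high-dAF enrichment ratio: {result.enrichment['enrichment_ratio']:.1f}")
```

prints

```
final regions: 5
sensitivity: 1.00
genome fraction covered: 0.076
high-dAF enrichment ratio: 13.4
```

All five injected sweeps are recovered (each final region is supported by all
three methods in both contrasts), the called regions cover 7.6% of the
genome, and SNVs with ΔAF > 0.8 are 13.4× denser inside the regions than
genome-wide. `scan_out/` holds the per-window score tables, per-method
thresholds, region BEDs, the ΔAF table and a JSON manifest.

The same pipeline runs from the shell on real data:

```
sweepscan simulate --seed 1 --outdir sim
sweepscan scan --vcf sim/panel.vcf --popmap sim/popmap.txt \
    --target-pop target --reference-pops ref1,ref2 --outdir scan_out
sweepscan roh --vcf sim/panel.vcf --popmap sim/popmap.txt --outdir roh_out
sweepscan ibs-tree --vcf sim/panel.vcf --popmap sim/popmap.txt --outdir tree_out
```

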