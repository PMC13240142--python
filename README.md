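# divscan

Sliding-window population-genomic scans for multi-population diploid SNP
panels: VCF site filtering, windowed nucleotide diversity (Pi), weighted
Weir–Cockerham FST and Tajima's D, joint FST-outlier + reduced-Pi candidate
window detection with region merging, region-vs-background enrichment
statistics (fold, percentile rank, exceedance fractions, Wilcoxon tests, Pi
ratio, ROD), and structure summaries (shared-allele p-distances,
neighbor-joining trees, PCA, a DAPC-style cluster procedure). A built-in
Balding–Nichols simulator generates panels with known truth — genome-wide
weak divergence plus an optional planted high-differentiation block — so the
whole pipeline is testable without external data.

## CLI

All subcommands operate on an uncompressed VCFv4.2 (diploid GT calls) plus a
two-column `sample<TAB>population` table.

```bash
# simulate a 3-population panel with a planted 100 kb block
divscan simulate --config sim.yaml --out-prefix fixture

# hard filters (QD/MQ/FS/SOR/MQRankSum/ReadPosRankSum) + QUAL/biallelic/MAF/call-rate
divscan filter --vcf fixture.vcf --pops fixture.pops.tsv --out filtered.vcf \
    --maf 0.05 --max-missing 0.95 --qual 40

# windowed Pi / Tajima's D / pairwise FST (100 kb windows, 10 kb steps)
divscan scan --vcf filtered.vcf --pops fixture.pops.tsv \
    --window 100000 --step 10000 --out scan.tsv

# candidate regions: FST above the top-5% genome-wide quantile AND reduced
# Pi (below the median) in at least one population; merged when adjacent
divscan regions --scan scan.tsv --pair ST,HN --q 0.95 --pi-quantile 0.5 \
    --out regions.bed

# region-vs-background enrichment battery
divscan enrich --scan scan.tsv --regions regions.bed --pair ST,HN \
    --focal ST --out enrich.tsv

# distances (PHYLIP), NJ tree (Newick), PCA scores, DAPC clusters
divscan structure --vcf filtered.vcf --pops fixture.pops.tsv \
    --out-prefix res --bootstrap 100
```

An example `sim.yaml`:

```yaml
pops:
  - {label: ST, n: 14, f: 0.001}
  - {label: ZH, n: 10, f: 0.001}
  - {label: HN, n: 10, f: 0.001}
chrom_lengths: {chr1: 1000000}
n_sites: 8400
seed: 1
block: {chrom: chr1, start: 450001, end: 550000, f_block: 0.05,
        focal_pop: ST, diversity_scale: 0.8}
```

## Conventions and caveats

- Windows are 1-based inclusive `[start, start + size − 1]`; BED output
  converts to 0-based half-open exactly (`bed_start = start − 1`).
- Window FST is the weighted (ratio-of-sums) Weir–Cockerham estimator; small
  negative values are reported as computed, not clamped.
- Pi is per-bp: the sum of per-site unbiased heterozygosity over the window
  divided by the window's bp span.
- Undefined statistics (no usable sites, n < 4 for Tajima's D) are NaN, never
  zero.
- Rank tests on member windows of a region do not correct for the
  autocorrelation induced by overlapping sliding windows; p-values for
  step < size designs are optimistic and should be read as descriptive.
- The simulator draws independent sites (no linkage); windows are
  exchangeable under the null.
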