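# aquascan

Selection-signature scans for group-structured haplotype alignments.

`aquascan` is for population geneticists who have a multi-strain genome
alignment, a partition of those strains into haplotype groups (for
example, wild yeast isolates split by which inactivating aquaporin allele
they carry), and a candidate locus — and who want to know whether the
variation around that locus is *unusual* for the genome, without leaning
on demographic model assumptions that messy microbial population data
routinely violate.

## What it computes

**Windowed diversity scan.** The average number of pairwise nucleotide
differences per kb, π, in sliding windows (1 kb / 100 bp step by
default), computed within the focal group (π_within) and between the
focal group and everyone else (π_between). Each strain pair is normalised
by its own callable sites, so unimputed, gap-rich alignments don't
deflate diversity; gaps and low-quality bases are treated as missing. A
recent partial sweep depresses π_within locally; balancing selection
inflates π_between.

**Outlier ranking.** Fixed-size regions are ranked genome-wide by mean
π_within (low percentile = candidate sweep). The difference profile
D = π_between − π_within is thresholded at 1.5× its chromosome-wide
mean; contiguous above-threshold runs are peaks, scored by trapezoidal
area and ranked genome-wide (low percentile = unusually skewed locus).

**F_ST scan.** Hudson-type multi-group F_ST = 1 − H_w/H_b per site, with
ratio-of-sums windows and genome-wide region ranking.

**Partitioning-sampling null.** To control for mosaic population
structure, strains are re-partitioned at one biallelic SNP (minor allele
in ≥ 3 strains) per 10 kb gridpoint genome-wide; around each SNP the
difference-profile peak is grown outward while D stays above a cutoff and
its area is one null draw. The focal locus is scored by the identical
procedure, partitioned by its own allele, and ranked against the null.

**Locus tests.** McDonald–Kreitman counts (SNP + indel channels) with
two-tailed Fisher's exact test, Tajima's D, Nei–Gojobori Ka/Ks with
Jukes–Cantor correction, and a 2×2 chi-square test of functional-status
independence between two loci.

**Synthetic truth.** A seeded generator produces group-structured genomes
with implanted sweep/divergent regions of known extent, coding loci with
prescribed MK tables, and balanced loci with two intermediate-frequency
haplotype classes — so every stage is testable end-to-end with known
answers. See `docs/methods.md` for the model and its limits.

## Worked example

Simulate the standard study genome (24 strains in 3 groups, 16 × 50 kb
chromosomes, ~5 diffs/kb background) with one implanted 5 kb sweep
(π_within ×0.1, π_between ×2) and run the full pipeline against it:

```python
from aquascan.studies import sweep_study

s = sweep_study(7)
print(f"within-variation percentile: {s['within_percentile']:.2f} of {s['within_n_regions']} regions")
print(f"peak-area percentile:        {s['peak_area_percentile']:.2f} of {s['peak_area_n_peaks']} peaks")
print(f"partitioning-null percentile:{s['null_percentile']:.2f} of {s['null_n_snps']} null SNPs")
print(f"focal peak: chr01:{s['focal_peak']['start']}-{s['focal_peak']['end']}  area {s['focal_peak']['area']:.1f}")
```

prints

```
within-variation percentile: 0.27 of 368 regions
peak-area percentile:        0.29 of 345 peaks
partitioning-null percentile:0.00 of 160 null SNPs
focal peak: chr01:19200-25700  area 483.9
```

The implanted locus (chr01:20000–25000) is recovered as the top-area
difference peak genome-wide (0.29th percentile of 345 peaks), its 5 kb
region has the lowest within-group variation of all 368 tiled regions
bar none (0.27th percentile), and no random-SNP partition of the strains
reproduces a peak of comparable area (0th percentile of 160 null draws) —
the three signatures of a recent partial sweep with group-divergent
alleles.

Locus-level tests work on coding alignments:

```python
from aquascan.locus_stats import MKTable, mk_test

r = mk_test(MKTable(Pn=5, Ps=4, Dn=11, Ds=49))
print(f"A/S polymorphism {r.ratio_poly:.2f} vs divergence {r.ratio_div:.2f}, p = {r.p:.3f}")
# A/S polymorphism 1.25 vs divergence 0.22, p = 0.026
```

An excess of replacement polymorphism relative to divergence (1.25 vs
0.22) rejects neutrality — the classic signature of relaxed or locally
adaptive constraint at a pseudogenizing locus.

The same machinery is available from the shell:

```
aquascan simulate --seed 1 --out sim/
aquascan scan sim/chr01.fasta --groups sim/groups.tsv --group G25-deletion --out profile.tsv
aquascan run --config run.yaml      # full pipeline from one YAML config
aquascan mk locus.fasta --outgroup Q69_8
```

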