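# Methods

`aquascan` implements an empirical, outlier-based battery for detecting
recent partial selective sweeps and incipient balancing selection in
group-structured haplotype samples, such as wild *Saccharomyces cerevisiae*
isolates subdivided by the inactivating allele they carry at a locus. The
tests are deliberately non-parametric: low-coverage population alignments
with heavy missing data, strong population structure, unknown demography
and partially clonal reproduction violate the assumptions of standard
model-based selection scans, whereas genome-wide percentile ranking and a
partitioning-sampling null need only exchangeability assumptions.

## Data model

A chromosome alignment is a dense `strains x positions` matrix over the
5-state alphabet {A, C, G, T, MISSING}. Gaps and IUPAC ambiguity codes are
converted to MISSING on load, as are bases below a per-base quality
threshold (default Q40) when a quality track is supplied; in low-coverage
alignments gap columns are dominated by alignment error, so no indel
information is retained at genome scale. Diploid calls with evidence of
heterozygosity can be collapsed to haplotype symbols with a seeded fair
coin; sites with more than two candidate alleles become MISSING. Internal
coordinates are 0-based half-open; human-readable reports are BED-style
TSV.

A strain grouping maps a subset of strains to named haplotype groups
(each group needs at least 2 members). Strains outside the map still
count on the "between" side of every comparison, mirroring a design where
some strains are typed but unassigned.

## Windowed diversity scan

The scan statistic is the average number of pairwise nucleotide
differences per 1,000 bp in sliding windows (defaults: 1 kb window, 100 bp
step; trailing partial windows are skipped). For a focal group, the
*within* curve averages over all unordered pairs inside the group and the
*between* curve over all pairs of one in-group and one out-group strain.
Each pair is normalised by its own number of both-called sites before the
×1000 scaling, then pairs are averaged; this per-pair normalisation keeps
windows with missing-data holes unbiased, whereas raw per-window counts
would deflate diversity in unimputed data. The choice is declared, not
inferred from any reference analysis. Windows where the callable fraction
of pair-site comparisons falls below a floor (default 0.2) are reported as
NaN, never as zero. Columns with three or more segregating alleles are
counted as a difference whenever the two compared symbols differ, with no
extra weighting.

All grouped statistics over one chromosome are averages over subsets of
strain pairs, so the per-pair windowed difference/comparable counts are
computed once (`PairwiseWindowStats`) and shared by the focal scan and by
every draw of the empirical null; this is what makes the
partitioning-sampling control affordable.

## Region ranking and difference-profile peaks

Two outlier statistics are ranked genome-wide:

* **Within-group variation of fixed-size regions.** All tiled regions
  (e.g. 50 kb regions every 20 kb, or 5 kb every 2 kb) are scored by their
  mean within-group window value, and a focal region's percentile is
  `100 x #(regions <= focal)/n`. Low percentiles flag swept regions.
* **Difference-profile peaks.** The difference profile (between − within)
  is thresholded at `1.5 x` its chromosome-wide mean (negative values are
  included in the mean: the full-profile mean is the natural null level of
  a signed difference). Maximal runs of consecutive windows strictly above
  threshold are peaks; undefined windows break runs. Each peak is scored
  by the trapezoidal area under the positive part of the difference curve,
  with the x-axis in window-step units (only ranks are compared across
  runs, so the unit convention cancels). A focal peak's percentile is
  `100 x #(areas >= focal)/n` over the pooled genome-wide peak list.

Ties count as "as extreme" (inclusive) in all percentiles — the
conservative convention. A single-window peak has zero trapezoidal area.

## F_ST scan

Per-site F_ST uses a Hudson-type frequency form: with sample allele
frequencies `p_g` per group, `Hw` is the mean within-group heterozygosity
`1 − Σ p_ga²` over groups with ≥ 2 called strains and `Hb` the mean
between-group heterozygosity `1 − Σ p_ga p_ha` over group pairs;
`F_ST = 1 − Hw/Hb`. This form is exactly 0 at identical frequencies and 1
at fixed differences, is invariant to allele relabeling and group order,
and preserves small negative values. Sites where fewer than two groups
have data, or where `Hb = 0`, are undefined. Windows combine sites by
ratio-of-sums of the per-site numerator `Hb − Hw` and denominator `Hb`,
which is more stable than averaging per-site ratios when windows contain
low-information sites. Windowed F_ST regions are ranked genome-wide the
same way as within-variation regions, on the high side. Absolute F_ST
values depend on the estimator; ranks are the comparable quantity.

## Partitioning-sampling null

Mosaic genomes can mimic sweep/balancing signatures under any locally
defined grouping. The control re-partitions strains at random SNPs:
every `grid` bp (default 10 kb) the first biallelic SNP at or after the
gridpoint whose minor allele is carried by ≥ 3 called strains defines a
bipartition (minor-allele class = focal side; strains uncalled at the SNP
sit the draw out). The difference profile is recomputed over a 20 kb span
centred on the SNP, a peak is grown outward from the SNP's window while
the difference stays ≥ a fixed cutoff, and its trapezoidal area is one
null draw. The focal locus is scored by the identical procedure with
strains partitioned by the focal allele class versus everyone else, and
its percentile is `100 x #(null areas >= focal)/n`.

Design choices: one SNP per gridpoint ("first at/after") keeps draws
quasi-independent and matches the sampling grid; the cutoff defaults to
the focal chromosome's `1.5 x`-mean peak threshold so the null and the
genome scan use the same definition of "elevated", with an override flag
to reproduce any fixed cutoff. A 5 kb fixed-span scoring variant can be
obtained by setting the span.

**Calibration.** The walk-out area is discrete at zero (draws whose centre
window is below the cutoff), so the deterministic ties-inclusive
percentile of an exchangeable draw cannot be uniform. For calibration the
package exposes a randomized tie-broken percentile (uniform rank inside
the tie block among the n+1 pooled draws), which is the exact
probability-integral transform for exchangeable draws. On a structureless
synthetic genome, randomized focal percentiles of 200 random draws pass a
Kolmogorov–Smirnov uniformity test at α = 0.01; the pipeline itself always
reports the deterministic, conservative percentile. In the calibration
study the cutoff is fixed from a 50-draw pilot set disjoint from both the
null and focal draws, so all ranked draws remain exchangeable.

## Locus-level tests

* **McDonald–Kreitman.** Codon by codon, ingroup sequences with a gap or
  missing base in the codon sit it out. A site segregating among the
  remaining ingroup codons is polymorphic; a site fixed in the ingroup and
  different from a clean outgroup codon is divergent; a site that is both
  counts as polymorphism only (standard MK practice). Variants are
  classified synonymous/nonsynonymous by substituting the variant base
  into the ingroup consensus codon; each divergent site is classified
  individually against that background so counts stay integers. Indels
  are scored as whole gap runs in a separate channel: runs segregating in
  the ingroup are polymorphic, runs fixed between ingroup and outgroup are
  divergent. The SNP test is Fisher's exact on (Pn, Ps | Dn, Ds); the
  indel test contrasts (P_indel, Ps) with (D_indel, Ds). Fisher's exact
  test uses the two-tailed minimum-likelihood convention (scipy). Because
  the pseudogene alleles are the object of study, internal stop codons
  warn rather than fail.
* **Tajima's D** is the standard 1989 statistic with the canonical
  a₁…e₂ constants; π is computed from mean pairwise differences after
  complete deletion of columns containing any gap/missing symbol (loci are
  short, matching classic implementations). No segregating sites gives an
  undefined marker, not 0. Significance against a locus set is left to
  the caller.
* **Ka/Ks** is Nei–Gojobori (1986): codon site counts as synonymous
  change fractions, multi-hit codons resolved by averaging over minimal
  mutational pathways (pathways through stop codons are used only when
  unavoidable; changes to stops count as nonsynonymous), Jukes–Cantor
  correction of the pN/pS proportions. Proportions ≥ 3/4 are flagged as
  saturated and yield NaN.
* **Two-locus independence** is a Pearson chi-square (df = 1) on the 2×2
  strain table of functional status at two loci, without Yates correction
  by default (exposed as a flag); a zero marginal makes the test
  undefined.

## Synthetic-data generator

The generator is a two-level mutation-placement model, not a coalescent:
the scan consumes diversity patterns, and direct placement gives exact
control of within/between expectations. An i.i.d. uniform ancestral
sequence is copied to all strains; SNPs are then placed in two layers —
*shared* SNPs segregating across the whole sample and *group-private*
SNPs confined to one group — with derived-allele counts drawn from a
neutral-shaped 1/k spectrum. Densities are calibrated in expected
pairwise differences per kb: the per-site placement rate is the target
density divided by the mean per-SNP heterozygosity under the 1/k
spectrum, so realised diversity matches the request in expectation.

Inside an implanted region both SNP layers are thinned by `within_scale`,
and group-fixed differences (each group assigned a distinct allele) are
added at `(between_scale − within_scale) x` the total background density,
so expected within-group diversity is `within_scale x` background while
between-group diversity rises toward `between_scale x` background. A
sweep implant uses (0.1, 2.0); a divergent implant for the F_ST study
uses (1.0, 3.0). Point missingness is i.i.d. per strain-site (default
2%), and gap runs start at a per-site rate (default 5 × 10⁻⁴) with
geometric lengths of mean 5 bp, exercising the gaps-as-missing path with
realistic runs. Identical seeds produce byte-identical FASTA/TSV/JSON
outputs.

The standard study conditions are 3 groups × 8 strains, 16 chromosomes ×
50 kb, and 3 + 2 diffs/kb of shared + private background (≈ 5/kb within
groups) — a genome scaled down ~240-fold from a real yeast genome so a
full multi-seed study runs on one CPU in minutes. What the generator does
*not* emulate: linkage/recombination genealogies, realistic site-frequency
spectra under demography, clonal population structure outside the group
labels, alignment error beyond uniform missingness, and base-composition
or mutation-spectrum biases. Passing the recovery studies therefore shows
the *statistics and ranking machinery* behave as designed under controlled
signal and missingness — not that any particular empirical dataset would
yield the same percentiles.

The coding-locus generator builds MK truth directly: every prescribed
event occupies its own codon of a Gly-codon background (third-position
changes synonymous, first-position changes nonsynonymous, no reachable
stops), polymorphic events are carried by a minority of ingroup sequences
and divergent events by the outgroup; indel events are whole-codon gap
runs kept non-adjacent so runs never merge. The classifier must recover
the prescribed table exactly. The balanced-locus generator emits two
haplotype classes at intermediate frequency separated by fixed
differences over singleton background noise — the classic positive
Tajima's D configuration.

## Numerical and edge-case conventions

* Undefined values are NaN throughout and propagate to "undefined", never
  silently to 0; errors are raised where the result would be meaningless
  (empty groups, all-undefined focal regions, empty nulls).
* Percentile ties are inclusive (conservative) except in the explicitly
  randomized calibration form.
* The trapezoid rule is applied to the positive part of the difference
  curve so areas are never negative even when the threshold is negative.
* Fisher p-values agree with published worked examples to the printed
  3-decimal precision; one published value (0.019) sits 9 × 10⁻⁴ below the
  recomputed exact two-tailed value (0.0199), consistent with rounding in
  the original software.
* Reproducibility: every stochastic component takes a seed or
  `numpy.random.Generator`; pipeline outputs are pure functions of
  (inputs, config, seed).

## Problem sizes used in the validation studies

Sweep recovery: 20 seeds × the standard genome, null grid 5 kb (≥ 100
null SNPs per run). F_ST outliers: 20 seeds. Null calibration: one
structureless genome, 640 grid SNPs split into 50 pilot / 200 focal /
~390 null draws. Tajima's D positivity: 40 seeded balanced loci. MK truth
recovery: 100 seeded loci. These sizes were chosen so the whole battery,
including the acceptance script, completes in a few minutes on one CPU
while keeping the binomial noise on recovery rates well inside the
asserted margins.
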