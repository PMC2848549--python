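"""Reference synthetic study designs exercising the whole pipeline.

These are the package's standard end-to-end experiments on generated data
with known implanted truth.  Each function simulates a genome under the
standard study conditions (24 strains in 3 haplotype groups, 16 chromosomes
of 50 kb, ~5 pairwise differences/kb of background diversity), runs the
relevant part of the pipeline, and returns the headline numbers.  They
serve both as validation experiments and as worked examples.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sstats

from .alignment_io import GenomicRegion
from .diversity_scan import PairwiseWindowStats
from .fst_scan import fst_region_percentile, window_fst
from .partition_null import (
    NullDistribution,
    focal_null_percentile,
    partition_peak_area,
    select_partition_snps,
)
from .pipeline import RunConfig, run_full_scan
from .synthetic_data import ImplantedRegion, SimulationConfig, simulate_genome

#: the standard implant: a 5 kb partial sweep on chr01
SWEEP_REGION = GenomicRegion("chr01", 20000, 25000)
#: the standard high-divergence implant for the F_ST experiment
DIVERGENT_REGION = GenomicRegion("chr01", 20000, 25000)


def sweep_study(seed: int, output_dir: str | None = None) -> dict:
    """One replicate of the sweep-recovery experiment.

    A 5 kb region with within-group diversity suppressed to 0.1x background
    and between-group diversity raised to 2x is implanted; the full pipeline
    then ranks the implanted locus genome-wide.  Returns the pipeline
    summary (peak-area, within-variation and partitioning-null percentiles).
    The null uses a 5 kb SNP grid so a 16 x 50 kb genome yields >= 100 null
    draws.
    """
    sim_cfg = SimulationConfig(
        implants=[ImplantedRegion(SWEEP_REGION, "sweep", within_scale=0.1,
                                  between_scale=2.0)],
        seed=seed,
    )
    sim = simulate_genome(sim_cfg)
    run_cfg = RunConfig(
        alignments={}, grouping="", focal_group=list(sim_cfg.group_sizes)[0],
        focal_region=SWEEP_REGION, region_size=5000, region_step=2000,
        null_grid=5000, seed=seed,
        output_dir=output_dir or "aquascan_out",
    )
    if output_dir is None:
        import tempfile

        with tempfile.TemporaryDirectory() as tmp:
            run_cfg.output_dir = tmp
            return run_full_scan(run_cfg, alignments=sim.alignments,
                                 grouping=sim.grouping)
    return run_full_scan(run_cfg, alignments=sim.alignments, grouping=sim.grouping)


def fst_study(seed: int) -> dict:
    """One replicate of the F_ST outlier experiment.

    A 5 kb region of elevated cross-group divergence (fixed differences, 3x
    background between-group diversity, unchanged within-group diversity) is
    implanted; windowed F_ST is computed genome-wide and the implanted
    region's mean F_ST is ranked against all tiled 5 kb regions.
    """
    sim_cfg = SimulationConfig(
        implants=[ImplantedRegion(DIVERGENT_REGION, "divergent",
                                  within_scale=1.0, between_scale=3.0)],
        seed=seed,
    )
    sim = simulate_genome(sim_cfg)
    profiles = {chrom: window_fst(aln, sim.grouping)
                for chrom, aln in sim.alignments.items()}
    rank = fst_region_percentile(profiles, DIVERGENT_REGION, 5000, 2000)
    return {"fst_percentile": rank.percentile, "n_regions": rank.n_regions,
            "statistic": rank.statistic}


def null_calibration_study(seed: int, n_focal: int = 200, grid: int = 1250) -> dict:
    """Calibration of the partitioning-sampling percentile on a structureless
    genome.

    Without population structure every strain bipartition at a random SNP is
    exchangeable, so the focal percentile of a random draw against the
    pooled null must be uniform.  Grid-selected SNPs are pooled genome-wide
    and split (seeded) into a pilot set that fixes the walk-out cutoff
    (1.5x the mean difference value over the pilot spans), ``n_focal`` focal
    draws, and the null set; focal areas are ranked with randomized
    tie-breaking (exact probability-integral transform for exchangeable
    draws).  Returns the Kolmogorov-Smirnov p-value against Uniform(0, 100).
    """
    rng = np.random.default_rng(seed)
    sim = simulate_genome(SimulationConfig(seed=seed))
    draws = []  # (chromosome, snp, stats)
    stats_by_chrom = {}
    for chrom, aln in sim.alignments.items():
        stats_by_chrom[chrom] = PairwiseWindowStats(aln)
        for snp in select_partition_snps(aln, grid=grid):
            draws.append((chrom, snp))
    if len(draws) < n_focal + 100:
        raise ValueError("too few qualifying SNPs for calibration")
    order = rng.permutation(len(draws))
    n_pilot = 50
    pilot = [draws[i] for i in order[:n_pilot]]
    focal = [draws[i] for i in order[n_pilot:n_pilot + n_focal]]
    null_snps = [draws[i] for i in order[n_pilot + n_focal:]]

    def draw_peak(chrom, snp, cutoff):
        stats = stats_by_chrom[chrom]
        n = stats.alignment.n_strains
        in_group = np.zeros(n, dtype=bool)
        in_group[snp.minor_strains] = True
        active = np.zeros(n, dtype=bool)
        active[snp.called_strains] = True
        return partition_peak_area(stats, in_group, active, snp.position,
                                   20000, cutoff)

    # pilot pass: fix the cutoff from mean pilot-span difference values
    pilot_means = []
    for chrom, snp in pilot:
        stats = stats_by_chrom[chrom]
        n = stats.alignment.n_strains
        in_group = np.zeros(n, dtype=bool)
        in_group[snp.minor_strains] = True
        active = np.zeros(n, dtype=bool)
        active[snp.called_strains] = True
        lo = max(0, snp.position - 10000)
        hi = min(stats.alignment.length, snp.position + 10000)
        cols = np.flatnonzero((stats.starts >= lo)
                              & (stats.starts + stats.window_size <= hi))
        if cols.size == 0:
            continue
        profile = stats.profile(in_group, active=active,
                                columns=slice(int(cols[0]), int(cols[-1]) + 1))
        d = profile.difference
        if np.isfinite(d).any():
            pilot_means.append(float(np.nanmean(d)))
    cutoff = 1.5 * float(np.mean(pilot_means))

    null_draw_areas = []
    for chrom, snp in null_snps:
        peak = draw_peak(chrom, snp, cutoff)
        if peak is not None:
            null_draw_areas.append(peak.area)
    null = NullDistribution(areas=np.array(null_draw_areas))

    percentiles = []
    for chrom, snp in focal:
        peak = draw_peak(chrom, snp, cutoff)
        if peak is None:
            continue
        percentiles.append(focal_null_percentile(peak.area, null,
                                                 randomized=True, rng=rng))
    ks = sstats.kstest(np.array(percentiles) / 100.0, "uniform")
    return {"ks_statistic": float(ks.statistic), "ks_p": float(ks.pvalue),
            "n_focal": len(percentiles), "n_null": null.n_snps,
            "cutoff": cutoff}
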