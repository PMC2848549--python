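"""End-to-end orchestration: load -> scan -> peaks -> rank -> F_ST -> null -> report.

A single run configuration (YAML or constructed in code) drives the whole
analysis and produces a reproducible report bundle: per-chromosome profile
TSVs, a genome-wide peak table, region-rank and F_ST tables, the
partitioning-sampling null table, and a summary JSON carrying the focal
locus's three headline numbers — its within-variation percentile, its
peak-area percentile, and its partitioning-null percentile, each with the
number of regions/peaks/SNPs it was ranked against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import region_ranking
from .alignment_io import (
    AlignmentError,
    GenomicRegion,
    HaplotypeAlignment,
    StrainGrouping,
    load_alignment,
)
from .diversity_scan import (
    DEFAULT_COMPARABLE_FLOOR,
    PairwiseWindowStats,
    scan_chromosome,
    write_profile_tsv,
)
from .fst_scan import fst_region_percentile, genome_mean_fst, window_fst, write_fst_tsv
from .partition_null import (
    focal_null_percentile,
    make_partition_snp,
    merge_nulls,
    null_areas,
    partition_peak_area,
    select_partition_snps,
    write_null_tsv,
)
from .region_ranking import detect_peaks, rank_peak_area, rank_region_within, write_peaks_tsv

log = logging.getLogger("aquascan")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    alignments: dict[str, str]      # chromosome -> FASTA path
    grouping: str                   # strain<TAB>group TSV
    focal_group: str
    focal_region: GenomicRegion
    window: int = 1000
    step: int = 100
    region_size: int = 50000
    region_step: int = 20000
    peak_multiplier: float = 1.5
    null_grid: int = 10000
    null_min_minor: int = 3
    null_span: int = 20000
    null_cutoff: float | None = None  # None: focal chromosome's peak threshold
    comparable_floor: float = DEFAULT_COMPARABLE_FLOOR
    quality_min: int = 40
    seed: int = 0
    output_dir: str = "aquascan_out"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        focal = raw.pop("focal_region")
        region = GenomicRegion(focal["chromosome"], int(focal["start"]), int(focal["end"]))
        null_cfg = raw.pop("null", {})
        return cls(
            focal_region=region,
            null_grid=int(null_cfg.get("grid", 10000)),
            null_min_minor=int(null_cfg.get("min_minor", 3)),
            null_span=int(null_cfg.get("span", 20000)),
            null_cutoff=null_cfg.get("cutoff"),
            **raw,
        )

    def validate(self) -> None:
        for chrom, path in self.alignments.items():
            if not Path(path).exists():
                raise PipelineError(f"config: alignment for {chrom} not found: {path}")
        if not Path(self.grouping).exists():
            raise PipelineError(f"config: grouping file not found: {self.grouping}")
        for name in ("window", "step", "region_size", "region_step",
                     "null_grid", "null_min_minor", "null_span"):
            if getattr(self, name) <= 0:
                raise PipelineError(f"config: {name} must be positive")


def run_full_scan(
    config: RunConfig,
    alignments: dict[str, HaplotypeAlignment] | None = None,
    grouping: StrainGrouping | None = None,
) -> dict:
    """Run the full analysis and write the report bundle.

    ``alignments``/``grouping`` may be passed in-memory (e.g. straight from
    the simulator); otherwise they are loaded from the configured paths.
    Outputs are a pure function of (inputs, config, seed).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("run_full_scan: config=%s", config)

    if alignments is None:
        config.validate()
        alignments = {}
        for chrom, path in sorted(config.alignments.items()):
            try:
                alignments[chrom] = load_alignment(path, quality_min=config.quality_min,
                                                   chromosome=chrom)
            except AlignmentError as e:
                raise PipelineError(f"load: {e}") from e
    if grouping is None:
        try:
            grouping = StrainGrouping.from_tsv(config.grouping)
        except AlignmentError as e:
            raise PipelineError(f"grouping: {e}") from e
    if config.focal_group not in grouping.groups:
        raise PipelineError(f"grouping: focal group {config.focal_group!r} not in grouping")
    for chrom, aln in alignments.items():
        try:
            grouping.validate_against(aln)
        except AlignmentError as e:
            raise PipelineError(f"grouping: chromosome {chrom}: {e}") from e
    if config.focal_region.chromosome not in alignments:
        raise PipelineError(f"config: focal chromosome {config.focal_region.chromosome!r} "
                            "has no alignment")

    # --- windowed diversity scan ------------------------------------------
    stats: dict[str, PairwiseWindowStats] = {}
    profiles = {}
    for chrom, aln in alignments.items():
        stats[chrom] = PairwiseWindowStats(aln, config.window, config.step)
        profiles[chrom] = scan_chromosome(
            aln, grouping, config.focal_group,
            window_size=config.window, step=config.step,
            comparable_floor=config.comparable_floor, stats=stats[chrom],
        )
        write_profile_tsv(profiles[chrom], out / f"profile_{chrom}.tsv")
    log.info("scan: %d chromosomes, window=%d step=%d",
             len(profiles), config.window, config.step)

    # --- within-variation region ranking ----------------------------------
    try:
        within_rank = rank_region_within(profiles, config.focal_region,
                                         config.region_size, config.region_step)
    except ValueError as e:
        raise PipelineError(f"rank: {e}") from e

    # --- difference-profile peaks and area ranking ------------------------
    all_peaks = []
    for chrom, profile in profiles.items():
        all_peaks.extend(detect_peaks(profile, config.peak_multiplier))
    if not all_peaks:
        raise PipelineError("peaks: no peaks detected genome-wide")
    write_peaks_tsv(all_peaks, out / "peaks.tsv")
    focal_peaks = [p for p in all_peaks if p.region.overlap(config.focal_region) > 0]
    if not focal_peaks:
        raise PipelineError(f"peaks: no peak overlaps the focal region {config.focal_region}")
    focal_peak = max(focal_peaks, key=lambda p: p.region.overlap(config.focal_region))
    area_rank = rank_peak_area(all_peaks, focal_peak)

    # --- F_ST --------------------------------------------------------------
    fst_profiles = {}
    for chrom, aln in alignments.items():
        fst_profiles[chrom] = window_fst(aln, grouping, config.window, config.step)
        write_fst_tsv(fst_profiles[chrom], out / f"fst_{chrom}.tsv")
    fst_mean = genome_mean_fst(fst_profiles)
    fst_rank = fst_region_percentile(fst_profiles, config.focal_region,
                                     config.region_size, config.region_step)

    # --- partitioning-sampling null ----------------------------------------
    focal_chrom = config.focal_region.chromosome
    if config.null_cutoff is None:
        cutoff = region_ranking.chromosome_threshold(profiles[focal_chrom],
                                                     config.peak_multiplier)
    else:
        cutoff = float(config.null_cutoff)
    log.info("null: cutoff=%.4g grid=%d span=%d", cutoff, config.null_grid, config.null_span)
    nulls = []
    for chrom, aln in sorted(alignments.items()):
        snps = select_partition_snps(aln, config.null_grid, config.null_min_minor)
        if snps:
            nulls.append(null_areas(aln, snps, cutoff,
                                    window_span=config.null_span,
                                    scan_window=config.window, scan_step=config.step,
                                    comparable_floor=config.comparable_floor,
                                    stats=stats[chrom]))
    null = merge_nulls(nulls)
    if null.n_snps == 0:
        raise PipelineError("null: no usable partitioning SNPs genome-wide")
    write_null_tsv(null, out / "null.tsv")

    # focal draw: identical procedure, partitioned by focal-group membership
    focal_aln = alignments[focal_chrom]
    in_group = np.zeros(focal_aln.n_strains, dtype=bool)
    in_group[focal_aln.strain_indices(grouping.members(config.focal_group))] = True
    centre = (config.focal_region.start + config.focal_region.end) // 2
    focal_null_peak = partition_peak_area(
        stats[focal_chrom], in_group, np.ones_like(in_group), centre,
        config.null_span, cutoff, config.comparable_floor,
    )
    if focal_null_peak is None:
        raise PipelineError("null: focal centre window undefined")
    null_pct = focal_null_percentile(focal_null_peak.area, null)

    summary = {
        "focal_group": config.focal_group,
        "focal_region": {
            "chromosome": focal_chrom,
            "start": config.focal_region.start,
            "end": config.focal_region.end,
        },
        "seed": config.seed,
        "within_percentile": within_rank.percentile,
        "within_n_regions": within_rank.n_regions,
        "within_statistic": within_rank.statistic,
        "peak_area_percentile": area_rank.percentile,
        "peak_area_n_peaks": area_rank.n_regions,
        "focal_peak": {
            "start": focal_peak.region.start,
            "end": focal_peak.region.end,
            "max_difference": focal_peak.max_difference,
            "area": focal_peak.area,
        },
        "null_percentile": null_pct,
        "null_n_snps": null.n_snps,
        "null_cutoff": cutoff,
        "focal_null_area": focal_null_peak.area,
        "fst_percentile": fst_rank.percentile,
        "fst_n_regions": fst_rank.n_regions,
        "fst_genome_mean": fst_mean,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("summary: within %.3g%%/%d, peak area %.3g%%/%d, null %.3g%%/%d",
             summary["within_percentile"], summary["within_n_regions"],
             summary["peak_area_percentile"], summary["peak_area_n_peaks"],
             summary["null_percentile"], summary["null_n_snps"])
    return summary
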