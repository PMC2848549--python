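"""Partitioning-sampling empirical null for the difference-profile scan.

Yeast strains have mosaic genomes: large chromosomal blocks with distinct
ancestries can mimic a sweep/balancing signature when strains are grouped
by any local haplotype.  The control is to re-partition the strains at
random SNPs sampled on a genome-wide grid, recompute the local
between-minus-within difference profile around each partitioning SNP, walk
outward from the SNP while the difference stays at or above a fixed
cutoff, and score the trapezoidal area of the resulting peak.  The focal
locus (strains partitioned by the focal allele, identical span, cutoff and
windowing) is then ranked against this empirical null: a focal area that
random mosaic structure rarely reaches is evidence of selection rather
than demography.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment_io import MISSING, GenomicRegion, HaplotypeAlignment
from .diversity_scan import PairwiseWindowStats, WindowProfile
from .region_ranking import Peak, peak_area


@dataclass
class PartitionSnp:
    """A biallelic SNP inducing a strain bipartition (minor side vs rest)."""

    chromosome: str
    position: int
    minor_count: int
    minor_strains: np.ndarray  # strain indices carrying the minor allele
    called_strains: np.ndarray  # strain indices with data at the SNP


@dataclass
class NullDraw:
    snp: PartitionSnp
    peak: Peak
    area: float


@dataclass
class NullDistribution:
    """Peak areas, one per usable partitioning SNP."""

    areas: np.ndarray
    draws: list[NullDraw] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return self.areas.shape[0]


def qualifying_sites(alignment: HaplotypeAlignment, min_minor: int = 3) -> np.ndarray:
    """Boolean mask of biallelic sites whose minor allele is carried by
    >= ``min_minor`` called strains."""
    m = alignment.matrix
    counts = np.stack([(m == a).sum(axis=0) for a in range(4)])  # (4, L)
    present = counts > 0
    biallelic = present.sum(axis=0) == 2
    nonzero = np.where(counts > 0, counts, np.iinfo(counts.dtype).max)
    minor = nonzero.min(axis=0)
    return biallelic & (minor >= min_minor)


def select_partition_snps(
    alignment: HaplotypeAlignment,
    grid: int = 10000,
    min_minor: int = 3,
) -> list[PartitionSnp]:
    """First qualifying SNP at/after each gridpoint (within grid distance).

    Gridpoints with no qualifying SNP before the next gridpoint are skipped,
    so draws stay roughly ``grid`` bp apart and quasi-independent.
    """
    mask = qualifying_sites(alignment, min_minor)
    positions = np.flatnonzero(mask)
    snps = []
    for gridpoint in range(0, alignment.length, grid):
        i = np.searchsorted(positions, gridpoint)
        if i == len(positions) or positions[i] >= gridpoint + grid:
            continue
        snps.append(make_partition_snp(alignment, int(positions[i])))
    return snps


def make_partition_snp(alignment: HaplotypeAlignment, position: int) -> PartitionSnp:
    """Build the bipartition induced by the (biallelic) SNP at ``position``."""
    col = alignment.matrix[:, position]
    called = np.flatnonzero(col != MISSING)
    alleles, counts = np.unique(col[called], return_counts=True)
    if alleles.shape[0] != 2:
        raise ValueError(f"site {position} on {alignment.chromosome} is not biallelic")
    minor_allele = alleles[np.argmin(counts)]
    minor = np.flatnonzero(col == minor_allele)
    return PartitionSnp(
        chromosome=alignment.chromosome,
        position=position,
        minor_count=int(counts.min()),
        minor_strains=minor,
        called_strains=called,
    )


def walk_out_peak(profile: WindowProfile, center_window: int, cutoff: float) -> Peak:
    """Expand left/right from ``center_window`` while difference >= cutoff.

    Undefined windows stop the walk.  If the centre window itself is below
    the cutoff the result is a degenerate single-window, zero-area peak.
    """
    diff = profile.difference
    n = diff.shape[0]
    if not (0 <= center_window < n):
        raise ValueError(f"center window {center_window} out of range")
    if not np.isfinite(diff[center_window]):
        raise ValueError(f"center window {center_window} is undefined")
    if diff[center_window] < cutoff:
        region = profile.window_region(center_window)
        return Peak(region=region, max_difference=float(diff[center_window]),
                    area=0.0, start_index=center_window, end_index=center_window)
    i = center_window
    while i > 0 and np.isfinite(diff[i - 1]) and diff[i - 1] >= cutoff:
        i -= 1
    j = center_window
    while j + 1 < n and np.isfinite(diff[j + 1]) and diff[j + 1] >= cutoff:
        j += 1
    region = GenomicRegion(
        profile.chromosome,
        int(profile.starts[i]),
        int(profile.starts[j]) + profile.window_size,
    )
    return Peak(region=region, max_difference=float(np.nanmax(diff[i:j + 1])),
                area=peak_area(diff[i:j + 1]), start_index=i, end_index=j)


def partition_peak_area(
    stats: PairwiseWindowStats,
    in_group: np.ndarray,
    active: np.ndarray,
    center: int,
    span: int,
    cutoff: float,
    comparable_floor: float = 0.2,
) -> Peak | None:
    """Difference-profile peak around ``center`` bp for one strain bipartition.

    The profile is computed over a ``span`` bp window centred on ``center``
    (truncated at chromosome ends), and the peak is grown outward from the
    window containing the centre.  None when the centre window is undefined.
    """
    half = span // 2
    lo = max(0, center - half)
    hi = min(stats.alignment.length, center + half)
    cols = np.flatnonzero((stats.starts >= lo) & (stats.starts + stats.window_size <= hi))
    if cols.size == 0:
        return None
    columns = slice(int(cols[0]), int(cols[-1]) + 1)
    profile = stats.profile(in_group, active=active, comparable_floor=comparable_floor,
                            columns=columns)
    centre_idx = profile.window_containing(center)
    if not np.isfinite(profile.difference[centre_idx]):
        return None
    return walk_out_peak(profile, centre_idx, cutoff)


def null_areas(
    alignment: HaplotypeAlignment,
    snps: list[PartitionSnp],
    cutoff: float,
    window_span: int = 20000,
    scan_window: int = 1000,
    scan_step: int = 100,
    comparable_floor: float = 0.2,
    stats: PairwiseWindowStats | None = None,
) -> NullDistribution:
    """One null peak area per partitioning SNP on this chromosome.

    For each SNP, strains are split by its alleles (strains with no call at
    the SNP sit out of the draw), the difference profile is computed over
    ``window_span`` bp centred on the SNP with the minor-allele class as the
    focal group, and the walk-out peak area at the chosen cutoff is one
    draw.  SNPs whose centre window is undefined are dropped.
    """
    if not snps:
        raise ValueError("no partitioning SNPs supplied")
    if stats is None:
        stats = PairwiseWindowStats(alignment, scan_window, scan_step)
    n = alignment.n_strains
    draws: list[NullDraw] = []
    for snp in snps:
        in_group = np.zeros(n, dtype=bool)
        in_group[snp.minor_strains] = True
        active = np.zeros(n, dtype=bool)
        active[snp.called_strains] = True
        peak = partition_peak_area(stats, in_group, active, snp.position,
                                   window_span, cutoff, comparable_floor)
        if peak is None:
            continue
        draws.append(NullDraw(snp=snp, peak=peak, area=peak.area))
    return NullDistribution(areas=np.array([d.area for d in draws]), draws=draws)


def merge_nulls(nulls: list[NullDistribution]) -> NullDistribution:
    """Pool per-chromosome null draws into one genome-wide distribution."""
    draws = [d for null in nulls for d in null.draws]
    return NullDistribution(areas=np.array([d.area for d in draws]), draws=draws)


def focal_null_percentile(
    focal_area: float,
    null: NullDistribution,
    randomized: bool = False,
    rng: np.random.Generator | None = None,
) -> float:
    """Percentile of the focal peak area in the empirical null (low = extreme).

    Default: 100 x (# null areas >= focal) / n, ties inclusive.  With
    ``randomized=True`` ties are broken by a seeded uniform rank among the
    n+1 pooled draws, which makes the percentile of an exchangeable draw
    exactly uniform — the form used for calibration checks on a
    structureless genome.
    """
    if null.n_snps == 0:
        raise ValueError("empty null distribution")
    areas = null.areas
    if not randomized:
        return 100.0 * float((areas >= focal_area).sum()) / null.n_snps
    if rng is None:
        raise ValueError("randomized percentile needs an rng")
    n_greater = int((areas > focal_area).sum())
    n_ties = int((areas == focal_area).sum())
    rank = n_greater + 1 + int(rng.integers(n_ties + 1))
    return 100.0 * rank / (null.n_snps + 1)


def write_null_tsv(null: NullDistribution, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tsnp_position\tminor_count\tpeak_start\tpeak_length\tarea\n")
        for d in null.draws:
            fh.write(
                f"{d.snp.chromosome}\t{d.snp.position}\t{d.snp.minor_count}\t"
                f"{d.peak.region.start}\t{d.peak.region.length}\t{d.area:.6g}\n"
            )
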