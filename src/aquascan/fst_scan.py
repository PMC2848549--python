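"""Per-site and windowed multi-group F_ST along a chromosome.

The estimator is Hudson-type: at each polymorphic site,

    F_ST = 1 - Hw / Hb

where Hw is the mean within-group heterozygosity (1 - sum p_a^2, averaged
over groups with >= 2 called strains) and Hb is the mean between-group
heterozygosity (1 - sum p_a q_a, averaged over unordered group pairs),
computed from sample allele frequencies.  The site decomposition
(numerator Hb - Hw, denominator Hb) is kept so windows can combine sites by
ratio-of-sums, which is robust to low-information sites; small negative
site values are preserved.  This frequency-based form is exactly 0 when all
groups share the same allele frequencies and exactly 1 when two groups are
fixed for different alleles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import MISSING, GenomicRegion, HaplotypeAlignment, StrainGrouping
from .diversity_scan import window_starts


@dataclass
class SiteAlleleCounts:
    """Per-group allele counts (n_groups x 4) at one site."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must be n_groups x 4")
        if (self.counts < 0).any():
            raise ValueError("allele counts must be >= 0")

    @property
    def sufficient(self) -> np.ndarray:
        """Groups with >= 2 called strains."""
        return self.counts.sum(axis=1) >= 2


def site_fst(counts: SiteAlleleCounts | np.ndarray):
    """Hudson-type F_ST at one site.

    Returns ``(fst, numerator, denominator)``; all NaN when the site is
    monomorphic among sufficient groups or fewer than 2 groups have >= 2
    called strains.
    """
    if not isinstance(counts, SiteAlleleCounts):
        counts = SiteAlleleCounts(counts)
    keep = counts.sufficient
    if keep.sum() < 2:
        return np.nan, np.nan, np.nan
    c = counts.counts[keep].astype(float)
    n = c.sum(axis=1, keepdims=True)
    p = c / n
    hw = float((1.0 - (p ** 2).sum(axis=1)).mean())
    g = p.shape[0]
    hb_vals = [1.0 - float((p[i] * p[j]).sum()) for i in range(g) for j in range(i + 1, g)]
    hb = float(np.mean(hb_vals))
    if hb <= 0.0:
        return np.nan, np.nan, np.nan
    return 1.0 - hw / hb, hb - hw, hb


def _site_components(alignment: HaplotypeAlignment, grouping: StrainGrouping):
    """Vectorised per-site (numerator, denominator) arrays over the chromosome."""
    L = alignment.length
    labels = grouping.groups
    n_groups = len(labels)
    freqs = np.zeros((n_groups, 4, L))
    totals = np.zeros((n_groups, L))
    for gi, label in enumerate(labels):
        idx = alignment.strain_indices(grouping.members(label))
        sub = alignment.matrix[idx]
        counts = np.stack([(sub == a).sum(axis=0) for a in range(4)]).astype(float)
        tot = counts.sum(axis=0)
        totals[gi] = tot
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[gi] = np.where(tot > 0, counts / np.maximum(tot, 1), 0.0)

    sufficient = totals >= 2  # (n_groups, L)
    n_suff = sufficient.sum(axis=0)
    usable = n_suff >= 2

    hw_site = 1.0 - (freqs ** 2).sum(axis=1)  # (n_groups, L)
    hw = np.where(usable, (hw_site * sufficient).sum(axis=0) / np.maximum(n_suff, 1), np.nan)

    hb_sum = np.zeros(L)
    hb_n = np.zeros(L)
    for i in range(n_groups):
        for j in range(i + 1, n_groups):
            pair_ok = sufficient[i] & sufficient[j]
            hb_pair = 1.0 - (freqs[i] * freqs[j]).sum(axis=0)
            hb_sum += np.where(pair_ok, hb_pair, 0.0)
            hb_n += pair_ok
    hb = np.where(usable & (hb_n > 0), hb_sum / np.maximum(hb_n, 1), np.nan)

    defined = usable & np.isfinite(hb) & (hb > 0.0)
    num = np.where(defined, hb - hw, 0.0)
    den = np.where(defined, hb, 0.0)
    return num, den, defined


@dataclass
class FstProfile:
    """Windowed ratio-of-sums F_ST along one chromosome (NaN = undefined)."""

    chromosome: str
    starts: np.ndarray
    window_size: int
    step: int
    fst: np.ndarray
    n_sites: np.ndarray  # defined polymorphic sites per window

    @property
    def n_windows(self) -> int:
        return self.starts.shape[0]


def window_fst(
    alignment: HaplotypeAlignment,
    grouping: StrainGrouping,
    window_size: int = 1000,
    step: int = 100,
) -> FstProfile:
    """Sliding-window F_ST as ratio-of-sums of per-site components."""
    num, den, defined = _site_components(alignment, grouping)
    starts = window_starts(alignment.length, window_size, step)
    ends = starts + window_size
    cs_num = np.concatenate([[0.0], np.cumsum(num)])
    cs_den = np.concatenate([[0.0], np.cumsum(den)])
    cs_n = np.concatenate([[0], np.cumsum(defined)])
    w_num = cs_num[ends] - cs_num[starts]
    w_den = cs_den[ends] - cs_den[starts]
    w_n = cs_n[ends] - cs_n[starts]
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(w_den > 0, w_num / np.where(w_den > 0, w_den, 1.0), np.nan)
    return FstProfile(
        chromosome=alignment.chromosome,
        starts=starts,
        window_size=window_size,
        step=step,
        fst=fst,
        n_sites=w_n.astype(np.int64),
    )


def genome_mean_fst(profiles: dict[str, FstProfile]) -> float:
    """Genome-wide mean over all defined windows (the grey reference line)."""
    vals = np.concatenate([p.fst[np.isfinite(p.fst)] for p in profiles.values()])
    return float(vals.mean()) if vals.size else np.nan


def fst_region_percentile(
    profiles: dict[str, FstProfile],
    focal_region: GenomicRegion,
    region_size: int,
    region_step: int,
) -> "RegionRank":
    """Percentile (low = unusually high F_ST) of a focal region's mean
    windowed F_ST among all tiled fixed-size regions genome-wide."""
    from .region_ranking import RegionRank

    def region_stat(profile: FstProfile, region: GenomicRegion) -> float:
        inside = (profile.starts >= region.start) & (profile.starts + profile.window_size <= region.end)
        vals = profile.fst[inside]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else np.nan

    focal_profile = profiles.get(focal_region.chromosome)
    if focal_profile is None:
        raise ValueError(f"no F_ST profile for chromosome {focal_region.chromosome!r}")
    focal_stat = region_stat(focal_profile, focal_region)
    if not np.isfinite(focal_stat):
        raise ValueError(f"focal region {focal_region} has no defined F_ST windows")
    stats = []
    for chrom, profile in profiles.items():
        span = int(profile.starts[-1]) + profile.window_size if profile.n_windows else 0
        for start in range(0, span - region_size + 1, region_step):
            s = region_stat(profile, GenomicRegion(chrom, start, start + region_size))
            if np.isfinite(s):
                stats.append(s)
    stats = np.array(stats)
    if not stats.size:
        raise ValueError("no comparable regions genome-wide")
    count = int((stats >= focal_stat).sum())
    return RegionRank(region=focal_region, statistic=focal_stat,
                      percentile=100.0 * count / stats.size, n_regions=int(stats.size))


def write_fst_tsv(profile: FstProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tfst\tn_sites\n")
        for i, s in enumerate(profile.starts):
            fh.write(
                f"{profile.chromosome}\t{int(s)}\t{int(s) + profile.window_size}\t"
                f"{profile.fst[i]:.6g}\t{int(profile.n_sites[i])}\n"
            )
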