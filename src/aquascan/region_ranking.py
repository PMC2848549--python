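"""Genome-wide percentile ranking of regions and difference-profile peaks.

Two empirical outlier tests run on the scan output:

* fixed-size regions (50 kb / 20 kb step, and 5 kb / 2 kb step) are ranked
  genome-wide by their mean within-group variation — a sweep shows up as a
  region in the lowest percentiles;
* contiguous runs of windows where the difference profile (between - within)
  exceeds 1.5x the chromosome-wide mean are called peaks, scored by the
  trapezoidal area under the difference curve, and ranked genome-wide by
  area — balancing selection shows up as a peak with an unusually large
  area.

Percentile ties count as "as extreme" (inclusive), the conservative choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import GenomicRegion
from .diversity_scan import WindowProfile


@dataclass
class Peak:
    """Contiguous above-threshold run of windows with its trapezoidal area."""

    region: GenomicRegion
    max_difference: float
    area: float
    start_index: int  # first window index (inclusive)
    end_index: int    # last window index (inclusive)


@dataclass
class RegionRank:
    region: GenomicRegion
    statistic: float
    percentile: float
    n_regions: int


def peak_area(values: np.ndarray) -> float:
    """Trapezoidal area under the positive part of a difference curve.

    x is measured in window-step units; a single-window peak has zero area.
    """
    values = np.clip(np.asarray(values, dtype=float), 0.0, None)
    if values.size < 2:
        return 0.0
    return float(np.trapezoid(values))


def chromosome_threshold(profile: WindowProfile, multiplier: float = 1.5) -> float:
    """``multiplier`` x the chromosome-wide mean of the defined difference values."""
    diff = profile.difference
    defined = np.isfinite(diff)
    if not defined.any():
        return np.nan
    return multiplier * float(diff[defined].mean())


def detect_peaks(profile: WindowProfile, multiplier: float = 1.5) -> list[Peak]:
    """Maximal runs of consecutive windows with difference strictly above
    ``multiplier`` x the chromosome-wide mean; undefined windows break runs."""
    diff = profile.difference
    threshold = chromosome_threshold(profile, multiplier)
    if not np.isfinite(threshold):
        return []
    above = np.isfinite(diff) & (diff > threshold)
    peaks = []
    i = 0
    n = diff.shape[0]
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            peaks.append(_make_peak(profile, i, j))
            i = j + 1
        else:
            i += 1
    return peaks


def _make_peak(profile: WindowProfile, i: int, j: int) -> Peak:
    vals = profile.difference[i:j + 1]
    region = GenomicRegion(
        profile.chromosome,
        int(profile.starts[i]),
        int(profile.starts[j]) + profile.window_size,
    )
    return Peak(
        region=region,
        max_difference=float(np.nanmax(vals)),
        area=peak_area(vals),
        start_index=i,
        end_index=j,
    )


def region_statistic(profile: WindowProfile, region: GenomicRegion, channel: str = "within") -> float:
    """Mean of the defined ``channel`` values over windows fully inside ``region``."""
    values = getattr(profile, channel)
    inside = (profile.starts >= region.start) & (profile.starts + profile.window_size <= region.end)
    vals = values[inside]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def _tiled_regions(profiles: dict[str, WindowProfile], region_size: int, region_step: int):
    for chrom, profile in profiles.items():
        span = int(profile.starts[-1]) + profile.window_size if profile.n_windows else 0
        for start in range(0, span - region_size + 1, region_step):
            yield GenomicRegion(chrom, start, start + region_size)


def rank_region_statistic(
    profiles: dict[str, WindowProfile],
    focal_region: GenomicRegion,
    region_size: int,
    region_step: int,
    channel: str = "within",
    side: str = "low",
) -> RegionRank:
    """Percentile of a focal region's mean ``channel`` value among all tiled
    fixed-size regions genome-wide.

    ``side='low'`` counts regions with statistic <= focal (low percentile =
    unusually low value); ``side='high'`` counts >= focal.  Ties are
    inclusive either way.
    """
    focal_profile = profiles.get(focal_region.chromosome)
    if focal_profile is None:
        raise ValueError(f"no profile for chromosome {focal_region.chromosome!r}")
    focal_stat = region_statistic(focal_profile, focal_region, channel)
    if not np.isfinite(focal_stat):
        raise ValueError(f"focal region {focal_region} has no defined windows")
    stats = []
    for region in _tiled_regions(profiles, region_size, region_step):
        s = region_statistic(profiles[region.chromosome], region, channel)
        if np.isfinite(s):
            stats.append(s)
    if not stats:
        raise ValueError("no comparable regions genome-wide")
    stats = np.array(stats)
    if side == "low":
        count = int((stats <= focal_stat).sum())
    elif side == "high":
        count = int((stats >= focal_stat).sum())
    else:
        raise ValueError("side must be 'low' or 'high'")
    return RegionRank(
        region=focal_region,
        statistic=focal_stat,
        percentile=100.0 * count / stats.size,
        n_regions=int(stats.size),
    )


def rank_region_within(
    profiles: dict[str, WindowProfile],
    focal_region: GenomicRegion,
    region_size: int,
    region_step: int,
) -> RegionRank:
    """Rank a region's mean within-group variation genome-wide (low = swept)."""
    return rank_region_statistic(profiles, focal_region, region_size, region_step,
                                 channel="within", side="low")


def rank_peak_area(all_peaks: list[Peak], focal_peak: Peak) -> RegionRank:
    """Percentile of a focal peak's area among genome-wide peaks (low = large).

    percentile = 100 x (# peaks with area >= focal) / n; if the focal peak is
    not among ``all_peaks`` it is pooled in before ranking.
    """
    if not all_peaks:
        raise ValueError("no peaks genome-wide to rank against")
    peaks = list(all_peaks)
    if focal_peak not in peaks:
        peaks.append(focal_peak)
    areas = np.array([p.area for p in peaks])
    count = int((areas >= focal_peak.area).sum())
    return RegionRank(
        region=focal_peak.region,
        statistic=focal_peak.area,
        percentile=100.0 * count / areas.size,
        n_regions=int(areas.size),
    )


def write_peaks_tsv(peaks: list[Peak], path) -> None:
    """Peak table: chromosome, start, length, max difference, area."""
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tlength\tmax_difference\tarea\n")
        for p in sorted(peaks, key=lambda p: (p.region.chromosome, p.region.start)):
            fh.write(
                f"{p.region.chromosome}\t{p.region.start}\t{p.region.length}\t"
                f"{p.max_difference:.6g}\t{p.area:.6g}\n"
            )
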