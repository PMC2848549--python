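"""Sliding-window within-group and between-group pairwise variation.

The scan statistic is the average number of pairwise nucleotide differences
per 1,000 bp, computed in overlapping windows (default 1 kb windows, 100 bp
step) for all strain pairs inside a focal haplotype group (the "within"
curve) and for all pairs straddling the group boundary (the "between"
curve).  A recent sweep in the focal group depresses the within curve
locally; balancing selection inflates the between curve, so the difference
profile (between - within) is the substrate for peak detection.

Missing data are handled per pair: each pair is normalised by its own count
of both-called sites before averaging, so windows rich in no-calls are not
biased toward zero.  Windows where too small a fraction of pair-site
comparisons is callable are reported as undefined (NaN), never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .alignment_io import MISSING, GenomicRegion, HaplotypeAlignment, StrainGrouping

#: minimum fraction of pair-site comparisons that must be callable
DEFAULT_COMPARABLE_FLOOR = 0.2


@dataclass
class WindowProfile:
    """Per-window values along one chromosome (NaN marks undefined windows)."""

    chromosome: str
    starts: np.ndarray  # window start positions, bp
    window_size: int
    step: int
    within: np.ndarray
    between: np.ndarray
    comparable_fraction: np.ndarray

    @property
    def difference(self) -> np.ndarray:
        return self.between - self.within

    @property
    def n_windows(self) -> int:
        return self.starts.shape[0]

    def window_region(self, index: int) -> GenomicRegion:
        s = int(self.starts[index])
        return GenomicRegion(self.chromosome, s, s + self.window_size)

    def window_containing(self, position: int) -> int:
        """Index of the window whose centre is nearest ``position``."""
        centres = self.starts + self.window_size / 2
        return int(np.argmin(np.abs(centres - position)))


def pairwise_diff(seq_a: np.ndarray, seq_b: np.ndarray, region: tuple[int, int] | None = None):
    """Count differing and comparable sites between two encoded sequences.

    A site is comparable when both symbols are non-MISSING; it is a
    difference when additionally the symbols differ.  Returns
    ``(diff_count, comparable_sites)``.
    """
    if region is not None:
        start, end = region
        seq_a = seq_a[start:end]
        seq_b = seq_b[start:end]
    comparable = (seq_a != MISSING) & (seq_b != MISSING)
    diffs = comparable & (seq_a != seq_b)
    return int(diffs.sum()), int(comparable.sum())


def _per_kb(diffs: int, comparable: int) -> float:
    return 1000.0 * diffs / comparable if comparable else np.nan


def window_within(alignment: HaplotypeAlignment, group: list[str], start: int, window_size: int) -> float:
    """Mean per-kb pairwise difference over all unordered pairs in ``group``.

    Pairs with no comparable sites in the window are excluded from the mean;
    NaN when every pair is empty.
    """
    if len(group) < 2:
        raise ValueError("within-group statistics need >= 2 strains")
    idx = alignment.strain_indices(group)
    region = (start, start + window_size)
    vals = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            d, c = pairwise_diff(alignment.matrix[idx[a]], alignment.matrix[idx[b]], region)
            if c:
                vals.append(_per_kb(d, c))
    return float(np.mean(vals)) if vals else np.nan


def window_between(alignment: HaplotypeAlignment, group: list[str], start: int, window_size: int) -> float:
    """Mean per-kb difference over all (in-group, outside) strain pairs."""
    inside = set(group)
    outside = [s for s in alignment.strains if s not in inside]
    if not outside:
        raise ValueError("between-group statistics need >= 1 strain outside the group")
    region = (start, start + window_size)
    vals = []
    for s_in in group:
        for s_out in outside:
            d, c = pairwise_diff(alignment.row(s_in), alignment.row(s_out), region)
            if c:
                vals.append(_per_kb(d, c))
    return float(np.mean(vals)) if vals else np.nan


def window_starts(length: int, window_size: int, step: int) -> np.ndarray:
    """Starts 0, step, 2*step, ... while start + window_size <= length."""
    if window_size < step or step < 1:
        raise ValueError("need window_size >= step >= 1")
    if length < window_size:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, length - window_size + 1, step, dtype=np.int64)


class PairwiseWindowStats:
    """Windowed difference/comparable counts for every strain pair, computed once.

    All grouped scans over one chromosome (the focal-group scan, every
    partitioning-sample draw of the empirical null) are averages over subsets
    of strain pairs, so the expensive per-pair sliding-window counts are
    computed a single time and reused.
    """

    def __init__(self, alignment: HaplotypeAlignment, window_size: int = 1000, step: int = 100):
        self.alignment = alignment
        self.window_size = int(window_size)
        self.step = int(step)
        self.starts = window_starts(alignment.length, self.window_size, self.step)
        n = alignment.n_strains
        pair_a, pair_b = np.triu_indices(n, k=1)
        self.pair_a = pair_a
        self.pair_b = pair_b
        n_pairs, n_win = pair_a.shape[0], self.starts.shape[0]
        self.diffs = np.zeros((n_pairs, n_win), dtype=np.int32)
        self.comps = np.zeros((n_pairs, n_win), dtype=np.int32)

        m = alignment.matrix
        called = m != MISSING
        ends = self.starts + self.window_size
        row = 0
        for i in range(n - 1):
            block_comp = called[i + 1:] & called[i]
            block_diff = block_comp & (m[i + 1:] != m[i])
            # windowed sums via cumulative sums along the chromosome
            cs_d = np.zeros((block_diff.shape[0], alignment.length + 1), dtype=np.int32)
            np.cumsum(block_diff, axis=1, out=cs_d[:, 1:])
            cs_c = np.zeros_like(cs_d)
            np.cumsum(block_comp, axis=1, out=cs_c[:, 1:])
            k = block_diff.shape[0]
            self.diffs[row:row + k] = cs_d[:, ends] - cs_d[:, self.starts]
            self.comps[row:row + k] = cs_c[:, ends] - cs_c[:, self.starts]
            row += k

        with np.errstate(invalid="ignore", divide="ignore"):
            self.rates = np.where(self.comps > 0, 1000.0 * self.diffs / np.maximum(self.comps, 1), np.nan)

    def pair_masks(self, in_group: np.ndarray, active: np.ndarray | None = None):
        """Boolean masks over pairs: both-in-group, and exactly-one-in-group.

        ``in_group``/``active`` are boolean arrays over strains; inactive
        strains (e.g. missing at a partitioning SNP) drop out of both sides.
        """
        if active is None:
            active = np.ones_like(in_group, dtype=bool)
        a_in = in_group[self.pair_a] & active[self.pair_a]
        b_in = in_group[self.pair_b] & active[self.pair_b]
        a_out = ~in_group[self.pair_a] & active[self.pair_a]
        b_out = ~in_group[self.pair_b] & active[self.pair_b]
        within = a_in & b_in
        between = (a_in & b_out) | (a_out & b_in)
        return within, between

    def profile(
        self,
        in_group: np.ndarray,
        active: np.ndarray | None = None,
        comparable_floor: float = DEFAULT_COMPARABLE_FLOOR,
        columns: slice | None = None,
    ) -> WindowProfile:
        """Within/between profile for a focal-group membership mask."""
        wmask, bmask = self.pair_masks(in_group, active)
        if columns is None:
            columns = slice(None)
        starts = self.starts[columns]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            within = np.nanmean(self.rates[wmask][:, columns], axis=0) if wmask.any() else np.full(starts.shape, np.nan)
            between = np.nanmean(self.rates[bmask][:, columns], axis=0) if bmask.any() else np.full(starts.shape, np.nan)
        used = wmask | bmask
        n_used = int(used.sum())
        if n_used:
            comp = self.comps[used][:, columns].sum(axis=0) / (n_used * self.window_size)
        else:
            comp = np.zeros(starts.shape)
        low = comp < comparable_floor
        within = np.where(low, np.nan, within)
        between = np.where(low, np.nan, between)
        return WindowProfile(
            chromosome=self.alignment.chromosome,
            starts=starts,
            window_size=self.window_size,
            step=self.step,
            within=within,
            between=between,
            comparable_fraction=comp,
        )


def scan_chromosome(
    alignment: HaplotypeAlignment,
    grouping: StrainGrouping,
    focal_group: str,
    window_size: int = 1000,
    step: int = 100,
    comparable_floor: float = DEFAULT_COMPARABLE_FLOOR,
    stats: PairwiseWindowStats | None = None,
) -> WindowProfile:
    """Sliding-window within/between profile for one focal haplotype group.

    ``stats`` may carry precomputed pair-window counts for this alignment
    (they are group-independent and reusable across focal groups).
    """
    if focal_group not in grouping.groups:
        raise ValueError(f"unknown group {focal_group!r}")
    members = grouping.members(focal_group)
    if len(members) < 2:
        raise ValueError(f"group {focal_group!r} needs >= 2 strains")
    if stats is None:
        stats = PairwiseWindowStats(alignment, window_size, step)
    elif (stats.window_size, stats.step) != (window_size, step):
        raise ValueError("precomputed stats use different window/step")
    in_group = np.zeros(alignment.n_strains, dtype=bool)
    in_group[alignment.strain_indices(members)] = True
    return stats.profile(in_group, comparable_floor=comparable_floor)


def write_profile_tsv(profile: WindowProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\twithin\tbetween\tdifference\tcomparable_fraction\n")
        diff = profile.difference
        for i, s in enumerate(profile.starts):
            fh.write(
                f"{profile.chromosome}\t{int(s)}\t{int(s) + profile.window_size}\t"
                f"{profile.within[i]:.6g}\t{profile.between[i]:.6g}\t"
                f"{diff[i]:.6g}\t{profile.comparable_fraction[i]:.6g}\n"
            )
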