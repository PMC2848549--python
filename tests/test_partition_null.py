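"""Partitioning-sampling null: SNP selection, walk-out peaks, percentiles."""

import numpy as np
import pytest

from aquascan.alignment_io import MISSING, GenomicRegion
from aquascan.diversity_scan import PairwiseWindowStats
from aquascan.partition_null import (
    NullDistribution,
    focal_null_percentile,
    make_partition_snp,
    null_areas,
    partition_peak_area,
    qualifying_sites,
    select_partition_snps,
    walk_out_peak,
)
from aquascan.synthetic_data import ImplantedRegion, SimulationConfig, simulate_genome

from conftest import make_alignment, random_alignment
from test_region_ranking import profile_from_difference


class TestSelectPartitionSnps:
    def test_monomorphic_chromosome_empty(self):
        aln = make_alignment(["ACGT" * 100] * 6)
        assert select_partition_snps(aln, grid=100) == []

    def test_single_qualifying_snp(self):
        # one biallelic site with minor count 3 at position 150 of a 400 bp chromosome
        seqs = ["A" * 400 for _ in range(8)]
        for i in range(3):
            seqs[i] = seqs[i][:150] + "G" + seqs[i][151:]
        aln = make_alignment(seqs)
        snps = select_partition_snps(aln, grid=100, min_minor=3)
        assert len(snps) == 1
        assert snps[0].position == 150
        assert snps[0].minor_count == 3
        assert set(snps[0].minor_strains) == {0, 1, 2}

    def test_min_minor_excludes_rare(self):
        seqs = ["A" * 200 for _ in range(8)]
        seqs[0] = "G" + seqs[0][1:]  # singleton
        aln = make_alignment(seqs)
        assert select_partition_snps(make_alignment(seqs), grid=50, min_minor=3) == []
        assert len(select_partition_snps(aln, grid=50, min_minor=1)) == 1

    def test_triallelic_not_qualifying(self):
        seqs = ["A" * 100 for _ in range(9)]
        for i in range(3):
            seqs[i] = "C" + seqs[i][1:]
        for i in range(3, 6):
            seqs[i] = "G" + seqs[i][1:]
        mask = qualifying_sites(make_alignment(seqs), min_minor=3)
        assert not mask[0]

    def test_first_at_or_after_each_gridpoint_matches_brute_force(self, rng):
        aln = random_alignment(rng, 10, 5000, missing_rate=0.1)
        grid, min_minor = 500, 3
        mask = qualifying_sites(aln, min_minor)
        expected = []
        for g in range(0, 5000, grid):
            for pos in range(g, min(g + grid, 5000)):
                if mask[pos]:
                    expected.append(pos)
                    break
        got = [s.position for s in select_partition_snps(aln, grid, min_minor)]
        assert got == expected
        # brute-force qualification check at the selected sites
        for s in select_partition_snps(aln, grid, min_minor):
            col = aln.matrix[:, s.position]
            col = col[col != MISSING]
            values, counts = np.unique(col, return_counts=True)
            assert len(values) == 2 and counts.min() >= min_minor

    def test_missing_strains_sit_out(self):
        seqs = ["A" * 100 for _ in range(8)]
        for i in range(3):
            seqs[i] = "G" + seqs[i][1:]
        seqs[7] = "N" + seqs[7][1:]
        snp = make_partition_snp(make_alignment(seqs), 0)
        assert 7 not in snp.called_strains
        assert snp.minor_count == 3


class TestWalkOutPeak:
    def test_all_below_cutoff_degenerate(self):
        profile = profile_from_difference(np.full(20, 1.0))
        peak = walk_out_peak(profile, 10, cutoff=5.0)
        assert peak.area == 0.0
        assert (peak.start_index, peak.end_index) == (10, 10)

    def test_plateau_extent(self):
        diff = np.zeros(20)
        diff[8:13] = 6.0
        peak = walk_out_peak(profile_from_difference(diff), 10, cutoff=3.54)
        assert (peak.start_index, peak.end_index) == (8, 12)

    def test_matches_brute_force_expansion(self, rng):
        for _ in range(50):
            diff = rng.normal(size=40)
            cutoff = float(rng.normal(scale=0.5))
            centre = int(rng.integers(40))
            profile = profile_from_difference(diff)
            peak = walk_out_peak(profile, centre, cutoff)
            if diff[centre] < cutoff:
                assert (peak.start_index, peak.end_index) == (centre, centre)
                assert peak.area == 0.0
                continue
            i = centre
            while i > 0 and diff[i - 1] >= cutoff:
                i -= 1
            j = centre
            while j + 1 < 40 and diff[j + 1] >= cutoff:
                j += 1
            assert (peak.start_index, peak.end_index) == (i, j)

    def test_undefined_center_errors(self):
        diff = np.full(10, np.nan)
        with pytest.raises(ValueError):
            walk_out_peak(profile_from_difference(diff), 5, 0.0)

    def test_undefined_window_stops_walk(self):
        diff = np.array([9.0, np.nan, 9.0, 9.0, 9.0])
        peak = walk_out_peak(profile_from_difference(diff), 2, cutoff=1.0)
        assert (peak.start_index, peak.end_index) == (2, 4)


class TestFocalNullPercentile:
    def test_focal_exceeds_all(self):
        null = NullDistribution(areas=np.arange(100, dtype=float))
        assert focal_null_percentile(1000.0, null) == pytest.approx(0.0)
        assert focal_null_percentile(99.0, null) == pytest.approx(1.0)

    def test_zero_on_positive_null(self):
        null = NullDistribution(areas=np.arange(1.0, 101.0))
        assert focal_null_percentile(0.0, null) == 100.0

    def test_matches_brute_force_count(self, rng):
        areas = rng.exponential(size=37)
        null = NullDistribution(areas=areas)
        for focal in [0.0, 0.5, 2.0, float(areas[3])]:
            expected = 100.0 * np.sum(areas >= focal) / 37
            assert focal_null_percentile(focal, null) == pytest.approx(expected)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            focal_null_percentile(1.0, NullDistribution(areas=np.empty(0)))

    def test_randomized_rank_within_tie_block(self, rng):
        null = NullDistribution(areas=np.zeros(9))
        vals = {focal_null_percentile(0.0, null, randomized=True, rng=rng)
                for _ in range(200)}
        assert vals <= {100.0 * r / 10 for r in range(1, 11)}
        assert len(vals) == 10  # every tie rank reachable


class TestNullAreas:
    def _panmictic(self, seed, n_chrom=2):
        cfg = SimulationConfig(
            chromosome_lengths={f"chr{i}": 30000 for i in range(n_chrom)},
            seed=seed, missing_rate=0.01, gap_rate=0.0,
        )
        return simulate_genome(cfg)

    def test_bookkeeping_counts(self):
        sim = self._panmictic(5)
        aln = sim.alignments["chr0"]
        snps = select_partition_snps(aln, grid=3000)
        null = null_areas(aln, snps, cutoff=2.0)
        assert null.n_snps == len(null.draws) <= len(snps)
        assert (null.areas >= 0).all()

    def test_unstructured_null_concentrates_near_zero(self):
        # simulation oracle: without structure most partitions give small areas
        sim = self._panmictic(11)
        areas = []
        for aln in sim.alignments.values():
            snps = select_partition_snps(aln, grid=2000)
            areas.append(null_areas(aln, snps, cutoff=2.0).areas)
        areas = np.concatenate(areas)
        assert np.median(areas) < 20.0

    def test_sweep_partition_in_extreme_tail(self):
        region = GenomicRegion("chr0", 12000, 17000)
        cfg = SimulationConfig(
            chromosome_lengths={"chr0": 30000, "chr1": 30000},
            implants=[ImplantedRegion(region, "sweep", 0.1, 2.0)],
            seed=7,
        )
        sim = simulate_genome(cfg)
        aln = sim.alignments["chr0"]
        stats = PairwiseWindowStats(aln)
        cutoff = 2.0
        null_parts = []
        for a in sim.alignments.values():
            snps = select_partition_snps(a, grid=2000)
            null_parts.append(null_areas(a, snps, cutoff).areas)
        null = NullDistribution(areas=np.concatenate(null_parts))
        in_group = np.zeros(aln.n_strains, dtype=bool)
        in_group[aln.strain_indices(sim.grouping.members("G25-deletion"))] = True
        peak = partition_peak_area(stats, in_group, np.ones_like(in_group),
                                   14500, 20000, cutoff)
        pct = focal_null_percentile(peak.area, null)
        assert pct <= 10.0

    def test_strain_order_invariance(self):
        sim = self._panmictic(3, n_chrom=1)
        aln = sim.alignments["chr0"]
        perm = np.random.default_rng(0).permutation(aln.n_strains)
        from aquascan.alignment_io import HaplotypeAlignment

        shuffled = HaplotypeAlignment(aln.chromosome,
                                      [aln.strains[i] for i in perm],
                                      aln.matrix[perm])
        s1 = select_partition_snps(aln, grid=3000)
        s2 = select_partition_snps(shuffled, grid=3000)
        a1 = null_areas(aln, s1, cutoff=2.0).areas
        a2 = null_areas(shuffled, s2, cutoff=2.0).areas
        np.testing.assert_allclose(a1, a2, atol=1e-9)
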