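"""Synthetic group-structured genomes and coding loci with known truth.

The genome generator emulates the statistical structure the scan consumes:
multi-strain haplotype alignments with a shared polymorphism background, a
group-private polymorphism background, and implanted regions where the
within-group and between-group diversity are rescaled to mimic a partial
selective sweep (low within / high between), a high-divergence region, or
a balanced region.  It is a two-level mutation-placement model, not a
coalescent: SNPs are placed site-by-site with controlled frequencies, which
gives exact control of the within/between expectations the sliding-window
scan measures.

Density parameters are calibrated in expected pairwise differences per kb
(i.e. per-kb nucleotide diversity): for each placed SNP, the derived-allele
count k is drawn from a neutral-shaped 1/k spectrum, and the per-site SNP
rate is the target density divided by the mean per-SNP heterozygosity under
that spectrum, so the realised diversity matches the requested value in
expectation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment_io import (
    MISSING,
    GenomicRegion,
    HaplotypeAlignment,
    StrainGrouping,
    write_alignment,
)
from .locus_stats import CodingAlignment

#: mean length of simulated gap runs (geometric), bp
GAP_RUN_MEAN = 5.0


@dataclass
class ImplantedRegion:
    region: GenomicRegion
    kind: str  # 'sweep' | 'divergent' | 'balanced'
    within_scale: float = 1.0
    between_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("sweep", "divergent", "balanced"):
            raise ValueError(f"unknown implant kind {self.kind!r}")
        if self.within_scale <= 0 or self.between_scale <= 0:
            raise ValueError("implant scales must be > 0")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic genome.

    Defaults mirror the scaled-down study design used throughout the test
    battery: 3 haplotype groups of 8 strains, 16 chromosomes of 50 kb, and
    ~5 pairwise differences per kb of background diversity split between a
    shared and a group-private layer.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"G25-deletion": 8, "11bp-deletion": 8, "full-length": 8}
    )
    chromosome_lengths: dict[str, int] = field(
        default_factory=lambda: {f"chr{i:02d}": 50000 for i in range(1, 17)}
    )
    shared_density: float = 3.0   # pairwise diffs per kb from SNPs shared across groups
    private_density: float = 2.0  # pairwise diffs per kb per group from private SNPs
    implants: list[ImplantedRegion] = field(default_factory=list)
    missing_rate: float = 0.02
    gap_rate: float = 0.0005      # gap-run starts per strain-site
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shared_density < 0 or self.private_density < 0:
            raise ValueError("densities must be >= 0")
        if not (0 <= self.missing_rate < 1 and 0 <= self.gap_rate < 1):
            raise ValueError("rates must be in [0, 1)")
        by_chrom: dict[str, list[ImplantedRegion]] = {}
        for imp in self.implants:
            L = self.chromosome_lengths.get(imp.region.chromosome)
            if L is None or imp.region.end > L:
                raise ValueError(f"implant {imp.region} outside the genome")
            by_chrom.setdefault(imp.region.chromosome, []).append(imp)
        for regs in by_chrom.values():
            regs = sorted(regs, key=lambda r: r.region.start)
            for a, b in zip(regs, regs[1:]):
                if a.region.end > b.region.start:
                    raise ValueError(f"overlapping implants {a.region} / {b.region}")

    @property
    def strains(self) -> list[str]:
        return [f"{label}_s{i}" for label in self.group_sizes for i in range(self.group_sizes[label])]

    def grouping(self) -> StrainGrouping:
        return StrainGrouping({s: s.rsplit("_s", 1)[0] for s in self.strains},
                              list(self.group_sizes))


@dataclass
class TruthSet:
    """Ground truth emitted alongside a simulated genome."""

    implants: list[ImplantedRegion]
    grouping: StrainGrouping
    background_density: float  # total within-group diffs/kb outside implants

    def to_json(self, path) -> None:
        payload = {
            "background_density": self.background_density,
            "groups": {g: self.grouping.members(g) for g in self.grouping.groups},
            "implants": [
                {
                    "chromosome": i.region.chromosome,
                    "start": i.region.start,
                    "end": i.region.end,
                    "kind": i.kind,
                    "within_scale": i.within_scale,
                    "between_scale": i.between_scale,
                }
                for i in self.implants
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class SimulatedGenome:
    alignments: dict[str, HaplotypeAlignment]
    grouping: StrainGrouping
    truth: TruthSet
    gap_masks: dict[str, np.ndarray]

    def write(self, directory) -> None:
        """Emit per-chromosome FASTA, the grouping TSV and the truth JSON."""
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for chrom, aln in self.alignments.items():
            write_alignment(aln, directory / f"{chrom}.fasta", gap_mask=self.gap_masks[chrom])
        self.grouping.to_tsv(directory / "groups.tsv")
        self.truth.to_json(directory / "truth.json")


def _sfs_draw(rng: np.random.Generator, n: int, size: int) -> np.ndarray:
    """Derived-allele counts in 1..n-1 with neutral 1/k weights."""
    k = np.arange(1, n)
    w = 1.0 / k
    return rng.choice(k, size=size, p=w / w.sum())


def _mean_heterozygosity(n: int) -> float:
    """E[2k(n-k)/(n(n-1))] under the 1/k spectrum: per-SNP expected
    contribution to pairwise diversity."""
    k = np.arange(1, n)
    w = (1.0 / k) / (1.0 / k).sum()
    h = 2.0 * k * (n - k) / (n * (n - 1))
    return float((w * h).sum())


def _place_snps(rng, matrix, positions, carriers_list, ancestral):
    for pos, carriers in zip(positions, carriers_list):
        anc = ancestral[pos]
        derived = (anc + 1 + rng.integers(3)) % 4
        matrix[carriers, pos] = derived


def simulate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> SimulatedGenome:
    """Simulate the full genome described by ``config``.

    Same seed, same byte-identical output.  Within each implanted region the
    shared/private SNP densities are multiplied by ``within_scale``, and
    group-fixed differences are added at a density of
    ``(between_scale - within_scale) x background`` per kb (each contributing
    one difference to every cross-group pair), so the region's expected
    within-group diversity is ``within_scale x`` background and the expected
    between-group diversity is raised toward ``between_scale x`` background.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    grouping = config.grouping()
    strains = config.strains
    n = len(strains)
    group_slices: dict[str, np.ndarray] = {}
    offset = 0
    for label, size in config.group_sizes.items():
        group_slices[label] = np.arange(offset, offset + size)
        offset += size
    background = config.shared_density + config.private_density

    alignments: dict[str, HaplotypeAlignment] = {}
    gap_masks: dict[str, np.ndarray] = {}
    for chrom, L in config.chromosome_lengths.items():
        ancestral = rng.integers(0, 4, size=L, dtype=np.uint8)
        matrix = np.tile(ancestral, (n, 1))

        # per-site density multiplier from implants
        within_mult = np.ones(L)
        implants_here = [i for i in config.implants if i.region.chromosome == chrom]
        for imp in implants_here:
            within_mult[imp.region.start:imp.region.end] = imp.within_scale

        # shared SNPs (segregating across the whole sample)
        if config.shared_density > 0:
            rate = (config.shared_density / 1000.0) / _mean_heterozygosity(n)
            mask = rng.random(L) < rate * within_mult
            positions = np.flatnonzero(mask)
            ks = _sfs_draw(rng, n, positions.size)
            carriers = [rng.choice(n, size=int(k), replace=False) for k in ks]
            _place_snps(rng, matrix, positions, carriers, ancestral)

        # group-private SNPs (one group per SNP, chosen uniformly)
        if config.private_density > 0:
            for label, idx in group_slices.items():
                m = idx.size
                if m < 2:
                    continue
                rate = (config.private_density / 1000.0) / _mean_heterozygosity(m)
                mask = rng.random(L) < rate * within_mult
                positions = np.flatnonzero(mask)
                ks = _sfs_draw(rng, m, positions.size)
                carriers = [idx[rng.choice(m, size=int(k), replace=False)] for k in ks]
                _place_snps(rng, matrix, positions, carriers, ancestral)

        # implant cross-group fixed differences
        for imp in implants_here:
            fd_density = max(imp.between_scale - imp.within_scale, 0.0) * background
            if fd_density <= 0:
                continue
            span = imp.region.length
            n_fd = rng.poisson(fd_density * span / 1000.0)
            positions = imp.region.start + rng.choice(span, size=min(n_fd, span), replace=False)
            for pos in positions:
                alleles = rng.permutation(4)[: len(group_slices)]
                for gi, idx in enumerate(group_slices.values()):
                    matrix[idx, pos] = alleles[gi]

        # missing data and gap runs
        if config.missing_rate > 0:
            matrix[rng.random(matrix.shape) < config.missing_rate] = MISSING
        gap_mask = np.zeros(matrix.shape, dtype=bool)
        if config.gap_rate > 0:
            starts = rng.random(matrix.shape) < config.gap_rate
            for i, j in zip(*np.nonzero(starts)):
                run = int(rng.geometric(1.0 / GAP_RUN_MEAN))
                gap_mask[i, j:j + run] = True
            matrix[gap_mask] = MISSING

        alignments[chrom] = HaplotypeAlignment(chromosome=chrom, strains=list(strains), matrix=matrix)
        gap_masks[chrom] = gap_mask

    truth = TruthSet(implants=list(config.implants), grouping=grouping,
                     background_density=background)
    return SimulatedGenome(alignments=alignments, grouping=grouping, truth=truth,
                           gap_masks=gap_masks)


# --- coding loci -----------------------------------------------------------

# base codon GGT (Gly): position 2 changes G->C are synonymous (GGN all Gly),
# position 1 changes are nonsynonymous (AGT=Ser); no stop codons reachable.
_BASE_CODON = "GGT"
_SYN_CODON = "GGC"    # silent third-position variant
_NONSYN_CODON = "AGT" # first-position replacement variant


def simulate_coding_locus(
    n_ingroup: int,
    n_codons: int,
    Pn: int,
    Ps: int,
    Dn: int,
    Ds: int,
    seed: int | None = None,
    P_indel: int = 0,
    D_indel: int = 0,
) -> CodingAlignment:
    """Build an ingroup + outgroup coding alignment whose MK classification
    is exactly the prescribed table.

    One event per codon: polymorphic events put the variant codon in a
    minority of ingroup sequences; divergent events put it in the outgroup.
    Indel events are whole-codon gap runs.  Raises when the events do not
    fit in ``n_codons``.
    """
    if n_ingroup < 2:
        raise ValueError("need >= 2 ingroup sequences")
    n_events = Pn + Ps + Dn + Ds + P_indel + D_indel
    if n_events > n_codons:
        raise ValueError(f"{n_events} events do not fit in {n_codons} codons")
    rng = np.random.default_rng(seed)
    codon_order = rng.permutation(n_codons)
    ingroup = [[_BASE_CODON] * n_codons for _ in range(n_ingroup)]
    outgroup = [_BASE_CODON] * n_codons
    max_minor = max(1, (n_ingroup - 1) // 2)

    remaining = codon_order.tolist()

    def next_codons(k: int) -> list[int]:
        out = remaining[:k]
        del remaining[:k]
        return out

    indel_taken: set[int] = set()

    def next_indel_codons(k: int) -> list[int]:
        # keep indel codons non-adjacent so gap runs never merge
        out = []
        for codon in list(remaining):
            if len(out) == k:
                break
            if codon - 1 in indel_taken or codon + 1 in indel_taken:
                continue
            out.append(codon)
            indel_taken.add(codon)
            remaining.remove(codon)
        if len(out) < k:
            raise ValueError("cannot place non-adjacent indel events; need more codons")
        return out

    for codon in next_codons(Pn):
        minor = rng.choice(n_ingroup, size=int(rng.integers(1, max_minor + 1)), replace=False)
        for i in minor:
            ingroup[i][codon] = _NONSYN_CODON
    for codon in next_codons(Ps):
        minor = rng.choice(n_ingroup, size=int(rng.integers(1, max_minor + 1)), replace=False)
        for i in minor:
            ingroup[i][codon] = _SYN_CODON
    for codon in next_codons(Dn):
        outgroup[codon] = _NONSYN_CODON
    for codon in next_codons(Ds):
        outgroup[codon] = _SYN_CODON
    for codon in next_indel_codons(P_indel):
        minor = rng.choice(n_ingroup, size=int(rng.integers(1, max_minor + 1)), replace=False)
        for i in minor:
            ingroup[i][codon] = "---"
    for codon in next_indel_codons(D_indel):
        outgroup[codon] = "---"

    return CodingAlignment(
        ingroup=["".join(s) for s in ingroup],
        outgroup="".join(outgroup),
    )


def simulate_balanced_locus(
    n: int,
    length: int,
    class_split: tuple[int, int],
    divergence: int,
    seed: int | None = None,
    noise_density: float = 0.5,
) -> list[str]:
    """Sequences with two deep haplotype classes at intermediate frequency.

    ``divergence`` fixed differences separate the two classes; background
    noise adds singleton mutations at ``noise_density`` per kb per
    sequence.  This is the allele-frequency signature of balancing
    selection (excess intermediate-frequency polymorphism, positive
    Tajima's D).
    """
    if sum(class_split) != n or min(class_split) < 2:
        raise ValueError("class sizes must sum to n and each be >= 2")
    if divergence < 0 or divergence > length:
        raise ValueError("divergence must be in [0, length]")
    rng = np.random.default_rng(seed)
    ancestral = rng.integers(0, 4, size=length, dtype=np.uint8)
    matrix = np.tile(ancestral, (n, 1))
    class_b = np.arange(class_split[0], n)
    div_pos = rng.choice(length, size=divergence, replace=False)
    for pos in div_pos:
        matrix[class_b, pos] = (ancestral[pos] + 1 + rng.integers(3)) % 4
    if noise_density > 0:
        for i in range(n):
            k = rng.poisson(noise_density * length / 1000.0)
            for pos in rng.choice(length, size=min(k, length), replace=False):
                matrix[i, pos] = (matrix[i, pos] + 1 + rng.integers(3)) % 4
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return [lut[row].tobytes().decode() for row in matrix]
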