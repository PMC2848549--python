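"""Reading, validating and masking multi-strain haplotype alignments.

Alignments are stored as dense ``strains x positions`` matrices over a
5-state alphabet (A, C, G, T, MISSING).  Gaps and sub-threshold-quality
bases are converted to MISSING on load: in low-coverage population
alignments, gap columns are dominated by alignment error rather than real
indel variation, so every downstream statistic treats them as no-calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: integer codes for the 5-state alphabet
A, C, G, T, MISSING = 0, 1, 2, 3, 4

#: symbol used on disk for a missing/no-call base
MISSING_CHAR = "N"

_SYMBOLS = np.frombuffer(b"ACGTN", dtype=np.uint8)

# byte -> code lookup; everything that is not an unambiguous base (gaps,
# IUPAC ambiguity codes, N, stray characters) maps to MISSING
_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _ENCODE[ord(_ch)] = _i
    _ENCODE[ord(_ch.lower())] = _i


class AlignmentError(ValueError):
    """Raised for malformed alignments or inconsistent inputs."""


@dataclass
class HaplotypeAlignment:
    """A per-chromosome matrix of strains x positions over {A,C,G,T,MISSING}."""

    chromosome: str
    strains: list[str]
    matrix: np.ndarray  # uint8, shape (n_strains, L)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise AlignmentError("alignment matrix must be 2-D")
        if len(self.strains) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.strains)} strain names for {self.matrix.shape[0]} rows"
            )
        if len(set(self.strains)) != len(self.strains):
            raise AlignmentError("strain names must be unique")
        if self.length < 1:
            raise AlignmentError("alignment length must be >= 1")
        if self.matrix.size and self.matrix.max() > MISSING:
            raise AlignmentError("alignment contains symbols outside the 5-state alphabet")
        self._index = {name: i for i, name in enumerate(self.strains)}

    @property
    def n_strains(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def row(self, strain: str) -> np.ndarray:
        return self.matrix[self._index[strain]]

    def strain_indices(self, strains) -> np.ndarray:
        return np.array([self._index[s] for s in strains], dtype=np.intp)

    def sequences(self) -> list[str]:
        """Decode rows back to strings (MISSING -> 'N')."""
        return [_SYMBOLS[row].tobytes().decode() for row in self.matrix]


@dataclass(frozen=True, order=True)
class GenomicRegion:
    """0-based half-open interval on one chromosome."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AlignmentError(f"invalid region {self.chromosome}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicRegion") -> int:
        if self.chromosome != other.chromosome:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicRegion") -> float:
        """min(overlap/len(self), overlap/len(other)) -- the reciprocal-overlap rule."""
        ov = self.overlap(other)
        return min(ov / self.length, ov / other.length)


@dataclass
class StrainGrouping:
    """Partition of a strain subset into named haplotype groups.

    Strains absent from ``group_of`` are "outside" strains: they never enter a
    within-group average but do count on the between side of every group.
    """

    group_of: dict[str, str]
    groups: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: list[str] = []
        for g in self.group_of.values():
            if g not in seen:
                seen.append(g)
        if not self.groups:
            self.groups = seen
        elif set(seen) - set(self.groups):
            raise AlignmentError("group_of refers to labels missing from groups")

    def members(self, label: str) -> list[str]:
        return [s for s, g in self.group_of.items() if g == label]

    def validate_against(self, alignment: HaplotypeAlignment, min_size: int = 2) -> None:
        missing = [s for s in self.group_of if s not in alignment.strains]
        if missing:
            raise AlignmentError(f"grouped strains absent from alignment: {missing}")
        for label in self.groups:
            n = len(self.members(label))
            if n < min_size:
                raise AlignmentError(
                    f"group {label!r} has {n} strains; >= {min_size} required for "
                    "within-group statistics"
                )

    @classmethod
    def from_tsv(cls, path) -> "StrainGrouping":
        group_of: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise AlignmentError(f"{path}:{lineno}: expected 'strain<TAB>group'")
                strain, group = parts
                if strain in group_of:
                    raise AlignmentError(f"{path}:{lineno}: duplicate strain {strain!r}")
                group_of[strain] = group
        if not group_of:
            raise AlignmentError(f"grouping file {path} assigns no strains")
        return cls(group_of)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for strain, group in self.group_of.items():
                fh.write(f"{strain}\t{group}\n")


def _read_quality_track(path) -> dict[str, np.ndarray]:
    """FASTA-style quality track: '>name' header, whitespace-separated ints."""
    tracks: dict[str, np.ndarray] = {}
    name = None
    values: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                if name is not None:
                    tracks[name] = np.array(values, dtype=np.int64)
                name = line[1:].split()[0]
                values = []
            elif line:
                values.extend(line.split())
    if name is not None:
        tracks[name] = np.array(values, dtype=np.int64)
    return tracks


def load_alignment(
    fasta_path,
    quality_path=None,
    quality_min: int = 40,
    chromosome: str | None = None,
) -> HaplotypeAlignment:
    """Load an aligned multi-FASTA into a :class:`HaplotypeAlignment`.

    Gaps, IUPAC ambiguity codes and (when a quality track is supplied) bases
    with quality < ``quality_min`` become MISSING.  All records must have the
    same length; violations name the offending record.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"{fasta_path}: no FASTA records")
    length = len(records[0].seq)
    rows = []
    names = []
    for rec in records:
        if len(rec.seq) != length:
            raise AlignmentError(
                f"{fasta_path}: record {rec.id!r} has length {len(rec.seq)}, "
                f"expected {length}"
            )
        rows.append(_ENCODE[np.frombuffer(str(rec.seq).encode(), dtype=np.uint8)])
        names.append(rec.id)
    matrix = np.vstack(rows)

    if quality_path is not None:
        tracks = _read_quality_track(quality_path)
        for i, name in enumerate(names):
            if name not in tracks:
                raise AlignmentError(f"{quality_path}: no quality track for {name!r}")
            qual = tracks[name]
            if qual.shape[0] != length:
                raise AlignmentError(
                    f"{quality_path}: track for {name!r} has {qual.shape[0]} values, "
                    f"expected {length}"
                )
            matrix[i, qual < quality_min] = MISSING

    if chromosome is None:
        chromosome = Path(str(fasta_path)).stem
    return HaplotypeAlignment(chromosome=chromosome, strains=names, matrix=matrix)


def write_alignment(alignment: HaplotypeAlignment, path, gap_mask: np.ndarray | None = None) -> None:
    """Write a 5-state alignment as multi-FASTA (MISSING -> 'N').

    ``gap_mask`` (same shape as the matrix) marks positions written as '-'
    instead of 'N', so simulated gap runs survive to disk; both decode to
    MISSING on re-load.
    """
    records = []
    for i, (name, seq) in enumerate(zip(alignment.strains, alignment.sequences())):
        if gap_mask is not None:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            arr[gap_mask[i]] = ord("-")
            seq = arr.tobytes().decode()
        records.append(SeqRecord(Seq(seq), id=name, description=""))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


def resolve_heterozygous_site(calls, rng: np.random.Generator) -> str:
    """Collapse a diploid call at one site to a single haplotype symbol.

    Two distinct candidate alleles are resolved by a fair seeded coin; more
    than two candidates cannot be interpreted and become MISSING.
    """
    alleles = sorted({c.upper() for c in calls})
    if len(alleles) == 1:
        return alleles[0]
    if len(alleles) == 2:
        return alleles[int(rng.integers(2))]
    return MISSING_CHAR


_REPORT_COLUMNS = ["chrom", "start", "end", "score", "percentile"]


def write_region_report(records, path) -> None:
    """Write scored regions as a BED-style 0-based half-open TSV.

    ``records`` is an iterable of ``(GenomicRegion, score, percentile)``;
    output is sorted by chromosome then start.
    """
    rows = []
    for region, score, percentile in records:
        if not np.isfinite(score) or not np.isfinite(percentile):
            raise AlignmentError(f"non-finite score for region {region}")
        rows.append((region.chromosome, region.start, region.end, float(score), float(percentile)))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_REPORT_COLUMNS) + "\n")
        for chrom, start, end, score, pct in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{score!r}\t{pct!r}\n")


def read_region_report(path) -> list[tuple[GenomicRegion, float, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise AlignmentError(f"{path}: missing region-report header")
        for line in fh:
            chrom, start, end, score, pct = line.rstrip("\n").split("\t")
            out.append((GenomicRegion(chrom, int(start), int(end)), float(score), float(pct)))
    return out
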