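"""Locus-level selection tests on in-frame coding alignments.

Implements the classic single-locus battery for a set of ingroup coding
sequences plus one outgroup sequence:

* McDonald-Kreitman contingency counts (nonsynonymous/synonymous x
  polymorphism/divergence, with an optional indel channel) and Fisher's
  exact test;
* Tajima's (1989) D from the ingroup sample;
* Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction for a pair of
  sequences;
* a generic 2x2 chi-square independence test (used for functional status
  at two paralogous loci across strains).

Pseudogenes are first-class input: internal stop codons warn rather than
fail, since the loci under study are inactivated alleles.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from Bio.Data.CodonTable import standard_dna_table

_CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TABLE[_stop] = "*"

_BASES = "ACGT"


def translate_codon(codon: str) -> str:
    """Amino acid for a codon; '*' for stops (pseudogene-tolerant)."""
    return _CODON_TABLE[codon]


def _is_clean(codon: str) -> bool:
    return all(b in _BASES for b in codon)


class FrameError(ValueError):
    """Raised when sequences violate the declared reading frame."""


@dataclass
class CodingAlignment:
    """In-frame ingroup sequences plus one outgroup sequence.

    Sequences are aligned strings over A/C/G/T, '-' (gap) and 'N'
    (missing); the aligned length must be a multiple of 3 in the reference
    reading frame.
    """

    ingroup: list[str]
    outgroup: str
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ingroup = [s.upper() for s in self.ingroup]
        self.outgroup = self.outgroup.upper()
        L = len(self.outgroup)
        for i, s in enumerate(self.ingroup):
            if len(s) != L:
                raise FrameError(f"ingroup sequence {i} has length {len(s)}, expected {L}")
        if L % 3 != 0:
            raise FrameError(f"aligned length {L} is not a multiple of 3")
        if not self.names:
            self.names = [f"strain{i}" for i in range(len(self.ingroup))]
        for s in self.ingroup + [self.outgroup]:
            for c0 in range(0, L, 3):
                codon = s[c0:c0 + 3]
                if _is_clean(codon) and translate_codon(codon) == "*" and c0 + 3 < L:
                    warnings.warn(
                        f"internal stop codon at {c0} (pseudogene?)", stacklevel=2
                    )
                    break

    @property
    def length(self) -> int:
        return len(self.outgroup)

    @property
    def n_codons(self) -> int:
        return self.length // 3


@dataclass
class MKTable:
    """2x2 (+ indel channel) counts for one locus."""

    Pn: int = 0
    Ps: int = 0
    Dn: int = 0
    Ds: int = 0
    P_indel: int = 0
    D_indel: int = 0

    def __post_init__(self) -> None:
        for name in ("Pn", "Ps", "Dn", "Ds", "P_indel", "D_indel"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    def snp_counts(self) -> tuple[int, int, int, int]:
        return self.Pn, self.Ps, self.Dn, self.Ds


def _gap_runs(seq: str) -> set[tuple[int, int]]:
    """Half-open (start, end) spans of contiguous '-' runs."""
    runs = set()
    i = 0
    L = len(seq)
    while i < L:
        if seq[i] == "-":
            j = i
            while j < L and seq[j] == "-":
                j += 1
            runs.add((i, j))
            i = j
        else:
            i += 1
    return runs


def _indel_counts(coding: CodingAlignment) -> tuple[int, int]:
    """Distinct gap runs: segregating in the ingroup -> polymorphic; fixed
    ingroup-vs-outgroup -> divergent; shared by everyone -> ignored."""
    ingroup_runs = [_gap_runs(s) for s in coding.ingroup]
    out_runs = _gap_runs(coding.outgroup)
    all_runs = set().union(out_runs, *ingroup_runs)
    p_indel = d_indel = 0
    for run in sorted(all_runs):
        carriers = sum(run in r for r in ingroup_runs)
        if 0 < carriers < len(ingroup_runs):
            p_indel += 1
        elif carriers == len(ingroup_runs) and run not in out_runs:
            d_indel += 1
        elif carriers == 0 and run in out_runs:
            d_indel += 1
    return p_indel, d_indel


def classify_sites(coding: CodingAlignment) -> MKTable:
    """McDonald-Kreitman site counts for one locus.

    Codon by codon, ingroup sequences whose codon contains a gap or missing
    base sit that codon out.  A site segregating among the remaining
    ingroup codons is polymorphic; a site fixed in the ingroup and
    different from a clean outgroup codon is divergent.  Sites both
    segregating and different from the outgroup count as polymorphism only.
    Each variant is classified synonymous/nonsynonymous by substituting it
    into the ingroup consensus (major-allele) codon.  Indels are scored as
    whole gap runs in a separate channel.
    """
    pn = ps = dn = ds = 0
    for c0 in range(0, coding.length, 3):
        codons = [s[c0:c0 + 3] for s in coding.ingroup]
        clean = [cd for cd in codons if _is_clean(cd)]
        out_codon = coding.outgroup[c0:c0 + 3]
        if len(clean) < 2:
            continue
        # consensus codon: majority base at each position among clean codons
        consensus = ""
        for pos in range(3):
            col = [cd[pos] for cd in clean]
            consensus += max(_BASES, key=col.count)
        aa_ref = translate_codon(consensus)
        for pos in range(3):
            col = [cd[pos] for cd in clean]
            alleles = sorted(set(col))
            if len(alleles) > 1:
                # polymorphic site: one count per non-major allele
                major = consensus[pos]
                for allele in alleles:
                    if allele == major:
                        continue
                    mutant = consensus[:pos] + allele + consensus[pos + 1:]
                    if translate_codon(mutant) == aa_ref:
                        ps += 1
                    else:
                        pn += 1
            elif _is_clean(out_codon) and out_codon[pos] != alleles[0]:
                mutant = consensus[:pos] + out_codon[pos] + consensus[pos + 1:]
                if translate_codon(mutant) == aa_ref:
                    ds += 1
                else:
                    dn += 1
    p_indel, d_indel = _indel_counts(coding)
    return MKTable(Pn=pn, Ps=ps, Dn=dn, Ds=ds, P_indel=p_indel, D_indel=d_indel)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for a 2x2 table (minimum-likelihood tail
    convention: sum of all tables with point probability <= observed)."""
    for v in (a, b, c, d):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        return 1.0
    return float(sstats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass
class MKResult:
    table: MKTable
    ratio_poly: float  # Pn/Ps, NaN when Ps == 0
    ratio_div: float   # Dn/Ds, NaN when Ds == 0
    p: float
    p_indel: float | None = None


def mk_test(table: MKTable) -> MKResult:
    """MK test: polymorphism vs divergence A/S ratios with Fisher's exact p.

    The indel channel, when populated, is tested as (P_indel, Ps) vs
    (D_indel, Ds) — indel polymorphism against the synonymous baseline.
    """
    ratio_poly = table.Pn / table.Ps if table.Ps else np.nan
    ratio_div = table.Dn / table.Ds if table.Ds else np.nan
    p = fisher_exact_2x2(*table.snp_counts())
    p_indel = None
    if table.P_indel or table.D_indel:
        p_indel = fisher_exact_2x2(table.P_indel, table.Ps, table.D_indel, table.Ds)
    return MKResult(table=table, ratio_poly=ratio_poly, ratio_div=ratio_div,
                    p=p, p_indel=p_indel)


def tajimas_d(sequences: list[str]) -> float:
    """Tajima's (1989) D for a sample of aligned sequences.

    Columns containing any gap/missing symbol are dropped (complete
    deletion).  NaN when there are no segregating sites.
    """
    n = len(sequences)
    if n < 4:
        raise ValueError("Tajima's D needs >= 4 sequences")
    m = np.array([list(s.upper()) for s in sequences])
    keep = np.ones(m.shape[1], dtype=bool)
    for b in "N-":
        keep &= (m != b).all(axis=0)
    m = m[:, keep]
    segregating = np.array([len(set(col)) > 1 for col in m.T])
    S = int(segregating.sum())
    if S == 0:
        return np.nan
    # mean pairwise differences (per locus, not per site)
    pi = 0.0
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pi += float((m[i] != m[j]).sum())
            n_pairs += 1
    pi /= n_pairs

    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n ** 2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float((pi - S / a1) / np.sqrt(var))


def _syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 possible changes at ``pos`` that are synonymous
    (changes to stop codons count as nonsynonymous)."""
    aa = translate_codon(codon)
    syn = 0
    for b in _BASES:
        if b == codon[pos]:
            continue
        mutant = codon[:pos] + b + codon[pos + 1:]
        if translate_codon(mutant) == aa and aa != "*":
            syn += 1
    return syn / 3.0


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon (NG86)."""
    s = sum(_syn_fraction(codon, pos) for pos in range(3))
    return s, 3.0 - s


def _pathway_changes(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged over all
    minimal mutational pathways; pathways through stop codons are skipped
    unless every pathway hits one."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    results_with_stops = []
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nonsyn += 1
            if translate_codon(nxt) == "*":
                through_stop = True
            cur = nxt
        (results_with_stops if through_stop else results).append((syn, nonsyn))
    pool = results if results else results_with_stops
    syn = float(np.mean([r[0] for r in pool]))
    nonsyn = float(np.mean([r[1] for r in pool]))
    return syn, nonsyn


@dataclass
class KaKsResult:
    Ka: float
    Ks: float
    ratio: float  # NaN when Ks == 0 or undefined
    saturated: bool = False


def ka_ks(seq_a: str, seq_b: str, frame: int = 0) -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Codons containing gaps or ambiguous bases in either sequence are
    skipped.  Proportions p >= 3/4 cannot be corrected (saturation) and
    yield NaN with the ``saturated`` flag set.
    """
    seq_a, seq_b = seq_a.upper()[frame:], seq_b.upper()[frame:]
    if len(seq_a) != len(seq_b):
        raise FrameError("sequences must have equal length")
    usable = len(seq_a) - len(seq_a) % 3
    S = N = Sd = Nd = 0.0
    for c0 in range(0, usable, 3):
        ca, cb = seq_a[c0:c0 + 3], seq_b[c0:c0 + 3]
        if not (_is_clean(ca) and _is_clean(cb)):
            continue
        sa, na = _codon_sites(ca)
        sb, nb = _codon_sites(cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        syn, nonsyn = _pathway_changes(ca, cb)
        Sd += syn
        Nd += nonsyn
    if S == 0 or N == 0:
        raise FrameError("no scorable codons")
    ps, pn = Sd / S, Nd / N

    def jc(p: float) -> float:
        return -0.75 * np.log(1 - 4 * p / 3) if p < 0.75 else np.nan

    ka, ks = jc(pn), jc(ps)
    saturated = bool(np.isnan(ka) or np.isnan(ks))
    ratio = ka / ks if (not saturated and ks > 0) else np.nan
    return KaKsResult(Ka=ka, Ks=ks, ratio=ratio, saturated=saturated)


def two_locus_independence(counts, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square test of independence for a 2x2 strain table
    (functional status at locus 1 x locus 2).

    Returns ``(chi2, p)``; ``(NaN, NaN)`` when a marginal is zero.  Yates
    continuity correction is off by default.
    """
    obs = np.asarray(counts, dtype=np.int64)
    if obs.shape != (2, 2) or (obs < 0).any():
        raise ValueError("counts must be a non-negative 2x2 table")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        return np.nan, np.nan
    chi2, p, _, _ = sstats.chi2_contingency(obs, correction=correction)
    return float(chi2), float(p)
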