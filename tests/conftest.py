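import numpy as np
import pytest

from aquascan.alignment_io import MISSING, HaplotypeAlignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": MISSING, "-": MISSING}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq.upper()], dtype=np.uint8)


def make_alignment(seqs, names=None, chrom="chrT") -> HaplotypeAlignment:
    names = names or [f"s{i}" for i in range(len(seqs))]
    return HaplotypeAlignment(chromosome=chrom, strains=list(names),
                              matrix=np.vstack([encode(s) for s in seqs]))


def random_alignment(rng, n_strains, length, missing_rate=0.0, chrom="chrT"):
    m = rng.integers(0, 4, size=(n_strains, length)).astype(np.uint8)
    if missing_rate:
        m[rng.random(m.shape) < missing_rate] = MISSING
    return HaplotypeAlignment(chromosome=chrom,
                              strains=[f"s{i}" for i in range(n_strains)], matrix=m)


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
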