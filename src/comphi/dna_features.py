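"""Length-agnostic nucleotide feature encodings.

Seven composition-style encodings per genome, concatenated into a fixed
340-dimensional vector:

    Kmer(64) | RCKmer(32) | CKSNAP(96) | PseEIIP(64) | NAC(4) | DNC(16) | TNC(64)

Denominator conventions follow the source formulas literally: Kmer and
RCKmer divide by the full sequence length N (not the window count N-k+1);
NAC/DNC/TNC divide by N, N-1, N-2; CKSNAP divides by the number of pair
positions L-g-1 for gap g; PseEIIP frequencies divide by the trinucleotide
window count L-2. Windows containing an ambiguous base (N) are excluded
from numerators only. The conventional window-count denominator for
Kmer/RCKmer is available via ``length_denominator=False``.
"""

from __future__ import annotations

from itertools import product

import numpy as np

NUCLEOTIDES = "ACGT"

# Electron-ion interaction potential of the four nucleotides.
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "T": 0.1335}

_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate(NUCLEOTIDES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

KMERS3 = ["".join(p) for p in product(NUCLEOTIDES, repeat=3)]
DIMERS = ["".join(p) for p in product(NUCLEOTIDES, repeat=2)]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmers(k: int = 3) -> list[str]:
    """Sorted canonical k-mer classes (lexicographic min of mer/revcomp)."""
    return sorted({min(m, reverse_complement(m)) for m in
                   ("".join(p) for p in product(NUCLEOTIDES, repeat=k))})


RCKMERS3 = canonical_kmers(3)


def _codes(genome: str) -> np.ndarray:
    if not genome:
        return np.empty(0, dtype=np.int64)
    return _CODE[np.frombuffer(genome.upper().encode("ascii"), dtype=np.uint8)]


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Counts over 4**k k-mers; windows containing an ambiguous base skipped."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j : j + n]
        idx = idx * 4 + np.where(c == 4, 0, c)
        valid &= c != 4
    return np.bincount(idx[valid], minlength=4 ** k)


def encode_kmer(genome: str, k: int = 3, length_denominator: bool = True) -> np.ndarray:
    """k-mer frequencies f(s) = N(s)/N in lexicographic order (64 values for k=3)."""
    if len(genome) < k:
        raise ValueError(f"sequence shorter than k={k}")
    codes = _codes(genome)
    denom = len(codes) if length_denominator else len(codes) - k + 1
    return _kmer_counts(codes, k) / denom


def encode_rckmer(genome: str, k: int = 3, length_denominator: bool = True) -> np.ndarray:
    """Strand-symmetric k-mer frequencies over canonical classes (32 for k=3).

    Each window is collapsed with its reverse complement into one canonical
    class before counting, so the encoding is invariant to which strand of
    the genome was sequenced.
    """
    if len(genome) < k:
        raise ValueError(f"sequence shorter than k={k}")
    canon = canonical_kmers(k)
    pos = {m: i for i, m in enumerate(canon)}
    all_mers = ["".join(p) for p in product(NUCLEOTIDES, repeat=k)]
    collapse = np.array(
        [pos[min(m, reverse_complement(m))] for m in all_mers], dtype=np.int64
    )
    counts = _kmer_counts(_codes(genome), k)
    canon_counts = np.bincount(collapse, weights=counts, minlength=len(canon))
    denom = len(genome) if length_denominator else len(genome) - k + 1
    return canon_counts / denom


def encode_cksnap(genome: str, max_gap: int = 5) -> np.ndarray:
    """Composition of nucleotide pairs separated by g = 0..max_gap bases.

    For each gap g the 16 pair frequencies are N_xy / (L - g - 1); gaps with
    no positions emit zeros. 6 x 16 = 96 values at the default max_gap=5.
    """
    if len(genome) < 2:
        raise ValueError("sequence shorter than 2")
    codes = _codes(genome)
    L = len(codes)
    blocks = []
    for g in range(max_gap + 1):
        n_total = L - g - 1
        if n_total <= 0:
            blocks.append(np.zeros(16))
            continue
        a = codes[:n_total]
        b = codes[g + 1 : g + 1 + n_total]
        valid = (a != 4) & (b != 4)
        idx = a[valid] * 4 + b[valid]
        blocks.append(np.bincount(idx, minlength=16) / n_total)
    return np.concatenate(blocks)


_EIIP_TRI = np.array(
    [EIIP[m[0]] + EIIP[m[1]] + EIIP[m[2]] for m in KMERS3]
)


def encode_pseeiip(genome: str) -> np.ndarray:
    """EIIP-weighted trinucleotide composition: V_xyz = EIIP_xyz * f_xyz.

    EIIP_xyz is the sum of the three single-nucleotide electron-ion
    interaction potentials; f_xyz is the trinucleotide frequency over the
    L-2 windows.
    """
    if len(genome) < 3:
        raise ValueError("sequence shorter than 3")
    counts = _kmer_counts(_codes(genome), 3)
    return _EIIP_TRI * (counts / (len(genome) - 2))


def encode_nac(genome: str) -> np.ndarray:
    """Single-nucleotide composition N(t)/N."""
    if len(genome) < 1:
        raise ValueError("empty sequence")
    codes = _codes(genome)
    return np.bincount(codes[codes != 4], minlength=4) / len(codes)


def encode_dnc(genome: str) -> np.ndarray:
    """Dinucleotide composition N_rs/(N-1)."""
    if len(genome) < 2:
        raise ValueError("sequence shorter than 2")
    return _kmer_counts(_codes(genome), 2) / (len(genome) - 1)


def encode_tnc(genome: str) -> np.ndarray:
    """Trinucleotide composition N_rst/(N-2)."""
    if len(genome) < 3:
        raise ValueError("sequence shorter than 3")
    return _kmer_counts(_codes(genome), 3) / (len(genome) - 2)


DNA_FEATURE_NAMES: list[str] = (
    [f"kmer_{m}" for m in KMERS3]
    + [f"rckmer_{m}" for m in RCKMERS3]
    + [f"cksnap_g{g}_{p}" for g in range(6) for p in DIMERS]
    + [f"pseeiip_{m}" for m in KMERS3]
    + [f"nac_{b}" for b in NUCLEOTIDES]
    + [f"dnc_{p}" for p in DIMERS]
    + [f"tnc_{m}" for m in KMERS3]
)

DNA_DIM = len(DNA_FEATURE_NAMES)  # 340


def encode_dna_all(genome: str, length_denominator: bool = True) -> np.ndarray:
    """Concatenate the seven encodings into the fixed 340-long DNA vector."""
    v = np.concatenate(
        [
            encode_kmer(genome, 3, length_denominator),
            encode_rckmer(genome, 3, length_denominator),
            encode_cksnap(genome, 5),
            encode_pseeiip(genome),
            encode_nac(genome),
            encode_dnc(genome),
            encode_tnc(genome),
        ]
    )
    assert v.shape == (DNA_DIM,)
    return v
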