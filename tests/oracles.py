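"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written the slow, obvious way (explicit window
enumeration, full dynamic-programming tables, all-pairs statistics) and
deliberately shares no code with the package.
"""

from itertools import product

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
BASES = "ACGT"

# atomic masses for the MW-from-atoms cross-check
ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007, "S": 32.06}


def revcomp(seq):
    return "".join(COMP[c] for c in reversed(seq))


def windows(seq, k):
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def kmer_freqs(seq, k, denom=None):
    """k-mer frequencies by explicit window listing; ambiguous windows skipped."""
    denom = len(seq) if denom is None else denom
    out = {}
    for mer in ("".join(p) for p in product(BASES, repeat=k)):
        out[mer] = sum(1 for w in windows(seq, k) if w == mer) / denom
    return out


def rckmer_freqs(seq, k=3):
    canon = sorted({min(m, revcomp(m)) for m in ("".join(p) for p in product(BASES, repeat=k))})
    counts = dict.fromkeys(canon, 0)
    for w in windows(seq, k):
        if any(c not in BASES for c in w):
            continue
        counts[min(w, revcomp(w))] += 1
    return {m: c / len(seq) for m, c in counts.items()}


def cksnap_freqs(seq, max_gap=5):
    out = []
    for g in range(max_gap + 1):
        n_total = len(seq) - g - 1
        for pair in ("".join(p) for p in product(BASES, repeat=2)):
            if n_total <= 0:
                out.append(0.0)
                continue
            n = sum(
                1
                for i in range(n_total)
                if seq[i] == pair[0] and seq[i + g + 1] == pair[1]
            )
            out.append(n / n_total)
    return out


def pseeiip_values(seq, eiip):
    out = []
    n_windows = len(seq) - 2
    for mer in ("".join(p) for p in product(BASES, repeat=3)):
        f = sum(1 for w in windows(seq, 3) if w == mer) / n_windows
        out.append((eiip[mer[0]] + eiip[mer[1]] + eiip[mer[2]]) * f)
    return out


def composition(seq, k):
    """NAC/DNC/TNC with the N-k+1 ... denominators N, N-1, N-2."""
    denom = len(seq) - k + 1 if k > 1 else len(seq)
    return [
        sum(1 for w in windows(seq, k) if w == mer) / denom
        for mer in ("".join(p) for p in product(BASES, repeat=k))
    ]


def smith_waterman(a, b, match=1.0, mismatch=-2.0, gap_open=5.0, gap_extend=2.0):
    """Full-table affine-gap local alignment; a gap of length L costs
    open + L*extend. Quadratic memory, no shortcuts."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_open - gap_extend, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - gap_open - gap_extend, F[i - 1][j] - gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


def auc_all_pairs(scores, labels):
    """AUC as the all-pairs rank statistic with 0.5 credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
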