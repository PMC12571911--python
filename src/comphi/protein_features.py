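"""Per-protein descriptors, organism-level aggregation, and normalization.

Each protein yields a 27-long descriptor: molecular weight (1), atom counts
of C/H/O/N/S (5), and amino-acid composition over the 20 standard residues
plus the translation stop symbol '*' (21). Because an organism carries many
proteins, six aggregation operators (mean, median, standard deviation,
variance, maximum, minimum) are applied columnwise, giving the fixed
162-dimensional per-organism protein vector.

Molecular weight uses the free-amino-acid weights with one water
(18.01 Da) subtracted per peptide bond: MW = sum(w_t) - (m-1)*18.01.
Atom counts mirror this by default (condensed chain: 2 H and 1 O removed
per bond); set ``condensed=False`` for free-residue totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AAC_SYMBOLS = "ACDEFGHIKLMNPQRSTVWY*"

# Free (unbound) amino acids: average molecular weight (Da) and atomic
# composition (C, H, O, N, S). Standard biochemical reference values.
_AA_TABLE: dict[str, tuple[float, tuple[int, int, int, int, int]]] = {
    "A": (89.09, (3, 7, 2, 1, 0)),
    "R": (174.20, (6, 14, 2, 4, 0)),
    "N": (132.12, (4, 8, 3, 2, 0)),
    "D": (133.10, (4, 7, 4, 1, 0)),
    "C": (121.16, (3, 7, 2, 1, 1)),
    "E": (147.13, (5, 9, 4, 1, 0)),
    "Q": (146.15, (5, 10, 3, 2, 0)),
    "G": (75.07, (2, 5, 2, 1, 0)),
    "H": (155.15, (6, 9, 2, 3, 0)),
    "I": (131.17, (6, 13, 2, 1, 0)),
    "L": (131.17, (6, 13, 2, 1, 0)),
    "K": (146.19, (6, 14, 2, 2, 0)),
    "M": (149.21, (5, 11, 2, 1, 1)),
    "F": (165.19, (9, 11, 2, 1, 0)),
    "P": (115.13, (5, 9, 2, 1, 0)),
    "S": (105.09, (3, 7, 3, 1, 0)),
    "T": (119.12, (4, 9, 3, 1, 0)),
    "W": (204.23, (11, 12, 2, 2, 0)),
    "Y": (181.19, (9, 11, 3, 1, 0)),
    "V": (117.15, (5, 11, 2, 1, 0)),
}

WATER_MW = 18.01
ELEMENTS = "CHONS"

AGGREGATION_OPERATORS = ("mean", "median", "std", "var", "max", "min")

PER_PROTEIN_NAMES = (
    ["mw"] + [f"ac_{el}" for el in ELEMENTS]
    + [f"aac_{'stop' if a == '*' else a}" for a in AAC_SYMBOLS]
)

PROTEIN_FEATURE_NAMES = [
    f"{op}_{name}" for op in AGGREGATION_OPERATORS for name in PER_PROTEIN_NAMES
]

PROTEIN_DIM = len(PROTEIN_FEATURE_NAMES)  # 162


def _residues(protein: str) -> list[str]:
    """Standard residues of the chain; '*' and 'X' are mass/atom-neutral."""
    return [a for a in protein.upper() if a in _AA_TABLE]


def protein_mw(protein: str) -> float:
    """Molecular weight in Daltons: sum(w_t) - (m-1)*18.01 over m residues."""
    if not protein:
        raise ValueError("empty protein sequence")
    res = _residues(protein)
    if not res:
        return 0.0
    return sum(_AA_TABLE[a][0] for a in res) - (len(res) - 1) * WATER_MW


def protein_ac(protein: str, condensed: bool = True) -> np.ndarray:
    """Atom counts (C, H, O, N, S) of the protein.

    With ``condensed=True`` (default) one water's worth of atoms (2 H, 1 O)
    is removed per peptide bond, mirroring the molecular-weight formula.
    """
    if not protein:
        raise ValueError("empty protein sequence")
    res = _residues(protein)
    counts = np.zeros(5, dtype=float)
    for a in res:
        counts += _AA_TABLE[a][1]
    if condensed and len(res) > 1:
        counts[1] -= 2 * (len(res) - 1)  # H
        counts[2] -= len(res) - 1  # O
    return counts


def protein_aac(protein: str) -> np.ndarray:
    """Composition over the 21 symbols (20 amino acids + '*'); X counts
    toward the length N but toward no numerator."""
    if not protein:
        raise ValueError("empty protein sequence")
    seq = protein.upper()
    n = len(seq)
    return np.array([seq.count(a) / n for a in AAC_SYMBOLS])


def per_protein_vector(protein: str, condensed: bool = True) -> np.ndarray:
    """The 27-long descriptor: MW(1) | AC(5) | AAC(21)."""
    return np.concatenate(
        [[protein_mw(protein)], protein_ac(protein, condensed), protein_aac(protein)]
    )


def aggregate_proteins(per_protein: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Aggregate per-protein descriptors into the 162-long organism vector.

    Applies mean, median, std, var, max, min columnwise. Variance and
    standard deviation are population-form (ddof=0) so a single protein
    yields zeros rather than NaN.
    """
    m = np.asarray(per_protein, dtype=float)
    if m.ndim != 2 or m.shape[0] == 0:
        raise ValueError("per_protein must be a non-empty list of descriptor vectors")
    out = np.concatenate(
        [
            m.mean(axis=0),
            np.median(m, axis=0),
            m.std(axis=0, ddof=0),
            m.var(axis=0, ddof=0),
            m.max(axis=0),
            m.min(axis=0),
        ]
    )
    assert out.shape == (PROTEIN_DIM,)
    return out


def encode_proteins_all(proteins: list[str], condensed: bool = True) -> np.ndarray:
    """Organism-level protein vector from its raw protein sequences."""
    if not proteins:
        raise ValueError(
            "organism has no proteins; mask protein features off instead"
        )
    return aggregate_proteins([per_protein_vector(p, condensed) for p in proteins])


# ---------------------------------------------------------------------------
# Min-max normalization (fit on training rows only)


@dataclass
class NormalizationModel:
    """Per-feature min/max learned on training data; application clips to [0,1]."""

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.mins)


def fit_minmax(train: np.ndarray) -> NormalizationModel:
    x = np.asarray(train, dtype=float)
    if x.ndim != 2 or x.shape[0] == 0:
        raise ValueError("training matrix must be 2-D and non-empty")
    return NormalizationModel(mins=x.min(axis=0), maxs=x.max(axis=0))


def apply_minmax(model: NormalizationModel, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != model.n_features:
        raise ValueError(
            f"feature count mismatch: model has {model.n_features}, data has {x.shape[1]}"
        )
    span = model.maxs - model.mins
    span = np.where(span == 0, 1.0, span)  # constant columns map to 0
    return np.clip((x - model.mins) / span, 0.0, 1.0)


def reshape_to_image(v: np.ndarray) -> np.ndarray:
    """Reshape a length-N vector into the smallest n x n grid with
    (n-1)^2 < N <= n^2, row-major, zero-padded at the tail."""
    v = np.asarray(v, dtype=float).ravel()
    if v.size < 1:
        raise ValueError("empty vector")
    n = int(np.ceil(np.sqrt(v.size)))
    out = np.zeros(n * n)
    out[: v.size] = v
    return out.reshape(n, n)
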