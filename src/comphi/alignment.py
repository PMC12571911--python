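"""Alignment bit-score structures for the composite model.

Three best-hit structures are built from nucleotide local alignments:

* ``bit_pp``  — per phage, the best bit score against every *other* phage,
  with the identity of that nearest phage (used to look up the host of the
  most similar phage);
* ``bit_ph``  — the phage x host best-hit bit-score matrix;
* ``bit_hh``  — the pairwise host x host best-hit matrix, symmetrized.

Two interchangeable backends satisfy the aligner contract:

* :class:`BlastBackend` shells out to NCBI BLAST+ (``makeblastdb`` /
  ``blastn``) and parses tabular output — the fast choice at genome scale;
* :class:`InternalAligner` is a deterministic affine-gap Smith-Waterman
  (numba-jitted) whose raw score S is converted to a bit score via the
  Karlin-Altschul form bits = (lambda*S - ln K) / ln 2, with the e-value
  K*m*n*exp(-lambda*S) tested against the cutoff.

Hits whose e-value exceeds the cutoff (default 1e-4) score 0.
"""

from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Protocol, Sequence

import numpy as np
from numba import njit

from .dataset_io import OrganismEntry

logger = logging.getLogger(__name__)

DEFAULT_EVALUE = 1e-4

_NEG = -1e18


@njit(cache=True)
def _sw_affine(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Best local-alignment raw score; a gap of length L costs open + L*extend."""
    n = a.shape[0]
    m = b.shape[0]
    h_prev = np.zeros(m + 1)
    h_cur = np.zeros(m + 1)
    f = np.full(m + 1, _NEG)
    best = 0.0
    for i in range(1, n + 1):
        e = _NEG
        h_cur[0] = 0.0
        ai = a[i - 1]
        for j in range(1, m + 1):
            e = max(h_cur[j - 1] - gap_open - gap_extend, e - gap_extend)
            f[j] = max(h_prev[j] - gap_open - gap_extend, f[j] - gap_extend)
            s = match if ai == b[j - 1] else mismatch
            h = h_prev[j - 1] + s
            if e > h:
                h = e
            if f[j] > h:
                h = f[j]
            if h < 0.0:
                h = 0.0
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
    return best


_ENC = np.full(256, 0, dtype=np.int8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


class AlignerBackend(Protocol):
    def max_bit_score(self, query: str, subject: str) -> float: ...

    def score_matrix(
        self, queries: Sequence[str], subjects: Sequence[str]
    ) -> np.ndarray: ...


@dataclass
class InternalAligner:
    """Built-in deterministic Smith-Waterman backend.

    Scoring defaults: match +1, mismatch -2, gap open 5, gap extend 2;
    Karlin-Altschul parameters lambda=0.625, K=0.41 for the bit/e-value
    conversion. All configurable.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = 5.0
    gap_extend: float = 2.0
    lam: float = 0.625
    K: float = 0.41
    evalue_cutoff: float = DEFAULT_EVALUE

    def raw_score(self, query: str, subject: str) -> float:
        if not query or not subject:
            raise ValueError("sequences must be non-empty")
        return float(
            _sw_affine(
                _encode(query),
                _encode(subject),
                self.match,
                self.mismatch,
                self.gap_open,
                self.gap_extend,
            )
        )

    def bit_score(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2.0)

    def evalue(self, raw: float, m: int, n: int) -> float:
        return self.K * m * n * math.exp(-self.lam * raw)

    def max_bit_score(self, query: str, subject: str) -> float:
        raw = self.raw_score(query, subject)
        if raw <= 0 or self.evalue(raw, len(query), len(subject)) > self.evalue_cutoff:
            return 0.0
        return self.bit_score(raw)

    def score_matrix(
        self, queries: Sequence[str], subjects: Sequence[str]
    ) -> np.ndarray:
        out = np.zeros((len(queries), len(subjects)))
        for i, q in enumerate(queries):
            for j, s in enumerate(subjects):
                out[i, j] = self.max_bit_score(q, s)
        return out


@dataclass
class BlastBackend:
    """External BLAST+ backend (``makeblastdb`` + ``blastn``)."""

    evalue_cutoff: float = DEFAULT_EVALUE
    task: str = "megablast"
    extra_args: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if shutil.which("blastn") is None or shutil.which("makeblastdb") is None:
            raise RuntimeError("BLAST+ executables (blastn/makeblastdb) not on PATH")

    @staticmethod
    def _write_fasta(path: Path, seqs: Sequence[str], prefix: str) -> None:
        with open(path, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">{prefix}{i}\n{s}\n")

    def max_bit_score(self, query: str, subject: str) -> float:
        return float(self.score_matrix([query], [subject])[0, 0])

    def score_matrix(
        self, queries: Sequence[str], subjects: Sequence[str]
    ) -> np.ndarray:
        if not queries or not subjects:
            raise ValueError("queries and subjects must be non-empty")
        out = np.zeros((len(queries), len(subjects)))
        with tempfile.TemporaryDirectory(prefix="comphi_blast_") as tmp:
            tmp = Path(tmp)
            qpath, spath = tmp / "q.fna", tmp / "s.fna"
            self._write_fasta(qpath, queries, "q")
            self._write_fasta(spath, subjects, "s")
            subprocess.run(
                ["makeblastdb", "-in", str(spath), "-dbtype", "nucl",
                 "-out", str(tmp / "db")],
                check=True, capture_output=True,
            )
            res = subprocess.run(
                [
                    "blastn", "-task", self.task,
                    "-query", str(qpath), "-db", str(tmp / "db"),
                    "-evalue", str(self.evalue_cutoff),
                    "-outfmt", "6 qseqid sseqid bitscore",
                    "-max_target_seqs", str(max(500, len(subjects))),
                    "-num_threads", "1",
                    "-dust", "no", "-soft_masking", "false",
                    *self.extra_args,
                ],
                check=True, capture_output=True, text=True,
            )
            for line in res.stdout.splitlines():
                q, s, bits = line.split("\t")
                i, j = int(q[1:]), int(s[1:])
                out[i, j] = max(out[i, j], float(bits))
        return out


def get_backend(name: str = "auto", **kwargs) -> AlignerBackend:
    """Resolve a backend by config key: ``internal``, ``blast`` or ``auto``
    (BLAST+ when on PATH, else the internal aligner)."""
    if name == "internal":
        return InternalAligner(**kwargs)
    if name == "blast":
        return BlastBackend(**kwargs)
    if name == "auto":
        try:
            return BlastBackend(**kwargs)
        except RuntimeError:
            return InternalAligner()
    raise ValueError(f"unknown alignment backend {name!r}")


def max_bit_score(query: str, subject: str, backend: AlignerBackend) -> float:
    """Best local-alignment bit score of query vs subject; 0 when no hit
    passes the e-value cutoff."""
    return backend.max_bit_score(query, subject)


# ---------------------------------------------------------------------------
# Bit-score store


def _best_nonself(
    ids: Sequence[str],
    scores: np.ndarray,
    self_id: str,
    candidates: Sequence[str],
) -> tuple[float, str]:
    """Best (score, id) over candidates excluding self; ties and the no-hit
    case resolve to the lexicographically smallest candidate id."""
    idx = {pid: k for k, pid in enumerate(ids)}
    best_score, best_id = -1.0, None
    for cid in sorted(candidates):
        if cid == self_id:
            continue
        sc = float(scores[idx[cid]])
        if sc > best_score:
            best_score, best_id = sc, cid
    if best_id is None:
        raise ValueError("no candidate phages besides the query itself")
    return best_score, best_id


@dataclass
class BitScoreStore:
    """The three best-hit bit-score structures plus normalization state."""

    bit_pp: dict[str, float]
    nearest_phage: dict[str, str]
    bit_ph: dict[tuple[str, str], float]
    bit_hh: dict[tuple[str, str], float]
    normalized: bool = False
    phage_ids: list[str] = field(default_factory=list)
    host_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_matrices(
        cls,
        phage_ids: Sequence[str],
        host_ids: Sequence[str],
        pp: np.ndarray,
        ph: np.ndarray,
        hh: np.ndarray,
        reference_phages: Sequence[str] | None = None,
    ) -> "BitScoreStore":
        """Assemble a store from raw score matrices.

        ``pp`` is phage x phage, ``ph`` phage x host, ``hh`` host x host.
        ``reference_phages`` restricts the nearest-phage search (e.g. to
        training phages so a test phage's neighbour always has a known
        host); defaults to all phages. ``hh`` is symmetrized by the
        elementwise max of the two search directions; its diagonal holds the
        self score but is never consulted by the composite equation.
        """
        phage_ids = list(phage_ids)
        host_ids = list(host_ids)
        reference = list(reference_phages) if reference_phages is not None else phage_ids
        hh_sym = np.maximum(hh, hh.T)

        bit_pp, nearest = {}, {}
        for i, pid in enumerate(phage_ids):
            score, nid = _best_nonself(phage_ids, pp[i], pid, reference)
            bit_pp[pid] = score
            nearest[pid] = nid
        bit_ph = {
            (p, h): float(ph[i, j])
            for i, p in enumerate(phage_ids)
            for j, h in enumerate(host_ids)
        }
        bit_hh = {
            (a, b): float(hh_sym[i, j])
            for i, a in enumerate(host_ids)
            for j, b in enumerate(host_ids)
        }
        return cls(
            bit_pp=bit_pp, nearest_phage=nearest, bit_ph=bit_ph, bit_hh=bit_hh,
            phage_ids=phage_ids, host_ids=host_ids,
        )

    def normalize(self, train_phages: Sequence[str] | None = None) -> "BitScoreStore":
        """Min-max scale ``bit_ph`` and ``bit_hh`` to [0,1].

        Statistics come from training rows of ``bit_ph`` (all rows by
        default) and from all ``bit_hh`` entries; out-of-range values are
        clipped. ``bit_pp`` stays raw — it feeds only an argmax, which any
        monotone rescaling leaves unchanged.
        """
        if self.normalized:
            raise ValueError("store is already normalized")
        train = set(train_phages) if train_phages is not None else set(self.phage_ids)
        ph_vals = [v for (p, _), v in self.bit_ph.items() if p in train]
        if not ph_vals:
            raise ValueError("no training phages available for normalization")
        hh_vals = [v for (a, b), v in self.bit_hh.items() if a != b]

        def scale(v: float, lo: float, hi: float) -> float:
            if hi <= lo:
                return 0.0
            return min(1.0, max(0.0, (v - lo) / (hi - lo)))

        ph_lo, ph_hi = min(ph_vals), max(ph_vals)
        hh_lo, hh_hi = (min(hh_vals), max(hh_vals)) if hh_vals else (0.0, 0.0)
        return replace(
            self,
            bit_ph={k: scale(v, ph_lo, ph_hi) for k, v in self.bit_ph.items()},
            bit_hh={k: scale(v, hh_lo, hh_hi) for k, v in self.bit_hh.items()},
            normalized=True,
        )


def pairwise_bit_matrix(
    queries: Sequence[OrganismEntry],
    subjects: Sequence[OrganismEntry],
    backend: AlignerBackend,
) -> np.ndarray:
    return backend.score_matrix(
        [e.genome for e in queries], [e.genome for e in subjects]
    )


def build_bit_pp(
    phages: Sequence[OrganismEntry], backend: AlignerBackend
) -> tuple[dict[str, float], dict[str, str]]:
    """Best non-self phage-phage bit score and nearest-phage map."""
    if len(phages) < 2:
        raise ValueError("need at least 2 phages")
    pp = pairwise_bit_matrix(phages, phages, backend)
    ids = [e.id for e in phages]
    store = BitScoreStore.from_matrices(ids, ["_h"], pp, np.zeros((len(ids), 1)),
                                        np.zeros((1, 1)))
    return store.bit_pp, store.nearest_phage


def build_bit_ph(
    phages: Sequence[OrganismEntry],
    hosts: Sequence[OrganismEntry],
    backend: AlignerBackend,
) -> dict[tuple[str, str], float]:
    """Phage x host best-hit bit scores (0 where no hit passes the cutoff)."""
    if not phages or not hosts:
        raise ValueError("phages and hosts must be non-empty")
    ph = pairwise_bit_matrix(phages, hosts, backend)
    return {
        (p.id, h.id): float(ph[i, j])
        for i, p in enumerate(phages)
        for j, h in enumerate(hosts)
    }


def build_bit_hh(
    hosts: Sequence[OrganismEntry], backend: AlignerBackend
) -> dict[tuple[str, str], float]:
    """Symmetrized pairwise host x host best-hit bit scores."""
    if len(hosts) < 2:
        raise ValueError("need at least 2 hosts")
    hh = pairwise_bit_matrix(hosts, hosts, backend)
    hh = np.maximum(hh, hh.T)
    return {
        (a.id, b.id): float(hh[i, j])
        for i, a in enumerate(hosts)
        for j, b in enumerate(hosts)
    }


def build_store(
    phages: Sequence[OrganismEntry],
    hosts: Sequence[OrganismEntry],
    backend: AlignerBackend,
    reference_phages: Sequence[str] | None = None,
) -> BitScoreStore:
    """Compute all three structures in one pass (raw, not yet normalized)."""
    pp = pairwise_bit_matrix(phages, phages, backend)
    ph = pairwise_bit_matrix(phages, hosts, backend)
    hh = pairwise_bit_matrix(hosts, hosts, backend)
    return BitScoreStore.from_matrices(
        [e.id for e in phages], [e.id for e in hosts], pp, ph, hh, reference_phages
    )


def normalize_store(
    store: BitScoreStore, train_phages: Sequence[str] | None = None
) -> BitScoreStore:
    return store.normalize(train_phages)
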