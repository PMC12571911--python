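"""Reading, writing and assembling phage-host interaction datasets.

Handles the external formats (nucleotide/protein FASTA, TSV interaction and
taxonomy tables), balanced negative sampling, and exact-duplicate removal.
Redundancy reduction by identity-threshold clustering (e.g. CD-HIT at 95%)
is delegated to an external-tool hook upstream of this package; here only
byte-identical genomes are collapsed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RANKS = ("species", "genus", "family", "order", "class", "phylum")

_DNA_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY*X")

Role = Literal["phage", "host"]


@dataclass
class OrganismEntry:
    """One phage or host: a genome plus the organism's protein set."""

    id: str
    role: Role
    genome: str = ""
    proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("organism id must be non-empty")
        if self.role not in ("phage", "host"):
            raise ValueError(f"unknown role {self.role!r}")


@dataclass
class InteractionSet:
    """Labeled (phage_id, host_id) pairs with per-pair provenance.

    Positives come from the interaction table; negatives are sampled from
    the complement of the positive set.
    """

    pairs: list[tuple[str, str, int]] = field(default_factory=list)
    provenance: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for p, h, label in self.pairs:
            if label not in (0, 1):
                raise ValueError(f"label must be 0/1, got {label!r}")
            if (p, h) in seen:
                raise ValueError(f"duplicate pair ({p}, {h})")
            seen.add((p, h))

    @property
    def positives(self) -> list[tuple[str, str]]:
        return [(p, h) for p, h, y in self.pairs if y == 1]

    @property
    def negatives(self) -> list[tuple[str, str]]:
        return [(p, h) for p, h, y in self.pairs if y == 0]

    def phage_ids(self) -> list[str]:
        return sorted({p for p, _, _ in self.pairs})

    def host_ids(self) -> list[str]:
        return sorted({h for _, h, _ in self.pairs})

    def host_of(self) -> dict[str, str]:
        """True host per phage, from the positive pairs."""
        return {p: h for p, h in self.positives}


class TaxonomyTable:
    """host_id -> complete six-rank lineage (species ... phylum)."""

    def __init__(self, records: dict[str, dict[str, str]]):
        for host_id, rec in records.items():
            missing = [r for r in RANKS if not rec.get(r)]
            if missing:
                raise ValueError(
                    f"host {host_id!r} has incomplete taxonomy (missing {missing})"
                )
        self._records = {h: {r: rec[r] for r in RANKS} for h, rec in records.items()}

    def __contains__(self, host_id: str) -> bool:
        return host_id in self._records

    def __len__(self) -> int:
        return len(self._records)

    def lineage(self, host_id: str) -> dict[str, str]:
        try:
            return self._records[host_id]
        except KeyError:
            raise KeyError(f"no taxonomy record for host {host_id!r}") from None

    def taxon(self, host_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.lineage(host_id)[rank]

    def host_ids(self) -> list[str]:
        return sorted(self._records)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(self._records, orient="index")
        df.index.name = "host_id"
        return df.reset_index()[["host_id", *RANKS]]


# ---------------------------------------------------------------------------
# Sequence normalization


def _normalize_nucleotide(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = sum(1 for c in s if c not in _DNA_ALPHABET)
    if bad:
        logger.info("record %s: %d non-ACGTN characters mapped to N", record_id, bad)
        s = "".join(c if c in _DNA_ALPHABET else "N" for c in s)
    return s


def _normalize_protein(seq: str, record_id: str) -> str:
    s = seq.upper()
    bad = sum(1 for c in s if c not in _PROTEIN_ALPHABET)
    if bad:
        logger.info("record %s: %d non-standard residues mapped to X", record_id, bad)
        s = "".join(c if c in _PROTEIN_ALPHABET else "X" for c in s)
    return s


def default_organism_of(record_id: str, description: str) -> str:
    """Map a protein record to its organism.

    Looks for an ``organism=<id>`` key in the description; otherwise the
    record id itself (token before the first whitespace) is the organism id.
    """
    for token in description.split():
        if token.startswith("organism="):
            return token[len("organism="):]
    return record_id


def read_fasta(
    path: str | Path,
    role: Role,
    kind: Literal["nucleotide", "protein"] = "nucleotide",
    organism_of: Callable[[str, str], str] | None = None,
) -> list[OrganismEntry]:
    """Read a FASTA file into per-organism entries.

    In nucleotide mode each record is one organism genome (id = token before
    the first whitespace). In protein mode many records map to one organism
    via `organism_of` (default: an ``organism=`` key in the header, falling
    back to the record id). Sequences are uppercased; U->T in nucleotide
    mode; characters outside the alphabet become N (DNA) or X (protein).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"empty or unreadable FASTA file: {path}")
    organism_of = organism_of or default_organism_of

    entries: dict[str, OrganismEntry] = {}
    if kind == "nucleotide":
        for rec in records:
            if not rec.id:
                raise ValueError(f"unparseable FASTA header in {path}")
            genome = _normalize_nucleotide(str(rec.seq), rec.id)
            if rec.id in entries:
                if entries[rec.id].genome != genome:
                    raise ValueError(f"duplicate genome records for id {rec.id!r}")
                continue
            entries[rec.id] = OrganismEntry(id=rec.id, role=role, genome=genome)
    elif kind == "protein":
        for rec in records:
            org = organism_of(rec.id, rec.description)
            if not org:
                raise ValueError(f"cannot map protein record {rec.id!r} to an organism")
            protein = _normalize_protein(str(rec.seq), rec.id)
            entries.setdefault(org, OrganismEntry(id=org, role=role)).proteins.append(
                protein
            )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return list(entries.values())


def merge_entries(
    genome_entries: Sequence[OrganismEntry], protein_entries: Sequence[OrganismEntry]
) -> list[OrganismEntry]:
    """Attach protein sets to genome entries by organism id."""
    proteins = {e.id: e.proteins for e in protein_entries}
    merged = []
    for e in genome_entries:
        merged.append(
            OrganismEntry(
                id=e.id, role=e.role, genome=e.genome, proteins=list(proteins.get(e.id, []))
            )
        )
    return merged


def write_fasta(
    entries: Sequence[OrganismEntry],
    path: str | Path,
    kind: Literal["nucleotide", "protein"] = "nucleotide",
) -> None:
    """Write genomes (one record per organism) or proteins (one record per
    protein, organism recorded as an ``organism=`` header key)."""
    records = []
    for e in entries:
        if kind == "nucleotide":
            records.append(SeqRecord(Seq(e.genome), id=e.id, description=""))
        else:
            for i, prot in enumerate(e.proteins):
                records.append(
                    SeqRecord(
                        Seq(prot),
                        id=f"{e.id}_p{i + 1}",
                        description=f"organism={e.id}",
                    )
                )
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Tables


def read_interactions(path: str | Path) -> list[tuple[str, str]]:
    """Read the positive interaction table (TSV: phage_id, host_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("phage_id", "host_id"):
        if col not in df.columns:
            raise ValueError(f"interaction table missing column {col!r}")
    pairs = list(zip(df["phage_id"], df["host_id"]))
    if len(set(pairs)) != len(pairs):
        raise ValueError("duplicate phage-host pairs in interaction table")
    return pairs


def write_interactions(pairs: Iterable[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(pairs, columns=["phage_id", "host_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_taxonomy(path: str | Path) -> TaxonomyTable:
    """Read the host taxonomy table (TSV: host_id, species ... phylum)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("host_id", *RANKS):
        if col not in df.columns:
            raise ValueError(f"taxonomy table missing column {col!r}")
    return TaxonomyTable(
        {row["host_id"]: {r: row[r] for r in RANKS} for _, row in df.iterrows()}
    )


def write_taxonomy(taxonomy: TaxonomyTable, path: str | Path) -> None:
    taxonomy.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Dataset assembly


def sample_negatives(
    positives: InteractionSet,
    n_per_positive: int = 1,
    seed: int = 0,
    phage_ids: Sequence[str] | None = None,
    host_ids: Sequence[str] | None = None,
) -> InteractionSet:
    """Add sampled negative pairs to a set of positive interactions.

    Negatives are drawn uniformly without replacement from the complement of
    the positive set over the phage x host grid. With one negative per
    positive this yields the balanced design used for training.
    """
    import numpy as np

    pos = positives.positives
    if positives.negatives:
        raise ValueError("input InteractionSet already contains negatives")
    phage_ids = sorted(phage_ids) if phage_ids is not None else positives.phage_ids()
    host_ids = sorted(host_ids) if host_ids is not None else positives.host_ids()
    pos_set = set(pos)
    complement = [
        (p, h) for p in phage_ids for h in host_ids if (p, h) not in pos_set
    ]
    n_needed = n_per_positive * len(pos)
    if len(complement) < n_needed:
        raise ValueError(
            f"complement too small: {len(complement)} candidate negatives "
            f"for {n_needed} requested"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(complement), size=n_needed, replace=False)
    negatives = [complement[i] for i in sorted(idx)]

    pairs = [(p, h, 1) for p, h in pos] + [(p, h, 0) for p, h in negatives]
    provenance = {(p, h): "given_positive" for p, h in pos}
    provenance.update({(p, h): "sampled_negative" for p, h in negatives})
    return InteractionSet(pairs=pairs, provenance=provenance)


def deduplicate_exact(entries: Sequence[OrganismEntry]) -> list[OrganismEntry]:
    """Collapse byte-identical genomes, keeping the first id in sorted order."""
    by_genome: dict[str, list[OrganismEntry]] = {}
    for e in entries:
        by_genome.setdefault(e.genome, []).append(e)
    kept, removed = [], []
    for group in by_genome.values():
        group = sorted(group, key=lambda e: e.id)
        kept.append(group[0])
        removed.extend(e.id for e in group[1:])
    if removed:
        logger.info("deduplicate_exact removed %d entries: %s", len(removed), removed)
    kept.sort(key=lambda e: e.id)
    return kept


@dataclass
class DatasetBundle:
    """A complete runnable dataset: organisms, labeled pairs, taxonomy."""

    phages: dict[str, OrganismEntry]
    hosts: dict[str, OrganismEntry]
    interactions: InteractionSet
    taxonomy: TaxonomyTable

    def __post_init__(self) -> None:
        for p, h, _ in self.interactions.pairs:
            if p not in self.phages:
                raise ValueError(f"interaction references unknown phage {p!r}")
            if h not in self.hosts:
                raise ValueError(f"interaction references unknown host {h!r}")
        for h in self.hosts:
            if h not in self.taxonomy:
                raise ValueError(f"host {h!r} lacks a taxonomy record")


def load_dataset(directory: str | Path, seed: int = 0, n_per_positive: int = 1) -> DatasetBundle:
    """Load a dataset directory (as written by the synthetic generator or
    assembled externally) and sample balanced negatives."""
    d = Path(directory)
    phages = read_fasta(d / "phages.fna", "phage")
    hosts = read_fasta(d / "hosts.fna", "host")
    if (d / "phage_proteins.faa").exists():
        phages = merge_entries(phages, read_fasta(d / "phage_proteins.faa", "phage", "protein"))
    if (d / "host_proteins.faa").exists():
        hosts = merge_entries(hosts, read_fasta(d / "host_proteins.faa", "host", "protein"))
    positives = InteractionSet(
        pairs=[(p, h, 1) for p, h in read_interactions(d / "interactions.tsv")]
    )
    interactions = sample_negatives(
        positives,
        n_per_positive=n_per_positive,
        seed=seed,
        phage_ids=[e.id for e in phages],
        host_ids=[e.id for e in hosts],
    )
    taxonomy = read_taxonomy(d / "taxonomy.tsv")
    return DatasetBundle(
        phages={e.id: e for e in phages},
        hosts={e.id: e for e in hosts},
        interactions=interactions,
        taxonomy=taxonomy,
    )
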