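"""Synthetic phage-host datasets with controllable planted signal.

The generator emulates the structure the predictor exploits in real data:

* hosts hang off a six-rank taxonomy tree (phylum ... species); each
  descent applies rank-specific point substitutions to the parent genome,
  so sequence identity increases toward the leaves — hosts in one genus are
  more alike than hosts in different phyla;
* each phage carries a tunable fraction ``homology_strength`` of its genome
  as mutated segments copied from its true host (the phage-host alignment
  signal) plus a backbone shared within its phage family (the phage-phage
  signal); the remainder is random sequence;
* proteins are drawn from a genus-specific residue-frequency profile, and a
  phage's proteins follow its true host's genus profile — an alignment-free
  signal the classifier can learn.

Substitution-only mutation (no indels) keeps the alignment oracle simple
and fast. With a fixed seed the output is byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dataset_io import (
    RANKS,
    DatasetBundle,
    InteractionSet,
    OrganismEntry,
    TaxonomyTable,
    sample_negatives,
    write_fasta,
    write_interactions,
    write_taxonomy,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: substitution rate applied when descending to each rank's nodes
DEFAULT_RANK_DIVERGENCE = {
    "class": 0.10,
    "order": 0.08,
    "family": 0.06,
    "genus": 0.04,
    "species": 0.02,
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    The default fanout (4 phyla x 1 class x 2 orders x 2 families x
    2 genera x 2 species) yields 64 hosts; with 200 phages, 5 kb host and
    1 kb phage genomes this is the desk-scale default on which the full
    pipeline runs in minutes on one CPU.
    """

    n_phyla: int = 4
    classes_per_phylum: int = 1
    orders_per_class: int = 2
    families_per_order: int = 2
    genera_per_family: int = 2
    hosts_per_genus: int = 2
    host_genome_length: int = 5000
    phage_genome_length: int = 1000
    rank_divergence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RANK_DIVERGENCE)
    )
    homology_strength: float = 0.5
    n_phages: int = 200
    phage_family_size: int = 4
    backbone_fraction: float = 0.3
    segment_mutation_rate: float = 0.02
    host_segment_length: int = 250
    proteins_per_organism: int = 5
    protein_length: tuple[int, int] = (80, 200)
    n_per_positive: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        rates = [self.homology_strength, self.segment_mutation_rate,
                 self.backbone_fraction, *self.rank_divergence.values()]
        if any(not 0.0 <= r <= 1.0 for r in rates):
            raise ValueError("all rates must lie in [0,1]")
        if self.host_genome_length < 50 or self.phage_genome_length < 50:
            raise ValueError("genome lengths must be >= 50")
        if min(self.n_phyla, self.classes_per_phylum, self.orders_per_class,
               self.families_per_order, self.genera_per_family,
               self.hosts_per_genus) < 1:
            raise ValueError("taxonomy fanout counts must be >= 1")
        if self.homology_strength * self.phage_genome_length > self.host_genome_length:
            raise ValueError(
                "host-derived phage content exceeds the host genome length"
            )

    @property
    def n_hosts(self) -> int:
        return (self.n_phyla * self.classes_per_phylum * self.orders_per_class
                * self.families_per_order * self.genera_per_family
                * self.hosts_per_genus)


def _random_genome(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(genome: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Point substitutions at the given per-base rate (always to a different base)."""
    out = genome.copy()
    hit = np.flatnonzero(rng.random(len(genome)) < rate)
    if len(hit):
        cur = np.searchsorted(_BASES, out[hit])
        out[hit] = _BASES[(cur + rng.integers(1, 4, size=len(hit))) % 4]
    return out


def _genus_profile(genus: str, seed: int) -> np.ndarray:
    """Deterministic residue-frequency profile per genus taxon."""
    prof_seed = (zlib.crc32(genus.encode()) ^ seed) % (2**31)
    return np.random.default_rng(prof_seed).dirichlet(np.full(20, 2.0))


def _sample_proteins(
    profile: np.ndarray, cfg: GeneratorConfig, rng: np.random.Generator
) -> list[str]:
    lo, hi = cfg.protein_length
    proteins = []
    for _ in range(cfg.proteins_per_organism):
        length = int(rng.integers(lo, hi + 1))
        idx = rng.choice(20, size=length, p=profile)
        proteins.append("".join(_AA20[i] for i in idx))
    return proteins


def generate_hosts(cfg: GeneratorConfig) -> tuple[list[OrganismEntry], TaxonomyTable]:
    """Hosts on a taxonomy tree with rank-dependent sequence divergence.

    Each phylum gets an independent random root genome; every descent to
    class/order/family/genus/species applies the corresponding
    ``rank_divergence`` substitution rate. Species are unique per host.
    """
    rng = np.random.default_rng(cfg.seed)
    fanout = [cfg.classes_per_phylum, cfg.orders_per_class, cfg.families_per_order,
              cfg.genera_per_family, cfg.hosts_per_genus]
    descent_ranks = ["class", "order", "family", "genus", "species"]

    hosts: list[OrganismEntry] = []
    records: dict[str, dict[str, str]] = {}

    def expand(genome: np.ndarray, lineage: dict[str, str], level: int,
               path: tuple[int, ...]) -> None:
        if level == len(descent_ranks):
            host_id = f"host{len(hosts) + 1:04d}"
            lineage = dict(lineage)
            lineage["species"] = f"sp_{host_id}"
            profile = _genus_profile(lineage["genus"], cfg.seed)
            hosts.append(
                OrganismEntry(
                    id=host_id, role="host", genome=genome.tobytes().decode(),
                    proteins=_sample_proteins(profile, cfg, rng),
                )
            )
            records[host_id] = lineage
            return
        rank = descent_ranks[level]
        for i in range(fanout[level]):
            child = _mutate(genome, cfg.rank_divergence.get(rank, 0.0), rng)
            child_path = path + (i + 1,)
            child_lineage = dict(lineage)
            if rank != "species":
                child_lineage[rank] = f"{rank}_" + ".".join(map(str, child_path))
            expand(child, child_lineage, level + 1, child_path)

    for p in range(cfg.n_phyla):
        root = _random_genome(rng, cfg.host_genome_length)
        expand(root, {"phylum": f"phylum_{p + 1}"}, 0, (p + 1,))
    return hosts, TaxonomyTable(records)


def generate_phages(
    cfg: GeneratorConfig,
    hosts: list[OrganismEntry],
    taxonomy: TaxonomyTable | None = None,
) -> tuple[list[OrganismEntry], InteractionSet]:
    """Phages with planted host homology and shared family backbones.

    A fraction ``homology_strength`` of each phage genome is segments
    copied from its (uniformly assigned) true host and mutated at
    ``segment_mutation_rate``; a backbone shared within the phage family
    fills up to ``backbone_fraction``; the rest is random. Proteins follow
    the true host's genus residue profile.
    """
    if not hosts:
        raise ValueError("hosts must be non-empty")
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.phage_genome_length
    h = cfg.homology_strength
    host_arr = {e.id: np.frombuffer(e.genome.encode(), dtype=np.uint8) for e in hosts}
    host_ids = sorted(host_arr)

    n_families = -(-cfg.n_phages // cfg.phage_family_size)
    backbone_len = int(round(min(cfg.backbone_fraction, 1.0 - h) * L))
    backbones = [_random_genome(rng, backbone_len) for _ in range(n_families)]

    phages, pairs = [], []
    for i in range(cfg.n_phages):
        pid = f"phage{i + 1:04d}"
        true_host = host_ids[int(rng.integers(len(host_ids)))]
        hg = host_arr[true_host]

        parts = []
        if backbone_len:
            parts.append(_mutate(backbones[i // cfg.phage_family_size],
                                 cfg.segment_mutation_rate, rng))
        remaining_host = int(round(h * L))
        while remaining_host > 0:
            seg_len = min(cfg.host_segment_length, remaining_host)
            start = int(rng.integers(0, len(hg) - seg_len + 1))
            parts.append(_mutate(hg[start:start + seg_len],
                                 cfg.segment_mutation_rate, rng))
            remaining_host -= seg_len
        filler = L - sum(len(p) for p in parts)
        if filler > 0:
            parts.append(_random_genome(rng, filler))
        genome = np.concatenate(parts)[:L]

        if taxonomy is not None and true_host in taxonomy:
            genus = taxonomy.taxon(true_host, "genus")
        else:
            genus = true_host
        profile = _genus_profile(genus, cfg.seed)
        phages.append(
            OrganismEntry(
                id=pid, role="phage", genome=genome.tobytes().decode(),
                proteins=_sample_proteins(profile, cfg, rng),
            )
        )
        pairs.append((pid, true_host, 1))

    positives = InteractionSet(
        pairs=pairs, provenance={(p, h_): "given_positive" for p, h_, _ in pairs}
    )
    return phages, positives


def generate_dataset(
    cfg: GeneratorConfig, out_dir: str | Path | None = None
) -> DatasetBundle:
    """Generate a complete runnable bundle; optionally write it to disk in
    the formats the dataset readers accept, plus a manifest of every
    parameter and seed."""
    hosts, taxonomy = generate_hosts(cfg)
    phages, positives = generate_phages(cfg, hosts, taxonomy)
    interactions = sample_negatives(
        positives,
        n_per_positive=cfg.n_per_positive,
        seed=cfg.seed + 2,
        phage_ids=[e.id for e in phages],
        host_ids=[e.id for e in hosts],
    )
    bundle = DatasetBundle(
        phages={e.id: e for e in phages},
        hosts={e.id: e for e in hosts},
        interactions=interactions,
        taxonomy=taxonomy,
    )
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        write_fasta(phages, d / "phages.fna", "nucleotide")
        write_fasta(hosts, d / "hosts.fna", "nucleotide")
        write_fasta(phages, d / "phage_proteins.faa", "protein")
        write_fasta(hosts, d / "host_proteins.faa", "protein")
        write_interactions(positives.positives, d / "interactions.tsv")
        write_taxonomy(taxonomy, d / "taxonomy.tsv")
        manifest = dataclasses.asdict(cfg)
        manifest["n_hosts"] = cfg.n_hosts
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle
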