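import json

import numpy as np
import pytest
from scipy import spatial

from comphi import (
    GeneratorConfig,
    InternalAligner,
    PipelineConfig,
    build_bit_pp,
    encode_tnc,
    generate_dataset,
    generate_hosts,
    generate_phages,
    repeated_split_eval,
)
from comphi.dataset_io import RANKS
from conftest import TINY_CFG

SMALL = dict(
    n_phyla=2, classes_per_phylum=1, orders_per_class=1, families_per_order=2,
    genera_per_family=2, hosts_per_genus=2, host_genome_length=800,
    phage_genome_length=300, n_phages=12, phage_family_size=3,
    proteins_per_organism=3, protein_length=(50, 80),
)


class TestHosts:
    def test_zero_divergence_collapses_phyla(self):
        cfg = GeneratorConfig(
            rank_divergence={r: 0.0 for r in
                             ("class", "order", "family", "genus", "species")},
            **SMALL,
        )
        hosts, taxonomy = generate_hosts(cfg)
        by_phylum = {}
        for h in hosts:
            by_phylum.setdefault(taxonomy.taxon(h.id, "phylum"), set()).add(h.genome)
        assert all(len(genomes) == 1 for genomes in by_phylum.values())

    def test_within_genus_more_similar_than_between_phyla(self):
        """3-mer cosine similarity reflects the taxonomy tree (10 seeds)."""
        wins = 0
        for seed in range(10):
            hosts, taxonomy = generate_hosts(GeneratorConfig(seed=seed, **SMALL))
            profile = {h.id: encode_tnc(h.genome) for h in hosts}
            genus, phylum = {}, {}
            for h in hosts:
                genus.setdefault(taxonomy.taxon(h.id, "genus"), []).append(h.id)
                phylum.setdefault(taxonomy.taxon(h.id, "phylum"), []).append(h.id)
            same_genus = next(ids for ids in genus.values() if len(ids) >= 2)[:2]
            phyla = sorted(phylum)
            cross = (phylum[phyla[0]][0], phylum[phyla[1]][0])
            sim = lambda a, b: 1 - spatial.distance.cosine(profile[a], profile[b])
            wins += sim(*same_genus) > sim(*cross)
        assert wins == 10

    def test_complete_six_rank_taxonomy(self):
        hosts, taxonomy = generate_hosts(GeneratorConfig(**SMALL))
        assert len(hosts) == GeneratorConfig(**SMALL).n_hosts
        for h in hosts:
            lineage = taxonomy.lineage(h.id)
            assert all(lineage[r] for r in RANKS)
        # species are unique per host
        species = {taxonomy.taxon(h.id, "species") for h in hosts}
        assert len(species) == len(hosts)


class TestPhages:
    def test_full_homology_without_mutation_is_exact_substring(self):
        cfg = GeneratorConfig(
            homology_strength=1.0, segment_mutation_rate=0.0,
            host_segment_length=10_000, **SMALL,
        )
        hosts, taxonomy = generate_hosts(cfg)
        phages, positives = generate_phages(cfg, hosts, taxonomy)
        host_by_id = {h.id: h for h in hosts}
        for p, h, _ in positives.pairs:
            phage = next(e for e in phages if e.id == p)
            assert phage.genome in host_by_id[h].genome

    def test_no_homology_rows_are_zero_under_strict_cutoff(self):
        cfg = GeneratorConfig(homology_strength=0.0, backbone_fraction=0.0, **SMALL)
        hosts, taxonomy = generate_hosts(cfg)
        phages, _ = generate_phages(cfg, hosts, taxonomy)
        aligner = InternalAligner()
        scores = [aligner.max_bit_score(p.genome, h.genome)
                  for p in phages[:3] for h in hosts[:3]]
        assert all(s == 0.0 for s in scores)

    def test_family_backbone_creates_phage_phage_signal(self):
        hits = 0
        for seed in range(10):
            cfg = GeneratorConfig(homology_strength=0.2, seed=seed, **SMALL)
            hosts, taxonomy = generate_hosts(cfg)
            phages, _ = generate_phages(cfg, hosts, taxonomy)
            _, nearest = build_bit_pp(phages, InternalAligner())
            fam = lambda pid: (int(pid.replace("phage", "")) - 1) // cfg.phage_family_size
            hits += np.mean([fam(nearest[p.id]) == fam(p.id) for p in phages]) > 0.5
        assert hits >= 8

    def test_excessive_homology_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            GeneratorConfig(homology_strength=1.0, phage_genome_length=900,
                            host_genome_length=800)


class TestDatasetBundle:
    def test_determinism(self):
        cfg = GeneratorConfig(seed=21, **SMALL)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert {k: v.genome for k, v in a.phages.items()} == \
               {k: v.genome for k, v in b.phages.items()}
        assert {k: v.proteins[0] for k, v in a.hosts.items()} == \
               {k: v.proteins[0] for k, v in b.hosts.items()}
        assert a.interactions.pairs == b.interactions.pairs

    def test_written_files_identical_across_runs(self, tmp_path):
        cfg = GeneratorConfig(seed=4, **SMALL)
        generate_dataset(cfg, tmp_path / "one")
        generate_dataset(cfg, tmp_path / "two")
        for name in ("phages.fna", "hosts.fna", "phage_proteins.faa",
                     "host_proteins.faa", "interactions.tsv", "taxonomy.tsv"):
            assert (tmp_path / "one" / name).read_bytes() == \
                   (tmp_path / "two" / name).read_bytes()
        manifest = json.loads((tmp_path / "one" / "manifest.json").read_text())
        assert manifest["seed"] == 4

    def test_balanced_labels(self):
        bundle = generate_dataset(GeneratorConfig(seed=2, **SMALL))
        labels = [y for _, _, y in bundle.interactions.pairs]
        assert sum(labels) * 2 == len(labels)


@pytest.fixture(scope="module")
def homology_sweep():
    """Full-pipeline species accuracy and pair AUCs over the homology grid,
    10 seeds each, at the default desk-scale study conditions."""
    out = {}
    cfg = PipelineConfig(grid_metric="top1_accuracy")
    for h in (0.0, 0.25, 0.5, 0.75, 1.0):
        records = []
        for seed in range(10):
            bundle = generate_dataset(GeneratorConfig(homology_strength=h, seed=seed))
            rep = repeated_split_eval(bundle, cfg, repeats=1, seed=seed)
            m = rep.mean
            records.append({
                "species": m["rank_accuracy"]["species"],
                "composite_auc": m["composite"]["auc"],
                "ml_auc": m["ml_only"]["auc"],
            })
        out[h] = records
    return out


class TestPipelineRecovery:
    def test_species_accuracy_recovered_at_high_homology(self, homology_sweep):
        """With >= 70% of the phage genome host-derived, the composite
        pipeline recovers the true host at species level."""
        for h in (0.75, 1.0):
            mean_acc = np.mean([r["species"] for r in homology_sweep[h]])
            assert mean_acc >= 0.8

    def test_no_homology_composite_matches_ml_only(self, homology_sweep):
        """Without planted homology the bit matrices carry no signal, so
        composite and RF-only AUC are indistinguishable (paired over seeds)."""
        diffs = np.array([r["composite_auc"] - r["ml_auc"]
                          for r in homology_sweep[0.0]])
        assert np.abs(diffs).mean() < 0.05

    def test_accuracy_increases_with_homology(self, homology_sweep):
        """Mean top-1 species accuracy rises with homology strength.

        The curve saturates near 1.0 by h=0.25, where seed-to-seed sampling
        noise exceeds any real adjacent-step change, so each step is
        required not to *significantly* decrease (within twice the paired
        standard error), and the overall rise must be large.
        """
        grid = (0.0, 0.25, 0.5, 0.75, 1.0)
        means = {h: np.mean([r["species"] for r in homology_sweep[h]]) for h in grid}
        for lo, hi in zip(grid, grid[1:]):
            step = np.array([a["species"] - b["species"]
                             for a, b in zip(homology_sweep[hi], homology_sweep[lo])])
            se = step.std(ddof=1) / np.sqrt(len(step))
            assert means[hi] - means[lo] >= -2 * se
        assert means[1.0] - means[0.0] > 0.5

    def test_alignment_dominates_when_homology_strong(self, homology_sweep):
        """Composite AUC is at least ML-only AUC in nearly every seed once
        half the phage genome is host-derived."""
        wins = sum(r["composite_auc"] >= r["ml_auc"] for r in homology_sweep[0.5])
        assert wins >= 8
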