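import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from comphi import GeneratorConfig, InternalAligner, generate_dataset

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


TINY_CFG = dict(
    n_phyla=2,
    classes_per_phylum=1,
    orders_per_class=1,
    families_per_order=2,
    genera_per_family=2,
    hosts_per_genus=2,
    host_genome_length=1200,
    phage_genome_length=400,
    n_phages=36,
    phage_family_size=3,
    proteins_per_organism=4,
    protein_length=(60, 120),
)


@pytest.fixture(scope="session")
def tiny_bundle():
    """16 hosts / 36 phages with moderate planted homology."""
    return generate_dataset(GeneratorConfig(homology_strength=0.6, seed=11, **TINY_CFG))


@pytest.fixture(scope="session")
def internal_aligner():
    return InternalAligner()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


def random_protein(rng, length):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
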