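import numpy as np
import pytest

from sulfopan.align import align_all_pairs
from sulfopan.records import GenomeBundle, ProteinRecord
from sulfopan.simulate import SynthSpec, generate_dataset

AAS = list("ACDEFGHIKLMNPQRSTVWY")


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(AAS)[rng.integers(0, 20, size=length)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20170606)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Four small genomes with planted families, aligned natively.

    Session-scoped because the native all-vs-all is the slow part; tests
    must not mutate the returned objects.
    """
    spec = SynthSpec(
        seed=11,
        n_genomes=4,
        n_core=6,
        n_softcore=3,
        n_rare=4,
        n_unique_per_genome=2,
        length_range=(80, 150),
        within_family_identity=0.85,
    )
    bundles, truth = generate_dataset(spec)
    hits = []
    for A in bundles:
        for B in bundles:
            hits.extend(align_all_pairs(A, B))
    return spec, bundles, truth, hits


def make_bundle(genome_id: str, seqs: dict[str, str]) -> GenomeBundle:
    return GenomeBundle(
        genome_id=genome_id,
        proteins=[
            ProteinRecord(protein_id=k, genome_id=genome_id, sequence=v)
            for k, v in seqs.items()
        ],
    )
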