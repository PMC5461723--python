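"""Ground-truth simulator: bookkeeping, determinism, planted structure."""

import numpy as np
import pytest

from sulfopan.io import read_gene_table, read_proteome
from sulfopan.pan import MatchCriteria
from sulfopan.records import protein_genome_map
from sulfopan.simulate import (
    MotifPlan,
    SynthSpec,
    evaluate_recovery,
    generate_dataset,
    write_dataset,
)


class TestBookkeeping:
    def test_planted_counts(self):
        spec = SynthSpec(seed=3, n_genomes=4, n_core=10, n_softcore=0,
                         n_rare=0, n_unique_per_genome=3,
                         length_range=(50, 80))
        bundles, truth = generate_dataset(spec)
        prevalences = [f["prevalence"] for f in truth.families.values()]
        assert prevalences.count(4) == 10
        assert prevalences.count(1) == 12  # 3 unique x 4 genomes
        assert truth.category_counts() == {
            "core": 10, "softcore": 0, "rare": 0, "unique": 3
        }

    def test_focal_contains_all_planted_categories(self):
        spec = SynthSpec(seed=5, n_genomes=6, n_core=4, n_softcore=3,
                         n_rare=5, n_unique_per_genome=2,
                         length_range=(50, 80))
        bundles, truth = generate_dataset(spec)
        assert truth.category_counts() == {
            "core": 4, "softcore": 3, "rare": 5, "unique": 2
        }
        assert len(bundles[0]) == 14

    def test_full_identity_gives_identical_members(self):
        spec = SynthSpec(seed=7, n_genomes=3, n_core=3, n_softcore=0,
                         n_rare=0, n_unique_per_genome=0,
                         length_range=(50, 60), within_family_identity=1.0)
        bundles, truth = generate_dataset(spec)
        by_id = {p.protein_id: p.sequence
                 for b in bundles for p in b.proteins}
        for fam in truth.families.values():
            seqs = {by_id[p] for _g, p in fam["members"]}
            assert len(seqs) == 1

    def test_planted_identity_near_target(self):
        spec = SynthSpec(seed=13, n_genomes=3, n_core=10, n_softcore=0,
                         n_rare=0, n_unique_per_genome=0,
                         length_range=(300, 400),
                         within_family_identity=0.85)
        bundles, truth = generate_dataset(spec)
        # members diverge from a common ancestor; identity to the ancestor is
        # not observable, but member pairs should sit near 0.85^2 + noise
        by_id = {p.protein_id: p.sequence for b in bundles for p in b.proteins}
        idents = []
        for fam in truth.families.values():
            (g1, p1), (g2, p2), *_ = fam["members"]
            a, b = by_id[p1], by_id[p2]
            idents.append(sum(x == y for x, y in zip(a, b)) / len(a))
        target = 0.85 * 0.85 + (1 - 0.85) ** 2 / 19
        assert abs(np.mean(idents) - target) < 0.03


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        spec = SynthSpec(seed=99, n_genomes=4, n_core=4, n_softcore=0,
                         n_rare=2, n_unique_per_genome=1,
                         length_range=(50, 80))
        out1, out2 = tmp_path / "a", tmp_path / "b"
        for out in (out1, out2):
            bundles, truth = generate_dataset(spec)
            write_dataset(bundles, truth, out)
        for f in sorted(out1.iterdir()):
            assert f.read_bytes() == (out2 / f.name).read_bytes()

    def test_different_seeds_differ(self):
        b1, _ = generate_dataset(SynthSpec(seed=1, n_genomes=2, n_core=2,
                                           n_softcore=0, n_rare=0,
                                           n_unique_per_genome=0,
                                           length_range=(50, 60)))
        b2, _ = generate_dataset(SynthSpec(seed=2, n_genomes=2, n_core=2,
                                           n_softcore=0, n_rare=0,
                                           n_unique_per_genome=0,
                                           length_range=(50, 60)))
        assert b1[0].proteins[0].sequence != b2[0].proteins[0].sequence


class TestEmittedFiles:
    def test_fasta_and_gff_reload_consistently(self, tmp_path):
        spec = SynthSpec(seed=17, n_genomes=2, n_core=3, n_softcore=0,
                         n_rare=0, n_unique_per_genome=1,
                         length_range=(50, 80))
        bundles, truth = generate_dataset(spec)
        write_dataset(bundles, truth, tmp_path)
        for b in bundles:
            re = read_proteome(tmp_path / f"{b.genome_id}.faa", b.genome_id)
            assert re.protein_ids == b.protein_ids
            assert {p.sequence for p in re} == {p.sequence for p in b}
            loci = read_gene_table(tmp_path / f"{b.genome_id}.gff3")
            for p in b.proteins:
                assert loci[p.protein_id] == p.locus

    def test_cds_translates_back_to_protein(self):
        from Bio.Seq import Seq

        spec = SynthSpec(seed=19, n_genomes=2, n_core=2, n_softcore=0,
                         n_rare=0, n_unique_per_genome=0,
                         length_range=(50, 60))
        bundles, _ = generate_dataset(spec)
        for b in bundles:
            contig = b.contigs[f"{b.genome_id}_c1"]
            for p in b.proteins:
                l = p.locus
                dna = contig[l.start - 1: l.end]
                if l.strand == "-":
                    dna = str(Seq(dna).reverse_complement())
                aa = str(Seq(dna).translate())
                assert aa == p.sequence + "*"


class TestRecoveryEvaluation:
    def test_perfect_inference_is_diagonal(self):
        import pandas as pd

        spec = SynthSpec(seed=23, n_genomes=4, n_core=2, n_softcore=0,
                         n_rare=1, n_unique_per_genome=1,
                         length_range=(50, 60))
        _, truth = generate_dataset(spec)
        observed = pd.DataFrame(
            {"category": pd.Series(truth.focal_categories)}
        )
        conf = evaluate_recovery(truth, observed)
        off_diag = conf.to_numpy().sum() - np.diag(
            conf.reindex(index=conf.columns, columns=conf.columns).fillna(0)
        ).sum()
        assert off_diag == 0

    def test_id_mismatch_errors(self):
        import pandas as pd

        spec = SynthSpec(seed=23, n_genomes=3, n_core=2, n_softcore=0,
                         n_rare=0, n_unique_per_genome=0,
                         length_range=(50, 60))
        _, truth = generate_dataset(spec)
        observed = pd.DataFrame({"category": pd.Series({"bogus": "core"})})
        with pytest.raises(ValueError):
            evaluate_recovery(truth, observed)


class TestCrossFamilyFalsePositives:
    def test_random_proteins_produce_no_filtered_hits(self):
        """Independent random proteins never pass the default criterion."""
        from sulfopan.blast import all_vs_all_blast
        from sulfopan.pan import filter_matches

        spec = SynthSpec(seed=29, n_genomes=2, n_core=0, n_softcore=0,
                         n_rare=0, n_unique_per_genome=60,
                         length_range=(200, 600))
        bundles, _ = generate_dataset(spec)
        hits = all_vs_all_blast(bundles)
        cross = [h for h in filter_matches(hits, MatchCriteria())
                 if h.query_genome != h.subject_genome]
        assert cross == []
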