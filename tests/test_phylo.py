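"""Progressive alignment, distances, NJ, bootstrap, RF."""

import math

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from sulfopan.phylo import (
    MSA,
    bipartitions,
    bootstrap,
    concatenate_homologs,
    distance,
    evolve_sequences,
    nj_tree,
    progressive_align,
    random_tree,
    robinson_foulds,
    tree_distance_matrix,
)

from conftest import random_protein


class TestProgressiveAlign:
    def test_identical_sequences_align_gap_free(self):
        msa = progressive_align({t: "MKVLAWEQ" for t in "abcd"})
        assert all(r == "MKVLAWEQ" for r in msa.rows)

    def test_two_sequences_equal_global_dp(self, rng):
        # oracle: Biopython's global aligner under identical scoring
        from Bio.Align import PairwiseAligner, substitution_matrices

        al = PairwiseAligner()
        al.mode = "global"
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -12
        al.extend_gap_score = -1
        local = np.random.default_rng(31)
        from sulfopan.align import ScoringScheme

        scheme = ScoringScheme()
        S = scheme.matrix
        idx = {c: i for i, c in enumerate(scheme.alphabet)}
        for _ in range(8):
            a = random_protein(local, int(local.integers(10, 40)))
            b = random_protein(local, int(local.integers(10, 40)))
            msa = progressive_align({"a": a, "b": b})
            ra, rb = msa.to_dict()["a"], msa.to_dict()["b"]
            score, state = 0, None
            for x, y in zip(ra, rb):
                if x != "-" and y != "-":
                    score += S[idx[x], idx[y]]
                    state = None
                elif x == "-":
                    score -= 12 if state != "y" else 1
                    state = "y"
                else:
                    score -= 12 if state != "x" else 1
                    state = "x"
            assert score == al.score(a, b)

    def test_msa_at_least_longest_input(self, rng):
        local = np.random.default_rng(37)
        seqs = {f"t{i}": random_protein(local, int(local.integers(20, 50)))
                for i in range(5)}
        msa = progressive_align(seqs)
        assert msa.length >= max(len(s) for s in seqs.values())
        for t, s in seqs.items():
            assert msa.ungapped(t) == s

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align({"a": "MKV"})


class TestDistance:
    def test_identical_rows_zero(self):
        d = distance(MSA(["a", "b"], ["MKVL", "MKVL"]))
        assert d["a", "b"] == 0.0

    def test_half_different(self):
        d = distance(MSA(["a", "b"], ["MKVL", "MKWW"]), model="p")
        assert d["a", "b"] == pytest.approx(0.5)
        dp = distance(MSA(["a", "b"], ["MKVL", "MKWW"]), model="poisson")
        assert dp["a", "b"] == pytest.approx(-math.log(0.5))

    def test_pairwise_deletion_of_gaps(self):
        d = distance(MSA(["a", "b"], ["MK-L", "MKW-"]), model="p")
        assert d["a", "b"] == 0.0  # only 2 comparable columns, both equal

    def test_all_gap_pair_errors(self):
        with pytest.raises(ValueError):
            distance(MSA(["a", "b"], ["M---", "---K"]))

    def test_saturation_capped(self):
        d = distance(MSA(["a", "b"], ["AAAA", "WWWW"]), model="poisson")
        assert d["a", "b"] == pytest.approx(-math.log(1 - 0.95))


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix([[0, 3, 4], [3, 0, 5], [4, 5, 0]], ["a", "b", "c"])
        tree = nj_tree(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_additive_matrices_recovered_exactly(self, rng):
        local = np.random.default_rng(41)
        for _ in range(20):
            taxa = [f"t{i}" for i in range(6)]
            true = random_tree(taxa, local)
            dm = tree_distance_matrix(true)
            est = nj_tree(dm)
            rf, _ = robinson_foulds(true, est)
            assert rf == 0
            back = tree_distance_matrix(est).filter(dm.ids)
            assert np.abs(back.data - dm.data).max() < 1e-9

    def test_taxon_order_invariance(self, rng):
        local = np.random.default_rng(43)
        true = random_tree([f"t{i}" for i in range(7)], local)
        dm = tree_distance_matrix(true)
        perm = list(dm.ids)[::-1]
        t1 = nj_tree(dm)
        t2 = nj_tree(dm.filter(perm))
        assert robinson_foulds(t1, t2)[0] == 0

    def test_agrees_with_reference_nj_on_random_matrices(self, rng):
        # independent route: scikit-bio's neighbor joining
        local = np.random.default_rng(47)
        for _ in range(5):
            n = 6
            base = local.random((n, n))
            D = (base + base.T) / 2 + 1.0
            np.fill_diagonal(D, 0.0)
            ids = [f"t{i}" for i in range(n)]
            dm = DistanceMatrix(D, ids)
            ours = nj_tree(dm)
            ref = skbio_nj(dm)
            assert robinson_foulds(ours, ref)[0] == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix([[0, 1], [1, 0]], ["a", "b"]))


class TestRF:
    def test_identical_trees_zero(self, rng):
        local = np.random.default_rng(53)
        t = random_tree([f"t{i}" for i in range(6)], local)
        assert robinson_foulds(t, t) == (0, 0.0)

    def test_four_taxon_topologies_maximally_distant(self):
        t1 = nj_tree(DistanceMatrix(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]],
            ["a", "b", "c", "d"]))
        t2 = nj_tree(DistanceMatrix(
            [[0, 4, 1, 4], [4, 0, 4, 1], [1, 4, 0, 4], [4, 1, 4, 0]],
            ["a", "b", "c", "d"]))
        rf, norm = robinson_foulds(t1, t2)
        assert rf == 2
        assert norm == 1.0

    def test_symmetric_and_leafset_checked(self, rng):
        local = np.random.default_rng(59)
        a = random_tree([f"t{i}" for i in range(6)], local)
        b = random_tree([f"t{i}" for i in range(6)], local)
        assert robinson_foulds(a, b)[0] == robinson_foulds(b, a)[0]
        c = random_tree([f"x{i}" for i in range(6)], local)
        with pytest.raises(ValueError):
            robinson_foulds(a, c)


class TestBootstrap:
    def _msa(self, rng, n=6, length=120, spread=(0.05, 0.15)):
        tree = random_tree([f"t{i}" for i in range(n)], rng, spread)
        seqs = evolve_sequences(tree, length, rng)
        return MSA(ids=sorted(seqs), rows=[seqs[k] for k in sorted(seqs)])

    def test_same_seed_identical_supports(self, rng):
        local = np.random.default_rng(61)
        msa = self._msa(local)
        t1 = bootstrap(msa, n_reps=30, seed=5)
        t2 = bootstrap(msa, n_reps=30, seed=5)
        s1 = sorted(n.name for n in t1.non_tips() if n.name)
        s2 = sorted(n.name for n in t2.non_tips() if n.name)
        assert s1 == s2

    def test_supports_in_unit_interval(self, rng):
        local = np.random.default_rng(67)
        msa = self._msa(local)
        t = bootstrap(msa, n_reps=25, seed=1)
        sups = [n.support for n in t.non_tips() if hasattr(n, "support")]
        assert sups and all(0.0 <= s <= 1.0 for s in sups)

    def test_repeated_identical_columns_fully_supported(self):
        # one informative column vector repeated: every replicate rebuilds
        # the same distance matrix, so every bipartition appears every time
        col = "AACCGG"[:6].replace("G", "W")  # AACCWW over 6 taxa
        msa = MSA(ids=[f"t{i}" for i in range(6)], rows=[c * 40 for c in col])
        t = bootstrap(msa, n_reps=20, seed=3, model="p")
        sups = [n.support for n in t.non_tips() if hasattr(n, "support")]
        assert sups and all(s == 1.0 for s in sups)


class TestConcatenation:
    def test_lengths_sum(self):
        groups = {"a": ["M" * 100, "K" * 50], "b": ["V" * 100, "W" * 50]}
        out = concatenate_homologs(groups)
        assert all(len(v) == 150 for v in out.values())

    def test_missing_slot_padded_with_gaps(self):
        groups = {"a": ["MKV", "WWWW"], "b": ["MRV", None]}
        out = concatenate_homologs(groups)
        assert out["b"] == "MRV----"
        assert len(out["a"]) == len(out["b"])

    def test_inconsistent_slot_counts_error(self):
        with pytest.raises(ValueError):
            concatenate_homologs({"a": ["M"], "b": ["M", "K"]})

    def test_slot_order_does_not_change_distances(self):
        g1 = {"a": ["MKVL", "WWAA"], "b": ["MKIL", "WWAV"]}
        g2 = {"a": ["WWAA", "MKVL"], "b": ["WWAV", "MKIL"]}
        d1 = distance(MSA(["a", "b"], list(concatenate_homologs(g1).values())))
        d2 = distance(MSA(["a", "b"], list(concatenate_homologs(g2).values())))
        assert d1["a", "b"] == d2["a", "b"]


class TestCongruence:
    def test_low_divergence_orthologs_reproduce_marker_topology(self, rng):
        local = np.random.default_rng(71)
        agree = 0
        for _ in range(10):
            tree = random_tree([f"s{i}" for i in range(8)], local, (0.03, 0.12))
            prot = evolve_sequences(tree, 300, local)
            marker = evolve_sequences(tree, 1200, local)
            tp = nj_tree(distance(progressive_align(prot), "poisson"))
            tm = nj_tree(distance(
                MSA(ids=list(marker), rows=list(marker.values())), "poisson"))
            if robinson_foulds(tp, tm)[1] == 0.0:
                agree += 1
        assert agree >= 9
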