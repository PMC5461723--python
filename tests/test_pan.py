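"""Match filtering, presence/absence, prevalence categories, sharing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sulfopan.align import SimilarityHit
from sulfopan.pan import (
    MatchCriteria,
    PrevalenceScheme,
    build_network,
    classify_prevalence,
    cluster_rows,
    filter_matches,
    linkage_heights,
    pairwise_shared,
    presence_matrix,
)


def make_hit(q, s, qg, sg, evalue=1e-30, covq=0.9, covs=0.9):
    return SimilarityHit(
        query_id=q, subject_id=s, raw_score=100, bit_score=50.0,
        evalue=evalue, percent_identity=90.0, percent_similarity=95.0,
        aligned_query_fraction=covq, aligned_subject_fraction=covs,
        query_span=(1, 10), subject_span=(1, 10),
        query_genome=qg, subject_genome=sg,
    )


class TestFilter:
    def test_passing_hit_kept(self):
        h = make_hit("a", "b", "g1", "g2", evalue=1e-21, covq=0.70, covs=0.66)
        assert filter_matches([h]) == [h]

    def test_evalue_at_threshold_dropped(self):
        h = make_hit("a", "b", "g1", "g2", evalue=1e-19, covq=0.9, covs=0.9)
        assert filter_matches([h]) == []

    def test_low_subject_coverage_dropped(self):
        h = make_hit("a", "b", "g1", "g2", covq=0.9, covs=0.6)
        assert filter_matches([h]) == []

    def test_self_hits_excluded(self):
        h = make_hit("a", "a", "g1", "g1")
        assert filter_matches([h]) == []

    hit_strategy = st.builds(
        make_hit,
        q=st.sampled_from(["p1", "p2", "p3"]),
        s=st.sampled_from(["q1", "q2", "q3"]),
        qg=st.just("g1"),
        sg=st.just("g2"),
        evalue=st.floats(1e-60, 1e-5),
        covq=st.floats(0.1, 1.0),
        covs=st.floats(0.1, 1.0),
    )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hits=st.lists(hit_strategy, max_size=30))
    def test_relaxing_thresholds_grows_kept_set(self, hits):
        strict = MatchCriteria(max_evalue=1e-20, min_coverage_both=0.65)
        looser_e = MatchCriteria(max_evalue=1e-10, min_coverage_both=0.65)
        looser_cov = MatchCriteria(max_evalue=1e-20, min_coverage_both=0.5)
        kept = set(map(id, filter_matches(hits, strict)))
        assert kept <= set(map(id, filter_matches(hits, looser_e)))
        assert kept <= set(map(id, filter_matches(hits, looser_cov)))


class TestPrevalenceScheme:
    @pytest.mark.parametrize(
        "prevalence,expected",
        [(14, "core"), (13, "softcore"), (9, "softcore"), (8, "rare"),
         (5, "rare"), (2, "rare"), (1, "unique")],
    )
    def test_14_genome_boundaries(self, prevalence, expected):
        scheme = PrevalenceScheme(N=14)
        assert scheme.category(prevalence) == expected

    def test_softcore_min_scales(self):
        assert PrevalenceScheme(N=8).softcore_min == 6  # ceil(9*8/14)

    def test_categories_partition_range(self):
        scheme = PrevalenceScheme(N=14)
        cats = [scheme.category(p) for p in range(1, 15)]
        assert cats[0] == "unique" and cats[-1] == "core"
        # each category occupies one contiguous band
        assert cats == sorted(cats, key=["unique", "rare", "softcore", "core"].index)


class TestPresence:
    def test_single_hit_tabulated(self):
        hits = [make_hit("p", "x2", "focal", "G2")]
        M = presence_matrix(hits, "focal", ["focal", "G2", "G3"], ["p", "p2"])
        assert M.table.loc["p"].tolist() == [True, True, False]
        assert M.table.loc["p2"].tolist() == [True, False, False]

    def test_no_hits_gives_prevalence_one(self):
        M = presence_matrix([], "focal", ["focal", "G2"], ["p1", "p2"])
        assert (M.prevalence() == 1).all()

    def test_reverse_direction_counts(self):
        hits = [make_hit("x2", "p", "G2", "focal")]
        M = presence_matrix(hits, "focal", ["focal", "G2"], ["p"])
        assert M.table.loc["p", "G2"]

    def test_unknown_focal_errors(self):
        with pytest.raises(ValueError):
            presence_matrix([], "nope", ["a", "b"], [])


class TestClassify:
    def test_counts_sum_to_proteome(self, tiny_dataset):
        spec, bundles, truth, hits = tiny_dataset
        filt = filter_matches(hits)
        M = presence_matrix(
            filt, "G01", [b.genome_id for b in bundles], bundles[0].protein_ids
        )
        assign, counts, pct = classify_prevalence(M, PrevalenceScheme(N=4))
        assert counts.sum() == len(bundles[0])
        assert pct.sum() == pytest.approx(100.0, abs=0.3)

    def test_recovers_planted_categories(self, tiny_dataset):
        spec, bundles, truth, hits = tiny_dataset
        filt = filter_matches(hits)
        M = presence_matrix(
            filt, "G01", [b.genome_id for b in bundles], bundles[0].protein_ids
        )
        assign, counts, _ = classify_prevalence(M, PrevalenceScheme(N=4))
        assert dict(counts) == truth.category_counts()


class TestSharing:
    def test_two_of_three_shared(self):
        hits = [make_hit("a1", "b1", "A", "B"), make_hit("a2", "b2", "A", "B")]
        sizes = {"A": 3, "B": 4}
        ca, cb, pa, pb = pairwise_shared(hits, "A", "B", sizes)
        assert (ca, cb) == (2, 2)
        assert pa == pytest.approx(66.7, abs=0.05)
        assert pb == pytest.approx(50.0)

    def test_same_genome_errors(self):
        with pytest.raises(ValueError):
            pairwise_shared([], "A", "A", {"A": 1})

    def test_no_hits_zero(self):
        assert pairwise_shared([], "A", "B", {"A": 2, "B": 2}) == (0, 0, 0.0, 0.0)

    def test_directional_counts_differ_with_paralogs(self):
        # two A-proteins hit the same single B protein
        hits = [make_hit("a1", "b1", "A", "B"), make_hit("a2", "b1", "A", "B")]
        ca, cb, _, _ = pairwise_shared(hits, "A", "B", {"A": 2, "B": 2})
        assert ca == 2 and cb == 1


class TestNetwork:
    def test_edges_only_where_sharing(self):
        hits = [make_hit("a1", "b1", "A", "B")]
        net = build_network(hits, {"A": 2, "B": 2, "C": 2})
        assert set(net.edges()) == {("A", "B")}
        assert net["A"]["B"]["weight"] == 1

    def test_complete_sharing_gives_all_pairs(self):
        hits = [
            make_hit("a", "b", "A", "B"),
            make_hit("a", "c", "A", "C"),
            make_hit("b", "c", "B", "C"),
        ]
        net = build_network(hits, {"A": 1, "B": 1, "C": 1})
        assert net.number_of_edges() == 3


class TestClusterRows:
    def _matrix(self, data, genomes):
        import pandas as pd

        from sulfopan.pan import PresenceAbsenceMatrix

        df = pd.DataFrame(data, columns=genomes).astype(bool)
        df.index = [f"p{i}" for i in range(len(df))]
        return PresenceAbsenceMatrix("g1", df)

    def test_identical_columns_adjacent(self):
        M = self._matrix(
            [[1, 1, 0], [1, 1, 0], [1, 1, 1], [1, 1, 0]], ["g1", "g2", "g3"]
        )
        order = cluster_rows(M)
        assert abs(order.index("g1") - order.index("g2")) == 1

    def test_row_permutation_invariant_heights(self):
        rng = np.random.default_rng(2)
        data = rng.random((12, 4)) > 0.5
        data[:, 0] = True
        M1 = self._matrix(data, ["g1", "g2", "g3", "g4"])
        M2 = self._matrix(data[rng.permutation(12)], ["g1", "g2", "g3", "g4"])
        assert np.allclose(linkage_heights(M1), linkage_heights(M2))
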