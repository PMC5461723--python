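"""Pan-proteome partitioning: match filtering, presence/absence, prevalence
categories, pairwise sharing, the genome-sharing network, and matrix
clustering.

A protein of the focal genome is "present" in another genome when at least one
filtered hit (in either search direction) links it to any protein of that
genome. Prevalence is the number of genomes a protein is present in, counting
the focal genome itself, and partitions the focal proteome into four
categories:

- ``core``       present in every genome (prevalence = N)
- ``softcore``   present in most genomes (default >= 9 of 14, scaled as
                 ceil(9 N / 14) for other N)
- ``rare``       present in a few genomes (2 up to the soft-core threshold)
- ``unique``     present in the focal genome only (prevalence 1)

The default match criterion keeps hits with E-value < 1e-20 where the local
alignment covers at least 65% of *both* protein lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .align import SimilarityHit

__all__ = [
    "MatchCriteria",
    "PrevalenceScheme",
    "PresenceAbsenceMatrix",
    "filter_matches",
    "presence_matrix",
    "classify_prevalence",
    "pairwise_shared",
    "build_network",
    "cluster_rows",
]

CATEGORIES = ("unique", "rare", "softcore", "core")


@dataclass(frozen=True)
class MatchCriteria:
    """Dual-coverage / E-value filter for calling two proteins a match."""

    max_evalue: float = 1e-20
    min_coverage_both: float = 0.65

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage_both <= 1):
            raise ValueError("min_coverage_both must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")

    def passes(self, h: SimilarityHit) -> bool:
        return (
            h.evalue < self.max_evalue
            and h.aligned_query_fraction >= self.min_coverage_both
            and h.aligned_subject_fraction >= self.min_coverage_both
        )


@dataclass(frozen=True)
class PrevalenceScheme:
    """Prevalence thresholds partitioning [1, N] into the four categories.

    ``softcore_min`` defaults to 9 when N = 14 and scales as ceil(9 N / 14)
    otherwise; a prevalence exactly at the soft-core threshold is soft-core,
    so the rare band is [rare_min, softcore_min - 1].
    """

    N: int = 14
    core_min: int | None = None
    softcore_min: int | None = None
    rare_min: int = 2

    def __post_init__(self) -> None:
        object.__setattr__(self, "core_min", self.core_min or self.N)
        object.__setattr__(
            self, "softcore_min", self.softcore_min or math.ceil(9 * self.N / 14)
        )
        if not (1 < self.rare_min <= self.softcore_min <= self.core_min <= self.N):
            raise ValueError(
                "require 1 < rare_min <= softcore_min <= core_min <= N"
            )

    def category(self, prevalence: int) -> str:
        if not (1 <= prevalence <= self.N):
            raise ValueError(f"prevalence {prevalence} outside [1, {self.N}]")
        if prevalence >= self.core_min:
            return "core"
        if prevalence >= self.softcore_min:
            return "softcore"
        if prevalence >= self.rare_min:
            return "rare"
        return "unique"


@dataclass
class PresenceAbsenceMatrix:
    """Focal-genome proteins x genomes boolean table."""

    focal_genome_id: str
    table: pd.DataFrame  # bool, rows = focal protein ids, cols = genome ids

    @property
    def n_genomes(self) -> int:
        return self.table.shape[1]

    def prevalence(self) -> pd.Series:
        return self.table.sum(axis=1).astype(int)


def filter_matches(
    hits: list[SimilarityHit], criteria: MatchCriteria | None = None
) -> list[SimilarityHit]:
    """Keep hits passing the dual-coverage/E-value criterion; drop self-hits.

    Monotone in both thresholds: relaxing either never shrinks the kept set.
    """
    criteria = criteria or MatchCriteria()
    return [h for h in hits if not h.is_self and criteria.passes(h)]


def _presence_pairs(filtered: list[SimilarityHit]):
    """Yield (protein, genome-it-is-present-in) in both hit directions."""
    for h in filtered:
        if h.subject_genome is not None:
            yield h.query_id, h.query_genome, h.subject_genome
        if h.query_genome is not None:
            yield h.subject_id, h.subject_genome, h.query_genome


def presence_matrix(
    filtered: list[SimilarityHit],
    focal: str,
    genomes: list[str],
    focal_proteins: list[str],
) -> PresenceAbsenceMatrix:
    """Build the focal-genome presence/absence table from filtered hits.

    ``cell(p, G)`` is true iff protein ``p`` of the focal genome has at least
    one filtered hit with any protein of ``G``, in either direction; the
    focal column is always true.
    """
    if focal not in genomes:
        raise ValueError(f"focal genome {focal!r} not among genomes")
    table = pd.DataFrame(
        False, index=list(focal_proteins), columns=list(genomes), dtype=bool
    )
    table[focal] = True
    known = set(table.index)
    for pid, pg, other in _presence_pairs(filtered):
        if pg == focal and pid in known and other in table.columns:
            table.loc[pid, other] = True
    return PresenceAbsenceMatrix(focal_genome_id=focal, table=table)


def classify_prevalence(
    M: PresenceAbsenceMatrix, scheme: PrevalenceScheme | None = None
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-protein category plus category counts and percentages.

    Returns ``(assignment, counts, percentages)``; the assignment frame has
    columns ``prevalence`` and ``category``, counts/percentages are indexed
    by category (all four always present) and percentages are rounded to 0.1.
    """
    scheme = scheme or PrevalenceScheme(N=M.n_genomes)
    if scheme.N != M.n_genomes:
        raise ValueError(
            f"scheme N={scheme.N} inconsistent with matrix N={M.n_genomes}"
        )
    prev = M.prevalence()
    cats = prev.map(scheme.category)
    assignment = pd.DataFrame({"prevalence": prev, "category": cats})
    counts = (
        cats.value_counts().reindex(CATEGORIES, fill_value=0).astype(int)
    )
    pct = (100.0 * counts / max(len(prev), 1)).round(1)
    return assignment, counts, pct


def pairwise_shared(
    filtered: list[SimilarityHit],
    A: str,
    B: str,
    proteome_sizes: dict[str, int],
) -> tuple[int, int, float, float]:
    """Directional sharing between two genomes.

    Returns ``(count_A, count_B, pct_A, pct_B)`` where ``count_A`` is the
    number of A's proteins with at least one filtered hit in B and ``pct_A``
    that count over A's proteome size (and symmetrically for B). The two
    directions can differ when paralogs exist and are both reported, never
    averaged.
    """
    if A == B:
        raise ValueError("pairwise sharing requires two distinct genomes")
    in_b: set[str] = set()
    in_a: set[str] = set()
    for pid, pg, other in _presence_pairs(filtered):
        if pg == A and other == B:
            in_b.add(pid)
        elif pg == B and other == A:
            in_a.add(pid)
    count_a, count_b = len(in_b), len(in_a)
    pct_a = 100.0 * count_a / proteome_sizes[A]
    pct_b = 100.0 * count_b / proteome_sizes[B]
    return count_a, count_b, pct_a, pct_b


def build_network(
    filtered: list[SimilarityHit],
    proteome_sizes: dict[str, int],
) -> nx.Graph:
    """Genome-sharing network: one node per genome, one edge per genome pair
    with any sharing; edge weight is the count of shared proteins (the larger
    of the two directional counts drives nothing — both are attributes, the
    ``weight`` is their maximum for line-width-style uses)."""
    genomes = sorted(proteome_sizes)
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    g = nx.Graph()
    g.add_nodes_from(genomes)
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            ca, cb, pa, pb = pairwise_shared(filtered, a, b, proteome_sizes)
            if ca or cb:
                g.add_edge(
                    a,
                    b,
                    weight=max(ca, cb),
                    **{
                        f"count_{a}": ca,
                        f"count_{b}": cb,
                        f"pct_{a}": round(pa, 1),
                        f"pct_{b}": round(pb, 1),
                    },
                )
    return g


def cluster_rows(M: PresenceAbsenceMatrix) -> list[str]:
    """Deterministic dendrogram leaf order of the genome columns.

    Agglomerative clustering on Euclidean distance between the boolean
    presence vectors, complete linkage, with columns pre-sorted
    lexicographically so ties break identically across runs.
    """
    if M.n_genomes < 2:
        raise ValueError("need at least two genomes to cluster")
    cols = sorted(M.table.columns)
    X = M.table[cols].T.to_numpy(dtype=float)
    d = pdist(X, metric="euclidean")
    Z = hierarchy.linkage(d, method="complete")
    order = hierarchy.leaves_list(Z)
    return [cols[i] for i in order]


def linkage_heights(M: PresenceAbsenceMatrix) -> np.ndarray:
    """Merge heights of the column clustering (row-order invariant)."""
    cols = sorted(M.table.columns)
    X = M.table[cols].T.to_numpy(dtype=float)
    Z = hierarchy.linkage(pdist(X), method="complete")
    return Z[:, 2]
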