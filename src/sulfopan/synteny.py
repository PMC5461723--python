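"""Gene-cluster synteny comparison across genomes via reciprocal best hits.

A reference cluster (an ordered run of genes from one genome) is mapped onto
each target genome: the homolog of each gene is its reciprocal best hit (RBH),
reported with percent identity/similarity, relative orientation, gene order,
and whether it lies in the same genomic region. "Same region" is
operationalised as membership in the largest chain of homologs on one contig
whose consecutive inter-gene gaps are at most ``max_locus_gap`` (default
10 kb); a homolog outside that chain is a relocation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import SimilarityHit
from .records import GenomeBundle

__all__ = [
    "ClusterSpec",
    "reciprocal_best_hits",
    "map_cluster",
    "compare_cluster",
    "prevalence_of_cluster",
]


@dataclass
class ClusterSpec:
    """An ordered, oriented gene cluster from a single reference genome."""

    name: str
    genome_id: str
    genes: list[tuple[str, str]]  # (gene_id, strand) in genomic order
    max_locus_gap: int = 10_000

    def __post_init__(self) -> None:
        if len(self.genes) < 2:
            raise ValueError("a cluster needs at least two genes")
        for g, s in self.genes:
            if s not in ("+", "-"):
                raise ValueError(f"gene {g}: strand must be '+' or '-'")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.genes]

    @classmethod
    def from_tsv(cls, path, name: str | None = None, max_locus_gap: int = 10_000):
        df = pd.read_csv(
            path, sep="\t", header=None, names=["gene_id", "genome_id", "strand"],
            comment="#",
        )
        genomes = df["genome_id"].unique()
        if len(genomes) != 1:
            raise ValueError("cluster genes must all come from one genome")
        return cls(
            name=name or "cluster",
            genome_id=str(genomes[0]),
            genes=list(zip(df["gene_id"], df["strand"])),
            max_locus_gap=max_locus_gap,
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [(g, self.genome_id, s) for g, s in self.genes]
        ).to_csv(path, sep="\t", header=False, index=False)


def _best_hit(candidates: list[SimilarityHit]) -> tuple[SimilarityHit | None, bool]:
    """Deterministic best hit: bit score, then lower E-value, then lexicographic
    subject id. Returns (best, had_tie) where had_tie flags a score/E tie."""
    if not candidates:
        return None, False
    ranked = sorted(
        candidates, key=lambda h: (-h.bit_score, h.evalue, h.subject_id)
    )
    best = ranked[0]
    tie = len(ranked) > 1 and (
        ranked[1].bit_score == best.bit_score and ranked[1].evalue == best.evalue
    )
    return best, tie


def _directional_hits(
    hits: list[SimilarityHit], qg: str, sg: str
) -> dict[str, list[SimilarityHit]]:
    """Candidates per query of genome qg against genome sg, normalising hit
    orientation so the query is always on the qg side."""
    out: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        if h.query_genome == qg and h.subject_genome == sg:
            out.setdefault(h.query_id, []).append(h)
        elif h.query_genome == sg and h.subject_genome == qg:
            out.setdefault(h.subject_id, []).append(h.swapped())
    return out


def reciprocal_best_hits(
    A: str, B: str, hits: list[SimilarityHit]
) -> list[tuple[str, str]]:
    """RBH pairs between genomes A and B from (filtered) hits.

    (a, b) is a pair iff b is a's top hit in B and a is b's top hit in A,
    under deterministic tie-breaking. Symmetric: swapping A and B transposes
    the pairs.
    """
    fwd = _directional_hits(hits, A, B)
    rev = _directional_hits(hits, B, A)
    best_fwd = {q: _best_hit(cs)[0] for q, cs in fwd.items()}
    best_rev = {q: _best_hit(cs)[0] for q, cs in rev.items()}
    pairs = []
    for a, h in best_fwd.items():
        if h is None:
            continue
        back = best_rev.get(h.subject_id)
        if back is not None and back.subject_id == a:
            pairs.append((a, h.subject_id))
    return sorted(pairs)


def _chain_homologs(loci: dict[str, "object"], max_gap: int) -> tuple[set[str], dict[str, int]]:
    """Largest max-gap chain of homolog loci on one contig.

    Returns (members of the main chain, order index within it, 1-based).
    """
    placed = sorted(
        ((l.contig_id, l.start, l.end, g) for g, l in loci.items()),
    )
    chains: list[list[str]] = []
    cur: list[str] = []
    prev = None
    for contig, start, end, gene in placed:
        if prev is not None and contig == prev[0] and start - prev[1] - 1 <= max_gap:
            cur.append(gene)
        else:
            if cur:
                chains.append(cur)
            cur = [gene]
        prev = (contig, end)
    if cur:
        chains.append(cur)
    main = max(chains, key=len) if chains else []
    return set(main), {g: i + 1 for i, g in enumerate(main)}


def map_cluster(
    cluster: ClusterSpec,
    reference: GenomeBundle,
    target: GenomeBundle,
    hits: list[SimilarityHit],
) -> pd.DataFrame:
    """One comparison column: the reference cluster mapped onto ``target``.

    Returns a frame with one row per reference gene: homolog id (or None),
    pct_identity, pct_similarity, strand ('same'/'opposite'), co_located,
    order_index. Mapping a cluster onto its own genome is the exact identity
    column.
    """
    if reference.genome_id != cluster.genome_id:
        raise ValueError("reference bundle does not match the cluster's genome")
    ref_proteins = reference.as_dict()
    for g in cluster.gene_ids:
        if g not in ref_proteins:
            raise ValueError(f"cluster gene {g!r} missing from reference genome")

    self_map = target.genome_id == reference.genome_id
    if self_map:
        homolog_of = {g: g for g in cluster.gene_ids}
        stats = {g: (100.0, 100.0) for g in cluster.gene_ids}
    else:
        rbh = dict(reciprocal_best_hits(reference.genome_id, target.genome_id, hits))
        fwd = _directional_hits(hits, reference.genome_id, target.genome_id)
        homolog_of = {g: rbh.get(g) for g in cluster.gene_ids}
        stats = {}
        for g, hom in homolog_of.items():
            if hom is None:
                continue
            rec = next((h for h in fwd.get(g, []) if h.subject_id == hom), None)
            stats[g] = (
                (rec.percent_identity, rec.percent_similarity)
                if rec is not None
                else (float("nan"), float("nan"))
            )

    target_proteins = target.as_dict()
    hom_loci = {
        g: target_proteins[hom].locus
        for g, hom in homolog_of.items()
        if hom is not None and target_proteins[hom].locus is not None
    }
    main, order = _chain_homologs(
        {homolog_of[g]: l for g, l in hom_loci.items()}, cluster.max_locus_gap
    ) if hom_loci else (set(), {})

    rows = []
    for gene_id, ref_strand in cluster.genes:
        hom = homolog_of.get(gene_id)
        if hom is None:
            rows.append(
                dict(ref_gene=gene_id, target_genome=target.genome_id,
                     homolog=None, pct_identity=None, pct_similarity=None,
                     strand=None, co_located=None, order_index=None)
            )
            continue
        pid, psim = stats.get(gene_id, (float("nan"), float("nan")))
        hloc = target_proteins[hom].locus
        strand = None
        if hloc is not None:
            strand = "same" if hloc.strand == ref_strand else "opposite"
        co = None
        oidx = None
        if hloc is not None:
            co = hom in main
            oidx = order.get(hom)
        rows.append(
            dict(ref_gene=gene_id, target_genome=target.genome_id,
                 homolog=hom, pct_identity=pid, pct_similarity=psim,
                 strand=strand, co_located=co, order_index=oidx)
        )
    return pd.DataFrame(rows)


def compare_cluster(
    cluster: ClusterSpec,
    reference: GenomeBundle,
    targets: list[GenomeBundle],
    hits: list[SimilarityHit],
) -> pd.DataFrame:
    """Long-format comparison of the cluster across all target genomes."""
    rows: list[dict] = []
    for t in targets:
        rows.extend(map_cluster(cluster, reference, t, hits).to_dict("records"))
    return pd.DataFrame(rows)


def prevalence_of_cluster(
    cluster: ClusterSpec, filtered: list[SimilarityHit]
) -> pd.Series:
    """Per reference gene: number of non-reference genomes with >= 1 filtered
    hit to it (paralogs in one genome still count once)."""
    ref = cluster.genome_id
    found: dict[str, set[str]] = {g: set() for g in cluster.gene_ids}
    for h in filtered:
        if h.query_genome == ref and h.query_id in found and h.subject_genome != ref:
            found[h.query_id].add(h.subject_genome)
        if h.subject_genome == ref and h.subject_id in found and h.query_genome != ref:
            found[h.subject_id].add(h.query_genome)
    return pd.Series({g: len(v) for g, v in found.items()}, name="prevalence")
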