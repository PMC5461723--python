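"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython; GFF3 CDS tables and 12-column tabular search
hits are line formats read directly with full validation. Matrices are CSV
via pandas, networks are GraphML/TSV via networkx, trees are Newick via
scikit-bio. All public coordinates are 1-based inclusive.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from urllib.parse import unquote

import networkx as nx
import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .align import SimilarityHit
from .records import GenomeBundle, Locus, ProteinRecord

__all__ = [
    "read_proteome",
    "read_dna",
    "read_gene_table",
    "attach_gene_table",
    "read_tabular_hits",
    "write_fasta",
    "write_matrix",
    "read_matrix",
    "write_network",
    "read_network",
    "write_newick",
    "read_newick",
    "hits_to_frame",
    "write_hits",
]

TABULAR_COLUMNS = [
    "query", "subject", "pident", "alnlen", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_proteome(path, genome_id: str) -> GenomeBundle:
    """Read one genome's protein FASTA into a :class:`GenomeBundle`.

    Sequences are uppercased and a single terminal ``*`` stop is stripped.
    Duplicate record ids and empty files are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    proteins = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        proteins.append(
            ProteinRecord(
                protein_id=rec.id,
                genome_id=genome_id,
                sequence=str(rec.seq),
                annotation=rec.description[len(rec.id):].strip(),
            )
        )
    return GenomeBundle(genome_id=genome_id, proteins=proteins)


def read_dna(path) -> dict[str, str]:
    """Contig FASTA -> {contig_id: uppercase DNA}."""
    contigs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"{path}: duplicate contig id {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper()
    if not contigs:
        raise ValueError(f"{path}: no FASTA records")
    return contigs


def _gff_attributes(field: str) -> dict[str, str]:
    out = {}
    for part in field.strip().split(";"):
        if not part:
            continue
        if "=" not in part:
            continue
        k, v = part.split("=", 1)
        out[k.strip()] = unquote(v.strip())
    return out


def read_gene_table(path) -> dict[str, Locus]:
    """GFF3 CDS features -> {protein_id (the ID attribute): Locus}.

    Only CDS features are considered; coordinates are kept exactly as
    written (1-based inclusive). A CDS without an ID, or with start > end,
    is an error.
    """
    loci: dict[str, Locus] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}:{ln}: expected 9 GFF3 columns, got {len(fields)}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            attr = _gff_attributes(attrs)
            if "ID" not in attr:
                raise ValueError(f"{path}:{ln}: CDS feature lacks an ID attribute")
            s, e = int(start), int(end)
            if s > e:
                raise ValueError(f"{path}:{ln}: CDS start {s} > end {e}")
            loci[attr["ID"]] = Locus(contig_id=contig, start=s, end=e, strand=strand)
    return loci


def attach_gene_table(bundle: GenomeBundle, loci: dict[str, Locus]) -> GenomeBundle:
    """Attach GFF-derived loci to a bundle's proteins in place (and return it)."""
    for p in bundle.proteins:
        if p.protein_id in loci:
            p.locus = loci[p.protein_id]
    return bundle


def read_tabular_hits(
    path,
    lengths: dict[str, int],
    genomes: dict[str, str] | None = None,
) -> list[SimilarityHit]:
    """Parse 12-column tabular search output into SimilarityHit records.

    Coverage fractions are recomputed from the alignment spans and the
    authoritative ``lengths`` map (never from optional qlen/slen columns).
    A 13th ``ppos`` column, when present, fills percent_similarity;
    otherwise it is NaN. ``genomes`` optionally maps protein ids to genome
    ids so hits can carry genome provenance.
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) not in (12, 13):
                raise ValueError(
                    f"{path}:{ln}: expected 12 (or 12+ppos) columns, got {len(f)}"
                )
            try:
                q, s = f[0], f[1]
                pident = float(f[2])
                qstart, qend = int(f[6]), int(f[7])
                sstart, send = int(f[8]), int(f[9])
                ev, bits = float(f[10]), float(f[11])
                ppos = float(f[12]) if len(f) == 13 else float("nan")
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: malformed row ({e})") from None
            for pid in (q, s):
                if pid not in lengths:
                    raise ValueError(f"{path}:{ln}: unknown protein id {pid!r}")
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    raw_score=0,
                    bit_score=bits,
                    evalue=ev,
                    percent_identity=pident,
                    percent_similarity=ppos,
                    aligned_query_fraction=(qend - qstart + 1) / lengths[q],
                    aligned_subject_fraction=(abs(send - sstart) + 1) / lengths[s],
                    query_span=(qstart, qend),
                    subject_span=(sstart, send),
                    query_genome=genomes.get(q) if genomes else None,
                    subject_genome=genomes.get(s) if genomes else None,
                )
            )
    return hits


def hits_to_frame(hits: list[SimilarityHit]) -> pd.DataFrame:
    """Match table: one row per hit, long format."""
    return pd.DataFrame(
        {
            "query": [h.query_id for h in hits],
            "subject": [h.subject_id for h in hits],
            "query_genome": [h.query_genome for h in hits],
            "subject_genome": [h.subject_genome for h in hits],
            "bit_score": [h.bit_score for h in hits],
            "evalue": [h.evalue for h in hits],
            "pct_identity": [h.percent_identity for h in hits],
            "pct_similarity": [h.percent_similarity for h in hits],
            "query_cov": [h.aligned_query_fraction for h in hits],
            "subject_cov": [h.aligned_subject_fraction for h in hits],
        }
    )


def write_hits(hits: list[SimilarityHit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_matrix(df: pd.DataFrame, path) -> None:
    """CSV with index; booleans serialised as 0/1 for round-trip safety."""
    out = df.copy()
    for c in out.columns:
        if out[c].dtype == bool:
            out[c] = out[c].astype(int)
    out.to_csv(path)


def read_matrix(path, boolean: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    if boolean:
        df = df.astype(bool)
    return df


def write_network(g: nx.Graph, path, fmt: str = "auto") -> None:
    """GraphML or TSV edge list, chosen by extension when fmt='auto'."""
    path = Path(path)
    if fmt == "auto":
        fmt = "graphml" if path.suffix == ".graphml" else "edgelist"
    if fmt == "graphml":
        nx.write_graphml(g, path)
    elif fmt == "edgelist":
        rows = [
            {"source": u, "target": v, **d} for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown network format {fmt!r}")


def read_network(path, fmt: str = "auto") -> nx.Graph:
    path = Path(path)
    if fmt == "auto":
        fmt = "graphml" if path.suffix == ".graphml" else "edgelist"
    if fmt == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    df = pd.read_csv(path, sep="\t")
    for _, row in df.iterrows():
        attrs = {k: row[k] for k in df.columns if k not in ("source", "target")}
        g.add_edge(row["source"], row["target"], **attrs)
    return g


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def tree_to_newick_string(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
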