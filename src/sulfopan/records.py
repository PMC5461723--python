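"""Core domain records shared by every pipeline stage.

All genomic coordinates in public records are 1-based inclusive (the GFF3
convention); readers and writers that speak 0-based half-open formats convert
at the boundary and never leak the other convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class Locus:
    """Genomic placement of a gene: contig, 1-based inclusive span, strand."""

    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"locus start {self.start} > end {self.end} on {self.contig_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """One annotated protein of one genome.

    ``length`` always equals ``len(sequence)``; terminal stop characters are
    stripped at parse time.
    """

    protein_id: str
    genome_id: str
    sequence: str
    locus: Locus | None = None
    annotation: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper().rstrip("*")
        bad = set(self.sequence) - AA_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.protein_id}: non-amino-acid characters {sorted(bad)}"
            )
        if not self.sequence:
            raise ValueError(f"protein {self.protein_id}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GenomeBundle:
    """All per-genome inputs: proteins, and optionally the contig DNA.

    Protein ids are unique within the bundle; when contigs are present every
    protein locus must resolve to one of them.
    """

    genome_id: str
    proteins: list[ProteinRecord] = field(default_factory=list)
    contigs: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for p in self.proteins:
            if p.protein_id in seen:
                raise ValueError(
                    f"genome {self.genome_id}: duplicate protein id {p.protein_id!r}"
                )
            seen.add(p.protein_id)
        if self.contigs:
            for p in self.proteins:
                if p.locus is not None and p.locus.contig_id not in self.contigs:
                    raise ValueError(
                        f"protein {p.protein_id}: locus contig "
                        f"{p.locus.contig_id!r} not among bundle contigs"
                    )

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self):
        return iter(self.proteins)

    def get(self, protein_id: str) -> ProteinRecord:
        for p in self.proteins:
            if p.protein_id == protein_id:
                return p
        raise KeyError(f"{protein_id!r} not in genome {self.genome_id}")

    @property
    def protein_ids(self) -> list[str]:
        return [p.protein_id for p in self.proteins]

    @property
    def total_residues(self) -> int:
        return sum(p.length for p in self.proteins)

    def as_dict(self) -> dict[str, ProteinRecord]:
        return {p.protein_id: p for p in self.proteins}


def protein_genome_map(bundles) -> dict[str, str]:
    """protein_id -> genome_id over a collection of bundles.

    Protein ids must be unique across the whole dataset; collisions raise.
    """
    out: dict[str, str] = {}
    for b in bundles:
        for p in b.proteins:
            if p.protein_id in out:
                raise ValueError(
                    f"protein id {p.protein_id!r} appears in both "
                    f"{out[p.protein_id]} and {b.genome_id}"
                )
            out[p.protein_id] = b.genome_id
    return out
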