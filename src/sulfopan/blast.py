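"""BLAST+ backend for genome-scale all-vs-all searches.

The native Smith-Waterman aligner is exact but O(mn) per pair in Python, so
datasets with thousands of proteins go through the standard search engine
(``makeblastdb``/``blastp``) and its tabular output is imported through the
same 12-column parser used for any externally supplied hit table. Hits are
requested with the extra ``ppos`` column so percent similarity is populated.
"""

from __future__ import annotations

import shutil
import subprocess
import tempfile
from pathlib import Path

from .align import SimilarityHit
from .io import read_tabular_hits, write_fasta
from .records import GenomeBundle, protein_genome_map

__all__ = ["blast_available", "all_vs_all_blast"]


def blast_available() -> bool:
    return shutil.which("blastp") is not None and shutil.which("makeblastdb") is not None


def all_vs_all_blast(
    bundles: list[GenomeBundle],
    *,
    evalue_cutoff: float = 1e-6,
    max_target_seqs: int = 200,
    threads: int = 1,
    workdir: str | Path | None = None,
) -> list[SimilarityHit]:
    """All proteins of all bundles searched against themselves with blastp.

    ``evalue_cutoff`` only trims the raw output (the pipeline's real filter
    is applied later); ``max_target_seqs`` bounds hits per query and must
    exceed the largest expected family size.
    """
    if not blast_available():  # pragma: no cover - present in target env
        raise RuntimeError("blastp/makeblastdb not found on PATH")
    seqs: dict[str, str] = {}
    lengths: dict[str, int] = {}
    for b in bundles:
        for p in b.proteins:
            seqs[p.protein_id] = p.sequence
            lengths[p.protein_id] = p.length
    genomes = protein_genome_map(bundles)

    def run(tmp: Path) -> list[SimilarityHit]:
        fasta = tmp / "all.faa"
        write_fasta(seqs, fasta)
        db = tmp / "db"
        subprocess.run(
            ["makeblastdb", "-in", str(fasta), "-dbtype", "prot", "-out", str(db),
             "-logfile", str(tmp / "makeblastdb.log")],
            check=True,
        )
        out = tmp / "hits.tsv"
        subprocess.run(
            [
                "blastp", "-query", str(fasta), "-db", str(db),
                "-outfmt", "6 std ppos",
                "-evalue", str(evalue_cutoff),
                "-max_target_seqs", str(max_target_seqs),
                "-num_threads", str(threads),
                "-out", str(out),
            ],
            check=True,
        )
        return read_tabular_hits(out, lengths, genomes)

    if workdir is not None:
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)
        return run(workdir)
    with tempfile.TemporaryDirectory() as td:
        return run(Path(td))
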