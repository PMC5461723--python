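"""Promoter scanning for a fixed-length regulatory motif.

The motif is supplied as an IUPAC consensus or a 4 x L position weight
matrix - it is an input, never hard-coded. Each gene's upstream window is
extracted on the coding strand (reverse-complemented for minus-strand genes)
and the motif is slid across it; the best-scoring placement above threshold is
reported with a signed offset and a three-way class:

- ``+``  hit within the proximal window (default 150 bp of the start codon)
- ``?``  hit above threshold but only further upstream
- ``-``  nothing above threshold

Offsets follow promoter-table convention: the position of the motif's
3'-most base on the coding strand, with -1 the base immediately before the
start codon, so a motif "at -46" ends 46 bp upstream of the gene.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GenomeBundle, ProteinRecord

__all__ = ["MotifModel", "MotifHit", "scan_upstream", "scan_gene_set"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """Log-odds position weight matrix over ACGT with a score threshold.

    ``pwm`` holds per-position log2-odds scores (L x 4) against the
    background; ``score_threshold`` is an absolute log2-odds score a window
    must reach to count as a hit.
    """

    pwm: np.ndarray
    score_threshold: float

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise ValueError("pwm must be L x 4 (columns A, C, G, T)")
        if self.score_threshold > float(self.pwm.max(axis=1).sum()):
            raise ValueError("score_threshold exceeds the maximum attainable score")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        *,
        mismatch_prob: float = 0.01,
        background: np.ndarray | None = None,
        threshold_fraction: float = 0.8,
    ) -> "MotifModel":
        """PWM from an IUPAC consensus: probability 1 - mismatch_prob spread
        over the allowed bases of each position, the rest over disallowed
        ones; threshold defaults to 80% of the maximum attainable score."""
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        rows = []
        for c in consensus.upper():
            allowed = IUPAC.get(c)
            if allowed is None:
                raise ValueError(f"not an IUPAC base code: {c!r}")
            p = np.full(4, 0.0)
            for b in allowed:
                p[_BASE_INDEX[b]] = (1.0 - mismatch_prob) / len(allowed)
            rest = [i for i in range(4) if _BASES[i] not in allowed]
            for i in rest:
                p[i] = mismatch_prob / max(len(rest), 1)
            rows.append(np.log2(np.maximum(p, 1e-9) / bg))
        pwm = np.array(rows)
        return cls(
            pwm=pwm,
            score_threshold=threshold_fraction * float(pwm.max(axis=1).sum()),
        )

    @classmethod
    def from_pwm_tsv(
        cls,
        path,
        *,
        score_threshold: float | None = None,
        threshold_fraction: float = 0.8,
        background: np.ndarray | None = None,
    ) -> "MotifModel":
        """4 x L (rows A, C, G, T) tab-separated count/probability matrix."""
        raw = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=float)
        if raw.shape[0] != 4:
            raise ValueError("PWM file must have 4 rows (A, C, G, T)")
        probs = raw / raw.sum(axis=0, keepdims=True)
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        pwm = np.log2(np.maximum(probs.T, 1e-9) / bg)
        thr = (
            score_threshold
            if score_threshold is not None
            else threshold_fraction * float(pwm.max(axis=1).sum())
        )
        return cls(pwm=pwm, score_threshold=thr)

    def score_window(self, window: str) -> float:
        if len(window) != self.length:
            raise ValueError("window length mismatch")
        idx = [_BASE_INDEX.get(c, -1) for c in window]
        if any(i < 0 for i in idx):
            return float("-inf")
        return float(self.pwm[np.arange(self.length), idx].sum())


@dataclass
class MotifHit:
    """Best motif placement upstream of one gene."""

    gene_id: str
    klass: str  # '+', '?' or '-'
    offset: int | None  # position of the motif's 3' end; always negative
    score: float | None
    n_above_threshold: int = 0
    truncated: bool = False


def upstream_window(
    genome: GenomeBundle, gene: ProteinRecord, window: int
) -> tuple[str, bool]:
    """Coding-strand upstream sequence; last base is position -1.

    Returns (sequence, truncated): truncated is set when the contig ends
    before a full window is available.
    """
    if gene.locus is None:
        raise ValueError(f"gene {gene.protein_id} has no locus")
    contig = genome.contigs.get(gene.locus.contig_id)
    if contig is None:
        raise ValueError(
            f"contig {gene.locus.contig_id!r} absent from genome "
            f"{genome.genome_id}"
        )
    if gene.locus.strand == "+":
        lo = gene.locus.start - 1 - window  # 0-based slice start
        truncated = lo < 0
        seq = contig[max(lo, 0) : gene.locus.start - 1]
    else:
        hi = gene.locus.end + window
        truncated = hi > len(contig)
        seq = reverse_complement(contig[gene.locus.end : min(hi, len(contig))])
    return seq, truncated


def scan_upstream(
    genome: GenomeBundle,
    gene: ProteinRecord,
    motif: MotifModel,
    window: int = 300,
    proximal_cutoff: int = 150,
) -> MotifHit:
    """Slide the motif over the gene's upstream window and classify.

    The best hit above threshold wins; ties prefer the placement closest to
    the start codon. A truncated window (gene near a contig edge) is scanned
    over whatever span exists and flagged.
    """
    if window < motif.length:
        raise ValueError("window shorter than the motif")
    seq, truncated = upstream_window(genome, gene, window)
    L = motif.length
    best: tuple[float, int] | None = None  # (score, offset)
    n_above = 0
    for i in range(len(seq) - L + 1):
        s = motif.score_window(seq[i : i + L])
        if s < motif.score_threshold:
            continue
        n_above += 1
        offset = (i + L) - len(seq) - 1  # 3' end position, -1 = last base
        if best is None or s > best[0] or (s == best[0] and offset > best[1]):
            best = (s, offset)
    if best is None:
        return MotifHit(gene.protein_id, "-", None, None, 0, truncated)
    score, offset = best
    klass = "+" if -offset <= proximal_cutoff else "?"
    return MotifHit(gene.protein_id, klass, offset, score, n_above, truncated)


def scan_gene_set(
    genome: GenomeBundle,
    genes: list[ProteinRecord],
    motif: MotifModel,
    window: int = 300,
    proximal_cutoff: int = 150,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Scan many genes; returns the per-gene table and per-class counts."""
    hits = [
        scan_upstream(genome, g, motif, window, proximal_cutoff) for g in genes
    ]
    table = pd.DataFrame(
        {
            "gene_id": [h.gene_id for h in hits],
            "class": [h.klass for h in hits],
            "offset": [h.offset for h in hits],
            "score": [h.score for h in hits],
            "n_above_threshold": [h.n_above_threshold for h in hits],
            "truncated": [h.truncated for h in hits],
        }
    )
    summary = {c: int((table["class"] == c).sum()) for c in ("+", "?", "-")}
    return table, summary
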