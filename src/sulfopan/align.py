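"""Local protein alignment with BLAST-like statistics.

The native aligner is an exact Smith-Waterman with affine gaps on BLOSUM62,
plus Karlin-Altschul bit scores and E-values, so that desk-scale analyses do
not need an external search engine. Genome-scale runs can instead import
tabular hits produced by an external search tool (see :mod:`sulfopan.blast`);
both routes emit identical :class:`SimilarityHit` records.

E-value model: ``bit = (lambda * raw - ln K) / ln 2`` and ``E = m * n * 2**-bit``
with the standard gapped-BLOSUM62 constants (lambda = 0.267, K = 0.041 for gap
open 11 / extend 1). The search space is the plain product of query length and
database residues, without edge-effect correction: the pipeline's 1e-20
cut-off needs a consistent scale, not engine parity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Align import substitution_matrices

__all__ = [
    "ScoringScheme",
    "SimilarityHit",
    "smith_waterman",
    "bit_score",
    "evalue",
    "align_all_pairs",
]

# traceback states
_STOP, _FROM_M, _FROM_IX, _FROM_IY = 0, 1, 2, 3


def _blosum62_with_neutral_x() -> tuple[np.ndarray, str]:
    """BLOSUM62 as a dense int matrix; X scores 0 against everything."""
    mat = substitution_matrices.load("BLOSUM62")
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    n = len(alphabet)
    dense = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            if a == "X" or b == "X":
                dense[i, j] = 0
            else:
                dense[i, j] = int(mat[a][b])
    return dense, alphabet


_B62, _ALPHABET = _blosum62_with_neutral_x()
_AA_INDEX = {a: i for i, a in enumerate(_ALPHABET)}


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties and E-value constants.

    Gap of length L costs ``gap_open + L * gap_extend`` (BLAST convention for
    open 11 / extend 1).
    """

    matrix: np.ndarray = field(default_factory=lambda: _B62, repr=False)
    alphabet: str = _ALPHABET
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lambda_ <= 0 or self.K <= 0:
            raise ValueError("lambda_ and K must be positive")

    def encode(self, seq: str) -> np.ndarray:
        try:
            return np.fromiter(
                (_AA_INDEX[c] for c in seq), dtype=np.int64, count=len(seq)
            )
        except KeyError as e:  # pragma: no cover - records validate upstream
            raise ValueError(f"residue {e} not in alphabet") from None


@dataclass
class SimilarityHit:
    """One scored local-alignment hit between two proteins.

    ``aligned_query_fraction`` / ``aligned_subject_fraction`` are the mutual
    coverage fractions: residues of that sequence inside the local alignment
    (gap positions excluded) divided by its full length. They feed the
    dual-coverage match filter. Spans are 1-based inclusive.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    evalue: float
    percent_identity: float
    percent_similarity: float
    aligned_query_fraction: float
    aligned_subject_fraction: float
    query_span: tuple[int, int]
    subject_span: tuple[int, int]
    query_genome: str | None = None
    subject_genome: str | None = None

    @property
    def is_self(self) -> bool:
        return self.query_id == self.subject_id and (
            self.query_genome == self.subject_genome
        )

    def swapped(self) -> "SimilarityHit":
        """The same hit viewed from the subject's side."""
        return replace(
            self,
            query_id=self.subject_id,
            subject_id=self.query_id,
            aligned_query_fraction=self.aligned_subject_fraction,
            aligned_subject_fraction=self.aligned_query_fraction,
            query_span=self.subject_span,
            subject_span=self.query_span,
            query_genome=self.subject_genome,
            subject_genome=self.query_genome,
        )


def bit_score(raw: float, scheme: ScoringScheme | None = None) -> float:
    scheme = scheme or ScoringScheme()
    return (scheme.lambda_ * raw - math.log(scheme.K)) / math.log(2.0)


def evalue(bits: float, m: int, n: int) -> float:
    """Expected chance hits at `bits` in an m x n residue search space."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return float(m) * float(n) * 2.0 ** (-bits)


def _sw_matrices(a_idx, b_idx, scheme):
    """Affine-gap Smith-Waterman DP. Returns M, and traceback pointers.

    M[i, j] is the best score of a local alignment ending with column
    (a_i, b_j); Ix ends with a gap in the subject (consumes query), Iy with a
    gap in the query. Adjacent opposite gaps are disallowed, which can never
    reduce the optimum because two gap openings always cost more than the
    worst substitution.
    """
    la, lb = len(a_idx), len(b_idx)
    go, ge = scheme.gap_open + scheme.gap_extend, scheme.gap_extend
    neg = -(10**9)
    M = np.zeros((la + 1, lb + 1), dtype=np.int64)
    Ix = np.full((la + 1, lb + 1), neg, dtype=np.int64)
    Iy = np.full((la + 1, lb + 1), neg, dtype=np.int64)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # state feeding M's diag
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    sub = scheme.matrix[a_idx][:, b_idx]  # (la, lb) substitution scores
    for i in range(1, la + 1):
        prev_m, prev_x, prev_y = M[i - 1], Ix[i - 1], Iy[i - 1]
        # Ix: vertical gap, vectorised over j
        open_x = prev_m - go
        ext_x = prev_x - ge
        Ix[i] = np.maximum(open_x, ext_x)
        ptr_x[i] = np.where(open_x >= ext_x, _FROM_M, _FROM_IX)
        # M: diagonal; prefer M over Ix over Iy on ties (deterministic)
        diag_m = prev_m[:-1] + sub[i - 1]
        diag_x = prev_x[:-1] + sub[i - 1]
        diag_y = prev_y[:-1] + sub[i - 1]
        best = np.maximum(np.maximum(diag_m, diag_x), diag_y)
        state = np.where(
            diag_m >= best, _FROM_M, np.where(diag_x >= best, _FROM_IX, _FROM_IY)
        )
        # a diagonal move out of a zero M cell is the *start* of the alignment
        state = np.where((state == _FROM_M) & (prev_m[:-1] == 0), _STOP, state)
        started = best > 0
        M[i, 1:] = np.where(started, best, 0)
        ptr_m[i, 1:] = np.where(started, state, _STOP)
        # Iy: horizontal gap, sequential in j
        row_m, row_y = M[i], Iy[i]
        pm = ptr_y[i]
        for j in range(1, lb + 1):
            o = row_m[j - 1] - go
            e = row_y[j - 1] - ge
            if o >= e:
                row_y[j] = o
                pm[j] = _FROM_M
            else:
                row_y[j] = e
                pm[j] = _FROM_IY
    return M, (ptr_m, ptr_x, ptr_y)


def smith_waterman(
    a: str,
    b: str,
    scheme: ScoringScheme | None = None,
    *,
    query_id: str = "query",
    subject_id: str = "subject",
    m: int | None = None,
    n: int | None = None,
) -> SimilarityHit | None:
    """Optimal local alignment of ``a`` (query) against ``b`` (subject).

    Returns ``None`` when the optimal score is not positive. ``m``/``n``
    override the search-space dimensions for the E-value (defaults: the two
    sequence lengths). Ties between co-optimal alignments are resolved
    deterministically: highest score, then smallest (query end, subject end),
    then a fixed state preference during traceback.
    """
    scheme = scheme or ScoringScheme()
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a_idx, b_idx = scheme.encode(a), scheme.encode(b)
    M, (ptr_m, ptr_x, ptr_y) = _sw_matrices(a_idx, b_idx, scheme)
    raw = int(M.max())
    if raw <= 0:
        return None
    end_i, end_j = np.unravel_index(int(np.argmax(M)), M.shape)  # row-major:
    # argmax already picks the smallest (i, j) among ties.
    # traceback
    i, j, state = int(end_i), int(end_j), _FROM_M
    cols_a: list[int] = []  # -1 for gap
    cols_b: list[int] = []
    while True:
        if state == _FROM_M:
            prev = ptr_m[i, j]
            cols_a.append(a_idx[i - 1])
            cols_b.append(b_idx[j - 1])
            i, j = i - 1, j - 1
            state = prev
            if state == _STOP:
                break
        elif state == _FROM_IX:
            prev = ptr_x[i, j]
            cols_a.append(a_idx[i - 1])
            cols_b.append(-1)
            i -= 1
            state = _FROM_M if prev == _FROM_M else _FROM_IX
        elif state == _FROM_IY:
            prev = ptr_y[i, j]
            cols_a.append(-1)
            cols_b.append(b_idx[j - 1])
            j -= 1
            state = _FROM_M if prev == _FROM_M else _FROM_IY
        else:  # pragma: no cover
            raise AssertionError("bad traceback state")
    cols_a.reverse()
    cols_b.reverse()
    ncol = len(cols_a)
    ident = sum(1 for x, y in zip(cols_a, cols_b) if x >= 0 and x == y)
    simil = sum(
        1
        for x, y in zip(cols_a, cols_b)
        if x >= 0 and y >= 0 and scheme.matrix[x, y] > 0
    )
    a_res = sum(1 for x in cols_a if x >= 0)
    b_res = sum(1 for y in cols_b if y >= 0)
    q_span = (i + 1, int(end_i))
    s_span = (j + 1, int(end_j))
    bits = bit_score(raw, scheme)
    E = evalue(bits, m if m is not None else len(a), n if n is not None else len(b))
    return SimilarityHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=raw,
        bit_score=bits,
        evalue=E,
        percent_identity=100.0 * ident / ncol,
        percent_similarity=100.0 * simil / ncol,
        aligned_query_fraction=a_res / len(a),
        aligned_subject_fraction=b_res / len(b),
        query_span=q_span,
        subject_span=s_span,
    )


def align_all_pairs(A, B, scheme: ScoringScheme | None = None) -> list[SimilarityHit]:
    """Every ordered (query in A, subject in B) pair through the native aligner.

    The E-value search space uses n = total residues of B, the database side,
    mirroring a one-genome-vs-one-genome search.
    """
    scheme = scheme or ScoringScheme()
    if not len(A) or not len(B):
        raise ValueError("bundles must be non-empty")
    n_db = B.total_residues
    hits: list[SimilarityHit] = []
    for q in A:
        for s in B:
            h = smith_waterman(
                q.sequence,
                s.sequence,
                scheme,
                query_id=q.protein_id,
                subject_id=s.protein_id,
                m=q.length,
                n=n_db,
            )
            if h is not None:
                h.query_genome = A.genome_id
                h.subject_genome = B.genome_id
                hits.append(h)
    return hits
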