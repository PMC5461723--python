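"""Distance-based phylogenetics for the comparison trees.

Maximum-likelihood inference is deliberately replaced by neighbor joining on
corrected distances: the pipeline's congruence statements are purely
topological (Robinson-Foulds), which NJ supports while staying exact on
additive matrices and cheap enough to bootstrap. The multiple aligner is a
progressive stand-in: a k-mer-distance guide tree followed by profile-profile
global alignment (affine gaps, BLOSUM62).

Distances use pairwise deletion of gapped columns; the Poisson correction
``-ln(1 - p)`` is capped at p = 0.95 (distance 2.996) so saturated pairs keep
NJ defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode

from .align import ScoringScheme

__all__ = [
    "MSA",
    "progressive_align",
    "distance",
    "nj_tree",
    "bootstrap",
    "bipartitions",
    "robinson_foulds",
    "concatenate_homologs",
    "random_tree",
    "tree_distance_matrix",
    "evolve_sequences",
]

P_CAP = 0.95  # saturation cap for the Poisson correction
_AAS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class MSA:
    """Equal-length gapped rows over residues plus '-'."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    def to_dict(self) -> dict[str, str]:
        return dict(zip(self.ids, self.rows))

    def ungapped(self, taxon: str) -> str:
        return self.to_dict()[taxon].replace("-", "")


# ---------------------------------------------------------------- alignment

def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        out[w] = out.get(w, 0) + 1
    return out


def _kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    k = min(k, min(len(s) for s in seqs))
    counts = [_kmer_counts(s, k) for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum(
                min(c, counts[j].get(w, 0)) for w, c in counts[i].items()
            )
            denom = min(len(seqs[i]), len(seqs[j])) - k + 1
            D[i, j] = D[j, i] = 1.0 - shared / max(denom, 1)
    return D


def _profile(rows: list[str], aa_index: dict[str, int]) -> np.ndarray:
    """Column residue frequencies over the alphabet; gaps contribute nothing."""
    L = len(rows[0])
    prof = np.zeros((L, len(aa_index)))
    for r in rows:
        for i, c in enumerate(r):
            if c != "-":
                prof[i, aa_index[c]] += 1.0
    return prof / len(rows)


def _profile_align(
    rows_a: list[str], rows_b: list[str], scheme: ScoringScheme
) -> tuple[list[str], list[str]]:
    """Global profile-profile alignment (Gotoh, penalized end gaps).

    For two single sequences this reduces exactly to pairwise global
    alignment under the same scoring.
    """
    aa_index = {a: i for i, a in enumerate(scheme.alphabet)}
    pa, pb = _profile(rows_a, aa_index), _profile(rows_b, aa_index)
    sub = pa @ scheme.matrix @ pb.T  # (la, lb) expected column score
    la, lb = sub.shape
    go = float(scheme.gap_open + scheme.gap_extend)
    ge = float(scheme.gap_extend)
    neg = -1e18
    M = np.full((la + 1, lb + 1), neg)
    Ix = np.full((la + 1, lb + 1), neg)  # gap in B (A column vs gaps)
    Iy = np.full((la + 1, lb + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, la + 1):
        Ix[i, 0] = -go - ge * (i - 1)
    for j in range(1, lb + 1):
        Iy[0, j] = -go - ge * (j - 1)
    ptr_m = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptr_x = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    ptr_y = np.zeros((la + 1, lb + 1), dtype=np.uint8)
    for i in range(1, la + 1):
        prev_m, prev_x, prev_y = M[i - 1], Ix[i - 1], Iy[i - 1]
        dm = prev_m[:-1] + sub[i - 1]
        dx = prev_x[:-1] + sub[i - 1]
        dy = prev_y[:-1] + sub[i - 1]
        best = np.maximum(np.maximum(dm, dx), dy)
        M[i, 1:] = best
        ptr_m[i, 1:] = np.where(dm >= best, 1, np.where(dx >= best, 2, 3))
        ox = prev_m - go
        ex = prev_x - ge
        Ix[i] = np.maximum(ox, ex)
        ptr_x[i] = np.where(ox >= ex, 1, 2)
        row_m, row_y, py = M[i], Iy[i], ptr_y[i]
        for j in range(1, lb + 1):
            o = row_m[j - 1] - go
            e = row_y[j - 1] - ge
            if o >= e:
                row_y[j] = o
                py[j] = 1
            else:
                row_y[j] = e
                py[j] = 3
    # traceback from the best end state (prefer M on ties)
    i, j = la, lb
    end_scores = (M[i, j], Ix[i, j], Iy[i, j])
    state = (1, 2, 3)[int(np.argmax(end_scores))]
    cols: list[str] = []  # 'M', 'X' (A col + gap), 'Y' (gap + B col)
    while i > 0 or j > 0:
        if state == 1:
            cols.append("M")
            state = int(ptr_m[i, j])
            i, j = i - 1, j - 1
        elif state == 2:
            cols.append("X")
            state = int(ptr_x[i, j])
            i -= 1
        else:
            cols.append("Y")
            state = int(ptr_y[i, j])
            j -= 1
    cols.reverse()
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for c in cols:
        if c in ("M", "X"):
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
        if c in ("M", "Y"):
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k in range(len(rows_b)):
                out_b[k] += "-"
    return out_a, out_b


def progressive_align(
    seqs: dict[str, str] | list[tuple[str, str]],
    scheme: ScoringScheme | None = None,
) -> MSA:
    """Progressive multiple alignment: k-mer guide tree (UPGMA) + iterative
    profile-profile merges. Deterministic for a fixed input order."""
    scheme = scheme or ScoringScheme()
    items = list(seqs.items()) if isinstance(seqs, dict) else list(seqs)
    if len(items) < 2:
        raise ValueError("need at least two sequences to align")
    names = [n for n, _ in items]
    raw = [s for _, s in items]
    D = _kmer_distance_matrix(raw)
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")
    # each cluster holds (member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [raw[i]]) for i in range(len(raw))
    }
    nxt = len(raw)
    for a, b, _h, _n in Z:
        ma, ra = clusters.pop(int(a))
        mb, rb = clusters.pop(int(b))
        na, nb = _profile_align(ra, rb, scheme)
        clusters[nxt] = (ma + mb, na + nb)
        nxt += 1
    members, rows = clusters.popitem()[1]
    ordered = sorted(range(len(members)), key=lambda k: members[k])
    return MSA(
        ids=[names[members[k]] for k in ordered],
        rows=[rows[k] for k in ordered],
    )


# ---------------------------------------------------------------- distances

def distance(msa: MSA, model: str = "p") -> DistanceMatrix:
    """Pairwise distances from an MSA with pairwise deletion of gap columns.

    ``p``: proportion of differing comparable columns. ``poisson``:
    ``-ln(1 - p)`` with p capped at 0.95. A pair with zero comparable
    columns is an error.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    n = len(msa)
    if n < 2:
        raise ValueError("need at least two rows")
    arr = np.array([list(r) for r in msa.rows])
    gap = arr == "-"
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gap[i] & ~gap[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]} and {msa.ids[j]}"
                )
            p = float((arr[i][ok] != arr[j][ok]).sum()) / m
            if model == "poisson":
                p = min(p, P_CAP)
                d = -math.log(1.0 - p)
            else:
                d = p
            D[i, j] = D[j, i] = d
    return DistanceMatrix(D, ids=msa.ids)


# ----------------------------------------------------------------------- NJ

def _as_dm(D) -> DistanceMatrix:
    return D if isinstance(D, DistanceMatrix) else DistanceMatrix(D)


def nj_tree(D) -> TreeNode:
    """Neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion break on the lexicographically smallest sorted
    pair of node labels (internal nodes carry synthetic labels). Negative
    branch-length estimates are clamped to zero with the deficit shifted to
    the sister edge, preserving the path length through the joined pair.
    Returns an unrooted tree (trifurcating root) whose path distances
    reproduce any additive input matrix exactly.
    """
    dm = _as_dm(D)
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs at least three taxa")
    labels = list(dm.ids)
    nodes: dict[str, TreeNode] = {l: TreeNode(name=l) for l in labels}
    d: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                d[(a, b)] = d[(b, a)] = float(dm[a, b])
    active = sorted(labels)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * d[(a, b)] - r[a] - r[b]
                key = (q, a, b)  # active is sorted -> lexicographic ties
                if best is None or key < best:
                    best = key
        _q, a, b = best
        la = 0.5 * d[(a, b)] + (r[a] - r[b]) / (2 * (n - 2))
        lb = d[(a, b)] - la
        if la < 0:
            la, lb = 0.0, d[(a, b)]
        elif lb < 0:
            la, lb = d[(a, b)], 0.0
        new = f"_nj{counter}"
        counter += 1
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = la, lb
        nodes[new] = TreeNode(children=[na, nb])
        nodes[new].name = None
        for c in active:
            if c in (a, b):
                continue
            nd = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
            d[(new, c)] = d[(c, new)] = nd
        active = sorted([x for x in active if x not in (a, b)] + [new])
    x, y, z = active
    lx = 0.5 * (d[(x, y)] + d[(x, z)] - d[(y, z)])
    ly = 0.5 * (d[(x, y)] + d[(y, z)] - d[(x, z)])
    lz = 0.5 * (d[(x, z)] + d[(y, z)] - d[(x, y)])
    children = []
    for lbl, ln in ((x, lx), (y, ly), (z, lz)):
        nd = nodes.pop(lbl)
        nd.length = max(0.0, ln)
        children.append(nd)
    root = TreeNode(children=children)
    root.name = None
    return root


# -------------------------------------------------------------- topology

def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Internal bipartitions of an unrooted tree, canonicalised as the side
    not containing the lexicographically smallest leaf."""
    leaves = frozenset(t.name for t in tree.tips())
    ref = min(leaves)
    out: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        out.add(side if ref not in side else leaves - side)
    return out


def robinson_foulds(t1: TreeNode, t2: TreeNode) -> tuple[int, float]:
    """Symmetric bipartition difference and its normalisation by 2(n-3)."""
    l1 = {t.name for t in t1.tips()}
    l2 = {t.name for t in t2.tips()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    rf = len(b1 ^ b2)
    denom = 2 * (len(l1) - 3)
    return rf, (rf / denom if denom > 0 else 0.0)


def bootstrap(
    msa: MSA,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    model: str = "poisson",
) -> TreeNode:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement ``n_reps`` times; the support of
    each internal edge is the fraction of replicate trees containing its
    bipartition. Supports are written to the internal nodes' names (two
    decimals) and kept as a ``support`` attribute. Reproducible given seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    tree = nj_tree(distance(msa, model))
    L = msa.length
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(tree)}
    arr = np.array([list(r) for r in msa.rows])
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        rep_rows = ["".join(row) for row in arr[:, cols]]
        rep = MSA(ids=list(msa.ids), rows=rep_rows)
        try:
            rep_bps = bipartitions(nj_tree(distance(rep, model)))
        except ValueError:  # a replicate with no comparable columns
            continue
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = frozenset(msa.ids)
    ref = min(leaves)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) <= 1 or len(side) >= len(leaves) - 1:
            continue
        bp = side if ref not in side else leaves - side
        support = counts.get(bp, 0) / n_reps
        node.support = support
        node.name = f"{support:.2f}"
    return tree


def concatenate_homologs(groups: dict[str, list[str | None]]) -> dict[str, str]:
    """Concatenate per-taxon ordered homolog lists into poly-proteins.

    Every taxon must present the same number of slots; a missing slot
    (None) is filled with a gap-only placeholder of the slot's aligned
    length, which requires the present members of that slot to share one
    length.
    """
    n_slots = {len(v) for v in groups.values()}
    if len(n_slots) != 1:
        raise ValueError("inconsistent slot counts across taxa")
    (k,) = n_slots
    out = {t: "" for t in groups}
    for s in range(k):
        lens = {len(v[s]) for v in groups.values() if v[s] is not None}
        if not lens:
            raise ValueError(f"slot {s}: missing in every taxon")
        if len(lens) > 1 and any(v[s] is None for v in groups.values()):
            raise ValueError(
                f"slot {s}: ragged lengths with missing members - align the "
                "slot first"
            )
        pad = "-" * max(lens)
        for t, v in groups.items():
            out[t] += v[s] if v[s] is not None else pad
    return out


# ------------------------------------------------------------- simulation

def random_tree(
    taxa: list[str],
    rng: np.random.Generator,
    branch_range: tuple[float, float] = (0.05, 0.3),
) -> TreeNode:
    """Random unrooted binary topology with uniform branch lengths.

    Grown by sequential attachment: each new taxon splits a uniformly chosen
    existing edge. Used to produce additive matrices and simulated
    orthologs for consistency tests.
    """
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    lo, hi = branch_range
    root = TreeNode(children=[TreeNode(name=t) for t in taxa[:3]])
    for t in taxa[3:]:
        edges = [n for n in root.traverse(include_self=False)]
        host = edges[int(rng.integers(0, len(edges)))]
        parent = host.parent
        parent.remove(host)
        mid = TreeNode(children=[host, TreeNode(name=t)])
        parent.append(mid)
    for node in root.traverse(include_self=False):
        node.length = float(rng.uniform(lo, hi))
    return root


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Additive leaf-to-leaf path-length matrix of a tree."""
    return tree.tip_tip_distances()


def evolve_sequences(
    tree: TreeNode,
    length: int,
    rng: np.random.Generator,
    root_seq: str | None = None,
) -> dict[str, str]:
    """Evolve a protein down the tree by site-independent substitution.

    Per branch of length b, each site substitutes with probability
    ``1 - exp(-b)`` to a uniformly chosen different residue - a minimal
    Poisson-style model adequate for topology-recovery tests, not a
    realistic evolutionary model.
    """
    aas = np.array(list(_AAS))
    if root_seq is None:
        root = rng.integers(0, len(aas), size=length)
    else:
        idx = {a: i for i, a in enumerate(_AAS)}
        root = np.array([idx[c] for c in root_seq])
        length = len(root)
    out: dict[str, str] = {}

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            b = child.length or 0.0
            p = 1.0 - math.exp(-b)
            s = seq.copy()
            hit = rng.random(length) < p
            if hit.any():
                shift = rng.integers(1, len(aas), size=int(hit.sum()))
                s[hit] = (s[hit] + shift) % len(aas)
            if child.is_tip():
                out[child.name] = "".join(aas[s])
            else:
                walk(child, s)

    walk(tree, root)
    return out
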