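"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's dynamic-programming code paths: the
local-alignment oracle enumerates every possible alignment path explicitly,
so it is exponential and only usable for sequences of length <= ~8.
"""

from __future__ import annotations

from sulfopan.align import ScoringScheme


def brute_force_local_score(a: str, b: str, scheme: ScoringScheme | None = None) -> int:
    """Optimal local alignment score by exhaustive path enumeration.

    Every start cell is tried; from each, all interleavings of
    match/insert/delete moves are walked recursively with affine gap costs
    (open + k * extend). Adjacent opposite-direction gaps are excluded, which
    cannot change the optimum since two gap openings cost more than any
    substitution. The empty alignment scores 0.
    """
    scheme = scheme or ScoringScheme()
    S = scheme.matrix
    idx = {c: i for i, c in enumerate(scheme.alphabet)}
    open_cost = scheme.gap_open + scheme.gap_extend
    ext_cost = scheme.gap_extend
    la, lb = len(a), len(b)
    best = 0

    def rec(i: int, j: int, score: int, state: str) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < la and j < lb:
            rec(i + 1, j + 1, score + int(S[idx[a[i]], idx[b[j]]]), "M")
        if i < la and state != "Y":
            rec(i + 1, j, score - (ext_cost if state == "X" else open_cost), "X")
        if j < lb and state != "X":
            rec(i, j + 1, score - (ext_cost if state == "Y" else open_cost), "Y")

    for i in range(la):
        for j in range(lb):
            rec(i, j, 0, "start")
    return best
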