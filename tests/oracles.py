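"""Independent brute-force oracles used to cross-check the implementations.

Everything here enumerates exhaustively or leans on a third-party library,
never on the code path under test.
"""

from __future__ import annotations

import itertools

NEG = float("-inf")


def brute_global_align(
    a: str,
    b: str,
    matrix: dict,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Optimal global affine-gap score by enumerating every alignment path.

    States track whether the previous column was a gap in a / in b, so a gap
    of length k costs gap_open + k * gap_extend.  Exponential — lengths <= 6.
    """

    best = [NEG]

    def rec(i: int, j: int, state: int, score: float) -> None:
        # state: 0 = last column substitution/start, 1 = gap in a, 2 = gap in b
        if i == len(a) and j == len(b):
            if score > best[0]:
                best[0] = score
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, 0, score + matrix[(a[i], b[j])])
        if j < len(b):  # gap in a, consume b[j]
            cost = gap_extend + (gap_open if state != 1 else 0.0)
            rec(i, j + 1, 1, score - cost)
        if i < len(a):  # gap in b, consume a[i]
            cost = gap_extend + (gap_open if state != 2 else 0.0)
            rec(i + 1, j, 2, score - cost)

    rec(0, 0, 0, 0.0)
    return best[0]


def brute_scan(residues: str, position_sets) -> list[int]:
    """Position-by-position motif scan, written independently of the engine."""
    k = len(position_sets)
    out = []
    for i in range(len(residues) - k + 1):
        ok = True
        for off in range(k):
            if residues[i + off] not in position_sets[off]:
                ok = False
                break
        if ok:
            out.append(i)
    return out


def brute_expansions(position_sets) -> set[str]:
    return {"".join(p) for p in itertools.product(*position_sets)}


def single_linkage_splits(labels, dist):
    """Non-trivial splits of the single-linkage dendrogram (scipy)."""
    import numpy as np
    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(np.asarray(dist)), method="single")
    n = len(labels)
    members = {k: frozenset([labels[k]]) for k in range(n)}
    splits = set()
    for k, (x, y, _, _) in enumerate(Z):
        merged = members[int(x)] | members[int(y)]
        members[n + k] = merged
        if 1 < len(merged) < n - 1:
            splits.add(merged)
    return splits
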