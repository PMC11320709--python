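"""Independent brute-force oracles used to pin down the optimized kernels.

These deliberately avoid the implementation's code paths: the chaining
oracle enumerates precursor paths recursively, and the alignment oracle is
a plain full-matrix three-state DP with no banding or rolling rows.
"""

from functools import lru_cache

import numpy as np

from invmap.anchors import Anchor, AnchorSet

NEG = -(10 ** 9)


def valid_precursor(ai: Anchor, aj: Anchor, d: int) -> bool:
    """May aj precede ai in a chain?"""
    if aj.seq_id != ai.seq_id or aj.dr != ai.dr or aj.dg != ai.dg:
        return False
    if not 0 < ai.pg - aj.pg <= d:
        return False
    if ai.dr == ai.dg:
        return 0 < ai.pr - aj.pr <= d
    return 0 < aj.pr - ai.pr <= d


def brute_chain_lengths(anchors: list[Anchor], d: int) -> list[int]:
    """Longest valid precursor path ending at each anchor (path length)."""
    n = len(anchors)
    preds = [[j for j in range(n) if valid_precursor(anchors[i], anchors[j], d)]
             for i in range(n)]

    @lru_cache(maxsize=None)
    def longest(i: int) -> int:
        return 1 + max((longest(j) for j in preds[i]), default=0)

    return [longest(i) for i in range(n)]


def random_anchor_instance(rng: np.random.Generator,
                           max_anchors: int = 12) -> tuple[AnchorSet, int]:
    n = int(rng.integers(1, max_anchors + 1))
    anchors = [Anchor(pr=int(rng.integers(0, 30)), pg=int(rng.integers(0, 30)),
                      dr=int(rng.integers(0, 2)), dg=int(rng.integers(0, 2)),
                      seq_id=int(rng.integers(0, 2)))
               for _ in range(n)]
    d = int(rng.integers(3, 40))
    return AnchorSet.from_anchors(anchors), d


def gotoh_oracle(a: str, b: str, match=2, mismatch=-4, gap_open=-4,
                 gap_ext=-2) -> int:
    """Full-matrix three-state affine DP; gap of length L costs
    open + L*ext."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    I = [[NEG] * (m + 1) for _ in range(n + 1)]
    D = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0
    for j in range(1, m + 1):
        D[0][j] = gap_open + gap_ext * j
    for i in range(1, n + 1):
        I[i][0] = gap_open + gap_ext * i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], I[i - 1][j - 1],
                          D[i - 1][j - 1]) + s
            I[i][j] = max(M[i - 1][j] + gap_open + gap_ext,
                          I[i - 1][j] + gap_ext,
                          D[i - 1][j] + gap_open + gap_ext)
            D[i][j] = max(M[i][j - 1] + gap_open + gap_ext,
                          I[i][j - 1] + gap_open + gap_ext,
                          D[i][j - 1] + gap_ext)
    return max(M[n][m], I[n][m], D[n][m])
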