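"""Independent brute-force oracles used to check the implementation.

The Smith-Waterman oracle is a plain three-state affine-gap dynamic
program written directly from the recursion, sharing no code with the
package's alignment path.  Gap convention: a gap of length k costs
open + k * extend.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def sw_score_oracle(a: str, b: str, matrix, gap_open: int, gap_extend: int) -> int:
    """Maximum affine-gap local alignment score, floored at 0.

    Three-state recursion: M (match/mismatch), X (gap in b / deletion),
    Y (gap in a / insertion).  ``matrix`` maps residue pairs to scores
    (Biopython substitution_matrices object works).
    """
    la, lb = len(a), len(b)
    first = gap_open + gap_extend  # cost of opening a length-1 gap
    M = [[0.0] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    Y = [[NEG_INF] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]),
            )
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return int(best)


def expected_identity_mc(path_probs, length, n_rep, rng) -> float:
    """Monte-Carlo estimate of per-site identity along a substitution
    path under the uniform 20-state model."""
    import numpy as np

    same = 0
    total = 0
    for _ in range(n_rep):
        start = rng.integers(0, 20, size=length)
        cur = start.copy()
        for p in path_probs:
            hit = rng.random(length) < p
            for idx in np.nonzero(hit)[0]:
                new = rng.integers(0, 19)
                if new >= cur[idx]:
                    new += 1
                cur[idx] = new
        same += int((cur == start).sum())
        total += length
    return same / total
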