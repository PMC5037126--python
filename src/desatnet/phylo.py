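"""Distance-based companion tree for a sub-cluster of the network.

This is deliberately an approximation: distances are derived from
pairwise local alignments (not a multiple alignment) and the tree is
built with neighbor joining, so it complements the SSN view of a
sub-cluster rather than reproducing a maximum-likelihood analysis.
Bootstrap support is out of scope (it would require columnar resampling
of an MSA).

The distance transform is a Poisson-style correction of fractional
identity p with a 20-letter random-identity floor of 0.05:

    d = -ln( max(p - 0.05, eps) / 0.95 )

so identical sequences are at distance 0 and pairs at or below random
identity are capped at a finite ceiling set by ``eps``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .align import DEFAULT_SCHEME, ScoringScheme, smith_waterman
from .seqio import ProteinRecord

RANDOM_IDENTITY_FLOOR = 0.05
DEFAULT_EPS = 0.01


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray  # symmetric, zero diagonal, finite

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=list(self.ids), columns=list(self.ids))


def identity_distance(p: float, eps: float = DEFAULT_EPS) -> float:
    """Corrected distance from fractional identity (see module docstring)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("fractional identity must lie in [0, 1]")
    return -math.log(max(p - RANDOM_IDENTITY_FLOOR, eps) / (1 - RANDOM_IDENTITY_FLOOR))


def distance_matrix(
    records: Sequence[ProteinRecord],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    eps: float = DEFAULT_EPS,
) -> DistanceMatrix:
    """All-pairs corrected distances from local-alignment identities."""
    if len(records) < 3:
        raise ValueError("a tree needs at least 3 records")
    ordered = sorted(records, key=lambda r: r.id)
    n = len(ordered)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = smith_waterman(
                ordered[i].sequence, ordered[j].sequence, scheme,
                query_id=ordered[i].id, subject_id=ordered[j].id,
            )
            d[i, j] = d[j, i] = identity_distance(aln.pct_identity / 100.0, eps)
    return DistanceMatrix(tuple(r.id for r in ordered), d)


@dataclass
class TreeNode:
    name: str  # leaf id, or internal placeholder
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """Unrooted binary tree serialised as newick rooted at a trifurcation."""

    root: TreeNode
    n_negative_clamped: int = 0

    def leaves(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return sorted(out)

    def n_edges(self) -> int:
        count = 0
        stack = [self.root]
        while stack:
            node = stack.pop()
            count += len(node.children)
            stack.extend(c for c, _ in node.children)
        return count

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            inner = ",".join(
                f"{fmt(child)}:{length:.10g}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (keys sorted id pairs)."""
        dists: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            # leaf -> distance to `node`
            if node.is_leaf:
                return {node.name: 0.0}
            below: list[dict[str, float]] = []
            for child, length in node.children:
                sub = walk(child)
                below.append({leaf: d + length for leaf, d in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da in below[i].items():
                        for lb, db in below[j].items():
                            key = (min(la, lb), max(la, lb))
                            dists[key] = da + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return dists


def _clamp(x: float, counter: list[int]) -> float:
    if x < 0:
        counter[0] += 1
        return 0.0
    return x


def neighbor_joining(dm: DistanceMatrix) -> Tree:
    """Neighbor joining with Studier-Keppler branch lengths.

    Ties in the Q criterion are broken by the lexicographically smallest
    (then second-smallest) leaf label under each candidate pair, so the
    topology is independent of input order.  Negative branch lengths are
    clamped to zero with a warning; on additive inputs none occur and the
    input distances are reproduced exactly as tree path lengths.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.ids]
    # sort key: smallest leaf label in each active subtree
    keys: list[str] = list(dm.ids)
    d = dm.d.astype(float).copy()
    active = list(range(n))
    clamped = [0]
    internal = 0

    while len(active) > 3:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        m = len(active)
        best: tuple[float, str, str, int, int] | None = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                lo, hi = sorted((keys[i], keys[j]))
                cand = (q, lo, hi, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, _, i, j = best
        bi = _clamp(d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2)), clamped)
        bj = _clamp(d[i, j] - (d[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))), clamped)
        internal += 1
        parent = TreeNode(f"_nj{internal}", [(nodes[i], bi), (nodes[j], bj)])
        # new distances to the remaining nodes
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = (d[i, k] + d[j, k] - d[i, j]) / 2
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row) - 1] = new_row[:-1]
        d[: len(new_row) - 1, -1] = new_row[:-1]
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = sorted(active, key=lambda idx: keys[idx])
    bi = _clamp((d[i, j] + d[i, k] - d[j, k]) / 2, clamped)
    bj = _clamp((d[i, j] + d[j, k] - d[i, k]) / 2, clamped)
    bk = _clamp((d[i, k] + d[j, k] - d[i, j]) / 2, clamped)
    root = TreeNode("_njroot", [(nodes[i], bi), (nodes[j], bj), (nodes[k], bk)])
    if clamped[0]:
        warnings.warn(
            f"{clamped[0]} negative branch length(s) clamped to 0",
            UserWarning,
            stacklevel=2,
        )
    return Tree(root=root, n_negative_clamped=clamped[0])


def write_newick(tree: Tree, path) -> None:
    from pathlib import Path

    Path(path).write_text(tree.to_newick() + "\n")


def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t")


def read_distance_tsv(path) -> DistanceMatrix:
    """Square TSV with ids as both index and header (PHYLIP-style square
    dialect with a leading id column also accepted)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = tuple(str(i) for i in df.index)
    if tuple(str(c) for c in df.columns) != ids:
        raise ValueError("row and column ids disagree")
    return DistanceMatrix(ids, df.to_numpy(dtype=float))
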