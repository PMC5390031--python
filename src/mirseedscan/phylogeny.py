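"""Distance-based phylogenies: p-distance, neighbor joining, bootstrap.

Neighbor joining follows the Saitou-Nei agglomeration with deterministic
tie-breaking (lexicographically smallest label pair); on an additive
distance matrix it provably recovers the generating tree. Branch lengths
that come out negative are clamped to zero with the deficit moved to the
sister edge, a common display convention. Bootstrap support resamples
alignment columns with replacement, rebuilds the NJ tree per replicate,
and reports the percentage of replicates containing each internal
bipartition of the original tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "d", d)


class TreeNode:
    """Minimal rooted tree node; leaves carry labels."""

    __slots__ = ("label", "children", "support")

    def __init__(self, label=None):
        self.label = label
        self.children: list[tuple["TreeNode", float]] = []
        self.support = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> set:
        if self.is_leaf():
            return {self.label}
        out = set()
        for c, _ in self.children:
            out |= c.leaves()
        return out

    def to_newick(self, with_support: bool = False) -> str:
        def rec(node, length):
            if node.is_leaf():
                core = str(node.label)
            else:
                inner = ",".join(rec(c, ln) for c, ln in node.children)
                lab = ""
                if with_support and node.support is not None:
                    lab = f"{node.support:g}"
                core = f"({inner}){lab}"
            return core if length is None else f"{core}:{length:.6g}"

        return rec(self, None) + ";"


@dataclass
class SupportTree:
    root: TreeNode
    labels: tuple
    support: dict = field(default_factory=dict)   # bipartition -> %
    degenerate: bool = False

    def newick(self, with_support: bool = False) -> str:
        return self.root.to_newick(with_support=with_support)

    def bipartitions(self) -> set:
        return bipartitions(self.root)


def p_distance(records) -> DistanceMatrix:
    """Proportion of differing sites per pair, gaps pairwise-deleted.

    ``records`` are aligned, equal-length SequenceRecord-like objects
    ('-' treated as a gap). A pair with zero comparable positions raises.
    """
    labels = tuple(r.id for r in records)
    seqs = [r.sequence.upper() for r in records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned to equal length")
    arr = np.array([list(s) for s in seqs])
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (arr[i] != "-") & (arr[j] != "-")
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable positions for {labels[i]}/{labels[j]}"
                )
            d[i, j] = d[j, i] = float((arr[i][ok] != arr[j][ok]).sum()) / m
    return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> SupportTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    nodes = [TreeNode(lab) for lab in dm.labels]
    # sort key per active node: smallest leaf label beneath it
    keys = [str(lab) for lab in dm.labels]
    d = dm.d.copy()
    active = list(range(n))
    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        R = sub.sum(axis=1)
        Q = (r - 2) * sub - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = [
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in zip(*np.where(np.isclose(Q, qmin)))
            if a < b
        ]
        _, ai, bi = min(ties)
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = dij / 2 + (R[ai] - R[bi]) / (2 * (r - 2))
        lj = dij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        parent = TreeNode()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        new_d = (d[i, :] + d[j, :] - dij) / 2
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # resolve the final three nodes as a star with closed-form lengths
    i, j, k = active
    li = (d[i, j] + d[i, k] - d[j, k]) / 2
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2
    root = TreeNode()
    root.children = [
        (nodes[i], max(li, 0.0)),
        (nodes[j], max(lj, 0.0)),
        (nodes[k], max(lk, 0.0)),
    ]
    return SupportTree(root=root, labels=dm.labels)


def bipartitions(root: TreeNode) -> set:
    """Non-trivial bipartitions of the unrooted tree, each canonicalized
    as the side not containing the lexicographically smallest leaf."""
    all_leaves = root.leaves()
    n = len(all_leaves)
    anchor = min(map(str, all_leaves))
    out = set()

    def rec(node):
        if node.is_leaf():
            return {node.label}
        below = set()
        for c, _ in node.children:
            below |= rec(c)
        if 2 <= len(below) <= n - 2:
            side = below if anchor not in set(map(str, below)) else all_leaves - below
            out.add(frozenset(side))
        return below

    rec(root)
    return out


def bootstrap_support(
    records, replicates: int = 1000, seed: int = 0
) -> SupportTree:
    """NJ tree with bootstrap support on internal edges.

    Columns are resampled with replacement per replicate; support is the
    percentage of replicate NJ trees containing each bipartition of the
    tree built from the full alignment. Deterministic for a fixed seed.
    Alignments with no variation are flagged degenerate (supports are
    then arbitrary).
    """
    if replicates < 1:
        raise ValueError("need >= 1 replicate")
    dm = p_distance(records)
    tree = neighbor_joining(dm)
    degenerate = bool(np.allclose(dm.d, 0.0))
    original = bipartitions(tree.root)
    counts = dict.fromkeys(original, 0)
    rng = np.random.default_rng(seed)
    length = len(records[0].sequence)
    seqs = np.array([list(r.sequence.upper()) for r in records])
    labels = [r.id for r in records]
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        boot = seqs[:, cols]
        reps = [
            _FakeRecord(lab, "".join(row)) for lab, row in zip(labels, boot)
        ]
        try:
            bt = neighbor_joining(p_distance(reps))
        except ValueError:
            continue
        bp = bipartitions(bt.root)
        for b in original:
            if b in bp:
                counts[b] += 1
    support = {b: 100.0 * c / replicates for b, c in counts.items()}
    _annotate_support(tree.root, support)
    return SupportTree(
        root=tree.root, labels=dm.labels, support=support, degenerate=degenerate
    )


def _annotate_support(root: TreeNode, support: dict) -> None:
    all_leaves = root.leaves()
    n = len(all_leaves)
    anchor = min(map(str, all_leaves))

    def rec(node):
        if node.is_leaf():
            return {node.label}
        below = set()
        for c, _ in node.children:
            below |= rec(c)
        if 2 <= len(below) <= n - 2:
            side = below if anchor not in set(map(str, below)) else all_leaves - below
            key = frozenset(side)
            if key in support:
                node.support = support[key]
        return below

    rec(root)


class _FakeRecord:
    __slots__ = ("id", "sequence")

    def __init__(self, rid, seq):
        self.id = rid
        self.sequence = seq
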