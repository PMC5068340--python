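"""Tree-based verification: K2P distances, neighbour joining, bootstrap.

Assignments are cross-checked by topology: conspecific query and reference
sequences should form monophyletic groups in a neighbour-joining tree built
from Kimura two-parameter (K2P) distances — the standard barcoding distance,
which corrects observed transition (P) and transversion (Q) proportions for
multiple hits:

    d = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

Neighbour joining follows the Saitou–Nei agglomeration with the usual
Q-criterion; ties break on the smallest (i, j) index pair and negative
branch lengths are clamped to zero with the deficit moved to the sister
branch, so results are deterministic.  Bootstrap support is the percentage
of column-resampled replicates containing each bipartition of the full-data
tree.  Trees are :class:`skbio.TreeNode` objects and serialise to newick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode


class SaturationError(ValueError):
    """Distance undefined: substitutions have saturated the K2P correction."""


_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("AGCT"):  # purines 0/1, pyrimidines 2/3
    _CODE[ord(b)] = i


def _encode(seqs: Sequence[str]) -> np.ndarray:
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError("sequences must be equal length (aligned)")
    return _CODE[
        np.frombuffer("".join(s.upper() for s in seqs).encode(), dtype=np.uint8)
    ].reshape(len(seqs), lengths.pop())


def _k2p_from_counts(ts: float, tv: float, n: int) -> float:
    p, q = ts / n, tv / n
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0.0 or a2 <= 0.0:
        raise SaturationError(
            f"K2P distance undefined for P={p:.3f}, Q={q:.3f} (saturated)"
        )
    return -0.5 * math.log(a1 * math.sqrt(a2))


def k2p_distance(s1: str, s2: str) -> float:
    """K2P distance between two aligned sequences.

    Sites with N or a gap in either sequence are excluded; raises
    :class:`SaturationError` when the correction's logarithm is undefined
    and ``ValueError`` when no unambiguous shared site exists.
    """
    x = _encode([s1, s2])
    a, b = x[0], x[1]
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no unambiguous shared sites")
    diff = valid & (a != b)
    ts = int((diff & ((a >> 1) == (b >> 1))).sum())  # within purines/pyrimidines
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(ts, tv, n)


def p_distance(s1: str, s2: str) -> float:
    """Raw proportion of differing unambiguous shared sites."""
    x = _encode([s1, s2])
    a, b = x[0], x[1]
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no unambiguous shared sites")
    return float((valid & (a != b)).sum()) / n


def k2p_matrix(seqs: Sequence[str], labels: Sequence[str]) -> DistanceMatrix:
    """Pairwise K2P distance matrix over equal-length sequences."""
    if len(seqs) != len(labels):
        raise ValueError("labels and sequences differ in number")
    x = _encode(seqs)
    return _k2p_matrix_encoded(x, labels)


def _k2p_matrix_encoded(x: np.ndarray, labels: Sequence[str]) -> DistanceMatrix:
    n = x.shape[0]
    d = np.zeros((n, n))
    valid = x >= 0
    half = x >> 1
    for i in range(n - 1):
        v = valid[i] & valid[i + 1 :]
        diff = v & (x[i] != x[i + 1 :])
        ts = (diff & (half[i] == half[i + 1 :])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        nsites = v.sum(axis=1)
        for j_off in range(len(ts)):
            if nsites[j_off] == 0:
                raise ValueError("no unambiguous shared sites for a pair")
            d[i, i + 1 + j_off] = _k2p_from_counts(
                float(ts[j_off]), float(tv[j_off]), int(nsites[j_off])
            )
    d += d.T
    return DistanceMatrix(d, ids=list(labels))


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbour-joining tree (Saitou–Nei) from a distance matrix.

    Deterministic: on equal Q-criterion values the smallest (i, j) pair in
    the current matrix order is joined.  Negative branch lengths are clamped
    to zero, moving the deficit to the sister branch.  The result is the
    standard unrooted representation (trifurcating root) with ≥3 taxa.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data.astype(float).copy()
        labels = list(dm.ids)
    else:
        d = np.asarray(dm, dtype=float).copy()
        if d.ndim != 2 or d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
            raise ValueError("distance matrix must be square and symmetric")
        labels = [f"t{i + 1}" for i in range(d.shape[0])]
    n = d.shape[0]
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")

    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = q[iu]
        k = int(np.argmin(flat))  # first minimum = smallest (i, j)
        i, j = int(iu[0][k]), int(iu[1][k])

        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj

        du = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k_ for k_ in range(m) if k_ not in (i, j)]
        new_d = np.empty((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = du[keep]
        new_d[-1, -1] = 0.0
        d = new_d
        nodes = [nodes[k_] for k_ in keep] + [parent]

    # terminal star: unique resolution of the last three nodes
    a, b, c = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    root = TreeNode(children=[a, b, c])
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    return root


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def tree_path_lengths(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (additivity checks)."""
    return tree.tip_tip_distances()


def _bipartitions(tree: TreeNode, ref_leaf: str) -> set[frozenset[str]]:
    """Non-trivial bipartitions, each canonicalised as the side not
    containing ``ref_leaf`` (so rootings compare equal)."""
    leaves = frozenset(t.name for t in tree.tips())
    out = set()
    for s in tree.subsets():
        side = frozenset(s)
        if ref_leaf in side:
            side = leaves - side
        if 1 < len(side) < len(leaves) - 1:
            out.add(side)
    return out


@dataclass
class BootstrapResult:
    tree: TreeNode
    n_reps: int
    completed: int
    skipped: int


def bootstrap_support(
    seqs: Sequence[str],
    labels: Sequence[str],
    n_reps: int = 100,
    seed: int = 0,
) -> BootstrapResult:
    """NJ tree with bootstrap support percentages on internal nodes.

    Columns of the (equal-length) alignment are resampled with replacement
    per replicate; support for each internal edge of the full-data tree is
    the percentage of completed replicates containing its bipartition.
    Replicates with a saturated pair are skipped and counted.
    """
    if len(seqs) < 4:
        raise ValueError("bootstrap needs at least 4 sequences")
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    x = _encode(seqs)
    full = nj_tree(_k2p_matrix_encoded(x, labels))
    ref_leaf = min(labels)
    target = _bipartitions(full, ref_leaf)
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    completed = skipped = 0
    n_cols = x.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        try:
            rep_tree = nj_tree(_k2p_matrix_encoded(x[:, cols], labels))
        except (SaturationError, ValueError):
            skipped += 1
            continue
        completed += 1
        rep_bps = _bipartitions(rep_tree, ref_leaf)
        for bp in target & rep_bps:
            counts[bp] += 1

    leaves = frozenset(labels)
    for node in full.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if ref_leaf in side:
            side = leaves - side
        if side in counts and completed:
            node.name = str(round(100.0 * counts[side] / completed))
    return BootstrapResult(full, n_reps, completed, skipped)


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree (branch lengths, integer supports as internal labels)."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def monophyly_fraction(tree: TreeNode, groups: dict[str, set[str]]) -> float:
    """Fraction of groups whose leaves form a clade (either side of an edge).

    Singleton groups are trivially monophyletic.
    """
    if not groups:
        raise ValueError("no groups given")
    leaves = frozenset(t.name for t in tree.tips())
    sides = set()
    for s in tree.subsets():
        sides.add(frozenset(s))
        sides.add(leaves - frozenset(s))
    for t in tree.tips():  # single leaves are clades too
        sides.add(frozenset([t.name]))
    ok = sum(
        1
        for members in groups.values()
        if len(members) <= 1 or frozenset(members) in sides
    )
    return ok / len(groups)
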