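"""Neighbor-joining protein phylogenies with nonparametric bootstrap.

Distances are uncorrected p-distances over an aligned protein family
(pairwise gap deletion by default, complete deletion optionally).  Trees
are built by Saitou-Nei neighbor joining with a deterministic tie rule
(taxa are sorted lexicographically and the smallest (i, j) index pair wins
among equal Q values) and negative branch lengths clamped to zero.
Bootstrap support resamples alignment columns with replacement and reports
the percentage of replicate trees containing each internal bipartition of
the point-estimate tree.  Trees are carried as dendropy objects and
serialized as Newick with supports as internal-node labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import UndefinedDistanceError

GAP_CHARS = frozenset("-.")


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be nonnegative")


def p_distance(
    alignment: Mapping[str, str], gap_mode: str = "pairwise"
) -> DistanceMatrix:
    """Proportion of differing residues between each pair of aligned sequences.

    ``gap_mode='pairwise'`` drops, per pair, only the columns gapped in that
    pair; ``'complete'`` drops columns gapped in any sequence.
    """
    if gap_mode not in ("pairwise", "complete"):
        raise ValueError(f"gap_mode must be 'pairwise' or 'complete', got {gap_mode!r}")
    taxa = list(alignment)
    if len(taxa) < 2:
        raise ValueError("need >= 2 sequences")
    seqs = [alignment[t].upper() for t in taxa]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must be aligned (equal length)")
    keep = None
    if gap_mode == "complete":
        keep = [i for i in range(L) if all(s[i] not in GAP_CHARS for s in seqs)]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cols = keep if keep is not None else [
                k for k in range(L)
                if seqs[i][k] not in GAP_CHARS and seqs[j][k] not in GAP_CHARS
            ]
            if not cols:
                raise UndefinedDistanceError(
                    f"no comparable columns between {taxa[i]!r} and {taxa[j]!r}"
                )
            diff = sum(1 for k in cols if seqs[i][k] != seqs[j][k])
            d[i, j] = d[j, i] = diff / len(cols)
    return DistanceMatrix(taxa=taxa, d=d)


@dataclass
class PhyloTree:
    """An unrooted tree plus bootstrap supports for its internal edges.

    ``support`` maps a canonical bipartition (the frozenset of leaf labels
    on the smaller side, ties broken lexicographically) to a percentage.
    """

    tree: dendropy.Tree
    support: dict[frozenset[str], float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())


class _Node:
    __slots__ = ("label", "children")  # children: list[(child, branch_length)]

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []

    def newick(self) -> str:
        if not self.children:
            return _quote_label(self.label)
        inner = ",".join(
            f"{child.newick()}:{length:.6g}" for child, length in self.children
        )
        return f"({inner})"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ()[]:;,'\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining with the standard Q-criterion.

    Taxa are processed in lexicographic order; among equal minimal Q values
    the smallest (i, j) index pair is joined, so the output is fully
    deterministic.  Negative branch-length estimates are clamped to zero.
    """
    if len(dm.taxa) < 3:
        raise ValueError("neighbor joining requires >= 3 taxa")
    order = sorted(range(len(dm.taxa)), key=lambda i: dm.taxa[i])
    labels = [dm.taxa[i] for i in order]
    d = dm.d[np.ix_(order, order)].astype(float)
    nodes: list[_Node] = [_Node(label=lab) for lab in labels]

    while len(nodes) > 3:
        n = len(nodes)
        row_sums = d.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - row_sums[i] - row_sums[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d2 = np.zeros((n - 1, n - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]

    # final star join of the remaining three nodes (closed form)
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    b0 = max((d01 + d02 - d12) / 2.0, 0.0)
    b1 = max((d01 + d12 - d02) / 2.0, 0.0)
    b2 = max((d02 + d12 - d01) / 2.0, 0.0)
    root = _Node(children=[(nodes[0], b0), (nodes[1], b1), (nodes[2], b2)])
    newick = root.newick() + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return PhyloTree(tree=tree)


def _bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Canonical nontrivial bipartitions of an unrooted tree."""
    all_taxa = frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        other = all_taxa - side
        if len(side) < 2 or len(other) < 2:
            continue  # trivial split
        canonical = min(
            (side, other), key=lambda s: (len(s), tuple(sorted(s)))
        )
        out.add(canonical)
    return out


def topologies_equal(a: dendropy.Tree, b: dendropy.Tree) -> bool:
    return _bipartitions(a) == _bipartitions(b)


def bootstrap_support(
    alignment: Mapping[str, str],
    n_reps: int = 1000,
    seed: int = 0,
    gap_mode: str = "pairwise",
) -> PhyloTree:
    """NJ point-estimate tree with column-resampling bootstrap supports."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    taxa = sorted(alignment)
    seqs = {t: alignment[t] for t in taxa}
    point = nj_tree(p_distance(seqs, gap_mode))
    splits = _bipartitions(point.tree)
    hits = {s: 0 for s in splits}
    L = len(next(iter(seqs.values())))
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = {t: "".join(seqs[t][c] for c in cols) for t in taxa}
        try:
            rep = nj_tree(p_distance(resampled, gap_mode))
        except UndefinedDistanceError:
            continue
        rep_splits = _bipartitions(rep.tree)
        for s in splits:
            if s in rep_splits:
                hits[s] += 1
    point.support = {s: 100.0 * hits[s] / n_reps for s in splits}
    _annotate_support(point)
    return point


def _annotate_support(ptree: PhyloTree) -> None:
    """Write supports onto internal-node labels (rounded percentages)."""
    all_taxa = frozenset(leaf.taxon.label for leaf in ptree.tree.leaf_node_iter())
    for node in ptree.tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        canonical = min(
            (side, all_taxa - side), key=lambda s: (len(s), tuple(sorted(s)))
        )
        if canonical in ptree.support:
            node.label = f"{ptree.support[canonical]:.0f}"


def write_newick(ptree: PhyloTree) -> str:
    """Serialize to Newick: 6-significant-digit branch lengths, supports as
    internal labels, labels quoted when they contain Newick metacharacters."""
    return ptree.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    ).strip()


def support_table(ptree: PhyloTree):
    """Bipartition-support TSV companion to the Newick output."""
    import pandas as pd

    rows = [
        {"bipartition": "|".join(sorted(s)), "support_pct": round(pct, 2)}
        for s, pct in sorted(ptree.support.items(), key=lambda kv: sorted(kv[0]))
    ]
    return pd.DataFrame(rows, columns=["bipartition", "support_pct"])


def random_additive_tree(
    n_taxa: int, seed: int, min_branch: float = 0.02, max_branch: float = 0.3
) -> tuple[dendropy.Tree, DistanceMatrix]:
    """A random unrooted binary tree and its additive path-distance matrix.

    Used for NJ consistency experiments: on an additive matrix NJ must
    recover the generating topology.
    """
    rng = np.random.default_rng(seed)
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    nodes = [_Node(label=lab) for lab in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        bi, bj = rng.uniform(min_branch, max_branch, size=2)
        parent = _Node(children=[(nodes[i], bi), (nodes[j], bj)])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
    b = rng.uniform(min_branch, max_branch, size=len(nodes))
    root = _Node(children=[(nd, float(bl)) for nd, bl in zip(nodes, b)])
    tree = dendropy.Tree.get(data=root.newick() + ";", schema="newick")
    tree.is_rooted = False
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(tax[labels[i]], tax[labels[j]])
    return tree, DistanceMatrix(taxa=labels, d=d)
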