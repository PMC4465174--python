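"""Neighbor-joining population trees from divergence matrices, with
per-locus site-bootstrap support on internal edges.

The agglomeration is Saitou-Nei with the Q criterion. Determinism: taxa are
sorted lexicographically up front and Q ties are broken by the lowest
(row, column) index pair. Negative branch lengths are kept but flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_io import LocusAlignment, Population, SampleTable
from .errors import BootstrapError, InputError
from .popgen_stats import DivergenceMatrix, divergence_matrix, COMBINED


@dataclass
class TreeNode:
    label: str | None = None  # leaf label; None for internal nodes
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None  # percent, internal edges only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PopulationTree:
    """Unrooted tree over populations; rooted arbitrarily at the last join."""

    root: TreeNode
    statistic: str
    has_negative_branches: bool = False

    @property
    def leaf_labels(self) -> set[str]:
        return set(self.root.leaves())

    def path_lengths(self) -> dict[frozenset[str], float]:
        """Leaf-to-leaf path lengths (sum of branch lengths)."""
        dists: dict[frozenset[str], float] = {}

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.label: 0.0}  # type: ignore[dict-item]
            below: list[dict[str, float]] = []
            for child, blen in node.children:
                sub = walk(child)
                below.append({leaf: d + blen for leaf, d in sub.items()})
            for i in range(len(below)):
                for j in range(i + 1, len(below)):
                    for la, da_ in below[i].items():
                        for lb, db in below[j].items():
                            dists[frozenset({la, lb})] = da_ + db
            merged: dict[str, float] = {}
            for sub in below:
                merged.update(sub)
            return merged

        walk(self.root)
        return dists

    def bipartitions(self) -> set[frozenset[str]]:
        """Internal-edge leaf bipartitions, each canonicalized as the side
        not containing the lexicographically smallest leaf."""
        all_leaves = self.leaf_labels
        anchor = min(all_leaves)
        splits: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.label}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2:
                    canon = side if anchor not in side else all_leaves - side
                    splits.add(frozenset(canon))
                below |= side
            return below

        walk(self.root)
        return splits

    def _edge_map(self) -> dict[frozenset[str], TreeNode]:
        all_leaves = self.leaf_labels
        anchor = min(all_leaves)
        edges: dict[frozenset[str], TreeNode] = {}

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.label}  # type: ignore[arg-type]
            below: set[str] = set()
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= len(all_leaves) - 2 and not child.is_leaf:
                    canon = side if anchor not in side else all_leaves - side
                    edges[frozenset(canon)] = child
                below |= side
            return below

        walk(self.root)
        return edges

    def newick(self, with_support: bool = False, comment: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                label = node.label or ""
                return f"'{label}'" if any(c in label for c in " (),:;") else label
            inner = ",".join(
                f"{fmt(child)}:{blen:.6f}" for child, blen in node.children
            )
            sup = ""
            if with_support and node.support is not None:
                sup = (
                    f"[&support={node.support:.0f}]" if comment
                    else f"{node.support:.0f}"
                )
            return f"({inner}){sup}"

        return fmt(self.root) + ";"


def neighbor_joining(matrix: DivergenceMatrix) -> PopulationTree:
    """Saitou-Nei neighbor joining on a symmetric divergence matrix."""
    n = len(matrix.populations)
    if n < 2:
        raise InputError("neighbor joining needs >= 2 populations")
    if not np.all(np.isfinite(matrix.values)):
        raise InputError("divergence matrix contains NaN cells")
    labels = [f"{sp}|{ba}" for sp, ba in matrix.populations]
    order = sorted(range(n), key=lambda i: labels[i])
    labels = [labels[i] for i in order]
    dist = matrix.values[np.ix_(order, order)].astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=lab) for lab in labels]
    negative = False

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = dist.sum(axis=1)
        q = (r - 2) * dist - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among ties
        best = None
        best_q = np.inf
        for i in range(r):
            for j in range(i + 1, r):
                if q[i, j] < best_q - 1e-12:
                    best_q = q[i, j]
                    best = (i, j)
        i, j = best  # type: ignore[misc]
        li = dist[i, j] / 2 + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = dist[i, j] - li
        if li < 0 or lj < 0:
            negative = True
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        d_new = 0.5 * (dist[i] + dist[j] - dist[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        dist = np.vstack([dist[np.ix_(keep, keep)], d_new[keep]])
        dist = np.hstack([dist, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    if len(nodes) == 2:
        root = TreeNode(children=[(nodes[0], dist[0, 1]), (nodes[1], 0.0)])
    else:
        d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
        l0 = (d01 + d02 - d12) / 2
        l1 = (d01 + d12 - d02) / 2
        l2 = (d02 + d12 - d01) / 2
        if min(l0, l1, l2) < 0:
            negative = True
        root = TreeNode(children=[(nodes[0], l0), (nodes[1], l1), (nodes[2], l2)])
    if negative:
        warnings.warn("NJ produced negative branch lengths (kept)", stacklevel=2)
    return PopulationTree(root, matrix.statistic, has_negative_branches=negative)


def _resample_columns(aln: LocusAlignment, rng: np.random.Generator) -> LocusAlignment:
    cols = rng.integers(0, aln.length, size=aln.length)
    seqs = tuple("".join(s[c] for c in cols) for s in aln.seqs)
    return LocusAlignment(aln.locus_name, aln.ids, seqs)


def bootstrap_support(
    alignments: Mapping[str, LocusAlignment],
    samples: SampleTable,
    statistic: str,
    B: int = 100,
    seed: int = 0,
    populations: Sequence[Population] | None = None,
    scope: str = COMBINED,
) -> PopulationTree:
    """NJ tree on the observed data with site-bootstrap support.

    Each replicate resamples alignment columns with replacement
    independently within each locus, recomputes the divergence matrix and
    the NJ tree; support is the percentage of retained replicates whose
    tree contains the same internal leaf bipartition. Replicates whose
    matrix contains undefined cells are dropped and counted; more than 50%
    dropped raises a bootstrap error.
    """
    if B < 1:
        raise InputError("bootstrap needs B >= 1 replicates")
    observed = neighbor_joining(
        divergence_matrix(alignments, samples, statistic, populations, scope)
    )
    rng = np.random.default_rng(seed)
    split_hits: dict[frozenset[str], int] = {bp: 0 for bp in observed.bipartitions()}
    dropped = 0
    kept = 0
    for _ in range(B):
        resampled = {
            locus: _resample_columns(aln, rng) for locus, aln in alignments.items()
        }
        try:
            mat = divergence_matrix(resampled, samples, statistic, populations, scope)
            tree = neighbor_joining(mat)
        except InputError:
            dropped += 1
            continue
        kept += 1
        for bp in tree.bipartitions():
            if bp in split_hits:
                split_hits[bp] += 1
    if dropped > B / 2:
        raise BootstrapError(
            f"{dropped}/{B} bootstrap replicates undefined for {statistic}"
        )
    edges = observed._edge_map()
    for bp, node in edges.items():
        node.support = 100.0 * split_hits.get(bp, 0) / kept if kept else 0.0
    return observed


def read_matrix_tsv(path) -> DivergenceMatrix:
    """Read a square TSV written by :func:`popgen_stats.write_matrix_tsv`."""
    import csv

    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise InputError(f"{path}: empty matrix file")
    statistic = rows[0][0]
    labels = rows[0][1:]
    pops = [tuple(lab.split("|", 1)) if "|" in lab else (lab, "") for lab in labels]
    values = np.array([[float(v) for v in row[1:]] for row in rows[1:]])
    return DivergenceMatrix(statistic, pops, values, np.zeros_like(values, dtype=int))
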