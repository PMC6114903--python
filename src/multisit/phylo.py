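"""Desk-scale phylogenetics for mature SIT units.

p-distances over a protein alignment, neighbor joining (via scikit-bio),
Newick round-tripping and bipartition-based monophyly queries — enough to
ask the questions the multi-SIT duplication history poses (are units A and
B sisters to the exclusion of C? do a set of units form a single clade?)
without a full ML/bootstrap pipeline.
"""

from __future__ import annotations

import io
import warnings
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .motifs import GAP_CHARS

__all__ = [
    "p_distance_matrix",
    "nj_tree",
    "to_newick",
    "from_newick",
    "is_monophyletic",
    "tree_distance_matrix",
]


def p_distance_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Pairwise mismatch fractions over columns where both rows are residues.

    Raises for a pair sharing no non-gap column (their distance is
    undefined), naming the pair.
    """
    ids = list(alignment)
    rows = [np.frombuffer(alignment[i].encode(), dtype="S1") for i in ids]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
    gap = np.isin(rows, [g.encode() for g in GAP_CHARS])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            total = int(shared.sum())
            if total == 0:
                raise ValueError(f"no shared non-gap columns between {ids[i]!r} and {ids[j]!r}")
            mism = int((rows[i][shared] != rows[j][shared]).sum())
            d[i, j] = d[j, i] = mism / total
    return DistanceMatrix(d, ids)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Neighbor joining; negative branch-length estimates are clamped to 0."""
    if matrix.shape[0] < 3:
        raise ValueError(f"neighbor joining needs >= 3 taxa, got {matrix.shape[0]}")
    tree = nj(matrix)
    clamped = 0
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
            clamped += 1
    if clamped:
        warnings.warn(f"clamped {clamped} negative NJ branch length(s) to 0")
    return tree


def to_newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(text: str) -> TreeNode:
    return TreeNode.read(io.StringIO(text), format="newick")


def tree_distance_matrix(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    return tree.tip_tip_distances()


def is_monophyletic(tree: TreeNode, taxa: Sequence[str]) -> bool:
    """True iff some edge bipartition isolates exactly ``taxa``.

    The test is unrooted: a subset equal to the tip set *below* some node,
    or to its complement, counts.  Unknown taxa raise.
    """
    tips = {t.name for t in tree.tips()}
    subset = set(taxa)
    unknown = subset - tips
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if subset == tips or len(subset) == 1:
        return True
    for node in tree.non_tips(include_self=True):
        below = {t.name for t in node.tips()}
        if below == subset or tips - below == subset:
            return True
    return False
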