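"""Tree I/O, cophenetic distances, neighbor joining and single-copy core
family selection.

The strain phylogeny is consumed as a Newick string (any rooted tree with
branch lengths). The cophenetic distance between two strains is the total
branch length along the tree path between their leaves; it is the "lineage
distance" that the habitat clustering operates on. Where no tree is
available, a neighbor-joining tree can be built from any distance matrix as
a desk-scale stand-in for a maximum-likelihood phylogeny.
"""

from __future__ import annotations

from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed or fails validation."""


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick 1.0 string into a rooted tree.

    Every non-root node must carry a branch length and tip labels must be
    unique; violations raise :class:`NewickParseError`.
    """
    try:
        tree = TreeNode.read(StringIO(text), format="newick",
                             convert_underscores=False)
    except Exception as exc:  # skbio raises NewickFormatError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if any(n is None for n in names):
        raise NewickParseError("unlabeled tip in tree")
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise NewickParseError(
                f"missing branch length on node {node.name or '<internal>'}"
            )
        if node.length < 0:
            raise NewickParseError("negative branch length")
    return tree


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to a Newick 1.0 string (round-trips with parse)."""
    buf = StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def cophenetic_matrix(tree: TreeNode) -> DistanceMatrix:
    """Pairwise path-length distances between all leaves.

    d(i, j) is the sum of branch lengths on the unique i-j path; the result
    is symmetric with zero diagonal, labeled by tip name in sorted order so
    downstream artifacts are independent of tree traversal order.
    """
    dm = tree.tip_tip_distances()
    order = sorted(dm.ids)
    return dm.filter(order)


def nj_tree(dist: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    On an additive matrix this reconstructs the generating (unrooted)
    topology. Negative estimated branch lengths are clamped to zero with the
    deficit shifted to the adjacent branch.
    """
    if dist.shape[0] < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    return nj(dist, neg_as_zero=True)


def single_copy_core_families(ortho: pd.DataFrame) -> list[str]:
    """Families present in exactly one copy in every strain.

    ``ortho`` is a strains x families count matrix. Returns family ids in
    stable column order. These are the loci a concatenated species tree
    would be built from.
    """
    if ortho.size == 0:
        raise ValueError("orthogroup matrix is empty")
    mask = (ortho.to_numpy() == 1).all(axis=0)
    return [f for f, m in zip(ortho.columns, mask) if m]


def distance_matrix_from_frame(frame: pd.DataFrame) -> DistanceMatrix:
    """Build a labeled DistanceMatrix from a square labeled DataFrame."""
    if list(frame.index) != list(frame.columns):
        raise ValueError("distance table must have identical row/column labels")
    return DistanceMatrix(frame.to_numpy(dtype=float), list(frame.index))


def distance_matrix_to_frame(dm: DistanceMatrix) -> pd.DataFrame:
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))


def subset_distance_matrix(dm: DistanceMatrix, ids: Sequence[str]) -> DistanceMatrix:
    """Restrict a distance matrix to the given ids (in the given order)."""
    return dm.filter(list(ids))
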