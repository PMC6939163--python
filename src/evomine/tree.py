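"""Tree building and leaf-to-leaf distances.

The default method is neighbor-joining (via scikit-bio) on Poisson-
corrected protein distances, d = -ln(1 - p), where p is the mismatch
fraction over columns where both rows have a residue. NJ is exact on
additive matrices and deterministic, which is what the downstream label
rules need: they only compare relative distances on the tree. An adapter
around an external FastTree binary is provided for approximate-ML parity
on large families. Negative NJ branch lengths are clamped to zero.
"""

from __future__ import annotations

import math
import shutil
import subprocess
import tempfile
from io import StringIO
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .msa import Alignment

#: p is capped here before Poisson correction so that saturated pairs get a
#: large finite distance instead of infinity.
MAX_P_DISTANCE = 0.95


def p_distance_matrix(aln: Alignment) -> DistanceMatrix:
    """Pairwise mismatch fractions over shared non-gap columns."""
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    gap = np.frombuffer(b"-", dtype="S1")[0]
    n = aln.n_rows
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = (rows[i] != gap) & (rows[j] != gap)
            total = int(shared.sum())
            if total == 0:
                p = MAX_P_DISTANCE
            else:
                p = float((rows[i][shared] != rows[j][shared]).sum()) / total
            d[i, j] = d[j, i] = min(p, MAX_P_DISTANCE)
    return DistanceMatrix(d, ids=aln.ids)


def poisson_distance_matrix(aln: Alignment) -> DistanceMatrix:
    pd = p_distance_matrix(aln)
    data = -np.log(1.0 - pd.data)
    np.fill_diagonal(data, 0.0)
    return DistanceMatrix(data, ids=pd.ids)


def build_tree(aln: Alignment) -> TreeNode:
    """Neighbor-joining tree from the curated alignment.

    With exactly two rows a two-leaf cherry is returned with the pairwise
    distance split evenly. Negative branch lengths are clamped to zero.
    """
    if aln.n_rows < 2:
        raise ValueError("need at least two rows to build a tree")
    dm = poisson_distance_matrix(aln)
    if aln.n_rows == 2:
        half = dm[aln.ids[0], aln.ids[1]] / 2.0
        return TreeNode.read(
            StringIO(f"({aln.ids[0]}:{half},{aln.ids[1]}:{half});"),
            format="newick",
        )
    tree = nj(dm, neg_as_zero=True)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def patristic_distance(tree: TreeNode, leaf_a: str, leaf_b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    try:
        a = next(t for t in tree.tips() if t.name == leaf_a)
    except StopIteration:
        raise KeyError(f"leaf {leaf_a!r} not in tree") from None
    if leaf_a == leaf_b:
        return 0.0
    try:
        b = next(t for t in tree.tips() if t.name == leaf_b)
    except StopIteration:
        raise KeyError(f"leaf {leaf_b!r} not in tree") from None
    return float(a.distance(b))


def patristic_matrix(tree: TreeNode) -> DistanceMatrix:
    """All-pairs leaf distances (delegates to skbio's tip-to-tip walk)."""
    return tree.tip_tip_distances()


def root_for_display(tree: TreeNode, outgroup: str | None = None) -> TreeNode:
    """Midpoint-root a copy of the tree, or root at a named outgroup leaf.

    Trees stay unrooted internally; rooting is for export only.
    """
    tree = tree.copy()
    if outgroup is None:
        return tree.root_at_midpoint()
    node = next((t for t in tree.tips() if t.name == outgroup), None)
    if node is None:
        raise KeyError(f"outgroup leaf {outgroup!r} not in tree")
    return tree.root_at(node.parent)


def build_tree_fasttree(aln: Alignment, binary: str = "fasttree") -> TreeNode:
    """External approximate-ML adapter (FastTree on the curated alignment)."""
    if shutil.which(binary) is None:
        raise RuntimeError(f"{binary} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "aln.faa"
        with open(fasta, "w") as fh:
            for rid, row in zip(aln.ids, aln.rows):
                fh.write(f">{rid}\n{row}\n")
        proc = subprocess.run(
            [binary, str(fasta)], capture_output=True, text=True, check=True,
        )
    tree = TreeNode.read(StringIO(proc.stdout), format="newick")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree
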