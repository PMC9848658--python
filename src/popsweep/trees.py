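"""Genotype distances and neighbor-joining lineage trees.

Sample relatedness is summarised by the allele-sharing distance
d_ij = mean over co-called sites of |g_i − g_j| / 2 (dosages g in {0,1,2}),
and clustered with the Saitou–Nei neighbor-joining algorithm.  NJ is exact
on additive distance matrices, so the recovered tree reproduces every
pairwise input distance when the input is tree-like.  Trees are
:class:`skbio.TreeNode` objects; Newick I/O goes through scikit-bio.
"""

from __future__ import annotations

import io
import logging

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .variants import MISSING, VariantTable

logger = logging.getLogger(__name__)


def genotype_distance(table: VariantTable) -> DistanceMatrix:
    """Allele-sharing distance matrix between all samples.

    For each pair, the mean over sites called in both samples of
    |g_i − g_j|/2; 0 for identical genotypes, 1 for opposite homozygotes at
    every co-called site.

    Raises
    ------
    ValueError
        If some pair shares no co-called site (the distance is undefined).
    """
    g = table.genotypes
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (g[:, i] != MISSING) & (g[:, j] != MISSING)
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"samples {table.samples[i]!r} and {table.samples[j]!r} "
                    "share no co-called site")
            diff = np.abs(g[both, i].astype(float) - g[both, j]) / 2.0
            d[i, j] = d[j, i] = diff.mean()
    return DistanceMatrix(d, ids=table.samples)


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Standard Saitou–Nei agglomeration minimising
    Q_ij = (m−2)·d_ij − r_i − r_j with the two-point branch-length formulas;
    ties in Q are broken by the smallest (row, column) index pair and
    negative estimated branch lengths are clamped to zero (logged).  The
    result is an unrooted tree returned with a trifurcating root.
    """
    labels = list(dm.ids)
    m = len(labels)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = np.array(dm.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=lab) for lab in labels]
    n_clamped = 0

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2.0) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin == smallest (i, j) among ties
        i, j = np.unravel_index(int(np.argmin(q)), q.shape)
        if i > j:
            i, j = j, i
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2.0))
        vj = d[i, j] - vi
        if vi < 0 or vj < 0:
            n_clamped += 1
            vi, vj = max(vi, 0.0), max(vj, 0.0)
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = vi
        child_j.length = vj
        new = TreeNode(children=[child_i, child_j])
        d_new = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d = np.vstack([d[np.ix_(keep, keep)], d_new[keep][None, :]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [new]

    # resolve the final 3-node star with the two-point equations
    va = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    vb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    vc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    lengths = [va, vb, vc]
    if any(v < 0 for v in lengths):
        n_clamped += 1
        lengths = [max(v, 0.0) for v in lengths]
    for node, v in zip(nodes, lengths):
        node.length = v
    if n_clamped:
        logger.info("nj_tree: clamped negative branch lengths at %d joins",
                    n_clamped)
    return TreeNode(children=nodes)


def tree_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree."""
    return tree.tip_tip_distances()


def has_bipartition(tree: TreeNode, group: set[str]) -> bool:
    """True if some edge splits the leaves into ``group`` vs the rest."""
    all_tips = {t.name for t in tree.tips()}
    if not group < all_tips:
        return False
    other = all_tips - group
    for node in tree.non_tips(include_self=True):
        below = {t.name for t in node.tips()}
        if below == group or below == other:
            return True
    return False


def write_newick(tree: TreeNode, path=None) -> str:
    """Serialise a tree to Newick; returns the text (and writes if path given)."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_newick(source) -> TreeNode:
    """Parse Newick text (or a file path) into a tree.

    Malformed input raises scikit-bio's parse error, which reports the
    offending position.
    """
    if isinstance(source, str) and ("(" in source or ";" in source):
        return TreeNode.read(io.StringIO(source), format="newick")
    return TreeNode.read(str(source), format="newick")
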