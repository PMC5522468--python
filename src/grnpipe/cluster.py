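"""Hierarchical clustering of log-scale expression profiles into response clusters.

Genes are clustered by Euclidean distance between their sample profiles with
agglomerative linkage (complete by default; average and Ward available), and
the merge tree is cut into exactly ``k`` clusters.  Default ``k`` is 11,
mirroring the number of main response clusters typically resolved on a
~126-gene panel across a two-condition three-timepoint design.

Determinism: genes are sorted lexicographically before distances are
computed, so the assignment is invariant to input row order; cluster ids are
relabelled 1..k by first occurrence in lexicographic gene order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix

__all__ = ["ClusterAssignment", "cluster_genes", "to_newick"]

LINKAGES = ("complete", "average", "ward")


@dataclass
class ClusterAssignment:
    assignment: dict[str, int]  # gene -> cluster id (1..k)
    k: int
    linkage: str
    linkage_matrix: np.ndarray  # scipy linkage over the sorted gene list
    genes: list[str]  # lexicographically sorted leaf order

    def frame(self) -> pd.DataFrame:
        """Gene -> cluster table including the dendrogram leaf position
        (the row ordering a heatmap of this clustering would use)."""
        order = {g: i for i, g in enumerate(self.leaf_order())}
        return pd.DataFrame(
            {
                "gene": list(self.assignment),
                "cluster_id": list(self.assignment.values()),
                "leaf_position": [order[g] for g in self.assignment],
            }
        )

    def leaf_order(self) -> list[str]:
        """Genes in dendrogram leaf order."""
        leaves = hierarchy.leaves_list(self.linkage_matrix)
        return [self.genes[i] for i in leaves]

    def members(self, cluster_id: int) -> list[str]:
        return [g for g, c in self.assignment.items() if c == cluster_id]


def cluster_genes(m: ExpressionMatrix, k: int = 11, linkage: str = "complete") -> ClusterAssignment:
    """Cut the Euclidean agglomerative merge tree into exactly k gene clusters."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if k < 1:
        raise ValueError("k must be >= 1")
    genes = sorted(m.genes)
    if k > len(genes):
        raise ValueError(f"k={k} exceeds number of genes ({len(genes)})")
    X = m.values.loc[genes].to_numpy(dtype=float)
    dists = pdist(X, metric="euclidean")
    if k > 1 and len(genes) > 1 and np.all(dists == 0):
        raise ValueError("all gene profiles identical: no meaningful cut for k > 1")
    Z = hierarchy.linkage(dists, method=linkage)
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    # relabel by first occurrence in lexicographic order
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap) + 1
    assignment = {g: remap[lab] for g, lab in zip(genes, labels)}
    return ClusterAssignment(assignment=assignment, k=k, linkage=linkage, linkage_matrix=Z, genes=genes)


def cluster_samples(m: ExpressionMatrix, k: int, linkage: str = "complete") -> ClusterAssignment:
    """Cluster samples instead of genes (the transposed call)."""
    from .io import SampleDesign

    dummy = [SampleDesign(sample_id=g, condition="x", timepoint=1.0, replicate=1) for g in m.genes]
    frame = m.values.T.set_axis(m.genes, axis=1).set_axis(m.sample_ids, axis=0)
    mt = ExpressionMatrix(values=frame, design=dummy, scale="log2")
    return cluster_genes(mt, k=k, linkage=linkage)


def to_newick(assignment: ClusterAssignment) -> str:
    """Serialize the merge tree as Newick with branch lengths from merge heights."""
    tree = hierarchy.to_tree(assignment.linkage_matrix)
    names = assignment.genes

    def rec(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = rec(node.get_left(), node.dist)
        right = rec(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"
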