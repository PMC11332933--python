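"""Control-inclusive hierarchical clustering of z-scaled log2 expression.

Mirrors the heatmap-style analysis: subset to the top-CV genes, z-scale each
gene row of the log2 matrix, then cluster samples (or genes) with average
linkage (UPGMA) on Pearson distances d = 1 - r.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage, to_tree
from scipy.spatial.distance import squareform

from .io_metadata import ExpressionMatrix


def zscale_rows(matrix_log2: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0, SD 1 (n-1 SD); constant rows are dropped."""
    if matrix_log2.n_samples < 2:
        raise ValueError("z-scaling needs >= 2 samples")
    sds = matrix_log2.values.std(axis=1, ddof=1)
    keep = sds > 0
    if not np.all(keep):
        dropped = [g for g, k in zip(matrix_log2.gene_ids, keep) if not k]
        warnings.warn(
            f"{len(dropped)} constant gene row(s) dropped before scaling "
            f"(first: {dropped[0]!r})",
            stacklevel=2,
        )
    values = matrix_log2.values[keep]
    means = values.mean(axis=1, keepdims=True)
    scaled = (values - means) / values.std(axis=1, ddof=1, keepdims=True)
    gene_ids = [g for g, k in zip(matrix_log2.gene_ids, keep) if k]
    return ExpressionMatrix(scaled, gene_ids, matrix_log2.sample_ids, nonnegative=False)


def pearson_distance(matrix: ExpressionMatrix, axis: str = "samples") -> np.ndarray:
    """Pairwise 1 - Pearson correlation between samples (columns) or genes (rows)."""
    if axis not in ("samples", "genes"):
        raise ValueError(f"axis must be 'samples' or 'genes', got {axis!r}")
    vectors = matrix.values.T if axis == "samples" else matrix.values
    names = matrix.sample_ids if axis == "samples" else matrix.gene_ids
    if vectors.shape[0] < 2:
        raise ValueError(f"need >= 2 {axis} for a distance matrix")
    sds = vectors.std(axis=1)
    for name, sd in zip(names, sds):
        if sd == 0:
            raise ValueError(f"zero-variance vector {name!r}: correlation undefined")
    dist = 1.0 - np.corrcoef(vectors)
    dist = (dist + dist.T) / 2.0  # symmetrize away rounding
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


@dataclass
class Dendrogram:
    """UPGMA merge tree: scipy linkage matrix plus the leaf names."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format
    leaf_ids: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.leaf_ids[i] for i in leaves_list(self.linkage_matrix)]

    def cophenetic(self) -> np.ndarray:
        return squareform(cophenet(self.linkage_matrix))

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights (height = 2x depth)."""
        tree = to_tree(self.linkage_matrix)

        def walk(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_ids[node.id]}:{length:.10g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return walk(tree, tree.dist).rsplit(":", 1)[0] + ";"

    def to_json(self, path: str | Path) -> None:
        tree = to_tree(self.linkage_matrix)

        def walk(node) -> dict:
            if node.is_leaf():
                return {"leaf": self.leaf_ids[node.id], "height": 0.0}
            return {
                "height": float(node.dist),
                "children": [walk(node.left), walk(node.right)],
            }

        payload = {"leaf_ids": self.leaf_ids, "tree": walk(tree)}
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def average_linkage(dist: np.ndarray, leaf_ids: list[str]) -> Dendrogram:
    """UPGMA agglomeration of a square distance matrix."""
    dist = np.asarray(dist, dtype=float)
    if dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0, atol=1e-12):
        raise ValueError("distance matrix must have a zero diagonal")
    if dist.shape[0] != len(leaf_ids):
        raise ValueError("leaf_ids length does not match distance matrix")
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="average")
    return Dendrogram(linkage_matrix=z, leaf_ids=list(leaf_ids))


def hierarchical_cluster(
    matrix_log2: ExpressionMatrix, axis: str = "samples"
) -> Dendrogram:
    """z-scale rows, take Pearson distances along ``axis``, run UPGMA."""
    scaled = zscale_rows(matrix_log2)
    dist = pearson_distance(scaled, axis=axis)
    leaf_ids = scaled.sample_ids if axis == "samples" else scaled.gene_ids
    return average_linkage(dist, list(leaf_ids))
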