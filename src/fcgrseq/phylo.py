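"""Distance-based phylogeny: distance matrices, hierarchical-clustering
trees with Newick export, classical MDS, and Robinson–Foulds comparison.

Trees are built by agglomerative clustering of the embedded sequence
vectors (one vector per whole input sequence, no chunking), by default
with average linkage on cosine distances. Robinson–Foulds distance is
computed on the unrooted interpretation of both trees as the size of the
symmetric difference of their non-trivial bipartition sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from io import StringIO

import dendropy
import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

METRICS = {"cosine": "cosine", "euclidean": "euclidean", "manhattan": "cityblock"}
LINKAGES = ("average", "complete", "single", "ward")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with leaf labels and the metric name."""

    labels: list[str]
    D: np.ndarray
    metric: str

    def condensed(self) -> np.ndarray:
        return ssd.squareform(self.D, checks=False)


@dataclass
class Tree:
    """Rooted binary merge tree from hierarchical clustering.

    ``Z`` is a scipy linkage matrix; leaf i carries ``labels[i]``. Merge
    heights are non-decreasing from leaves to root; Newick branch lengths
    are parent height minus child height.
    """

    Z: np.ndarray
    labels: list[str]

    def to_newick(self, branch_lengths: bool = True) -> str:
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        for j, row in enumerate(self.Z):
            heights[n + j] = float(row[2])

        def render(node: int, parent_height: float) -> str:
            if node < n:
                body = self.labels[node].replace(" ", "_")
            else:
                a, b = int(self.Z[node - n, 0]), int(self.Z[node - n, 1])
                h = heights[node]
                body = f"({render(a, h)},{render(b, h)})"
            if branch_lengths:
                return f"{body}:{parent_height - heights[node]:.10g}"
            return body

        root = n + len(self.Z) - 1
        if branch_lengths:
            a, b = int(self.Z[-1, 0]), int(self.Z[-1, 1])
            h = heights[root]
            return f"({render(a, h)},{render(b, h)});"
        return render(root, 0.0) + ";"


def distance_matrix(
    vectors: np.ndarray, labels: list[str], metric: str = "cosine"
) -> DistanceMatrix:
    """Pairwise distances between embedded vectors.

    Cosine distance is 1 - u.v/(|u||v|), range [0, 2]; a zero vector has no
    direction, so cosine distance rejects it by id.
    """
    vectors = np.asarray(vectors, dtype=float)
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}")
    if len(vectors) != len(labels):
        raise ValueError("vectors and labels must have equal length")
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    if metric == "cosine":
        norms = np.linalg.norm(vectors, axis=1)
        if (norms == 0).any():
            bad = labels[int(np.argmin(norms))]
            raise ValueError(f"zero vector ({bad!r}) has no cosine distance")
    D = ssd.squareform(ssd.pdist(vectors, metric=METRICS[metric]))
    np.fill_diagonal(D, 0.0)
    return DistanceMatrix(labels=list(labels), D=D, metric=metric)


def build_tree(dm: DistanceMatrix, linkage: str = "average") -> Tree:
    """Agglomerative clustering of a distance matrix (default average
    linkage, UPGMA-style). Deterministic; scipy breaks merge ties by the
    smallest pair indices."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if len(dm.labels) < 2:
        raise ValueError("need at least 2 leaves to build a tree")
    Z = sch.linkage(dm.condensed(), method=linkage)
    return Tree(Z=Z, labels=list(dm.labels))


def classical_mds(
    dm: DistanceMatrix, dims: int = 2, return_eigenvalues: bool = False
):
    """Classical (Torgerson) multidimensional scaling.

    Double-centres the squared-distance matrix, B = -1/2 J D∘D J, and embeds
    on the top ``dims`` eigenpairs. Negative eigenvalues (non-Euclidean
    distances) are truncated to zero; coordinates are centred at the origin
    with each column's sign fixed so its largest-magnitude entry is
    positive. Distances that are exactly Euclidean-embeddable in ``dims``
    dimensions are reproduced to machine precision.
    """
    D = np.asarray(dm.D, dtype=float)
    n = D.shape[0]
    if n <= dims:
        raise ValueError(f"need more than dims={dims} points, got {n}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D * D) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1][:dims]
    vals = np.clip(eigvals[order], 0.0, None)
    vecs = eigvecs[:, order]
    coords = vecs * np.sqrt(vals)
    idx = np.argmax(np.abs(coords), axis=0)
    signs = np.sign(coords[idx, np.arange(dims)])
    signs[signs == 0] = 1.0
    coords = coords * signs
    if return_eigenvalues:
        return coords, np.clip(np.sort(eigvals)[::-1], 0.0, None)
    return coords


def _as_dendropy(tree, taxon_namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    if isinstance(tree, Tree):
        tree = tree.to_newick()
    if isinstance(tree, str):
        return dendropy.Tree.get(
            data=tree, schema="newick", taxon_namespace=taxon_namespace,
            preserve_underscores=True
        )
    if isinstance(tree, dendropy.Tree):
        return dendropy.Tree.get(
            data=tree.as_string(schema="newick"),
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
        )
    raise TypeError(f"cannot interpret {type(tree)!r} as a tree")


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an (unrooted) tree, each canonicalised
    as the frozenset of leaf names on the side not containing the first
    taxon in sorted order."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    all_leaves, ref = frozenset(leaves), leaves[0]
    splits: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def robinson_foulds(t1, t2) -> int:
    """Robinson–Foulds distance: bipartitions present in exactly one tree.

    Accepts :class:`Tree` objects, Newick strings, or dendropy trees; leaf
    sets must coincide.
    """
    ns = dendropy.TaxonNamespace()
    d1, d2 = _as_dendropy(t1, ns), _as_dendropy(t2, ns)
    leaves1 = {lf.taxon.label for lf in d1.leaf_node_iter()}
    leaves2 = {lf.taxon.label for lf in d2.leaf_node_iter()}
    if leaves1 != leaves2:
        raise ValueError(
            f"leaf sets differ: {sorted(leaves1 ^ leaves2)}"
        )
    return len(bipartitions(d1) ^ bipartitions(d2))


def read_newick(path) -> dendropy.Tree:
    """Read one tree from a Newick file."""
    with open(path) as handle:
        return dendropy.Tree.get(
            file=StringIO(handle.read()), schema="newick", preserve_underscores=True
        )
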