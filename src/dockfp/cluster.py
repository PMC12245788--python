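"""Fingerprint comparison: all-against-all RMSD and Ward clustering.

Two ligands with similar binding patterns have similar Z-score fingerprints,
which is quantified by the root-mean-square deviation over the full shared
target list:

    R_{l,k} = sqrt( (1/N_t) * sum_i (Z_l(i) - Z_k(i))^2 )

This is the Euclidean distance between fingerprints scaled by 1/sqrt(N_t),
hence a true metric.  The resulting distance matrix is clustered with Ward
(minimum variance) agglomerative linkage; merge heights stay on the RMSD
scale, so a statement like "clusters separated at RMSD > 1.5" reads directly
off the dendrogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .fingerprint import FingerprintSet

log = logging.getLogger(__name__)


class ClusterError(ValueError):
    pass


@dataclass
class FingerprintDistanceMatrix:
    """Symmetric Eq.-style RMSD matrix between ligand fingerprints."""

    R: pd.DataFrame
    n_targets: int

    @property
    def ligands(self) -> list[str]:
        return list(self.R.index)

    def condensed(self) -> np.ndarray:
        return squareform(self.R.to_numpy(), checks=False)

    def to_csv(self, path: str | Path) -> None:
        self.R.to_csv(path, index_label="ligand_id")


@dataclass
class LinkageTree:
    """Agglomerative merge sequence in SciPy linkage form plus leaf labels.

    ``merges`` is the (n-1, 4) linkage array: merged cluster ids, merge
    height on the distance scale, and new cluster size.  Leaf i carries
    ``labels[i]``.
    """

    merges: np.ndarray
    labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2].copy()

    def cophenetic(self) -> pd.DataFrame:
        d = squareform(hierarchy.cophenet(self.merges))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.merges,
                          columns=["merge_a", "merge_b", "height", "size"])
        df["merge_a"] = df["merge_a"].astype(int)
        df["merge_b"] = df["merge_b"].astype(int)
        df["size"] = df["size"].astype(int)
        df.to_csv(path, index=False)


def fingerprint_rmsd(fps: FingerprintSet) -> FingerprintDistanceMatrix:
    """All-against-all fingerprint RMSD over the full shared target list.

    Computed over ALL common targets (never a curated subset): the larger
    set makes the pairwise comparison statistically robust.
    """
    if len(fps.ligands) < 2:
        raise ClusterError("need at least 2 ligands to compare fingerprints")
    Z = fps.Z.to_numpy(float)
    n_t = Z.shape[1]
    R = squareform(pdist(Z, metric="euclidean") / np.sqrt(n_t))
    df = pd.DataFrame(R, index=fps.ligands, columns=fps.ligands)
    return FingerprintDistanceMatrix(R=df, n_targets=n_t)


def ward_linkage(dm: FingerprintDistanceMatrix) -> LinkageTree:
    """Ward (minimum variance) agglomerative clustering of the RMSD matrix.

    Entries are treated as Euclidean distances (which fingerprint RMSDs are,
    up to the fixed 1/sqrt(N_t) factor) and merged with the standard
    Lance-Williams Ward update; heights are reported on the distance scale.
    The merge order is deterministic for a given matrix.
    """
    if len(dm.ligands) < 2:
        raise ClusterError("need at least 2 ligands to cluster")
    merges = hierarchy.linkage(dm.condensed(), method="ward")
    return LinkageTree(merges=merges, labels=list(dm.ligands))


def cut_tree(
    tree: LinkageTree, height: float | None = None, k: int | None = None
) -> pd.Series:
    """Flat cluster labels from a height or a cluster-count cut.

    Exactly one of ``height`` / ``k`` must be given.  Cutting at height h
    applies every merge strictly below h; cutting at k applies the first
    (n - k) merges.  Labels are contiguous integers from 0, assigned in
    leaf order of first appearance, so they are deterministic given the
    tree.
    """
    n = tree.n_leaves
    if (height is None) == (k is None):
        raise ClusterError("give exactly one of height= or k=")
    if k is not None:
        if not 1 <= k <= n:
            raise ClusterError(f"k must be in [1, {n}], got {k}")
        n_merges = n - k
    else:
        n_merges = int(np.sum(tree.merges[:, 2] < height))

    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n_merges):
        a, b = int(tree.merges[j, 0]), int(tree.merges[j, 1])
        parent[find(a)] = parent[find(b)] = n + j
    roots: dict[int, int] = {}
    labels = []
    for leaf in range(n):
        r = find(leaf)
        labels.append(roots.setdefault(r, len(roots)))
    return pd.Series(labels, index=tree.labels, name="cluster")


def _quantize(h: float) -> float:
    """Snap a height onto the 10-significant-digit grid the writer prints.

    Both the writer and the parser quantize heights the same way, so
    export -> parse -> re-export is a byte-identical fixed point.
    """
    return float(f"{float(h):.10g}")


def _node_entries(tree: LinkageTree):
    """(leaves, height, newick) for every cluster id, children ordered
    smaller-subtree-first then by alphabetical first leaf."""
    n = tree.n_leaves
    entries: dict[int, tuple[list[str], float]] = {
        i: ([tree.labels[i]], 0.0) for i in range(n)
    }
    texts: dict[int, str] = {i: tree.labels[i] for i in range(n)}
    for j, (a, b, raw_h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        h = _quantize(raw_h)
        kids = sorted(
            (a, b),
            key=lambda c: (len(entries[c][0]), min(entries[c][0])))
        parts = []
        for c in kids:
            blen = h - entries[c][1]
            parts.append(f"{texts[c]}:{blen:.10g}")
        node = n + j
        entries[node] = (entries[kids[0]][0] + entries[kids[1]][0], h)
        texts[node] = "(" + ",".join(parts) + ")"
    return texts[2 * n - 2]


def newick_export(tree: LinkageTree, out: str | Path) -> str:
    """Write the dendrogram as a rooted Newick string with branch lengths.

    A child's branch length is its parent's merge height minus its own
    (leaves sit at height 0), so leaf-to-ancestor path lengths reproduce the
    merge heights.  Children are ordered smaller-subtree-first, ties by
    alphabetical first leaf, making the output deterministic.
    """
    text = _node_entries(tree) + ";"
    Path(out).write_text(text + "\n")
    return text


def read_newick(source: str | Path) -> LinkageTree:
    """Parse a Newick dendrogram back into a LinkageTree.

    Assumes the binary, ultrametric trees this package writes.  Merge
    heights are recovered from root-to-leaf branch length sums; merges are
    ordered by height (ties by smallest contained leaf label), which
    reproduces the cophenetic structure exactly.
    """
    import dendropy

    path = Path(source)
    text = path.read_text() if path.exists() else str(source)
    t = dendropy.Tree.get(data=text, schema="newick")
    t.calc_node_root_distances()
    root_depth = max(lf.root_distance for lf in t.leaf_node_iter())

    internal = []
    for node in t.preorder_node_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            raise ClusterError("newick tree is not binary")
        height = _quantize(root_depth - node.root_distance)
        leaves = sorted(lf.taxon.label for lf in node.leaf_iter())
        internal.append((height, leaves, node))
    internal.sort(key=lambda e: (e[0], e[1][0]))

    labels = sorted(lf.taxon.label for lf in t.leaf_node_iter())
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    cluster_of: dict[int, int] = {}  # node id -> current cluster id

    def cluster_id(node) -> int:
        if node.is_leaf():
            return index[node.taxon.label]
        return cluster_of[id(node)]

    merges = np.zeros((n - 1, 4))
    sizes = {i: 1 for i in range(n)}
    for j, (height, _, node) in enumerate(internal):
        a, b = (cluster_id(c) for c in node.child_nodes())
        a, b = min(a, b), max(a, b)
        merges[j] = [a, b, height, sizes[a] + sizes[b]]
        sizes[n + j] = sizes[a] + sizes[b]
        cluster_of[id(node)] = n + j
    return LinkageTree(merges=merges, labels=labels)


def dendrogram_export(tree: LinkageTree, out: str | Path) -> None:
    """Render the dendrogram to an image file (format from the extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 0.4 * tree.n_leaves + 2))
    hierarchy.dendrogram(tree.merges, labels=tree.labels,
                         orientation="left", ax=ax)
    ax.set_xlabel("fingerprint RMSD (merge height)")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
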