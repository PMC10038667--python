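"""Tree inference and spectral comparison of MSA phylogenies.

Trees are inferred by neighbor joining on normalised Hamming distance
matrices (an approximate-ML program could be substituted via Newick
import; the tree-shape statistics of interest here are coarse). The
modified graph Laplacian (MGL) of a tree is D - Delta, where Delta is the
matrix of patristic distances (sum of branch lengths along the path
between two nodes) and D is the diagonal matrix of its row sums. Row sums
of the MGL vanish by construction, so 0 is always an eigenvalue; the
shape of the remaining spectrum summarises tree topology — densities
shifted right or with negative skewness correspond to "tippy" trees
(long tip branches), the opposite to "stemmy" trees rich in recent splits.

For deep MSAs the spectral density is bootstrap-aggregated: many trees
are inferred from random sub-MSAs and their MGL eigenvalues pooled into a
single density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .msa import Msa
from .msastats import pairwise_hamming

logger = logging.getLogger(__name__)


def nj_tree(distances: np.ndarray, labels: list[str]) -> TreeNode:
    """Neighbor-joining tree from a symmetric zero-diagonal distance matrix.

    Negative estimated branch lengths are clamped to zero (logged).
    On additive matrices NJ recovers the generating tree exactly.
    """
    distances = np.asarray(distances, dtype=np.float64)
    if distances.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    distances = (distances + distances.T) / 2.0  # guard float asymmetry
    dm = DistanceMatrix(distances, ids=list(labels))
    tree = nj(dm, neg_as_zero=True)
    n_clamped = sum(1 for n in tree.traverse()
                    if n.length is not None and n.length == 0.0)
    if n_clamped:
        logger.debug("%d zero-length branches after clamping", n_clamped)
    return tree


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def patristic_matrix(tree: TreeNode, nodes: str = "all") -> tuple[np.ndarray, list]:
    """Matrix of path branch-length sums between nodes of a tree.

    ``nodes="all"`` (default) includes internal nodes and leaves;
    ``nodes="leaves"`` restricts to tips. Returns (matrix, node list).
    """
    if nodes not in ("all", "leaves"):
        raise ValueError("nodes must be 'all' or 'leaves'")
    all_nodes = list(tree.traverse(include_self=True))
    index = {id(n): k for k, n in enumerate(all_nodes)}
    n = len(all_nodes)
    # adjacency of the unrooted graph with branch lengths
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for node in all_nodes:
        if node.parent is not None:
            u, v = index[id(node)], index[id(node.parent)]
            w = float(node.length or 0.0)
            adj[u].append((v, w))
            adj[v].append((u, w))
    full = np.zeros((n, n))
    for src in range(n):
        dist = np.full(n, np.nan)
        dist[src] = 0.0
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if np.isnan(dist[v]):
                    dist[v] = dist[u] + w
                    stack.append(v)
        full[src] = dist
    if nodes == "leaves":
        keep = [k for k, nd in enumerate(all_nodes) if nd.is_tip()]
        return full[np.ix_(keep, keep)], [all_nodes[k] for k in keep]
    return full, all_nodes


def mgl_matrix(tree: TreeNode, nodes: str = "all") -> np.ndarray:
    """Modified graph Laplacian D - Delta (symmetric, zero row sums)."""
    delta, _ = patristic_matrix(tree, nodes=nodes)
    return np.diag(delta.sum(axis=1)) - delta


def mgl_spectrum(tree: TreeNode, nodes: str = "all") -> np.ndarray:
    """Real eigenvalues of the MGL, sorted descending; 0 is always present."""
    return np.linalg.eigvalsh(mgl_matrix(tree, nodes=nodes))[::-1]


@dataclass
class SpectralDensity:
    """Pooled MGL eigenvalues with a Gaussian KDE and sample skewness."""

    eigenvalues: np.ndarray
    n_trees: int
    subsample: int
    bandwidth: float
    skewness: float

    def density(self, grid: np.ndarray) -> np.ndarray:
        kde = stats.gaussian_kde(self.eigenvalues, bw_method="scott")
        return kde(np.asarray(grid))


def tree_from_msa(msa: Msa) -> TreeNode:
    """Neighbor-joining tree on the MSA's normalised Hamming distances."""
    d = pairwise_hamming(msa.data)
    # NJ requires unique ids; also break exact-duplicate zero distances is fine
    labels = [f"{k}_{sid}" for k, sid in enumerate(msa.ids)]
    return nj_tree(d, labels)


def bootstrap_spectral_density(msa: Msa, n_trees: int = 200,
                               subsample: int = 500, seed: int = 0,
                               nodes: str = "all",
                               log_transform: bool = False) -> SpectralDensity:
    """Bootstrap-aggregated MGL spectral density of an MSA's phylogeny.

    Each replicate draws a uniform random sub-MSA of ``subsample``
    sequences (reduced to M with a warning if the MSA is shallower),
    infers a neighbor-joining tree, and pools the MGL eigenvalues across
    replicates. The kernel bandwidth follows Scott's rule; skewness is
    the adjusted Fisher–Pearson sample skewness. ``log_transform`` pools
    ln(eigenvalues) instead, dropping non-positive ones.
    """
    rng = np.random.default_rng(seed)
    if subsample > msa.depth:
        logger.warning("subsample %d exceeds MSA depth %d; using full MSA",
                       subsample, msa.depth)
        subsample = msa.depth
    pooled = []
    for _ in range(n_trees):
        rows = (rng.choice(msa.depth, size=subsample, replace=False)
                if subsample < msa.depth else np.arange(msa.depth))
        tree = tree_from_msa(msa.subset(rows))
        pooled.append(mgl_spectrum(tree, nodes=nodes))
    eig = np.concatenate(pooled)
    if log_transform:
        eig = np.log(eig[eig > 0])
    kde = stats.gaussian_kde(eig, bw_method="scott")
    return SpectralDensity(eigenvalues=eig, n_trees=n_trees,
                           subsample=subsample, bandwidth=float(kde.factor),
                           skewness=float(stats.skew(eig, bias=False)))
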