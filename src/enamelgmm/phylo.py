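"""Phylogenetic comparative layer.

Consumes a rooted molecular phylogeny with branch lengths (newick, via
dendropy) and species mean shapes, and provides:

* the Brownian-motion phylogenetic covariance matrix C (shared root-to-MRCA
  path lengths);
* the multivariate phylogenetic-signal statistic K (the multivariate
  generalization of Blomberg's K, expectation 1 under Brownian motion) with
  a tip-randomization permutation test;
* squared-change-parsimony ancestral shape estimation (equivalent to
  maximum likelihood under Brownian motion) by solving the stationarity
  system exactly;
* phylomorphospace projection: tips plus reconstructed internal nodes in a
  principal-component plane with tree edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .stats import PcaModel, pca as _pca

log = logging.getLogger(__name__)


@dataclass
class Phylogeny:
    """Rooted tree with branch lengths and unique tip labels."""

    tree: dendropy.Tree
    tip_labels: list[str]

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree, unit_lengths: bool = False) -> "Phylogeny":
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate tip labels")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                if unit_lengths:
                    edge.length = 1.0
                else:
                    raise ValueError(
                        "tree has missing branch lengths (required for K and "
                        "squared-change parsimony); pass unit_lengths=True to "
                        "assume unit branches"
                    )
            if edge.length < 0:
                raise ValueError("negative branch length")
        return cls(tree=tree, tip_labels=labels)

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def pruned_to(self, labels: list[str]) -> "Phylogeny":
        """Subtree spanning the given tips (unifurcations suppressed,
        branch lengths summed)."""
        keep = [l for l in self.tip_labels if l in set(labels)]
        if len(keep) < 2:
            raise ValueError("cannot prune tree below 2 tips")
        sub = self.tree.extract_tree_with_taxa_labels(
            labels=keep, suppress_unifurcations=True
        )
        return Phylogeny.from_dendropy(sub)

    def write_newick(self, path: str | Path) -> None:
        Path(path).write_text(
            self.tree.as_string(schema="newick", suppress_rooting=True)
        )


def read_newick(path: str | Path, unit_lengths: bool = False) -> Phylogeny:
    """Read a rooted newick tree with branch lengths; polytomies allowed."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    return Phylogeny.from_dendropy(tree, unit_lengths=unit_lengths)


def phylogeny_from_newick_string(s: str, unit_lengths: bool = False) -> Phylogeny:
    tree = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    return Phylogeny.from_dendropy(tree, unit_lengths=unit_lengths)


def phylo_covariance(phy: Phylogeny) -> tuple[np.ndarray, list[str]]:
    """Brownian-motion covariance: C[i, j] = root-to-MRCA path length.

    Returns (C, tip_order).
    """
    tree = phy.tree
    # depth of every node from the root
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    tips = list(tree.leaf_node_iter())
    order = [t.taxon.label for t in tips]
    n = len(tips)
    C = np.zeros((n, n))
    # C[i, j] = depth of MRCA(i, j); accumulate by postorder leaf-set sweep
    leafset: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafset[id(node)] = [order.index(node.taxon.label)]
            C[leafset[id(node)][0], leafset[id(node)][0]] = depth[id(node)]
        else:
            children = [leafset[id(ch)] for ch in node.child_nodes()]
            for a in range(len(children)):
                for b in range(a + 1, len(children)):
                    for i in children[a]:
                        for j in children[b]:
                            C[i, j] = C[j, i] = depth[id(node)]
            leafset[id(node)] = [i for ch in children for i in ch]
    return C, order


@dataclass
class KmultResult:
    k_obs: float
    p_perm: float
    n_perm: int
    permutation_distribution: np.ndarray
    seed: int


def _k_statistic(Y: np.ndarray, C: np.ndarray, Cinv: np.ndarray | None = None) -> float:
    """Multivariate K: ratio of observed to BM-expected deviation ratios."""
    n = C.shape[0]
    if Cinv is None:
        Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    denom_a = ones @ Cinv @ ones
    a = (ones @ Cinv @ Y) / denom_a          # GLS phylogenetic mean, (d,)
    D = Y - a
    mse0 = float(np.sum(D * D))              # tr(D' D)
    mse = float(np.sum(D * (Cinv @ D)))      # tr(D' C^-1 D)
    if mse0 <= 0:
        raise ValueError("all tip values identical; K undefined (zero variance)")
    expected = (np.trace(C) - n / denom_a) / (n - 1)
    return (mse0 / mse) / expected


def kmult(
    Y: np.ndarray,
    phy: Phylogeny,
    species: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> KmultResult:
    """Multivariate phylogenetic signal K with a permutation test.

    Parameters
    ----------
    Y:
        (N, d) species mean shapes (Procrustes coordinates or PC scores),
        rows ordered as ``species``.
    species:
        Species labels matching the tree's tips (intersected; species absent
        from the tree, or tips without data, are dropped with a log message).
    n_perm:
        Tip-randomization permutations (rows of Y shuffled across tips).

    The permutation p-value uses the add-one convention (the observed value
    is counted among the permutations), so it is never exactly zero.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.ndim != 2:
        raise ValueError("Y must be (N, d)")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    C, order = phylo_covariance(phy)
    common = [s for s in order if s in species]
    dropped_data = sorted(set(species) - set(order))
    dropped_tips = sorted(set(order) - set(species))
    if dropped_data or dropped_tips:
        log.info(
            "intersecting species with tree tips: dropped data rows %s, tips %s",
            dropped_data, dropped_tips,
        )
    if len(common) < 3:
        raise ValueError("need at least 3 species shared between data and tree")
    row_of = {s: i for i, s in enumerate(species)}
    Y = Y[[row_of[s] for s in common]]
    keep = [i for i, s in enumerate(order) if s in species]
    C = C[np.ix_(keep, keep)]
    # drop zero-variance columns
    var = Y.var(axis=0)
    if np.any(var == 0):
        log.warning("dropping %d zero-variance trait columns", int((var == 0).sum()))
        Y = Y[:, var > 0]
    if Y.shape[1] == 0:
        raise ValueError("all trait columns have zero variance")
    try:
        Cinv = np.linalg.inv(C)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular phylogenetic covariance matrix") from exc

    k_obs = _k_statistic(Y, C, Cinv)
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    dist = np.empty(n_perm)
    for b in range(n_perm):
        dist[b] = _k_statistic(Y[rng.permutation(n)], C, Cinv)
    p = (1 + int(np.sum(dist >= k_obs))) / (n_perm + 1)
    return KmultResult(
        k_obs=k_obs, p_perm=p, n_perm=n_perm,
        permutation_distribution=dist, seed=seed,
    )


@dataclass
class AncestralShapes:
    """Squared-change-parsimony estimates at internal nodes."""

    node_values: dict[str, np.ndarray]     # internal node id -> (d,) estimate
    root_id: str
    edges: list[tuple[str, str]]           # (parent, child) using node/tip ids
    tip_values: dict[str, np.ndarray]

    @property
    def root_value(self) -> np.ndarray:
        return self.node_values[self.root_id]

    def objective(self, lengths: dict[tuple[str, str], float]) -> float:
        """Sum over edges of squared change divided by branch length."""
        values = {**self.node_values, **self.tip_values}
        return float(
            sum(
                np.sum((values[p] - values[c]) ** 2) / lengths[(p, c)]
                for p, c in self.edges
            )
        )


def _node_ids(phy: Phylogeny) -> dict[int, str]:
    ids = {}
    k = 0
    for node in phy.tree.preorder_node_iter():
        if node.is_leaf():
            ids[id(node)] = node.taxon.label
        else:
            ids[id(node)] = f"node{k}"
            k += 1
    return ids


def squared_change_parsimony(
    phy: Phylogeny, Y: np.ndarray, species: list[str]
) -> AncestralShapes:
    """Ancestral values minimizing the branch-length-weighted squared change.

    Solves the exact sparse linear system whose stationarity conditions make
    every internal node the inverse-branch-length-weighted average of its
    neighbours, with tips fixed at the observed values.  Equivalent to the
    maximum-likelihood (generalized least squares) reconstruction under
    Brownian motion.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    row_of = {s: i for i, s in enumerate(species)}
    missing = [t for t in phy.tip_labels if t not in row_of]
    if missing:
        raise ValueError(f"tips without data: {missing}")
    ids = _node_ids(phy)
    internal = [n for n in phy.tree.preorder_node_iter() if not n.is_leaf()]
    pos = {id(n): k for k, n in enumerate(internal)}
    m = len(internal)
    d = Y.shape[1]
    A = np.zeros((m, m))
    rhs = np.zeros((m, d))
    edges: list[tuple[str, str]] = []
    for node in internal:
        i = pos[id(node)]
        neighbours = list(node.child_nodes())
        if node.parent_node is not None:
            neighbours.append(node.parent_node)
        for nb in neighbours:
            if nb is node.parent_node:
                length = node.edge.length
            else:
                length = nb.edge.length
            if length is None or length <= 0:
                length = 1e-8   # collapsed zero-length edge
                log.warning("zero-length internal edge treated as near-zero")
            w = 1.0 / length
            A[i, i] += w
            if nb.is_leaf():
                rhs[i] += w * Y[row_of[nb.taxon.label]]
            else:
                A[i, pos[id(nb)]] -= w
    for node in phy.tree.preorder_node_iter():
        for ch in node.child_nodes():
            edges.append((ids[id(node)], ids[id(ch)]))
    sol = np.linalg.solve(A, rhs)
    node_values = {ids[id(n)]: sol[pos[id(n)]] for n in internal}
    tip_values = {t: Y[row_of[t]] for t in phy.tip_labels}
    return AncestralShapes(
        node_values=node_values,
        root_id=ids[id(phy.tree.seed_node)],
        edges=edges,
        tip_values=tip_values,
    )


@dataclass
class Phylomorphospace:
    """Tree projected into the first principal components of species means."""

    pca: PcaModel
    tip_coords: dict[str, np.ndarray]      # label -> retained PC scores
    node_coords: dict[str, np.ndarray]
    root_id: str
    edges: list[tuple[str, str]]
    root_shape: np.ndarray                 # (p, 2) reconstructed root shape
    tip_shape_differences: dict[str, np.ndarray]   # tip shape - root shape

    def coords(self, node_id: str) -> np.ndarray:
        return self.tip_coords.get(node_id, self.node_coords.get(node_id))


def phylomorphospace(
    Y: np.ndarray,
    species: list[str],
    phy: Phylogeny,
    threshold: float = 0.99,
) -> Phylomorphospace:
    """Project tips and squared-change-parsimony node estimates onto PCs.

    A PCA of the species mean shapes defines the plane; ancestral estimates
    are computed on the retained scores (the reconstruction is linear, so
    this equals projecting coordinate-space reconstructions).  Also returns
    per-species shape differences versus the reconstructed root, for outline
    visualizations.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    model = _pca(Y, threshold=threshold)
    scores = model.retained_scores
    anc = squared_change_parsimony(phy, scores, species)
    tip_coords = {s: scores[i] for i, s in enumerate(species)}
    root_scores = anc.root_value
    root_flat = model.mean + root_scores @ model.vectors[:, : model.retained_m].T
    root_shape = root_flat.reshape(-1, 2)
    diffs = {
        s: Y[i].reshape(-1, 2) - root_shape for i, s in enumerate(species)
    }
    return Phylomorphospace(
        pca=model,
        tip_coords=tip_coords,
        node_coords=anc.node_values,
        root_id=anc.root_id,
        edges=anc.edges,
        root_shape=root_shape,
        tip_shape_differences=diffs,
    )


def species_mean_shapes(
    configs: np.ndarray, labels, taxa: list[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Species mean shapes after a fresh superimposition of the subset.

    Re-runs a generalized Procrustes superimposition on the selected
    specimens before averaging per species, so the means live in their own
    shape space (the convention used for phylogenetic-signal analyses).

    Parameters
    ----------
    configs:
        (n, p, 2) configurations (raw or previously aligned).
    labels:
        Per-specimen species labels.
    taxa:
        Optional subset of species to keep (e.g. the tree's 10 tips).

    Returns
    -------
    (N, 2p) matrix of species mean Procrustes coordinates and the species
    order.
    """
    from .procrustes import gpa

    labels = np.asarray([str(l) for l in labels])
    if taxa is not None:
        mask = np.isin(labels, list(taxa))
        configs = np.asarray(configs)[mask]
        labels = labels[mask]
    levels = [str(l) for l in np.unique(labels)]
    aligned = gpa(list(configs), slide=False)
    X = aligned.coords
    means = np.vstack([X[labels == l].mean(axis=0) for l in levels])
    return means, levels
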