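"""Taxonomy trees, Grafen branch lengths and Pagel's lambda.

The analysis has no dated phylogeny, only a ranked taxonomic hierarchy per
taxon (e.g. class/order/family/genus/species).  A tree is built from those
paths, given ultrametric branch lengths by the Grafen method (node height =
descendant-leaf count minus one, scaled to root height 1), and used to ask
whether model residuals carry phylogenetic signal: Pagel's lambda scales the
off-diagonal of the Brownian-motion covariance implied by the tree, with
lambda = 0 meaning independent residuals and lambda = 1 full Brownian
structure.  lambda is estimated by profile maximum likelihood on [0, 1] and
tested against the star tree (lambda = 0) with a chi-square(1) LRT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2

from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "build_tree",
    "grafen_lengths",
    "tree_covariance",
    "pagel_lambda",
    "lambda_lrt",
    "simulate_trait",
    "PhyloSignalResult",
]

_LOG2PI = float(np.log(2.0 * np.pi))
_RIDGE = 1e-10


@dataclass
class PhyloSignalResult:
    """Pagel's lambda estimate with its boundary LRT against the star tree."""

    lambda_hat: float
    loglik_tree: float
    loglik_star: float
    lrt_stat: float
    p: float


def build_tree(hierarchies: dict) -> dendropy.Tree:
    """Rooted tree from ranked hierarchy paths.

    Parameters
    ----------
    hierarchies : mapping taxon_id -> sequence of rank names from the root
        down (the taxon itself becomes the leaf below the last rank).
        Partial paths attach their leaf at the deepest resolvable node.

    The tree has one internal node per distinct (rank depth, name); the same
    name appearing at one depth under two different parents is an error.
    """
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    tree.seed_node.label = "root"
    nodes = {(): tree.seed_node}
    parent_of = {}
    for taxon_id in sorted(hierarchies, key=str):
        path = tuple(hierarchies[taxon_id])
        for depth in range(1, len(path) + 1):
            key = (depth, path[depth - 1])
            parent_key = (depth - 1, path[depth - 2]) if depth > 1 else ()
            if key in parent_of:
                if parent_of[key] != parent_key:
                    raise ValidationError(
                        f"node {path[depth - 1]!r} at rank depth {depth} has "
                        "conflicting parentage"
                    )
            else:
                parent_of[key] = parent_key
                parent = nodes[parent_key if depth > 1 else ()]
                child = parent.new_child()
                child.label = path[depth - 1]
                nodes[key] = child
        leaf_parent = nodes[(len(path), path[-1])] if path else tree.seed_node
        leaf = leaf_parent.new_child()
        leaf.taxon = taxon_ns.new_taxon(label=str(taxon_id))
    return tree


def grafen_lengths(tree: dendropy.Tree, rho: float = 1.0) -> dendropy.Tree:
    """Assign Grafen heights and branch lengths in place (and return tree).

    Node height = (number of descendant leaves - 1), scaled so the root has
    height 1, then raised to the power ``rho``; the branch above a node has
    length parent height - node height.  Every leaf ends at height 0, so the
    tree is ultrametric with depth 1.
    """
    leaves_below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leaves_below[node] = 1
        else:
            leaves_below[node] = sum(leaves_below[c] for c in node.child_nodes())
    total = leaves_below[tree.seed_node]
    if total < 2:
        raise InsufficientDataError("Grafen lengths need >= 2 leaves")
    for node in tree.preorder_node_iter():
        h = (leaves_below[node] - 1) / (total - 1)
        node.grafen_height = h**rho if h > 0 else 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.grafen_height - node.grafen_height
    tree.seed_node.edge.length = None
    return tree


def tree_covariance(tree: dendropy.Tree) -> tuple[list, np.ndarray]:
    """Brownian-motion covariance implied by a Grafen-scaled tree.

    Returns (leaf labels, V) where V[i, j] is the root-to-MRCA depth of
    leaves i and j (= 1 - Grafen height of the MRCA) and V[i, i] = 1.
    """
    if not hasattr(tree.seed_node, "grafen_height"):
        grafen_lengths(tree)
    leaves = [lf for lf in tree.leaf_node_iter()]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    V = np.zeros((n, n))
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = [index[id(node)]]
            continue
        children = [below[id(c)] for c in node.child_nodes()]
        depth = 1.0 - node.grafen_height
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                V[np.ix_(ia, ib)] = depth
                V[np.ix_(ib, ia)] = depth
        below[id(node)] = [i for ch in children for i in ch]
    np.fill_diagonal(V, 1.0)
    labels = [lf.taxon.label for lf in leaves]
    return labels, V


def _profile_loglik(lam, lam_eigs, ytil, xtil, n):
    d = 1.0 - lam + lam * lam_eigs
    if np.any(d <= 0):
        d = np.maximum(d, _RIDGE)
        logger.debug("singular lambda covariance; ridge %g applied", _RIDGE)
    mu = float(np.sum(xtil * ytil / d) / np.sum(xtil * xtil / d))
    r = ytil - mu * xtil
    sigma2 = float(np.sum(r * r / d) / n)
    sigma2 = max(sigma2, 1e-300)
    return -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0) - 0.5 * float(
        np.sum(np.log(d))
    )


def pagel_lambda(V: np.ndarray, values: np.ndarray, xatol: float = 1e-6) -> PhyloSignalResult:
    """ML estimate of Pagel's lambda for values observed at the tree's leaves.

    The Gaussian model has mean mu * 1 and covariance
    sigma^2 * [lambda * (V - diag V) + diag V]; mu and sigma^2 are profiled
    out analytically (GLS mean, ML variance) and lambda is maximised over
    [0, 1] by bounded one-dimensional search.  ``loglik_star`` is the
    likelihood at lambda = 0 (star tree: all taxa equally related).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        raise InsufficientDataError(f"Pagel's lambda needs >= 3 leaves, got {n}")
    if V.shape != (n, n):
        raise ValidationError("V and values dimensions differ")
    scale = np.sqrt(np.diag(V))
    Vn = V / np.outer(scale, scale)  # unit diagonal (no-op for Grafen trees)
    eigs, Q = np.linalg.eigh(Vn)
    ytil = Q.T @ values
    xtil = Q.T @ np.ones(n)
    obj = lambda lam: -_profile_loglik(lam, eigs, ytil, xtil, n)
    res = minimize_scalar(obj, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": xatol})
    candidates = [(float(res.x), -res.fun), (0.0, -obj(0.0)), (1.0, -obj(1.0))]
    lam_hat, ll_tree = max(candidates, key=lambda t: t[1])
    ll_star = -obj(0.0)
    lrt = max(0.0, 2.0 * (ll_tree - ll_star))
    return PhyloSignalResult(
        lambda_hat=lam_hat,
        loglik_tree=ll_tree,
        loglik_star=ll_star,
        lrt_stat=lrt,
        p=float(chi2.sf(lrt, df=1)),
    )


def lambda_lrt(result: PhyloSignalResult, mixture: bool = False) -> float:
    """P-value for the lambda LRT against the star tree.

    Default is the upper tail of chi-square(1) at the LRT statistic; since
    lambda = 0 sits on the parameter boundary this is conservative.  With
    ``mixture=True`` the 50:50 mixture of chi-square(0) and chi-square(1)
    reference is used instead.
    """
    if result.lrt_stat <= 0:
        return 1.0
    p = float(chi2.sf(result.lrt_stat, df=1))
    return 0.5 * p if mixture else p


def simulate_trait(
    V: np.ndarray, lam: float, sigma: float, rng: np.random.Generator, mu: float = 0.0
) -> np.ndarray:
    """Draw one trait vector from N(mu, sigma^2 * V(lambda)) on the tree."""
    n = V.shape[0]
    Vl = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    L = np.linalg.cholesky(Vl + _RIDGE * np.eye(n))
    return mu + sigma * (L @ rng.standard_normal(n))
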