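"""Phylogenetic signal in species-level traits: Pagel's lambda.

Under Brownian-motion trait evolution on a rooted tree with branch lengths,
tip values are multivariate normal with covariance proportional to C, where
C[i, i] is tip i's root-to-tip path length and C[i, j] the shared path
length of tips i and j.  Pagel's lambda multiplies the off-diagonal of C by
a factor in [0, 1]: lambda = 1 leaves the Brownian structure intact (full
phylogenetic signal), lambda = 0 renders tips independent (no signal).

For fixed lambda, the root state mu and rate sigma^2 have closed-form
generalized-least-squares ML estimates, so the likelihood is profiled over
lambda by bounded scalar search.  Likelihood-ratio statistics against the
boundary values give p0 (is there any signal?) and p1 (is the signal less
than fully Brownian?), referred to chi-square with 1 df — the standard
convention, conservative at the lambda = 0 boundary.

Because tree topology is itself uncertain, estimates are aggregated over a
set of candidate trees: mean and SD of lambda-hat, p0 and p1 per trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .table import TRAITS


def tree_covariance(tree: dendropy.Tree) -> tuple[np.ndarray, list[str]]:
    """Brownian tip covariance C and the tip-label order it is indexed by.

    C[i][j] for i != j is the root-to-MRCA path length of tips i and j;
    the diagonal holds root-to-tip path lengths.  Computed in one postorder
    sweep: every internal node at depth d contributes d as the covariance
    of all tip pairs split across its children.
    """
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate tip labels")
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        length = node.edge.length
        if length is None or length <= 0:
            raise ValueError("all branch lengths must be positive")
        depth[id(node)] = depth[id(node.parent_node)] + length

    tipsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            tipsets[id(node)] = [i]
            C[i, i] = depth[id(node)]
            continue
        child_sets = [tipsets.pop(id(ch)) for ch in node.child_nodes()]
        d = depth[id(node)]
        for a in range(len(child_sets)):
            for b in range(a + 1, len(child_sets)):
                ia = np.array(child_sets[a])
                ib = np.array(child_sets[b])
                C[np.ix_(ia, ib)] = d
                C[np.ix_(ib, ia)] = d
        tipsets[id(node)] = [i for s in child_sets for i in s]
    return C, labels


def lambda_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal shared-history covariance by lambda."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


@dataclass
class LambdaEstimate:
    lambda_hat: float
    sigma2_hat: float
    mu_hat: float
    loglik: float
    loglik_0: float
    loglik_1: float
    p0: float
    p1: float


def _profile_loglik(y: np.ndarray, C: np.ndarray, lam: float):
    """(loglik, mu_hat, sigma2_hat) at fixed lambda, ML over mu and sigma2."""
    n = len(y)
    V = lambda_covariance(C, lam)
    try:
        chol = linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        return -np.inf, np.nan, np.nan
    one = np.ones(n)
    z_y = linalg.solve_triangular(chol, y, lower=True)
    z_1 = linalg.solve_triangular(chol, one, lower=True)
    mu = float(z_1 @ z_y / (z_1 @ z_1))
    resid = z_y - mu * z_1
    sigma2 = float(resid @ resid / n)
    if sigma2 <= 0:
        return -np.inf, mu, sigma2
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return ll, mu, sigma2


def estimate_lambda(
    tree_or_C: dendropy.Tree | np.ndarray,
    trait: pd.Series | np.ndarray,
    xatol: float = 1e-8,
) -> LambdaEstimate:
    """ML estimate of Pagel's lambda for one trait on one tree.

    ``trait`` may be a Series indexed by tip label (matched against the
    tree) or a plain vector already in tip-covariance order.  The profile
    likelihood is maximized over [0, 1] by bounded scalar search; the
    boundary values are always evaluated too, and ties resolve toward the
    boundary.
    """
    if isinstance(tree_or_C, np.ndarray):
        C = tree_or_C
        labels = None
    else:
        C, labels = tree_covariance(tree_or_C)
    if isinstance(trait, pd.Series):
        if labels is not None:
            missing = sorted(set(labels) - set(trait.index))
            extra = sorted(set(trait.index) - set(labels))
            if missing or extra:
                raise ValueError(
                    f"tip/trait label mismatch: missing from traits {missing}, "
                    f"absent from tree {extra}")
            y = trait.loc[labels].to_numpy(dtype=float)
        else:
            y = trait.to_numpy(dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 tips")
    if np.ptp(y) < 1e-14:
        raise ValueError("trait is constant across tips")

    ll0, mu0, s0 = _profile_loglik(y, C, 0.0)
    ll1, mu1, s1 = _profile_loglik(y, C, 1.0)
    res = optimize.minimize_scalar(
        lambda lam: -_profile_loglik(y, C, lam)[0],
        bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol})
    cands = [(ll0, 0.0), (ll1, 1.0), (-res.fun, float(res.x))]
    # ties resolve toward the boundary: boundary candidates listed first
    best_ll, best_lam = max(cands, key=lambda t: t[0])
    _, mu_hat, s2_hat = _profile_loglik(y, C, best_lam)
    p0 = float(stats.chi2.sf(max(2.0 * (best_ll - ll0), 0.0), df=1))
    p1 = float(stats.chi2.sf(max(2.0 * (best_ll - ll1), 0.0), df=1))
    return LambdaEstimate(best_lam, s2_hat, mu_hat, best_ll, ll0, ll1, p0, p1)


def species_trait_means(table: pd.DataFrame, traits=TRAITS) -> pd.DataFrame:
    """Per-species mean of each trait — the tip values for signal analysis."""
    return table.groupby("species")[list(traits)].mean()


@dataclass
class TreeSetSummary:
    per_tree: pd.DataFrame  # tree_index, trait, lambda_hat, p0, p1
    summary: pd.DataFrame   # per trait: mean/SD of lambda, p0, p1; n_trees_used
    n_trees_skipped: int


def summarize_over_trees(
    trees: list[dendropy.Tree],
    species_means: pd.DataFrame,
    traits=None,
) -> TreeSetSummary:
    """Estimate lambda for every trait on every tree and aggregate.

    Trees missing any species are skipped with a warning and counted.
    """
    traits = list(species_means.columns) if traits is None else list(traits)
    species = set(species_means.index)
    records = []
    skipped = 0
    for t_idx, tree in enumerate(trees):
        C, labels = tree_covariance(tree)
        if not species <= set(labels):
            warnings.warn(f"tree {t_idx} missing species; skipped", stacklevel=2)
            skipped += 1
            continue
        keep = [i for i, lab in enumerate(labels) if lab in species]
        C_sub = C[np.ix_(keep, keep)]
        labs = [labels[i] for i in keep]
        for trait in traits:
            y = species_means.loc[labs, trait].to_numpy(dtype=float)
            est = estimate_lambda(C_sub, y)
            records.append({
                "tree_index": t_idx, "trait": trait,
                "lambda_hat": est.lambda_hat, "p0": est.p0, "p1": est.p1,
            })
    per_tree = pd.DataFrame(records)
    if per_tree.empty:
        raise ValueError("no usable trees: every tree was missing species")
    grouped = per_tree.groupby("trait", sort=False)
    summary = pd.DataFrame({
        "mean_lambda": grouped["lambda_hat"].mean(),
        "sd_lambda": grouped["lambda_hat"].std(ddof=1).fillna(0.0),
        "mean_p0": grouped["p0"].mean(),
        "sd_p0": grouped["p0"].std(ddof=1).fillna(0.0),
        "mean_p1": grouped["p1"].mean(),
        "sd_p1": grouped["p1"].std(ddof=1).fillna(0.0),
        "n_trees_used": grouped["lambda_hat"].count(),
    }).reset_index()
    return TreeSetSummary(per_tree, summary, skipped)


def read_trees(path) -> list[dendropy.Tree]:
    """Read one or more newick trees from a file."""
    trees = dendropy.TreeList.get(path=str(path), schema="newick")
    return list(trees)
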