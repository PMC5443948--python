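"""Pagel's lambda: covariance construction, ML estimation, tree-set summaries."""

import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eggspace.physignal import (
    estimate_lambda,
    lambda_covariance,
    species_trait_means,
    summarize_over_trees,
    tree_covariance,
)
from eggspace.simulate import TreeSimSpec, simulate_lambda_traits, simulate_tree


def newick(s):
    return dendropy.Tree.get(data=s, schema="newick")


def test_three_tip_covariance_closed_form():
    tree = newick("((A:1.0,B:2.0):0.5,C:3.0);")
    C, labels = tree_covariance(tree)
    idx = {lab: i for i, lab in enumerate(labels)}
    a, b, c = idx["A"], idx["B"], idx["C"]
    assert C[a, a] == pytest.approx(1.5)
    assert C[b, b] == pytest.approx(2.5)
    assert C[c, c] == pytest.approx(3.0)
    assert C[a, b] == pytest.approx(0.5)  # shared stem
    assert C[a, c] == 0.0 and C[b, c] == 0.0


def test_lambda_one_is_brownian_and_zero_is_diagonal():
    tree = simulate_tree(12, seed=1)
    C, _ = tree_covariance(tree)
    assert np.allclose(lambda_covariance(C, 1.0), C)
    assert np.allclose(lambda_covariance(C, 0.0), np.diag(np.diag(C)))
    half = lambda_covariance(C, 0.5)
    off = ~np.eye(len(C), dtype=bool)
    assert np.allclose(half[off], 0.5 * C[off])


def test_loglik_at_zero_equals_independent_normal_product():
    tree = simulate_tree(20, seed=2)
    C, labels = tree_covariance(tree)
    traits = simulate_lambda_traits(tree, TreeSimSpec(n_tips=20, seed=3))
    est = estimate_lambda(tree, traits)
    y = traits.loc[labels].to_numpy()
    depths = np.diag(C)
    one = np.ones(len(y))
    # GLS at lambda=0: weighted mean and ML variance under independence
    w = 1.0 / depths
    mu = (w @ y) / w.sum()
    sigma2 = np.mean((y - mu) ** 2 / depths)
    ll = stats.norm.logpdf(y, mu, np.sqrt(sigma2 * depths)).sum()
    assert est.loglik_0 == pytest.approx(ll)


def test_mle_loglik_dominates_boundaries():
    for seed in range(8):
        tree = simulate_tree(25, seed=seed)
        traits = simulate_lambda_traits(
            tree, TreeSimSpec(n_tips=25, lambda_true=0.5, seed=seed + 50))
        est = estimate_lambda(tree, traits)
        assert est.loglik >= est.loglik_0 - 1e-8
        assert est.loglik >= est.loglik_1 - 1e-8


def test_lambda_invariant_to_branch_length_rescaling():
    tree = simulate_tree(30, seed=4)
    traits = simulate_lambda_traits(
        tree, TreeSimSpec(n_tips=30, lambda_true=0.7, seed=5))
    est = estimate_lambda(tree, traits)
    C, labels = tree_covariance(tree)
    est_scaled = estimate_lambda(7.3 * C, traits.loc[labels].to_numpy())
    assert est_scaled.lambda_hat == pytest.approx(est.lambda_hat, abs=1e-4)
    assert est_scaled.sigma2_hat == pytest.approx(est.sigma2_hat / 7.3, rel=1e-3)


def test_shuffled_traits_lose_signal():
    tree = simulate_tree(80, seed=6)
    traits = simulate_lambda_traits(
        tree, TreeSimSpec(n_tips=80, lambda_true=1.0, seed=7))
    rng = np.random.default_rng(8)
    shuffled = pd.Series(rng.permutation(traits.to_numpy()), index=traits.index)
    est = estimate_lambda(tree, shuffled)
    assert est.lambda_hat < 0.3


def test_brownian_traits_recover_high_lambda():
    hats = []
    for seed in range(10):
        tree = simulate_tree(100, seed=seed + 20)
        traits = simulate_lambda_traits(
            tree, TreeSimSpec(n_tips=100, lambda_true=1.0, seed=seed + 200))
        hats.append(estimate_lambda(tree, traits).lambda_hat)
    assert np.mean(hats) > 0.85


def test_estimate_matches_phytools_oracle(tmp_path):
    # independent reference: phytools::phylosig maximum-likelihood lambda
    tree = simulate_tree(40, seed=3)
    traits = simulate_lambda_traits(
        tree, TreeSimSpec(n_tips=40, lambda_true=0.6, sigma2=1.0, seed=5))
    est = estimate_lambda(tree, traits)
    nwk = tmp_path / "t.nwk"
    csv = tmp_path / "x.csv"
    tree.write(path=str(nwk), schema="newick")
    traits.to_csv(csv, header=False)
    script = (
        'suppressMessages(library(phytools));'
        f'tr <- ape::read.tree("{nwk}");'
        f'x <- read.csv("{csv}", header=FALSE); v <- setNames(x$V2, x$V1);'
        'res <- phylosig(tr, v, method="lambda");'
        'cat(res$lambda, res$logL)'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, check=True)
    ref_lambda, ref_loglik = map(float, out.stdout.split())
    assert est.lambda_hat == pytest.approx(ref_lambda, abs=1e-4)
    assert est.loglik == pytest.approx(ref_loglik, abs=1e-4)


def test_constant_trait_rejected():
    tree = simulate_tree(10, seed=9)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    with pytest.raises(ValueError, match="constant"):
        estimate_lambda(tree, pd.Series(1.0, index=labels))


def test_label_mismatch_lists_missing_tips():
    tree = simulate_tree(8, seed=10)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    traits = pd.Series(np.arange(7, dtype=float), index=labels[:-1])
    with pytest.raises(ValueError, match=labels[-1]):
        estimate_lambda(tree, traits)


def test_identical_trees_summarize_with_zero_sd():
    tree = simulate_tree(12, seed=11)
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    rng = np.random.default_rng(12)
    means = pd.DataFrame({"luminance": rng.standard_normal(12),
                          "uv": rng.standard_normal(12)}, index=labels)
    res = summarize_over_trees([tree, tree, tree], means)
    assert np.allclose(res.summary["sd_lambda"], 0.0)
    assert np.allclose(res.summary["sd_p0"], 0.0)
    assert (res.summary["n_trees_used"] == 3).all()


def test_summary_mean_equals_recomputed_per_tree_mean():
    trees = [simulate_tree(10, seed=s) for s in (13, 14, 15)]
    labels = sorted(lf.taxon.label for lf in trees[0].leaf_node_iter())
    for t in trees[1:]:
        for leaf, name in zip(t.leaf_node_iter(), labels):
            leaf.taxon.label = name
    rng = np.random.default_rng(16)
    means = pd.DataFrame({"uv": rng.standard_normal(10)}, index=labels)
    res = summarize_over_trees(trees, means)
    per_tree = [estimate_lambda(t, means["uv"]).lambda_hat for t in trees]
    assert res.summary.loc[0, "mean_lambda"] == pytest.approx(np.mean(per_tree))


def test_tree_missing_species_skipped_with_warning():
    good = simulate_tree(10, seed=17)
    labels = sorted(lf.taxon.label for lf in good.leaf_node_iter())
    bad = simulate_tree(10, seed=18)
    for i, leaf in enumerate(bad.leaf_node_iter()):
        leaf.taxon.label = f"other_{i}"  # no overlap with the trait index
    rng = np.random.default_rng(19)
    means = pd.DataFrame({"uv": rng.standard_normal(10)}, index=labels)
    with pytest.warns(UserWarning, match="missing"):
        res = summarize_over_trees([good, bad], means)
    assert res.n_trees_skipped == 1


def test_species_trait_means_are_groupwise_averages(small_community):
    means = species_trait_means(small_community)
    direct = small_community.groupby("species")["uv"].mean()
    assert np.allclose(means["uv"], direct)
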