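"""Discriminant machinery against independent oracles and invariants."""

import numpy as np
import pytest
from scipy import stats

from eggspace.classify import (
    classify,
    classify_logistic,
    df_scores_and_ellipses,
    fit_lda,
    fit_multinomial_logistic,
    jackknife_confusion,
    logistic_confusion,
    monte_carlo_split_accuracy,
    predict_proba_logistic,
    resubstitution_confusion,
)
from eggspace.table import trait_matrix
from conftest import community_with_separation, two_cluster_data


def naive_jackknife(X, labels):
    """Literal leave-one-out loop: refit from scratch, classify held-out row."""
    labels = np.asarray(labels)
    assigned = []
    for i in range(len(X)):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        model = fit_lda(X[mask], labels[mask])
        assigned.append(classify(model, X[i:i + 1])[0])
    return np.array(assigned)


def gaussian_posterior_oracle(model, X):
    """Assign by direct equal-covariance Gaussian density x prior evaluation."""
    cov = model.pooled_cov
    posts = np.column_stack([
        stats.multivariate_normal.logpdf(X, mean=m, cov=cov) + np.log(p)
        for m, p in zip(model.means, model.priors)
    ])
    return model.groups[np.argmax(posts, axis=1)]


def test_mean_shift_along_one_axis_gives_that_discriminant():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((400, 5))
    X[200:, 0] += 3.0
    labels = np.array(["a"] * 200 + ["b"] * 200)
    model = fit_lda(X, labels)
    v = model.axes[:, 0] / np.linalg.norm(model.axes[:, 0])
    assert abs(v[0]) > 0.97  # DF1 essentially along axis 0


@pytest.mark.parametrize("k, d", [(2, 4), (3, 6), (5, 3)])
def test_number_of_axes_is_min_k_minus_one_d(k, d):
    rng = np.random.default_rng(1)
    X = rng.standard_normal((40 * k, d))
    labels = np.repeat([f"g{i}" for i in range(k)], 40)
    model = fit_lda(X, labels)
    assert model.axes.shape[1] == min(k - 1, d)


def test_axes_match_reference_lda_up_to_sign_and_scale():
    sklearn_lda = pytest.importorskip("sklearn.discriminant_analysis")
    rng = np.random.default_rng(2)
    X = rng.standard_normal((150, 6))
    labels = np.repeat(["a", "b", "c"], 50)
    X[50:100, 1] += 2.0
    X[100:, 3] -= 1.5
    model = fit_lda(X, labels)
    ref = sklearn_lda.LinearDiscriminantAnalysis(solver="eigen").fit(X, labels)
    for j in range(model.axes.shape[1]):
        cos = np.dot(model.axes[:, j], ref.scalings_[:, j]) / (
            np.linalg.norm(model.axes[:, j]) * np.linalg.norm(ref.scalings_[:, j]))
        assert abs(abs(cos) - 1.0) < 1e-6


def test_point_at_group_mean_classified_to_that_group():
    X, labels = two_cluster_data(40, distance=2.0, seed=3)
    model = fit_lda(X, labels, priors=np.array([0.5, 0.5]))
    assert classify(model, model.means[1:2])[0] == model.groups[1]


def test_midpoint_goes_to_larger_prior_group():
    X, labels = two_cluster_data(40, distance=2.0, seed=4)
    model = fit_lda(X, labels, priors=np.array([0.9, 0.1]))
    midpoint = model.means.mean(axis=0, keepdims=True)
    assert classify(model, midpoint)[0] == model.groups[0]


def test_classification_agrees_with_gaussian_posterior_oracle():
    rng = np.random.default_rng(5)
    X, labels = two_cluster_data(60, distance=1.0, seed=5)
    model = fit_lda(X, labels)
    query = rng.standard_normal((200, X.shape[1]))
    assert np.array_equal(classify(model, query),
                          gaussian_posterior_oracle(model, query))


def test_separated_clusters_jackknife_perfectly():
    X, labels = two_cluster_data(25, distance=12.0, seed=6)
    assert jackknife_confusion(X, labels).accuracy == 1.0


def test_identical_distributions_jackknife_at_chance():
    X, labels = two_cluster_data(100, distance=0.0, seed=7)
    assert abs(jackknife_confusion(X, labels).accuracy - 0.5) < 0.15


def test_jackknife_equals_naive_per_row_refit(small_community):
    X = trait_matrix(small_community)
    labels = small_community["species"].to_numpy()
    conf = jackknife_confusion(X, labels)
    naive = naive_jackknife(X, labels)
    index = {g: i for i, g in enumerate(conf.groups)}
    naive_counts = np.zeros_like(conf.counts)
    for t, a in zip(labels, naive):
        naive_counts[index[t], index[a]] += 1
    assert np.array_equal(conf.counts, naive_counts)


def test_confusion_row_sums_equal_group_sizes(small_community):
    X = trait_matrix(small_community)
    labels = small_community["species"].to_numpy()
    conf = jackknife_confusion(X, labels)
    for g, row_sum in zip(conf.groups, conf.counts.sum(axis=1)):
        assert row_sum == (labels == g).sum()
    assert conf.n == len(labels)


def test_jackknife_not_more_optimistic_than_resubstitution():
    # leave-one-out accuracy <= resubstitution accuracy on average
    diffs = []
    for seed in range(40):
        table = community_with_separation([15, 15, 15], separation=0.5, seed=seed)
        X = trait_matrix(table)
        labels = table["species"].to_numpy()
        diffs.append(resubstitution_confusion(X, labels).accuracy
                     - jackknife_confusion(X, labels).accuracy)
    assert np.mean(diffs) >= 0


def test_monte_carlo_split_perfect_on_separated_clusters():
    X, labels = two_cluster_data(30, distance=12.0, seed=8)
    out = monte_carlo_split_accuracy(X, labels, n_reps=20, seed=1)
    assert out.mean == 1.0


def test_monte_carlo_deterministic_in_seed():
    X, labels = two_cluster_data(30, distance=1.0, seed=9)
    a = monte_carlo_split_accuracy(X, labels, n_reps=15, seed=3)
    b = monte_carlo_split_accuracy(X, labels, n_reps=15, seed=3)
    assert np.array_equal(a.accuracies, b.accuracies)


def test_monte_carlo_tracks_jackknife_at_mid_separation(small_community):
    X = trait_matrix(small_community)
    labels = small_community["species"].to_numpy()
    jk = jackknife_confusion(X, labels).accuracy_pct
    mc = monte_carlo_split_accuracy(X, labels, n_reps=100, seed=2).mean_pct
    assert abs(jk - mc) < 5.0


def test_logistic_separable_groups_fit_perfectly():
    X, labels = two_cluster_data(30, distance=10.0, seed=10)
    assert logistic_confusion(X, labels).accuracy == 1.0


def test_logistic_probabilities_half_at_symmetric_centroid():
    rng = np.random.default_rng(11)
    center = np.array([1.0, 0.0, 0.0, 0.0])
    Xa = rng.standard_normal((50, 4)) + [2.0, 0, 0, 0]
    Xb = 2 * center - Xa  # exact point reflection of group a about `center`
    Xs = np.vstack([Xa, Xb])
    labels = np.array(["a"] * 50 + ["b"] * 50)
    model = fit_multinomial_logistic(Xs, labels)
    probs = predict_proba_logistic(model, center[None, :])
    assert np.allclose(probs, 0.5, atol=1e-6)


def test_logistic_gradient_vanishes_and_matches_finite_differences():
    X, labels = two_cluster_data(40, distance=1.0, seed=12)
    model = fit_multinomial_logistic(X, labels, tol=1e-8)
    assert model.converged and model.final_grad_norm < 1e-8
    # finite-difference check of the penalized NLL gradient at the optimum
    groups, y = np.unique(labels, return_inverse=True)
    Xt = np.hstack([np.ones((len(X), 1)), X])
    pen_mask = np.ones(Xt.shape[1]); pen_mask[0] = 0.0

    def nll(beta):
        Z = Xt @ beta.T
        Z = Z - Z.max(axis=1, keepdims=True)
        ll = np.sum(Z[np.arange(len(y)), y] - np.log(np.exp(Z).sum(axis=1)))
        return -ll + 0.5 * model.ridge * np.sum((beta * pen_mask) ** 2)

    eps = 1e-5
    base = model.coef
    for idx in [(0, 0), (0, 3), (1, 1)]:
        up = base.copy(); up[idx] += eps
        dn = base.copy(); dn[idx] -= eps
        fd = (nll(up) - nll(dn)) / (2 * eps)
        assert abs(fd) < 1e-4


def test_logistic_and_lda_agree_on_gaussian_data():
    # both approximate the Bayes rule under equal-covariance Gaussians
    for seed in range(5):
        table = community_with_separation([40, 40, 40], separation=0.6, seed=seed)
        X = trait_matrix(table)
        labels = table["species"].to_numpy()
        lda_acc = resubstitution_confusion(X, labels).accuracy_pct
        log_acc = logistic_confusion(X, labels).accuracy_pct
        assert abs(lda_acc - log_acc) < 5.0


def test_classification_invariant_under_affine_transform(small_community):
    X = trait_matrix(small_community)
    labels = small_community["species"].to_numpy()
    rng = np.random.default_rng(13)
    A = rng.standard_normal((X.shape[1], X.shape[1]))
    A += X.shape[1] * np.eye(X.shape[1])  # well-conditioned
    b = rng.standard_normal(X.shape[1])
    base = classify(fit_lda(X, labels), X)
    trans = classify(fit_lda(X @ A + b, labels), X @ A + b)
    assert np.array_equal(base, trans)


def test_group_of_one_raises_with_group_name():
    X = np.random.default_rng(14).standard_normal((11, 3))
    labels = np.array(["a"] * 10 + ["lonely"])
    with pytest.raises(ValueError, match="lonely"):
        fit_lda(X, labels)


def test_ellipse_sds_match_direct_projection_sds(small_community):
    X = trait_matrix(small_community)
    labels = small_community["species"].to_numpy()
    model = fit_lda(X, labels)
    scores, ellipses = df_scores_and_ellipses(model, X, labels)
    for ell in ellipses:
        pts = scores[labels == ell.group]
        assert ell.half_width == pytest.approx(pts[:, 0].std(ddof=0))
        assert ell.half_height == pytest.approx(pts[:, 1].std(ddof=0))


def test_tight_cluster_has_degenerate_ellipse():
    rng = np.random.default_rng(15)
    X = np.vstack([rng.standard_normal((30, 4)) * 1e-6,
                   rng.standard_normal((30, 4)) * 1e-6 + 5])
    labels = np.array(["a"] * 30 + ["b"] * 30)
    model = fit_lda(X, labels)
    _, ellipses = df_scores_and_ellipses(model, X, labels)
    # scores are sphered to unit pooled within-group variance, so "tight" means
    # tiny relative to the centroid separation
    sep = abs(ellipses[0].center[0] - ellipses[1].center[0])
    assert ellipses[0].half_width < 1e-3 * sep


def test_doubling_traits_leaves_assignments_unchanged(small_community):
    X = trait_matrix(small_community)
    labels = small_community["species"].to_numpy()
    a = classify(fit_lda(X, labels), X)
    b = classify(fit_lda(2 * X, labels), 2 * X)
    assert np.array_equal(a, b)
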