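"""Linear discriminant classification, written from first principles.

Phenotypic partitioning is quantified as the accuracy with which eggs can
be assigned back to their species from their traits.  The machinery here is
deliberately self-contained: discriminant axes come from the generalized
eigenproblem B v = theta W v (between- vs pooled within-group scatter),
classification uses the Gaussian equal-covariance discriminant score, and
accuracy is estimated by leave-one-out jack-knifing (implemented with
rank-one Sherman--Morrison downdates of the pooled scatter inverse, so each
omission is exact but no full refit is needed) or by Monte-Carlo stratified
sample splitting.  A ridge-penalized multinomial logistic regression fit by
damped Newton iterations provides an assumption-lean cross-check.

Priors default to group sample-size proportions throughout, consistent
with a chance null driven by relative sample sizes.  Ties in scores are
broken toward the lowest group index, so reruns are deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


@dataclass
class DiscriminantModel:
    groups: np.ndarray          # group labels, fixed order
    counts: np.ndarray          # per-group n
    means: np.ndarray           # k x d group means
    grand_mean: np.ndarray      # weighted grand mean
    within_scatter: np.ndarray  # pooled within-group scatter W (d x d)
    axes: np.ndarray            # d x m discriminant axes, descending eigenvalue
    eigenvalues: np.ndarray
    priors: np.ndarray

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def pooled_cov(self) -> np.ndarray:
        return self.within_scatter / (self.n - len(self.groups))


@dataclass
class ConfusionMatrix:
    groups: np.ndarray
    counts: np.ndarray  # k x k, rows = true group, cols = assigned

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_correct(self) -> int:
        return int(np.trace(self.counts))

    @property
    def accuracy(self) -> float:
        return self.n_correct / self.n

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy


@dataclass
class SDEllipse:
    group: str
    center: tuple[float, float]  # centroid on (DF1, DF2)
    half_width: float            # SD of DF1
    half_height: float           # SD of DF2


def _group_stats(X: np.ndarray, labels: np.ndarray):
    groups, y = np.unique(labels, return_inverse=True)
    counts = np.bincount(y, minlength=len(groups))
    if counts.min() < 2:
        small = groups[counts < 2]
        raise ValueError(f"groups with fewer than 2 rows: {list(small)}")
    d = X.shape[1]
    means = np.zeros((len(groups), d))
    W = np.zeros((d, d))
    for g in range(len(groups)):
        Xg = X[y == g]
        means[g] = Xg.mean(axis=0)
        R = Xg - means[g]
        W += R.T @ R
    return groups, y, counts, means, W


def fit_lda(
    X: np.ndarray,
    labels,
    priors: np.ndarray | None = None,
) -> DiscriminantModel:
    """Fit linear discriminant axes and group statistics.

    B is the between-group scatter of the group means about the weighted
    grand mean (weighted by group size); W the pooled within-group scatter.
    Axes solve B v = theta W v and are scaled to unit pooled within-group
    variance.  A singular W is ridge-stabilized with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups, y, counts, means, W = _group_stats(X, labels)
    n, d = X.shape
    k = len(groups)
    grand = counts @ means / n
    Mc = means - grand
    B = (means - grand).T @ (counts[:, None] * Mc)
    try:
        linalg.cholesky(W, lower=True)
    except linalg.LinAlgError:
        ridge = 1e-8 * np.trace(W) / d
        warnings.warn("singular within-group scatter; ridge-stabilizing", stacklevel=2)
        W = W + ridge * np.eye(d)
    theta, V = linalg.eigh(B, W)
    order = np.argsort(theta)[::-1][: min(k - 1, d)]
    axes = V[:, order] * np.sqrt(n - k)  # unit pooled within-group variance
    if priors is None:
        priors = counts / n
    else:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()
    return DiscriminantModel(groups, counts, means, grand, W, axes,
                             theta[order], priors)


def _discriminant_scores(means, cov_inv, priors, X):
    A = means @ cov_inv                       # k x d
    const = -0.5 * np.sum(A * means, axis=1) + np.log(priors)
    return X @ A.T + const                    # n x k


def classify(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Assign rows to the group with maximal Gaussian discriminant score."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.means.shape[1]:
        raise ValueError("trait dimension does not match the fitted model")
    cov_inv = linalg.inv(model.pooled_cov)
    scores = _discriminant_scores(model.means, cov_inv, model.priors, X)
    return model.groups[np.argmax(scores, axis=1)]  # argmax takes lowest index on ties


def resubstitution_confusion(X, labels, priors=None) -> ConfusionMatrix:
    model = fit_lda(X, labels, priors)
    return _confusion(model.groups, np.asarray(labels), classify(model, X))


def _confusion(groups, true_labels, assigned) -> ConfusionMatrix:
    index = {g: i for i, g in enumerate(groups)}
    counts = np.zeros((len(groups), len(groups)), dtype=int)
    for t, a in zip(true_labels, assigned):
        counts[index[t], index[a]] += 1
    return ConfusionMatrix(groups, counts)


def jackknife_confusion(X, labels, priors: np.ndarray | None = None) -> ConfusionMatrix:
    """Leave-one-out classification: omit each egg, refit, classify it.

    The refit is exact but incremental: removing row x from group g shifts
    that group's mean and subtracts a rank-one term c u u' (u = x - m_g,
    c = n_g/(n_g - 1)) from the pooled scatter, so the downdated inverse
    follows from the Sherman--Morrison identity instead of a fresh
    decomposition.  Fixed priors may be supplied; by default priors track
    the leave-one-out group sizes.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups, y, counts, means, W = _group_stats(X, labels)
    n, d = X.shape
    k = len(groups)
    W_inv = linalg.inv(W)
    assigned = np.empty(n, dtype=object)
    for i in range(n):
        g = y[i]
        ng = counts[g]
        u = X[i] - means[g]
        c = ng / (ng - 1.0)
        Wu = W_inv @ u
        denom = 1.0 - c * (u @ Wu)
        if denom <= 1e-12:
            # downdated scatter (numerically) singular: fall back to refit
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            sub = fit_lda(X[mask], labels[mask],
                          None if priors is None else priors)
            assigned[i] = classify(sub, X[i:i + 1])[0]
            continue
        W_inv_i = W_inv + (c / denom) * np.outer(Wu, Wu)
        means_i = means.copy()
        means_i[g] = (ng * means[g] - X[i]) / (ng - 1.0)
        counts_i = counts.copy()
        counts_i[g] -= 1
        cov_inv = W_inv_i * (n - 1 - k)
        pri = counts_i / (n - 1) if priors is None else priors
        scores = _discriminant_scores(means_i, cov_inv, pri, X[i:i + 1])
        assigned[i] = groups[int(np.argmax(scores[0]))]
    return _confusion(groups, labels, assigned)


def jackknife_accuracy(X, labels, priors=None) -> float:
    return jackknife_confusion(X, labels, priors).accuracy


@dataclass
class SplitAccuracies:
    accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def mean_pct(self) -> float:
        return 100.0 * self.mean


def monte_carlo_split_accuracy(
    X,
    labels,
    train_fraction: float = 0.75,
    n_reps: int = 100,
    seed: int = 0,
    priors=None,
) -> SplitAccuracies:
    """Repeated stratified train/test splits scoring the held-out fraction."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups, y, counts, _, _ = _group_stats(X, labels)
    n_train = np.maximum(2, np.ceil(train_fraction * counts).astype(int))
    if np.any(n_train > counts) or np.all(n_train == counts):
        raise ValueError("infeasible stratification: adjust train_fraction")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_reps)
    for rep in range(n_reps):
        train_idx = []
        for g in range(len(groups)):
            idx = np.where(y == g)[0]
            train_idx.append(rng.permutation(idx)[: n_train[g]])
        train = np.concatenate(train_idx)
        test = np.setdiff1d(np.arange(len(y)), train)
        model = fit_lda(X[train], labels[train], priors)
        accs[rep] = float(np.mean(classify(model, X[test]) == labels[test]))
    return SplitAccuracies(accs)


# ---------------------------------------------------------------------------
# Multinomial logistic regression
# ---------------------------------------------------------------------------

@dataclass
class MultinomialLogitModel:
    groups: np.ndarray
    coef: np.ndarray            # k x (d + 1), column 0 = intercept
    converged: bool
    n_iter: int
    final_grad_norm: float
    ridge: float
    history: list = field(default_factory=list, repr=False)


def _softmax(Z):
    Z = Z - Z.max(axis=1, keepdims=True)
    E = np.exp(Z)
    return E / E.sum(axis=1, keepdims=True)


def fit_multinomial_logistic(
    X,
    labels,
    ridge: float | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MultinomialLogitModel:
    """Softmax regression by damped Newton steps on the penalized likelihood.

    The full k-class parameterization is identified through a ridge penalty
    on the non-intercept coefficients (default 1e-6 * n), which also keeps
    Newton stable on linearly separable groups; with ridge 0 on separable
    data the fit would diverge, so a minimal ridge is imposed automatically
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    groups, y = np.unique(labels, return_inverse=True)
    n, d = X.shape
    k = len(groups)
    if n < k:
        raise ValueError("need at least as many rows as groups")
    if ridge is None:
        ridge = 1e-6 * n
    elif ridge <= 0:
        warnings.warn("ridge <= 0 is unstable on separable data; using 1e-10 * n",
                      stacklevel=2)
        ridge = 1e-10 * n
    Xt = np.hstack([np.ones((n, 1)), X])
    Y = np.zeros((n, k))
    Y[np.arange(n), y] = 1.0
    p_dim = d + 1
    beta = np.zeros((k, p_dim))
    pen_mask = np.ones(p_dim)
    pen_mask[0] = 0.0  # intercepts unpenalized

    def nll(b):
        Z = Xt @ b.T
        Z = Z - Z.max(axis=1, keepdims=True)
        log_norm = np.log(np.exp(Z).sum(axis=1))
        ll = np.sum(Z[np.arange(n), y] - log_norm)
        return -ll + 0.5 * ridge * np.sum((b * pen_mask) ** 2)

    grad_norm = np.inf
    it = 0
    value = nll(beta)
    for it in range(1, max_iter + 1):
        P = _softmax(Xt @ beta.T)
        G = (P - Y).T @ Xt + ridge * beta * pen_mask  # k x p
        grad_norm = float(np.linalg.norm(G))
        if grad_norm < tol:
            break
        # block Hessian of the penalized NLL
        H = np.zeros((k * p_dim, k * p_dim))
        for a in range(k):
            for b_ in range(a, k):
                w = P[:, a] * ((a == b_) - P[:, b_])
                block = Xt.T @ (w[:, None] * Xt)
                H[a * p_dim:(a + 1) * p_dim, b_ * p_dim:(b_ + 1) * p_dim] = block
                if b_ != a:
                    H[b_ * p_dim:(b_ + 1) * p_dim, a * p_dim:(a + 1) * p_dim] = block
        H += ridge * np.diag(np.tile(pen_mask, k))
        H += 1e-10 * np.trace(H) / H.shape[0] * np.eye(H.shape[0])
        step = np.linalg.solve(H, G.ravel()).reshape(k, p_dim)
        t = 1.0
        for _ in range(30):  # backtracking keeps Newton monotone
            cand = beta - t * step
            cand_value = nll(cand)
            if cand_value <= value:
                break
            t /= 2
        beta = beta - t * step
        value = nll(beta)
    return MultinomialLogitModel(groups, beta, grad_norm < tol, it, grad_norm, ridge)


def classify_logistic(model: MultinomialLogitModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Xt = np.hstack([np.ones((X.shape[0], 1)), X])
    return model.groups[np.argmax(Xt @ model.coef.T, axis=1)]


def predict_proba_logistic(model: MultinomialLogitModel, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Xt = np.hstack([np.ones((X.shape[0], 1)), X])
    return _softmax(Xt @ model.coef.T)


def logistic_confusion(X, labels, **kwargs) -> ConfusionMatrix:
    """Resubstitution confusion matrix of the multinomial logistic fit."""
    labels = np.asarray(labels)
    model = fit_multinomial_logistic(X, labels, **kwargs)
    return _confusion(model.groups, labels, classify_logistic(model, X))


# ---------------------------------------------------------------------------
# Discriminant scores for plotting
# ---------------------------------------------------------------------------

def df_scores_and_ellipses(
    model: DiscriminantModel, X, labels
) -> tuple[np.ndarray, list[SDEllipse]]:
    """(DF1, DF2) scores per row plus a one-SD ellipse per group."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    centred = X - model.grand_mean
    scores = centred @ model.axes[:, :2]
    if scores.shape[1] < 2:
        scores = np.hstack([scores, np.zeros((len(X), 1))])
    ellipses = []
    for g in model.groups:
        S = scores[labels == g]
        ellipses.append(SDEllipse(
            group=str(g),
            center=(float(S[:, 0].mean()), float(S[:, 1].mean())),
            half_width=float(S[:, 0].std(ddof=0)),
            half_height=float(S[:, 1].std(ddof=0)),
        ))
    return scores, ellipses
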