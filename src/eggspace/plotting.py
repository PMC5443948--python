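"""Discriminant-space figures: group scatter with one-SD ellipses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Ellipse

from .classify import DiscriminantModel, SDEllipse, df_scores_and_ellipses


def plot_df_space(
    model: DiscriminantModel,
    X: np.ndarray,
    labels,
    path=None,
    title: str = "",
    dashed_groups: set[str] | None = None,
    ax=None,
):
    """Scatter of (DF1, DF2) scores with a one-SD ellipse per group.

    Ellipse half-width/-height are the per-group SDs of DF1 and DF2.
    Groups named in ``dashed_groups`` (e.g. parasitic host-races) get
    dashed ellipses; hosts get solid ones.
    """
    labels = np.asarray(labels)
    scores, ellipses = df_scores_and_ellipses(model, X, labels)
    own_fig = ax is None
    if own_fig:
        _, ax = plt.subplots(figsize=(6, 5))
    cmap = plt.get_cmap("tab10")
    dashed_groups = dashed_groups or set()
    for i, ell in enumerate(ellipses):
        g = ell.group
        pts = scores[labels == g]
        color = cmap(i % 10)
        ax.scatter(pts[:, 0], pts[:, 1], s=8, alpha=0.5, color=color, label=g)
        style = "--" if g in dashed_groups else "-"
        ax.add_patch(Ellipse(ell.center, 2 * ell.half_width, 2 * ell.half_height,
                             fill=False, edgecolor=color, linestyle=style, lw=1.5))
    ax.set_xlabel("Discriminant function 1")
    ax.set_ylabel("Discriminant function 2")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="best")
    if own_fig and path is not None:
        plt.tight_layout()
        plt.savefig(path, dpi=150)
        plt.close()
    return ax


def plot_pairwise_accuracies(results: dict[str, np.ndarray], path=None, ax=None):
    """Strip plot of pairwise classification accuracies per group."""
    own_fig = ax is None
    if own_fig:
        _, ax = plt.subplots(figsize=(4, 5))
    rng = np.random.default_rng(0)
    for i, (name, vals) in enumerate(results.items()):
        x = i + rng.uniform(-0.08, 0.08, size=len(vals))
        ax.plot(x, vals, "o", alpha=0.6)
        ax.hlines(np.mean(vals), i - 0.2, i + 0.2, color="k")
    ax.set_xticks(range(len(results)), list(results))
    ax.set_ylabel("Pairwise classification accuracy (%)")
    if own_fig and path is not None:
        plt.tight_layout()
        plt.savefig(path, dpi=150)
        plt.close()
    return ax
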