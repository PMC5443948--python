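"""Data hygiene before discriminant analysis.

Four steps, each optional and individually seeded/configured: random
selection of one egg per clutch (avoiding pseudoreplication), Mahalanobis
outlier removal against a chi-square cutoff, a Pearson collinearity screen
over the trait columns, and an arcsine-square-root variance-stabilizing
transform (after min-max scaling to [0, 1]).  Every step records what it
did in a provenance dictionary suitable for a sidecar JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .table import TRAITS, trait_matrix


def select_one_egg_per_clutch(table: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Keep exactly one uniformly chosen egg per clutch (deterministic in seed)."""
    rng = np.random.default_rng(seed)
    # stable order first so the same seed gives the same pick regardless of
    # the incoming row order within a clutch
    out = (
        table.sample(frac=1.0, random_state=rng)
        .groupby("clutch_id", sort=False)
        .head(1)
    )
    return out.sort_index().reset_index(drop=True)


def mahalanobis_outliers(
    table: pd.DataFrame,
    alpha: float = 0.001,
    traits: tuple[str, ...] = TRAITS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag and drop rows far from the pooled multivariate trait mean.

    The squared Mahalanobis distance of every row to the pooled mean under
    the pooled covariance is compared with the upper-``alpha`` quantile of
    the chi-square distribution with d = len(traits) degrees of freedom.
    Returns ``(clean, flagged)``; ``flagged`` carries a ``mahalanobis_d2``
    column for the report.
    """
    X = trait_matrix(table, traits)
    n, d = X.shape
    if n <= d:
        raise ValueError(f"need more rows ({n}) than traits ({d}) for outlier screening")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValueError(
            "pooled trait covariance is singular; run the collinearity screen "
            "and drop redundant traits first"
        ) from None
    from scipy.linalg import solve_triangular

    w = solve_triangular(chol, (X - mean).T, lower=True)
    d2 = np.sum(w**2, axis=0)
    cutoff = stats.chi2.ppf(1 - alpha, df=d)
    bad = d2 > cutoff
    flagged = table.loc[bad].copy()
    flagged["mahalanobis_d2"] = d2[bad]
    return table.loc[~bad].reset_index(drop=True), flagged.reset_index(drop=True)


@dataclass
class CollinearityReport:
    flagged_pairs: list[tuple[str, str, float]]
    suggested_drops: list[str]
    constant_columns: list[str] = field(default_factory=list)


def collinearity_screen(
    table: pd.DataFrame,
    r_threshold: float = 0.8,
    traits: tuple[str, ...] = TRAITS,
) -> CollinearityReport:
    """List trait pairs with |Pearson r| above threshold and suggest drops.

    When the flagged pairs are exactly the UV--MW and SW--LW photon-catch
    pairs — the collinearity structure real cone catches show — the
    suggestion is to drop MW and LW, keeping the shorter-wavelength catch of
    each pair.  Otherwise the later trait (in canonical order) of each
    flagged pair is suggested.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    X = trait_matrix(table, traits)
    sd = X.std(axis=0)
    constant = [t for t, s in zip(traits, sd) if s < 1e-12]
    active = [t for t in traits if t not in constant]
    corr = pd.DataFrame(X, columns=list(traits))[active].corr()
    flagged = []
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            r = corr.loc[a, b]
            if abs(r) > r_threshold:
                flagged.append((a, b, float(r)))
    pair_set = {frozenset((a, b)) for a, b, _ in flagged}
    if pair_set == {frozenset(("uv", "mw")), frozenset(("sw", "lw"))}:
        drops = ["mw", "lw"]
    else:
        order = {t: k for k, t in enumerate(traits)}
        drops = sorted({max(a, b, key=order.get) for a, b, _ in flagged},
                       key=order.get)
    return CollinearityReport(flagged, drops, constant)


@dataclass
class ScalingParams:
    """Per-trait min-max parameters so the transform is invertible."""

    mins: dict[str, float]
    maxs: dict[str, float]


def arcsine_sqrt_transform(
    table: pd.DataFrame,
    traits: tuple[str, ...] = TRAITS,
    scaling: ScalingParams | None = None,
) -> tuple[pd.DataFrame, ScalingParams]:
    """Min-max scale each trait to [0, 1] then apply ``asin(sqrt(x))``.

    The transform stabilizes the variance of proportion-like traits; the
    min-max step maps unbounded traits (photon catches) into its domain.
    Pass a previously returned ``ScalingParams`` to apply the identical
    scaling to new data; values then falling outside [0, 1] raise.
    """
    out = table.copy()
    if scaling is None:
        scaling = ScalingParams(
            {t: float(table[t].min()) for t in traits},
            {t: float(table[t].max()) for t in traits},
        )
    for t in traits:
        lo, hi = scaling.mins[t], scaling.maxs[t]
        span = hi - lo
        x = (table[t].to_numpy(float) - lo) / span if span > 0 else np.zeros(len(table))
        if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
            raise ValueError(f"trait {t!r} falls outside [0, 1] after scaling")
        out[t] = np.arcsin(np.sqrt(np.clip(x, 0.0, 1.0)))
    return out, scaling


def inverse_arcsine_sqrt(
    table: pd.DataFrame,
    scaling: ScalingParams,
    traits: tuple[str, ...] = TRAITS,
) -> pd.DataFrame:
    out = table.copy()
    for t in traits:
        lo, hi = scaling.mins[t], scaling.maxs[t]
        x = np.sin(out[t].to_numpy(float)) ** 2
        out[t] = x * (hi - lo) + lo
    return out
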