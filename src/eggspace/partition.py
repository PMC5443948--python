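"""Phenotypic-partitioning inference: chance nulls and group contrasts.

The central question — do parasitized species partition egg phenotype space
more strongly than unparasitized species? — is answered by comparing
observed classification accuracy with the accuracy expected by chance given
relative sample sizes alone.  If eggs were assigned to species with
probability proportional to species sample size, an egg of species i
(frequency n_i/N) would be assigned correctly with probability n_i/N, so

    expected accuracy = sum_i (n_i / N)^2,
    expected correct  = sum_i n_i^2 / N.

Groupwise analyses compare the single observed jack-knifed (or logistic)
classification rate of a group with this null by Fisher's exact test and
report Wald binomial confidence intervals.  Pairwise analyses repeat the
comparison over every pair of species within a group, giving distributions
that two groups' partitioning can be compared on with Welch's t-test on
ranks.  No multiple-testing correction is applied: each pairwise value is a
discriminant rate, not a significance test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import (
    ConfusionMatrix,
    jackknife_confusion,
    logistic_confusion,
)
from .table import ROLE_HOST, ROLE_UNPARASITIZED, TRAITS, trait_matrix

PARASITIZED = "parasitized"
UNPARASITIZED = "unparasitized"
_ROLE_OF_GROUP = {PARASITIZED: ROLE_HOST, UNPARASITIZED: ROLE_UNPARASITIZED}


def expected_accuracy(sizes) -> tuple[float, float]:
    """Chance-level accuracy and correct count from group sample sizes."""
    sizes = np.asarray(sizes, dtype=float)
    if len(sizes) < 1 or np.any(sizes < 1):
        raise ValueError("need at least one group, every size >= 1")
    N = sizes.sum()
    prop = float(np.sum(sizes**2) / N**2)
    return prop, float(np.sum(sizes**2) / N)


def binomial_wald_ci(correct: int, n: int, z: float = 1.96) -> float:
    """Wald binomial CI half-width, in percentage points."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= correct <= n:
        raise ValueError("correct must lie in [0, n]")
    p = correct / n
    return float(z * np.sqrt(p * (1 - p) / n) * 100.0)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    With margins fixed, the first cell follows a hypergeometric
    distribution; the two-sided p sums the probabilities of every table no
    more probable than the observed one (with a small relative tolerance on
    the comparison, as is conventional).
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    n = a + b + c + d
    if n == 0 or (a + b == 0 and c + d == 0) or (a + c == 0 and b + d == 0):
        return 1.0
    row1, col1 = a + b, a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return min(p, 1.0)


@dataclass
class GroupAnalysisResult:
    group: str
    method: str
    n: int
    n_species: int
    sizes: dict[str, int]
    expected_correct: float
    observed_correct: int
    accuracy_pct: float
    ci_halfwidth_pct: float
    expected_accuracy_pct: float
    improvement_pct: float
    fisher_p: float
    confusion: ConfusionMatrix


def summarize_counts(
    group: str, method: str, sizes: dict[str, int],
    observed_correct: int, confusion: ConfusionMatrix | None = None,
) -> GroupAnalysisResult:
    """Table-style summary arithmetic from sizes and an observed count.

    accuracy = 100 * observed / N; expected from the size-driven chance
    null; improvement = accuracy - expected accuracy; Fisher's exact test
    contrasts (correct, incorrect) splits of the chance expectation
    (rounded to the nearest egg) and the observation.
    """
    n_vec = list(sizes.values())
    N = int(sum(n_vec))
    exp_prop, exp_correct = expected_accuracy(n_vec)
    accuracy_pct = 100.0 * observed_correct / N
    expected_pct = 100.0 * exp_prop
    exp_int = int(round(exp_correct))
    fisher_p = fisher_exact_2x2(exp_int, N - exp_int,
                                observed_correct, N - observed_correct)
    return GroupAnalysisResult(
        group=group, method=method, n=N, n_species=len(sizes), sizes=dict(sizes),
        expected_correct=exp_correct, observed_correct=int(observed_correct),
        accuracy_pct=accuracy_pct,
        ci_halfwidth_pct=binomial_wald_ci(observed_correct, N),
        expected_accuracy_pct=expected_pct,
        improvement_pct=accuracy_pct - expected_pct,
        fisher_p=fisher_p,
        confusion=confusion,
    )


def _subset_group(table: pd.DataFrame, group: str) -> pd.DataFrame:
    if group not in _ROLE_OF_GROUP:
        raise ValueError(f"group must be one of {sorted(_ROLE_OF_GROUP)}")
    sub = table[table["role"] == _ROLE_OF_GROUP[group]]
    if sub["species"].nunique() < 2:
        raise ValueError(f"fewer than 2 species in group {group!r}")
    return sub


def groupwise_analysis(
    table: pd.DataFrame,
    group: str,
    method: str = "dfa",
    traits=TRAITS,
) -> GroupAnalysisResult:
    """Observed vs chance classification accuracy for one group of species.

    ``method='dfa'`` scores jack-knifed discriminant classification;
    ``method='logistic'`` scores the multinomial logistic regression by
    resubstitution (the assumption-lean confirmatory analysis).
    """
    sub = _subset_group(table, group)
    X = trait_matrix(sub, traits)
    labels = sub["species"].to_numpy()
    if method == "dfa":
        conf = jackknife_confusion(X, labels)
    elif method == "logistic":
        conf = logistic_confusion(X, labels)
    else:
        raise ValueError("method must be 'dfa' or 'logistic'")
    sizes = {str(g): int(c) for g, c in zip(conf.groups, conf.counts.sum(axis=1))}
    return summarize_counts(group, method, sizes, conf.n_correct, conf)


def compare_groups(res_a: GroupAnalysisResult, res_b: GroupAnalysisResult) -> float:
    """Fisher's exact p contrasting two groups' observed correct rates."""
    return fisher_exact_2x2(
        res_a.observed_correct, res_a.n - res_a.observed_correct,
        res_b.observed_correct, res_b.n - res_b.observed_correct,
    )


@dataclass
class PairwiseResult:
    group: str
    pairs: pd.DataFrame  # species_a, species_b, n_a, n_b, expected_pct, observed_pct

    @property
    def expected(self) -> np.ndarray:
        return self.pairs["expected_pct"].to_numpy()

    @property
    def observed(self) -> np.ndarray:
        return self.pairs["observed_pct"].to_numpy()


def pairwise_analysis(table: pd.DataFrame, group: str, traits=TRAITS) -> PairwiseResult:
    """Two-species jack-knifed accuracy for every pair within a group."""
    sub = _subset_group(table, group)
    species = sorted(sub["species"].unique())
    rows = []
    for a, b in combinations(species, 2):
        pair = sub[sub["species"].isin([a, b])]
        X = trait_matrix(pair, traits)
        labels = pair["species"].to_numpy()
        conf = jackknife_confusion(X, labels)
        n_a = int((labels == a).sum())
        n_b = int((labels == b).sum())
        exp_prop, _ = expected_accuracy([n_a, n_b])
        rows.append({
            "species_a": a, "species_b": b, "n_a": n_a, "n_b": n_b,
            "expected_pct": 100.0 * exp_prop,
            "observed_pct": conf.accuracy_pct,
        })
    return PairwiseResult(group, pd.DataFrame(rows))


@dataclass
class RankedWelchResult:
    statistic: float
    df: float
    p_value: float


def ranked_welch(values_a, values_b) -> RankedWelchResult:
    """Welch's unequal-variances t-test applied to pooled midranks.

    The pooled sample is midrank-transformed, then the ordinary Welch
    statistic with Welch--Satterthwaite degrees of freedom is computed on
    the ranks; two-sided p from Student's t.  A robust two-sample location
    comparison for distributions of classification rates.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 values per sample")
    ranks = stats.rankdata(np.concatenate([a, b]))
    ra, rb = ranks[: len(a)], ranks[len(a):]
    va, vb = ra.var(ddof=1), rb.var(ddof=1)
    if va == 0 and vb == 0:
        return RankedWelchResult(0.0, float(len(a) + len(b) - 2), 1.0)
    se2 = va / len(a) + vb / len(b)
    t = (ra.mean() - rb.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return RankedWelchResult(float(t), float(df), float(p))


def table_report(results: list[GroupAnalysisResult]) -> pd.DataFrame:
    """Long-format summary table mirroring the groupwise report layout."""
    rows = []
    for r in results:
        rows.append({
            "group": r.group, "method": r.method, "n": r.n,
            "n_species": r.n_species,
            "accuracy_pct": round(r.accuracy_pct, 1),
            "ci_halfwidth_pct": round(r.ci_halfwidth_pct, 2),
            "expected_correct": int(round(r.expected_correct)),
            "observed_correct": r.observed_correct,
            "fisher_p": r.fisher_p,
            "improvement_pct": round(r.improvement_pct, 1),
        })
    return pd.DataFrame(rows)
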