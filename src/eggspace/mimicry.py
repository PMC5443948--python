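"""Host-race specialization: does each parasite match its own host best?

For every parasitic host-race, a two-group jack-knifed discriminant
classification is run between the race's eggs and its own host's eggs, and
between the race and each other host species in turn.  Low accuracy means
the two sets of eggs are hard to tell apart — good mimicry; high accuracy
means they are phenotypically distinct.  The specialization signal is the
mean of (own-host accuracy minus other-host accuracy) per race: negative
values say the race resembles its own host more than the other hosts.

Significance is assessed with a paired t-test pairing each race's own-host
accuracy with the mean of its other-host accuracies (one pair per race,
df = number of races - 1).  Races with very few eggs are excluded from the
test but still reported, flagged, for completeness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import jackknife_confusion
from .table import ROLE_HOST, ROLE_PARASITE, TRAITS, trait_matrix


def hostrace_vs_host_accuracy(
    race_eggs: pd.DataFrame, host_eggs: pd.DataFrame, traits=TRAITS
) -> float:
    """Two-group jack-knifed accuracy (percent) of race vs host eggs."""
    if len(race_eggs) < 3 or len(host_eggs) < 3:
        raise ValueError("need at least 3 eggs on each side")
    both = pd.concat([race_eggs, host_eggs], ignore_index=True)
    labels = np.concatenate([
        np.full(len(race_eggs), "race"), np.full(len(host_eggs), "host")])
    conf = jackknife_confusion(trait_matrix(both, traits), labels)
    return conf.accuracy_pct


@dataclass
class MimicryResult:
    matrix: pd.DataFrame          # race x host accuracies (%), NaN if not computed
    summary: pd.DataFrame         # per race: n, own, mean_other, difference, included
    mean_difference: float        # across included races
    se_difference: float
    t_statistic: float
    df: int
    p_value: float
    tested: bool


def mimicry_analysis(
    table: pd.DataFrame,
    min_race_n: int = 3,
    traits=TRAITS,
) -> MimicryResult:
    """Own- vs other-host accuracy matrix and the paired specialization test.

    Races with fewer than ``min_race_n`` eggs appear in the outputs flagged
    as excluded and contribute nothing to the paired t-test.  With fewer
    than two included races the matrix is still returned but the test is
    skipped (statistics reported as NaN).
    """
    hosts = table[table["role"] == ROLE_HOST]
    races = table[table["role"] == ROLE_PARASITE]
    if races.empty:
        raise ValueError("no parasite rows in table")
    host_species = sorted(hosts["species"].unique())
    race_names = sorted(races["species"].unique())
    matrix = pd.DataFrame(np.nan, index=race_names, columns=host_species)
    rows = []
    for race_name in race_names:
        race_eggs = races[races["species"] == race_name]
        own_host = race_eggs["target_host"].iloc[0]
        if own_host not in host_species:
            raise ValueError(f"race {race_name!r} targets unknown host {own_host!r}")
        included = len(race_eggs) >= min_race_n
        own_acc, others = np.nan, []
        if included:
            for host_name in host_species:
                host_eggs = hosts[hosts["species"] == host_name]
                acc = hostrace_vs_host_accuracy(race_eggs, host_eggs, traits)
                matrix.loc[race_name, host_name] = acc
                if host_name == own_host:
                    own_acc = acc
                else:
                    others.append(acc)
        rows.append({
            "race": race_name, "own_host": own_host, "n_eggs": len(race_eggs),
            "own_accuracy_pct": own_acc,
            "mean_other_accuracy_pct": float(np.mean(others)) if others else np.nan,
            "difference_pct": own_acc - float(np.mean(others)) if others else np.nan,
            "included": included,
        })
    summary = pd.DataFrame(rows)
    diffs = summary.loc[summary["included"], "difference_pct"].to_numpy()
    if len(diffs) >= 2:
        # paired t across races == one-sample t on per-race differences
        t, p = stats.ttest_1samp(diffs, 0.0)
        result = MimicryResult(
            matrix, summary,
            mean_difference=float(diffs.mean()),
            se_difference=float(diffs.std(ddof=1) / np.sqrt(len(diffs))),
            t_statistic=float(t), df=len(diffs) - 1, p_value=float(p),
            tested=True,
        )
    else:
        result = MimicryResult(
            matrix, summary,
            mean_difference=float(diffs.mean()) if len(diffs) else np.nan,
            se_difference=np.nan, t_statistic=np.nan,
            df=max(len(diffs) - 1, 0), p_value=np.nan, tested=False,
        )
    return result
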