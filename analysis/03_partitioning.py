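"""Partitioning analyses: groupwise chance nulls and pairwise contrasts.

For each family: jack-knifed DFA and multinomial-logistic classification of
eggs to species within the parasitized and unparasitized groups, compared
with the size-driven chance expectation (Fisher's exact tests, Wald CIs);
then every within-group species pair, contrasted across groups by Welch's
t on ranks.  Writes the summary tables and discriminant-space figures.
"""

from pathlib import Path

import pandas as pd

from eggspace.classify import fit_lda
from eggspace.partition import (
    compare_groups,
    groupwise_analysis,
    pairwise_analysis,
    ranked_welch,
    table_report,
)
from eggspace.plotting import plot_df_space
from eggspace.table import read_table, trait_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
FIG = BASE / "figures"
FIG.mkdir(parents=True, exist_ok=True)

for name in ("warbler_like", "weaver_like"):
    table = read_table(BASE / "data" / f"{name}_clean.csv")
    results = [groupwise_analysis(table, group, method=method)
               for group in ("parasitized", "unparasitized")
               for method in ("dfa", "logistic")]
    report = table_report(results)
    report.to_csv(BASE / f"{name}_groupwise.tsv", sep="\t", index=False)
    dfa = [r for r in results if r.method == "dfa"]
    print(f"\n== {name} ==")
    print(report.to_string(index=False))
    print(f"cross-group Fisher p (DFA observed): {compare_groups(*dfa):.2e}")

    pw = {g: pairwise_analysis(table, g) for g in ("parasitized", "unparasitized")}
    pd.concat([p.pairs.assign(group=g) for g, p in pw.items()],
              ignore_index=True).to_csv(BASE / f"{name}_pairwise.csv", index=False)
    w_obs = ranked_welch(pw["parasitized"].observed, pw["unparasitized"].observed)
    w_exp = ranked_welch(pw["parasitized"].expected, pw["unparasitized"].expected)
    print(f"pairwise observed: parasitized {pw['parasitized'].observed.mean():.1f}% "
          f"vs unparasitized {pw['unparasitized'].observed.mean():.1f}% "
          f"(Welch-on-ranks t={w_obs.statistic:.2f}, df={w_obs.df:.1f}, "
          f"p={w_obs.p_value:.4f})")
    print(f"pairwise expected-by-chance contrast: t={w_exp.statistic:.2f}, "
          f"p={w_exp.p_value:.4f}")

    for group, role in (("parasitized", "host"), ("unparasitized", "unparasitized")):
        sub = table[table["role"] == role]
        model = fit_lda(trait_matrix(sub), sub["species"].to_numpy())
        plot_df_space(model, trait_matrix(sub), sub["species"].to_numpy(),
                      path=FIG / f"{name}_{group}_df_space.png",
                      title=f"{name} {group}")
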