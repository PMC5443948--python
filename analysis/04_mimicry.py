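"""Host-race specialization: own-host vs other-host matching.

For every parasitic host-race, a two-group jack-knifed DFA against its own
host and against each other host; the mean own-minus-other accuracy
difference per race and the paired t-test across races.  Negative
differentials mean races resemble their own host more than other hosts
(specialist mimicry); near-zero means generalism.
"""

from pathlib import Path

import pandas as pd

from eggspace.classify import fit_lda
from eggspace.mimicry import mimicry_analysis
from eggspace.plotting import plot_df_space
from eggspace.table import read_table, trait_matrix

BASE = Path(__file__).resolve().parent.parent / "results"
FIG = BASE / "figures"
FIG.mkdir(parents=True, exist_ok=True)

for name in ("warbler_like", "weaver_like"):
    table = read_table(BASE / "data" / f"{name}_clean.csv")
    res = mimicry_analysis(table, min_race_n=3)
    res.matrix.to_csv(BASE / f"{name}_mimicry_matrix.csv")
    res.summary.to_csv(BASE / f"{name}_mimicry_summary.tsv", sep="\t", index=False)
    print(f"\n== {name} ==")
    print(res.summary.to_string(index=False))
    if res.tested:
        print(f"mean own-minus-other difference: {res.mean_difference:.1f} "
              f"± {res.se_difference:.2f}% "
              f"(paired t{res.df} = {res.t_statistic:.2f}, p = {res.p_value:.3f})")
    else:
        print("fewer than 2 races with enough eggs: paired test skipped")

    both = table[table["role"].isin(["host", "parasite"])]
    counts = both["species"].value_counts()
    both = both[both["species"].isin(counts[counts >= 2].index)]  # plottable groups
    model = fit_lda(trait_matrix(both), both["species"].to_numpy())
    races = set(both.loc[both["role"] == "parasite", "species"])
    plot_df_space(model, trait_matrix(both), both["species"].to_numpy(),
                  path=FIG / f"{name}_mimicry_df_space.png",
                  title=f"{name} hosts (solid) and host-races (dashed)",
                  dashed_groups=races)
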