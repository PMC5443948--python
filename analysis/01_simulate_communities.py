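"""Generate the two synthetic egg communities and write them to results/data.

A warbler-like family (5 strongly partitioned parasitized species + 6
overlapping unparasitized species + 5 specialist host-races, two of them
with deliberately tiny samples) and a weaver-like family (10 overlapping
parasitized species + 4 distinct unparasitized species + 5 near-generalist
host-races).
"""

from pathlib import Path

from eggspace.simulate import (
    community_spec_to_json,
    generate_community,
    generate_host_races,
    warbler_like_spec,
    weaver_like_spec,
)
from eggspace.table import write_table

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

for name, preset in (("warbler_like", warbler_like_spec),
                     ("weaver_like", weaver_like_spec)):
    spec = preset(seed=SEED)
    table = generate_host_races(generate_community(spec), spec.host_races,
                                seed=SEED + 1)
    write_table(table, OUT / f"{name}_community.csv")
    community_spec_to_json(spec, OUT / f"{name}_spec.json")
    by_role = table.groupby("role").size().to_dict()
    print(f"{name}: {len(table)} eggs "
          f"({by_role.get('host', 0)} host, "
          f"{by_role.get('unparasitized', 0)} unparasitized, "
          f"{by_role.get('parasite', 0)} parasitic) "
          f"across {table['species'].nunique()} species/races")
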