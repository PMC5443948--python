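"""Config-driven end-to-end runs with provenance.

One call takes a community (a preset of the synthetic generator, or a user
CSV) through preprocessing, groupwise and pairwise partitioning analyses,
the host-race mimicry analysis, and phylogenetic-signal estimation, writing
every stage's table plus a provenance log to an output directory.  All
randomness is seeded from the config, so reruns are byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mimicry import mimicry_analysis
from .partition import (
    PARASITIZED,
    UNPARASITIZED,
    compare_groups,
    groupwise_analysis,
    pairwise_analysis,
    ranked_welch,
    table_report,
)
from .physignal import species_trait_means, summarize_over_trees
from .preprocess import (
    arcsine_sqrt_transform,
    collinearity_screen,
    mahalanobis_outliers,
    select_one_egg_per_clutch,
)
from .simulate import (
    generate_community,
    generate_host_races,
    simulate_tree,
    warbler_like_spec,
    weaver_like_spec,
)
from .table import ROLE_PARASITE, TRAITS, read_table, write_table

_PRESETS = {"warbler_like": warbler_like_spec, "weaver_like": weaver_like_spec}


def _version() -> str:
    from . import __version__

    return __version__


@dataclass
class RunConfig:
    preset: str | None = "warbler_like"   # or None with input_csv set
    input_csv: str | None = None
    seed: int = 0
    select_one_per_clutch: bool = True
    outlier_alpha: float | None = 0.001
    apply_transform: bool = False         # headline analyses run untransformed
    drop_collinear: bool = False          # and keep correlated traits
    r_threshold: float = 0.8
    min_race_n: int = 3
    n_trees: int = 25
    methods: tuple[str, ...] = ("dfa", "logistic")
    outdir: str | None = None

    def validate(self) -> None:
        if (self.preset is None) == (self.input_csv is None):
            raise ValueError("set exactly one of preset / input_csv")
        if self.preset is not None and self.preset not in _PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {sorted(_PRESETS)}")
        for m in self.methods:
            if m not in ("dfa", "logistic"):
                raise ValueError(f"unknown method {m!r}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["methods"] = tuple(payload.get("methods", ("dfa", "logistic")))
        return cls(**payload)


@dataclass
class PipelineReport:
    config: RunConfig
    table: pd.DataFrame
    groupwise: pd.DataFrame
    group_contrasts: dict
    pairwise: dict
    welch: dict
    mimicry: object
    lambda_summary: pd.DataFrame | None
    provenance: dict = field(default_factory=dict)


def _load_table(config: RunConfig) -> pd.DataFrame:
    if config.input_csv is not None:
        return read_table(config.input_csv)
    spec = _PRESETS[config.preset](seed=config.seed)
    community = generate_community(spec)
    return generate_host_races(community, spec.host_races, seed=spec.seed + 1)


def run_pipeline(config: RunConfig) -> PipelineReport:
    config.validate()
    t0 = time.time()
    provenance = {"eggspace_version": _version(), "config": asdict(config),
                  "stages": []}

    def stage(name, **info):
        provenance["stages"].append({"stage": name, "t": round(time.time() - t0, 3), **info})

    table = _load_table(config)
    stage("load", rows=len(table))

    if config.select_one_per_clutch:
        table = select_one_egg_per_clutch(table, seed=config.seed + 101)
        stage("one_egg_per_clutch", rows=len(table))

    if config.outlier_alpha is not None:
        table, flagged = mahalanobis_outliers(table, alpha=config.outlier_alpha)
        stage("outliers", flagged=len(flagged),
              flagged_species=flagged["species"].tolist())

    screen = collinearity_screen(table, r_threshold=config.r_threshold)
    traits = tuple(t for t in TRAITS if t not in screen.suggested_drops) \
        if config.drop_collinear else TRAITS
    stage("collinearity",
          flagged_pairs=[(a, b, round(r, 3)) for a, b, r in screen.flagged_pairs],
          dropped=list(screen.suggested_drops) if config.drop_collinear else [])

    if config.apply_transform:
        table, scaling = arcsine_sqrt_transform(table, traits=traits)
        stage("arcsine_sqrt", mins=scaling.mins, maxs=scaling.maxs)

    groupwise_results = []
    for group in (PARASITIZED, UNPARASITIZED):
        for method in config.methods:
            groupwise_results.append(
                groupwise_analysis(table, group, method=method, traits=traits))
    groupwise = table_report(groupwise_results)
    contrasts = {}
    for method in config.methods:
        pair = [r for r in groupwise_results if r.method == method]
        contrasts[method] = {
            "fisher_p_observed": compare_groups(pair[0], pair[1]),
            "fisher_p_expected": compare_groups(
                # contrast of the size-driven chance expectations
                _expected_as_result(pair[0]), _expected_as_result(pair[1])),
        }
    stage("groupwise")

    pairwise = {g: pairwise_analysis(table, g, traits=traits)
                for g in (PARASITIZED, UNPARASITIZED)}
    welch = {
        "observed": ranked_welch(pairwise[PARASITIZED].observed,
                                 pairwise[UNPARASITIZED].observed),
        "expected": ranked_welch(pairwise[PARASITIZED].expected,
                                 pairwise[UNPARASITIZED].expected),
    }
    stage("pairwise",
          n_pairs={g: len(p.pairs) for g, p in pairwise.items()})

    mimicry = None
    if (table["role"] == ROLE_PARASITE).any():
        mimicry = mimicry_analysis(table, min_race_n=config.min_race_n, traits=traits)
        stage("mimicry", tested=mimicry.tested,
              mean_difference=None if np.isnan(mimicry.mean_difference)
              else round(mimicry.mean_difference, 3))

    lambda_summary = None
    if config.n_trees > 0:
        host_table = table[table["role"] != ROLE_PARASITE]
        means = species_trait_means(host_table, traits=traits)
        if len(means) >= 4:
            trees = []
            for t_idx in range(config.n_trees):
                tree = simulate_tree(len(means), seed=config.seed + 500 + t_idx)
                for leaf, name in zip(tree.leaf_node_iter(), sorted(means.index)):
                    leaf.taxon.label = name
                trees.append(tree)
            lambda_summary = summarize_over_trees(trees, means).summary
            stage("physignal", n_trees=config.n_trees)

    report = PipelineReport(config, table, groupwise, contrasts, pairwise,
                            welch, mimicry, lambda_summary, provenance)
    if config.outdir is not None:
        _write_outputs(report, Path(config.outdir))
    return report


def _expected_as_result(res):
    """View a group result's chance expectation as a pseudo-observation."""
    from dataclasses import replace

    return replace(res, observed_correct=int(round(res.expected_correct)))


def _welch_row(name, w):
    return {"comparison": name, "statistic": round(w.statistic, 3),
            "df": round(w.df, 2), "p_value": w.p_value}


def _write_outputs(report: PipelineReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(report.table, outdir / "phenotypes_clean.csv")
    report.groupwise.to_csv(outdir / "groupwise_summary.tsv", sep="\t", index=False)
    pd.concat(
        [p.pairs.assign(group=g) for g, p in report.pairwise.items()],
        ignore_index=True,
    ).to_csv(outdir / "pairwise_accuracies.csv", index=False)
    pd.DataFrame([_welch_row(k, w) for k, w in report.welch.items()]).to_csv(
        outdir / "pairwise_welch.tsv", sep="\t", index=False)
    if report.mimicry is not None:
        report.mimicry.matrix.to_csv(outdir / "mimicry_matrix.csv")
        report.mimicry.summary.to_csv(outdir / "mimicry_summary.tsv",
                                      sep="\t", index=False)
    if report.lambda_summary is not None:
        report.lambda_summary.to_csv(outdir / "lambda_summary.tsv",
                                     sep="\t", index=False)
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(report.provenance, fh, indent=1, default=str)
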