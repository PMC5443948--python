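"""Conventions for the egg phenotype table.

The unit of every analysis in this package is a tidy table with one row per
egg.  Metadata columns identify the species, the clutch the egg came from,
its role in the community (host of a brood parasite, unparasitized
bystander, or parasitic egg laid by a host-race), and — for parasitic eggs —
the host species the race specializes on.  The ten trait columns hold a
luminance index (double-cone photon catch), four single-cone photon catches
(UV, SW, MW, LW) and five pattern metrics derived from granularity analysis
of egg photographs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Fixed trait order used throughout the package.
TRAITS: tuple[str, ...] = (
    "luminance",
    "uv",
    "sw",
    "mw",
    "lw",
    "marking_size",
    "main_contribution",
    "contrast",
    "coverage",
    "dispersion",
)

#: Trait columns that are proportions / bounded pattern statistics in [0, 1].
PATTERN_TRAITS: tuple[str, ...] = (
    "marking_size",
    "main_contribution",
    "contrast",
    "coverage",
    "dispersion",
)

META_COLUMNS: tuple[str, ...] = ("species", "clutch_id", "role", "target_host")

COLUMNS: tuple[str, ...] = META_COLUMNS + TRAITS

ROLE_HOST = "host"
ROLE_UNPARASITIZED = "unparasitized"
ROLE_PARASITE = "parasite"
ROLES = (ROLE_HOST, ROLE_UNPARASITIZED, ROLE_PARASITE)


def validate_table(table: pd.DataFrame, traits: tuple[str, ...] | list[str] = TRAITS) -> None:
    """Raise ``ValueError`` if *table* violates the phenotype-table contract."""
    missing = [c for c in META_COLUMNS if c not in table.columns]
    missing += [c for c in traits if c not in table.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    bad_roles = set(table["role"].unique()) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles in table: {sorted(bad_roles)}")
    values = table[list(traits)].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite trait values in phenotype table")


def trait_matrix(table: pd.DataFrame, traits: tuple[str, ...] | list[str] = TRAITS) -> np.ndarray:
    """Return the n x d float matrix of trait values in canonical order."""
    return table[list(traits)].to_numpy(dtype=float)


def read_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_table(table)
    return table


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)
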