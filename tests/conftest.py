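import numpy as np
import pandas as pd
import pytest

from eggspace.simulate import (
    CommunitySpec,
    HostRaceSpec,
    SpeciesSpec,
    default_within_cov,
    generate_community,
    generate_host_races,
    make_species_specs,
    warbler_like_spec,
)
from eggspace.table import TRAITS


def two_cluster_data(n_per_group=30, distance=0.0, d=10, seed=0):
    """Two spherical Gaussian groups separated by `distance` along axis 0."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_group, d))
    b = rng.standard_normal((n_per_group, d))
    b[:, 0] += distance
    X = np.vstack([a, b])
    labels = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    return X, labels


def community_with_separation(sizes, separation, seed, parasitized=True):
    rng = np.random.default_rng(seed)
    specs = make_species_specs(
        [f"sp{i}" for i in range(len(sizes))], parasitized, sizes, separation, rng)
    return generate_community(CommunitySpec(species=specs, seed=seed + 1))


@pytest.fixture(scope="session")
def warbler_table():
    """Warbler-like preset community with host-race eggs appended."""
    spec = warbler_like_spec(seed=11)
    community = generate_community(spec)
    return generate_host_races(community, spec.host_races, seed=12)


@pytest.fixture(scope="session")
def small_community():
    """3 well-sampled species at moderate separation, 60 rows total."""
    return community_with_separation([20, 20, 20], separation=0.8, seed=5)
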