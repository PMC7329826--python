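import numpy as np
import pytest

from neurodyad.connectivity import fisher_z
from neurodyad.social import build_social_graph, detect_communities, social_distance
from neurodyad.synthetic import (
    SimConfig,
    planted_groups,
    simulate_social_roster,
    simulate_subject_connectomes,
)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """A desk-scale cohort: 18 students, 3 groups, 16 parcels."""
    return SimConfig(
        n_students=18, n_parcels=16, n_timepoints=100, n_groups=3,
        theta=0.4, eta=0.3, seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """Roster, graph, distances, partition, connectomes and z-matrices."""
    roster = simulate_social_roster(small_config)
    graph = build_social_graph(roster, threshold=4, mode="reciprocal")
    distances = social_distance(graph)
    partition = detect_communities(graph, seed=1, restarts=25)
    matrices, truth = simulate_subject_connectomes(
        planted_groups(small_config), small_config
    )
    zmats = [fisher_z(m) for m in matrices]
    return {
        "config": small_config,
        "roster": roster,
        "graph": graph,
        "distances": distances,
        "partition": partition,
        "matrices": matrices,
        "truth": truth,
        "zmats": zmats,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
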