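import networkx as nx
import pytest

from jmenet import BrainNetwork, ConnectivityChangeRecord, RecordSet


def make_record(
    pair,
    direction=None,
    raw_r=None,
    study="S01",
    indicator="FC",
    modality="MRI",
    n_patients=20,
    n_controls=20,
):
    return ConnectivityChangeRecord(
        study_id=study,
        modality=modality,
        indicator=indicator,
        region_a=pair[0],
        region_b=pair[1],
        direction=direction,
        raw_r=raw_r,
        n_patients=n_patients,
        n_controls=n_controls,
    )


def record_set(specs):
    """Build a RecordSet from (pair, direction[, study]) tuples."""
    records = []
    for i, spec in enumerate(specs):
        pair, direction = spec[0], spec[1]
        study = spec[2] if len(spec) > 2 else f"S{i:02d}"
        records.append(make_record(pair, direction=direction, study=study))
    return RecordSet(records=records)


@pytest.fixture
def path_p3():
    return BrainNetwork(nx.path_graph(["a", "b", "c"]))


@pytest.fixture
def cycle_c4():
    return BrainNetwork(nx.cycle_graph(4))


def random_connected_graph(rng, n_nodes, p=0.35):
    """Seeded G(n, p) conditioned on connectivity (resample until connected)."""
    while True:
        g = nx.gnp_random_graph(n_nodes, p, seed=int(rng.integers(2**31)))
        if g.number_of_nodes() and nx.is_connected(g):
            return g
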