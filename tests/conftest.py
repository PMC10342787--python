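import networkx as nx
import numpy as np
import pytest

from fusionpace import (
    AnatomySpec,
    CohortSpec,
    HeartGraph,
    PatientParams,
    build_heart_graph,
    calibrate_conduction,
    place_leads,
)


def make_heart_graph(positions, edges, region=None, layer=None,
                     breakout=None, rv_lead=None, lv_lead=None) -> HeartGraph:
    """Hand-built HeartGraph for small deterministic tests.

    ``edges`` is an iterable of (u, v, time_ms).
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    region = np.asarray(region if region is not None else ["rv_free_wall"] * n)
    layer = np.asarray(layer if layer is not None else ["endo"] * n)
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, pos=positions[i], region=region[i], layer=layer[i])
    for u, v, t in edges:
        g.add_edge(u, v, time_ms=float(t))
    return HeartGraph(
        graph=g,
        positions=positions,
        region=region,
        layer=layer,
        intrinsic_breakout_nodes=list(breakout or []),
        rv_lead=rv_lead,
        lv_lead=lv_lead,
    )


def random_heart_graph(rng: np.random.Generator, n_max: int = 50) -> HeartGraph:
    """Random connected weighted graph wrapped as a HeartGraph."""
    n = int(rng.integers(3, n_max + 1))
    g = nx.Graph()
    positions = rng.normal(size=(n, 3)) * 10.0
    edges = []
    order = rng.permutation(n)
    for i in range(1, n):  # random spanning tree guarantees connectivity
        j = order[int(rng.integers(0, i))]
        edges.append((int(order[i]), int(j), float(rng.uniform(0.5, 20.0))))
    n_extra = int(rng.integers(0, 2 * n))
    for _ in range(n_extra):
        u, v = rng.integers(0, n, size=2)
        if u != v:
            edges.append((int(u), int(v), float(rng.uniform(0.5, 20.0))))
    return make_heart_graph(positions, edges)


@pytest.fixture(scope="session")
def anatomy() -> AnatomySpec:
    return AnatomySpec()


@pytest.fixture(scope="session")
def heart(anatomy) -> HeartGraph:
    return place_leads(build_heart_graph(anatomy))


@pytest.fixture(scope="session")
def mean_patient() -> PatientParams:
    return PatientParams(
        patient_id="P01", pr_interval_ms=189.0, target_native_vat_ms=181.6
    )


@pytest.fixture(scope="session")
def calibrated_patient(heart, mean_patient) -> PatientParams:
    return calibrate_conduction(heart, mean_patient, tol_ms=0.5)


@pytest.fixture()
def chain_graph() -> HeartGraph:
    """3-node chain with 10 ms edges; node 0 is breakout and RV lead."""
    return make_heart_graph(
        positions=[(0, 0, 0), (10, 0, 0), (20, 0, 0)],
        edges=[(0, 1, 10.0), (1, 2, 10.0)],
        breakout=[0],
        rv_lead=0,
        lv_lead=2,
    )


@pytest.fixture(scope="session")
def default_cohort_spec() -> CohortSpec:
    return CohortSpec()
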