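import itertools

import numpy as np
import pytest

from cocoanet.network import (
    build_network,
    connected_components,
    export_network,
    read_edge_csv,
    size_curve,
    sweep,
)
from tests.conftest import matrix_from_array


def test_build_keeps_edges_at_or_above_threshold():
    m = matrix_from_array(
        [[1.0, 0.9, 0.2], [0.9, 1.0, -0.1], [0.2, -0.1, 1.0]], ids=["s1", "s2", "s3"]
    )
    net = build_network(m, 0.5)
    assert net.edges == [("s1", "s2")]
    assert net.isolated_nodes == ["s3"]
    assert net.graph["s1"]["s2"]["weight"] == pytest.approx(0.9)


def test_threshold_one_gives_empty_network(four_node_matrix):
    net = build_network(four_node_matrix, 1.0)
    assert net.n_edges == 0
    assert set(net.isolated_nodes) == set(net.nodes)


def test_threshold_zero_excludes_nonpositive_correlations(four_node_matrix):
    # 4 positive off-diagonal pairs; -0.2 and 0.0 never form edges
    net = build_network(four_node_matrix, 0.0)
    assert net.n_edges == 4
    assert ("A1", "B2") not in [tuple(sorted(e)) for e in net.edges]


def test_all_positive_matrix_gives_complete_graph():
    n = 5
    arr = np.full((n, n), 0.3)
    net = build_network(matrix_from_array(arr), 0.0)
    assert net.n_edges == n * (n - 1) // 2


@pytest.mark.parametrize("threshold", [-0.1, 1.5])
def test_threshold_out_of_range_rejected(four_node_matrix, threshold):
    with pytest.raises(ValueError):
        build_network(four_node_matrix, threshold)


def test_sweep_requires_increasing_thresholds(four_node_matrix):
    with pytest.raises(ValueError):
        sweep(four_node_matrix, [0.5, 0.3])


def test_sweep_edge_sets_are_nested(four_node_matrix):
    nets = sweep(four_node_matrix, [round(0.1 * k, 1) for k in range(1, 10)])
    edge_sets = [set(map(tuple, map(sorted, n.edges))) for n in nets]
    for low, high in zip(edge_sets, edge_sets[1:]):
        assert high <= low
    counts = [len(s) for s in edge_sets]
    assert counts == sorted(counts, reverse=True)


def test_sweep_step_function_around_uniform_weight():
    arr = np.full((4, 4), 0.55)
    nets = sweep(matrix_from_array(arr), [0.5, 0.6])
    assert nets[0].n_edges == 6
    assert nets[1].n_edges == 0


def test_size_curve_counts():
    m = matrix_from_array(
        [
            [1.0, 0.9, 0.0, 0.0, 0.0],
            [0.9, 1.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.8, 0.0],
            [0.0, 0.0, 0.8, 1.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 1.0],
        ]
    )
    curve = size_curve(sweep(m, [0.5, 0.95]))
    assert curve.loc[0].tolist() == [0.5, 2, 4, 2]  # two disjoint edges
    assert curve.loc[1].tolist() == [0.95, 0, 0, 0]  # empty network


def test_single_edge_size_curve(four_node_matrix):
    curve = size_curve([build_network(four_node_matrix, 0.85)])
    row = curve.iloc[0]
    assert (row.n_edges, row.n_connected_nodes, row.n_components) == (1, 2, 1)


def _closure_components(nodes, edges):
    """Brute-force transitive closure oracle."""
    reach = {n: {n} for n in nodes}
    for a, b in edges:
        reach[a].add(b)
        reach[b].add(a)
    changed = True
    while changed:
        changed = False
        for n in nodes:
            new = set().union(*(reach[m] for m in reach[n]))
            if new != reach[n]:
                reach[n] = new
                changed = True
    comps = {frozenset(reach[n]) for n in nodes if len(reach[n]) > 1}
    return {tuple(sorted(c)) for c in comps}


def test_components_match_transitive_closure_oracle():
    rng = np.random.default_rng(3)
    for _ in range(20):
        n = 20
        arr = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.08:
                arr[i, j] = arr[j, i] = rng.uniform(0.5, 1.0)
        net = build_network(matrix_from_array(arr), 0.4)
        ours = {tuple(c) for c in connected_components(net)}
        oracle = _closure_components(net.nodes, net.edges)
        assert ours == oracle


def test_components_sorted_by_size_then_smallest_member():
    m = matrix_from_array(
        [
            [1.0, 0.9, 0.0, 0.0, 0.0, 0.0],
            [0.9, 1.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 1.0, 0.9, 0.9, 0.0],
            [0.0, 0.0, 0.9, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.9, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 1.0],
        ],
        ids=["e", "f", "a", "b", "c", "z"],
    )
    comps = connected_components(build_network(m, 0.5))
    assert comps == [["a", "b", "c"], ["e", "f"]]


def test_sif_export_single_edge(tmp_path, four_node_matrix):
    net = build_network(four_node_matrix, 0.85)
    path = tmp_path / "net.sif"
    export_network(net, path, "sif")
    assert path.read_text().strip() == "A1 cc A2"


def test_edge_csv_round_trip(tmp_path, four_node_matrix):
    net = build_network(four_node_matrix, 0.0)
    path = tmp_path / "net.csv"
    export_network(net, path, "edge-csv")
    parsed = read_edge_csv(path)
    expected = {
        (a, b): net.graph[a][b]["weight"] for a, b in net.edges
    }
    assert {(a, b): w for a, b, w in parsed} == {
        (min(a, b), max(a, b)): w for (a, b), w in expected.items()
    }


def test_empty_network_export_writes_full_node_file(tmp_path, four_node_matrix):
    import pandas as pd

    net = build_network(four_node_matrix, 1.0)
    path = tmp_path / "empty.csv"
    export_network(net, path, "edge-csv")
    assert len(read_edge_csv(path)) == 0
    nodes = pd.read_csv(tmp_path / "empty_nodes.csv")
    assert len(nodes) == 4 and nodes["isolated"].all()
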