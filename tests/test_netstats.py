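import itertools

import numpy as np
import pandas as pd
import pytest

from cocoanet.errors import UndefinedValueError, ValidationError
from cocoanet.netstats import (
    accuracy_curve,
    confusion_counts,
    edge_similarity,
    ideal_network,
    null_ensemble,
    similarity_curves,
)
from cocoanet.network import build_network
from tests.conftest import matrix_from_array


def test_similarity_one_when_all_labels_equal(four_node_matrix):
    net = build_network(four_node_matrix, 0.0)
    labels = {n: "X" for n in net.nodes}
    assert edge_similarity(net, labels) == 1.0


def test_similarity_hand_count(four_node_matrix, four_node_labels):
    # edges at t=0: (A1,A2) same, (A1,B1) cross, (B1,B2) same, (A2,B2) cross
    net = build_network(four_node_matrix, 0.0)
    assert edge_similarity(net, four_node_labels) == 0.5


def test_similarity_undefined_on_empty_network(four_node_matrix, four_node_labels):
    net = build_network(four_node_matrix, 1.0)
    with pytest.raises(UndefinedValueError):
        edge_similarity(net, four_node_labels)


def test_similarity_missing_label_is_validation_error(four_node_matrix):
    net = build_network(four_node_matrix, 0.0)
    with pytest.raises(ValidationError):
        edge_similarity(net, {"A1": "A", "A2": "A", "B1": "B"})


def test_similarity_curves_match_hand_counts(four_node_matrix, four_node_labels):
    curves = similarity_curves(
        four_node_matrix, {"labels": four_node_labels}, [0.3, 0.5, 0.7, 0.95]
    )
    by_t = curves.set_index("threshold")
    # t=0.3: edges 0.9,0.6,0.8,0.4 -> same-label 0.9,0.8 of 4
    assert by_t.loc[0.3, "similarity"] == 0.5
    # t=0.5: edges 0.9,0.6,0.8 -> 2/3
    assert by_t.loc[0.5, "similarity"] == pytest.approx(2 / 3)
    # t=0.7: edges 0.9,0.8 -> 1
    assert by_t.loc[0.7, "similarity"] == 1.0
    # t=0.95: no edges -> undefined (NaN), never 0
    assert np.isnan(by_t.loc[0.95, "similarity"])
    assert by_t.loc[0.95, "n_edges"] == 0


def test_ideal_network_edges_iff_same_label():
    labels = pd.Series({"a": "A", "b": "A", "c": "B"})
    net = ideal_network(labels)
    assert [tuple(sorted(e)) for e in net.edges] == [("a", "b")]


def test_ideal_network_all_distinct_is_empty():
    net = ideal_network(pd.Series({"a": 1, "b": 2, "c": 3}))
    assert net.n_edges == 0


def test_ideal_network_pair_counting():
    labels = pd.Series({k: ("X" if k < "d" else "Y") for k in "abcde"})
    # class sizes (3, 2) -> 3 + 1 = 4 edges
    assert ideal_network(labels).n_edges == 4


def test_accuracy_worked_four_node_example(four_node_labels):
    # network edges {(A1,A2), (A1,B1)} -> TP=1, FP=1, FN=1, TN=3, alpha=4/6
    arr = np.zeros((4, 4))
    ids = ["A1", "A2", "B1", "B2"]
    arr[0, 1] = arr[1, 0] = 0.9
    arr[0, 2] = arr[2, 0] = 0.9
    m = matrix_from_array(arr, ids)
    curve = accuracy_curve(m, four_node_labels, [0.5])
    row = curve.iloc[0]
    assert (row.tp, row.tn, row.fp, row.fn) == (1, 3, 1, 1)
    assert row.accuracy == pytest.approx(4 / 6)


def test_accuracy_one_when_network_equals_ideal(four_node_labels):
    arr = np.zeros((4, 4))
    arr[0, 1] = arr[1, 0] = 0.9  # A1-A2
    arr[2, 3] = arr[3, 2] = 0.9  # B1-B2
    m = matrix_from_array(arr, ["A1", "A2", "B1", "B2"])
    assert accuracy_curve(m, four_node_labels, [0.5]).iloc[0].accuracy == 1.0


def test_empty_network_accuracy_counts_cross_label_absences(four_node_labels):
    # P=6 pairs, k=2 same-label pairs -> alpha = (6-2)/6
    arr = np.zeros((4, 4))
    m = matrix_from_array(arr, ["A1", "A2", "B1", "B2"])
    row = accuracy_curve(m, four_node_labels, [0.5]).iloc[0]
    assert (row.tp, row.tn, row.fp, row.fn) == (0, 4, 0, 2)
    assert row.accuracy == pytest.approx(4 / 6)


def _brute_force_confusion(nodes, edges, labels):
    edge_set = {frozenset(e) for e in edges}
    tp = tn = fp = fn = 0
    for a, b in itertools.combinations(nodes, 2):
        present = frozenset((a, b)) in edge_set
        same = labels[a] == labels[b]
        if present and same:
            tp += 1
        elif present:
            fp += 1
        elif same:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def test_confusion_matches_pair_enumeration_oracle_on_random_graphs():
    rng = np.random.default_rng(11)
    for _ in range(50):
        n = int(rng.integers(3, 9))
        ids = [f"s{k}" for k in range(n)]
        arr = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.4:
                arr[i, j] = arr[j, i] = rng.uniform(0.3, 1.0)
        labels = {s: rng.choice(["A", "B", "C"]) for s in ids}
        net = build_network(matrix_from_array(arr, ids), 0.25)
        ours = confusion_counts(net, labels)
        oracle = _brute_force_confusion(ids, net.edges, labels)
        assert ours == oracle
        assert sum(ours) == n * (n - 1) // 2


def test_null_mean_one_sd_zero_for_identical_labels(four_node_matrix):
    labels = {n: "X" for n in four_node_matrix.sample_ids}
    out = null_ensemble(four_node_matrix, {"all": labels}, [0.3, 0.7], n_reps=10, seed=0)
    assert (out["null_mean"] == 1.0).all()
    assert (out["null_sd"] == 0.0).all()


def test_null_mean_matches_full_network_similarity(four_node_matrix, four_node_labels):
    """Expected null similarity at any threshold equals the threshold-0 value.

    A weight-permuted thresholded network is a uniformly random k-subset
    of the positive pairs, so E[similarity] = s0 at every threshold.
    """
    s0 = edge_similarity(build_network(four_node_matrix, 0.0), four_node_labels)
    out = null_ensemble(
        four_node_matrix, {"labels": four_node_labels}, [0.3, 0.5, 0.7], n_reps=2000, seed=5
    )
    for _, row in out.iterrows():
        se = row.null_sd / np.sqrt(2000)
        assert abs(row.null_mean - s0) <= max(3 * se, 0.02)


def test_null_ensemble_is_deterministic_under_seed(four_node_matrix, four_node_labels):
    kwargs = dict(n_reps=100, seed=42)
    a = null_ensemble(four_node_matrix, {"l": four_node_labels}, [0.3, 0.7], **kwargs)
    b = null_ensemble(four_node_matrix, {"l": four_node_labels}, [0.3, 0.7], **kwargs)
    pd.testing.assert_frame_equal(a, b)


def test_null_ensemble_requires_positive_weights(four_node_labels):
    arr = np.zeros((4, 4))
    m = matrix_from_array(arr, ["A1", "A2", "B1", "B2"])
    with pytest.raises(UndefinedValueError):
        null_ensemble(m, {"l": four_node_labels}, [0.1], n_reps=5, seed=0)


def test_null_permute_all_pairs_variant_runs(four_node_matrix, four_node_labels):
    out = null_ensemble(
        four_node_matrix, {"l": four_node_labels}, [0.3], n_reps=50, seed=1,
        permute_all_pairs=True,
    )
    assert out["null_mean"].between(0, 1).all()
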