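"""Edge-similarity statistics, null ensembles and ideal-network accuracy.

Edge similarity of a labeled network is the fraction of edges whose two
endpoint samples carry the same attribute value (processing stage, or
origin). It is an edge-level statistic, never a cluster-level one. The
null model permutes the multiset of positive correlations over the node
pairs that carry a positive correlation, re-thresholds, and reports the
ensemble mean and standard deviation; since a weight-permuted thresholded
network is a uniformly random k-subset of the full edge set, its expected
similarity at every threshold equals the full-network similarity — the
flat null line against which enrichment is judged.

Accuracy compares a thresholded network with the attribute-defined ideal
network (edge iff the endpoints share the attribute): every unordered
sample pair is a true/false positive/negative, and accuracy is
(TP + TN) / (n(n-1)/2).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from cocoanet.correlation import CorrelationMatrix
from cocoanet.errors import UndefinedValueError, ValidationError
from cocoanet.network import ThresholdedNetwork, build_network, sweep

Labels = Mapping | pd.Series


def _label_array(labels: Labels, nodes: Sequence) -> np.ndarray:
    missing = [n for n in nodes if n not in labels or pd.isna(labels[n])]
    if missing:
        raise ValidationError(f"nodes without labels: {missing[:5]}")
    return np.asarray([labels[n] for n in nodes], dtype=object)


def edge_similarity(network: ThresholdedNetwork, labels: Labels) -> float:
    """Fraction of edges joining same-label endpoints.

    Raises :class:`UndefinedValueError` on an edgeless network (an empty
    denominator, not a similarity of 0).
    """
    _label_array(labels, network.nodes)  # validate coverage
    edges = network.edges
    if not edges:
        raise UndefinedValueError(
            f"similarity undefined: no edges at threshold {network.threshold}"
        )
    same = sum(1 for a, b in edges if labels[a] == labels[b])
    return same / len(edges)


def similarity_curves(
    matrix: CorrelationMatrix,
    labels_by_attribute: Mapping[str, Labels],
    thresholds: Sequence[float],
) -> pd.DataFrame:
    """Edge similarity per attribute across a threshold sweep.

    Returns a tidy frame (threshold, attribute, similarity, n_edges);
    undefined points carry NaN similarity.
    """
    rows = []
    for net in sweep(matrix, thresholds):
        for attribute, labels in labels_by_attribute.items():
            try:
                sim = edge_similarity(net, labels)
            except UndefinedValueError:
                sim = np.nan
            rows.append(
                {
                    "threshold": net.threshold,
                    "attribute": attribute,
                    "similarity": sim,
                    "n_edges": net.n_edges,
                }
            )
    return pd.DataFrame(rows)


def _positive_pairs(matrix: CorrelationMatrix):
    """Upper-triangle pairs with strictly positive correlation."""
    values = matrix.values.to_numpy()
    rows, cols = np.triu_indices(matrix.n_samples, k=1)
    weights = values[rows, cols]
    keep = weights > 0
    return rows[keep], cols[keep], weights[keep]


def null_ensemble(
    matrix: CorrelationMatrix,
    labels_by_attribute: Mapping[str, Labels],
    thresholds: Sequence[float],
    n_reps: int = 100,
    seed: int | np.random.Generator | None = None,
    *,
    permute_all_pairs: bool = False,
) -> pd.DataFrame:
    """Null similarity bands from weight-permuted control networks.

    Each replicate permutes the positive correlations uniformly at random
    over the pairs that carry positive weight in the full (threshold-0)
    network, preserving the correlation distribution, then re-thresholds
    and recomputes edge similarity. With ``permute_all_pairs`` the weights
    are instead scattered over all n(n-1)/2 pairs (zero elsewhere), a
    sensitivity variant. Returns (threshold, attribute, null_mean,
    null_sd); one random stream, seeded once, drives all replicates.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates for a mean and sd")
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    rng = np.random.default_rng(seed)
    ids = matrix.sample_ids
    rows, cols, weights = _positive_pairs(matrix)
    if weights.size == 0:
        raise UndefinedValueError("no positive correlations: null model undefined")

    if permute_all_pairs:
        all_rows, all_cols = np.triu_indices(len(ids), k=1)
        slots = np.stack([all_rows, all_cols], axis=1)
    else:
        slots = np.stack([rows, cols], axis=1)

    label_arrays = {
        attr: _label_array(labels, ids) for attr, labels in labels_by_attribute.items()
    }
    same = {
        attr: arr[slots[:, 0]] == arr[slots[:, 1]] for attr, arr in label_arrays.items()
    }

    sims = {attr: np.full((n_reps, len(thresholds)), np.nan) for attr in same}
    slot_weights = np.zeros(len(slots))
    for rep in range(n_reps):
        positions = (
            rng.choice(len(slots), size=weights.size, replace=False)
            if permute_all_pairs
            else rng.permutation(len(slots))
        )
        slot_weights[:] = 0.0
        slot_weights[positions] = weights
        for j, t in enumerate(thresholds):
            mask = (slot_weights >= t) & (slot_weights > 0)
            if mask.any():
                for attr, s in same.items():
                    sims[attr][rep, j] = s[mask].mean()

    records = []
    for attr in same:
        for j, t in enumerate(thresholds):
            column = sims[attr][:, j]
            column = column[np.isfinite(column)]
            records.append(
                {
                    "threshold": t,
                    "attribute": attr,
                    # population sd over replicates, the ensemble's "mean
                    # and standard deviation of the studied property"
                    "null_mean": column.mean() if column.size else np.nan,
                    "null_sd": column.std() if column.size else np.nan,
                }
            )
    return pd.DataFrame(records)


def ideal_network(labels: Labels, nodes: Sequence | None = None) -> ThresholdedNetwork:
    """Attribute-defined reference network: edge iff labels match.

    Its edge count is sum over label classes c of n_c(n_c-1)/2.
    """
    if nodes is None:
        nodes = list(labels.keys()) if isinstance(labels, Mapping) else list(labels.index)
    arr = _label_array(labels, nodes)
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    n = len(nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if arr[i] == arr[j]:
                graph.add_edge(nodes[i], nodes[j], weight=1.0)
    isolated = {u: d == 0 for u, d in graph.degree}
    nx.set_node_attributes(graph, isolated, "isolated")
    return ThresholdedNetwork(graph=graph, threshold=0.0, method="ideal")


def confusion_counts(
    network: ThresholdedNetwork, labels: Labels
) -> tuple[int, int, int, int]:
    """(tp, tn, fp, fn) of the network's edges against the ideal network."""
    nodes = network.nodes
    arr = _label_array(labels, nodes)
    index = {n: k for k, n in enumerate(nodes)}
    n = len(nodes)
    total = n * (n - 1) // 2
    same_pairs = sum(
        int(c * (c - 1) // 2) for c in pd.Series(arr).value_counts()
    )
    tp = fp = 0
    for a, b in network.edges:
        if arr[index[a]] == arr[index[b]]:
            tp += 1
        else:
            fp += 1
    fn = same_pairs - tp
    tn = total - tp - fp - fn
    return tp, tn, fp, fn


def accuracy_curve(
    matrix: CorrelationMatrix,
    labels: Labels,
    thresholds: Sequence[float],
    attribute: str = "labels",
) -> pd.DataFrame:
    """TP/TN/FP/FN and accuracy against the ideal network, per threshold.

    Every unordered sample pair is classified; accuracy is
    (TP + TN) / (n(n-1)/2).
    """
    n = matrix.n_samples
    total = n * (n - 1) // 2
    rows = []
    for net in sweep(matrix, thresholds):
        tp, tn, fp, fn = confusion_counts(net, labels)
        rows.append(
            {
                "threshold": net.threshold,
                "attribute": attribute,
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
                "accuracy": (tp + tn) / total,
            }
        )
    return pd.DataFrame(rows)
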