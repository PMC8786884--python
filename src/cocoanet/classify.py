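"""Neighbor majority-vote inference of a sample's stage or origin.

A new sample's category can be read off a correlation network: the most
frequent label among its neighbors at a suitable threshold predicts its
processing stage (intermediate thresholds) or origin (high thresholds).
Votes are evaluated leave-one-out — the queried node's own label is never
consulted — and can optionally extend to next-to-nearest neighbors when
direct neighborhoods are sparse. A tie, or an empty voter set, yields an
explicit undefined outcome rather than an arbitrary choice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from cocoanet.correlation import CorrelationMatrix
from cocoanet.netstats import Labels, _label_array
from cocoanet.network import ThresholdedNetwork, build_network

CORRECT = "correct"
INCORRECT = "incorrect"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class PredictionGrid:
    """Vote outcomes for every node across a threshold sweep.

    ``outcomes``: node x threshold frame of {correct, incorrect, undefined};
    ``predicted``: the voted label where defined, else NaN.
    An outcome is undefined exactly when the node has no voters at that
    threshold or the vote ties.
    """

    attribute: str
    outcomes: pd.DataFrame
    predicted: pd.DataFrame

    @property
    def thresholds(self) -> list[float]:
        return list(self.outcomes.columns)

    @property
    def nodes(self) -> list:
        return list(self.outcomes.index)


def _voters(graph: nx.Graph, node, radius: int) -> set:
    voters = set(graph.neighbors(node))
    if radius == 2:
        for nb in list(voters):
            voters.update(graph.neighbors(nb))
        voters.discard(node)
    return voters


def majority_vote(
    network: ThresholdedNetwork,
    labels: Labels,
    node,
    radius: int = 1,
    *,
    weighted: bool = False,
):
    """Predict ``node``'s label from its neighbors' labels, or None.

    Radius-2 voters are every node at graph distance 1 or 2, counted once.
    With ``weighted``, each voter contributes its edge correlation instead
    of a unit vote (a distance-2 voter contributes its best two-step path
    strength, the max over intermediates of the product of the two edge
    weights). Returns None on zero voters or a tied top count.
    """
    graph = network.graph
    if node not in graph:
        raise ValueError(f"unknown node {node!r}")
    if radius not in (1, 2):
        raise ValueError("radius must be 1 or 2")
    voters = _voters(graph, node, radius)
    if not voters:
        return None

    if weighted:
        scores: Counter = Counter()
        direct = set(graph.neighbors(node))
        for v in voters:
            if v in direct:
                w = graph[node][v]["weight"]
            else:
                w = max(
                    graph[node][k]["weight"] * graph[k][v]["weight"]
                    for k in direct
                    if v in graph[k]
                )
            scores[labels[v]] += w
    else:
        scores = Counter(labels[v] for v in voters)

    ranked = scores.most_common(2)
    if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
        return None
    return ranked[0][0]


def prediction_grid(
    matrix: CorrelationMatrix,
    labels: Labels,
    thresholds: Sequence[float],
    attribute: str = "labels",
    radius: int = 1,
    *,
    weighted: bool = False,
) -> PredictionGrid:
    """Leave-one-out majority vote for every node at every threshold.

    The node's true label is hidden from its own vote (it is never a
    voter) but scores the prediction: correct iff the voted label equals
    the true label.
    """
    thresholds = list(thresholds)
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    nodes = matrix.sample_ids
    truth = dict(zip(nodes, _label_array(labels, nodes)))
    outcomes = pd.DataFrame(UNDEFINED, index=nodes, columns=thresholds, dtype=object)
    predicted = pd.DataFrame(np.nan, index=nodes, columns=thresholds, dtype=object)
    for t in thresholds:
        net = build_network(matrix, t)
        for node in nodes:
            vote = majority_vote(net, labels, node, radius, weighted=weighted)
            if vote is None:
                continue
            predicted.loc[node, t] = vote
            outcomes.loc[node, t] = CORRECT if vote == truth[node] else INCORRECT
    return PredictionGrid(attribute=attribute, outcomes=outcomes, predicted=predicted)


def mean_prediction_score(grid: PredictionGrid) -> pd.Series:
    """Per-threshold fraction of correct votes among defined outcomes.

    Thresholds where every outcome is undefined yield NaN (an explicit
    null, never 0).
    """
    scores = {}
    for t in grid.thresholds:
        col = grid.outcomes[t]
        defined = int((col != UNDEFINED).sum())
        scores[t] = (col == CORRECT).sum() / defined if defined else np.nan
    return pd.Series(scores, name="mean_prediction_score")


def write_grid_csv(grid: PredictionGrid, path: str | Path) -> None:
    """CSV matrix: rows = sample ids, columns = thresholds, cells = outcome."""
    grid.outcomes.to_csv(path, index_label="sample_id")


def write_score_csv(grid: PredictionGrid, path: str | Path) -> None:
    scores = mean_prediction_score(grid)
    pd.DataFrame(
        {
            "threshold": scores.index,
            "attribute": grid.attribute,
            "mean_prediction_score": scores.to_numpy(),
        }
    ).to_csv(path, index=False)
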