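"""Thresholded correlation networks and the threshold sweep.

An edge joins two samples when their correlation is both at least the
threshold and strictly positive; negative correlations never form edges,
so the threshold-0 network contains exactly the positive correlations.
All samples stay in the node set — isolation is a per-node flag, and the
"dropped isolates" convention of size reporting only affects counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from cocoanet.correlation import CorrelationMatrix

ExportFormat = Literal["sif", "edge-csv"]


@dataclass(frozen=True)
class ThresholdedNetwork:
    """Correlation network surviving a threshold.

    ``graph`` holds every sample as a node (boolean attribute ``isolated``)
    and an ``weight`` attribute per edge carrying the correlation.
    """

    graph: nx.Graph
    threshold: float
    method: str

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def edges(self) -> list[tuple]:
        return list(self.graph.edges)

    @property
    def connected_nodes(self) -> list:
        return [n for n, d in self.graph.degree if d > 0]

    @property
    def isolated_nodes(self) -> list:
        return [n for n, d in self.graph.degree if d == 0]


def build_network(matrix: CorrelationMatrix, threshold: float) -> ThresholdedNetwork:
    """Build the network of sample pairs with correlation >= threshold (> 0).

    Raises
    ------
    ValueError
        If ``threshold`` lies outside [0, 1].
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    ids = matrix.sample_ids
    values = matrix.values.to_numpy()
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    rows, cols = np.triu_indices(len(ids), k=1)
    keep = (values[rows, cols] >= threshold) & (values[rows, cols] > 0.0)
    for r, c in zip(rows[keep], cols[keep]):
        graph.add_edge(ids[r], ids[c], weight=float(values[r, c]))
    isolated = {n: d == 0 for n, d in graph.degree}
    nx.set_node_attributes(graph, isolated, "isolated")
    return ThresholdedNetwork(graph=graph, threshold=float(threshold), method=matrix.method)


def sweep(
    matrix: CorrelationMatrix, thresholds: Sequence[float]
) -> list[ThresholdedNetwork]:
    """One network per threshold from the same matrix.

    Thresholds must be strictly increasing, so edge sets are nested:
    every edge at a higher threshold is present at every lower one.
    """
    thresholds = list(thresholds)
    if not thresholds:
        raise ValueError("empty threshold list")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return [build_network(matrix, t) for t in thresholds]


def connected_components(network: ThresholdedNetwork) -> list[list]:
    """Components among connected (non-isolated) nodes.

    Ordered by size descending, ties by smallest member id; member lists
    are sorted.
    """
    comps = [
        sorted(c, key=str)
        for c in nx.connected_components(network.graph)
        if len(c) > 1
    ]
    comps.sort(key=lambda c: (-len(c), str(c[0])))
    return comps


def size_curve(networks: Iterable[ThresholdedNetwork]) -> pd.DataFrame:
    """Per-threshold edge, connected-node and component counts."""
    networks = list(networks)
    if not networks:
        raise ValueError("empty network list")
    rows = []
    for net in networks:
        rows.append(
            {
                "threshold": net.threshold,
                "n_edges": net.n_edges,
                "n_connected_nodes": len(net.connected_nodes),
                "n_components": len(connected_components(net)),
            }
        )
    return pd.DataFrame(rows)


def export_network(
    network: ThresholdedNetwork, path: str | Path, fmt: ExportFormat = "edge-csv"
) -> None:
    """Write a Cytoscape-importable edge file plus a node attribute file.

    SIF lines read ``source cc target``; edge CSV columns are (source,
    target, weight). Endpoints are ordered by their position in the node
    list. The node attribute CSV (<stem>_nodes.csv) lists every sample
    with its isolation flag, so empty networks still document their nodes.
    """
    path = Path(path)
    order = {n: k for k, n in enumerate(network.nodes)}
    edges = sorted(
        (
            (a, b) if order[a] < order[b] else (b, a)
            for a, b in network.graph.edges
        ),
        key=lambda e: (order[e[0]], order[e[1]]),
    )
    if fmt == "sif":
        with open(path, "w") as fh:
            for a, b in edges:
                fh.write(f"{a} cc {b}\n")
    elif fmt == "edge-csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight"])
            for a, b in edges:
                writer.writerow([a, b, repr(network.graph[a][b]["weight"])])
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    node_path = path.with_name(path.stem + "_nodes.csv")
    pd.DataFrame(
        {
            "sample_id": network.nodes,
            "isolated": [network.graph.nodes[n]["isolated"] for n in network.nodes],
        }
    ).to_csv(node_path, index=False)


def read_edge_csv(path: str | Path) -> list[tuple[str, str, float]]:
    """Parse an exported edge CSV back into (source, target, weight) rows."""
    frame = pd.read_csv(path)
    return [
        (str(r.source), str(r.target), float(r.weight))
        for r in frame.itertuples(index=False)
    ]
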