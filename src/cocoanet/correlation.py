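"""Pairwise sample-sample correlation matrices.

For LC-MS profiles l^alpha (one vector of compound peak areas per sample)
the Pearson correlation between samples alpha and beta is

    r_ab = cov(l^a, l^b) / (sigma_a * sigma_b)

and the Spearman correlation is the Pearson correlation of the rank
vectors, with ties receiving average (mid) ranks. The sample-vs-population
covariance normalization cancels in the ratio, so either convention yields
the same r.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from cocoanet.errors import DegenerateVarianceError
from cocoanet.lcms_io import PeakTable

Method = Literal["pearson", "spearman"]


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric sample-sample correlation matrix with unit diagonal.

    ``values`` is a square DataFrame indexed by sample id on both axes;
    every entry lies in [-1, 1].
    """

    values: pd.DataFrame
    method: Method

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _check_variance(matrix: np.ndarray, sample_ids, what: str) -> None:
    stds = matrix.std(axis=1)
    degenerate = np.flatnonzero(stds == 0)
    if degenerate.size:
        names = [sample_ids[k] for k in degenerate]
        raise DegenerateVarianceError(
            f"constant {what} profile(s), correlation undefined: {names}"
        )


def _corrcoef(matrix: np.ndarray, sample_ids, what: str) -> np.ndarray:
    _check_variance(matrix, sample_ids, what)
    values = np.corrcoef(matrix)
    # guard against |r| overshooting 1 by float error
    np.clip(values, -1.0, 1.0, out=values)
    np.fill_diagonal(values, 1.0)
    return values


def pearson_matrix(table: PeakTable) -> CorrelationMatrix:
    """Pearson correlation between every pair of sample profiles."""
    if table.n_compounds < 2:
        raise ValueError("need at least 2 compounds to correlate samples")
    data = table.intensities.to_numpy()
    values = _corrcoef(data, table.sample_ids, "peak-area")
    frame = pd.DataFrame(values, index=table.sample_ids, columns=table.sample_ids)
    return CorrelationMatrix(values=frame, method="pearson")


def spearman_matrix(table: PeakTable) -> CorrelationMatrix:
    """Spearman rank correlation between every pair of sample profiles.

    Each profile is replaced by its within-sample average ranks before the
    Pearson formula is applied, making the result invariant under any
    strictly increasing transform of the peak areas.
    """
    if table.n_compounds < 2:
        raise ValueError("need at least 2 compounds to correlate samples")
    ranks = rankdata(table.intensities.to_numpy(), method="average", axis=1)
    values = _corrcoef(ranks, table.sample_ids, "rank")
    frame = pd.DataFrame(values, index=table.sample_ids, columns=table.sample_ids)
    return CorrelationMatrix(values=frame, method="spearman")


def correlation_matrix(table: PeakTable, method: Method) -> CorrelationMatrix:
    if method == "pearson":
        return pearson_matrix(table)
    if method == "spearman":
        return spearman_matrix(table)
    raise ValueError(f"unknown correlation method {method!r}")


def write_matrix_csv(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Square CSV with sample ids as header row and first column."""
    matrix.values.to_csv(path, index_label="sample_id")


def read_matrix_csv(path: str | Path, method: Method = "spearman") -> CorrelationMatrix:
    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    return CorrelationMatrix(values=frame, method=method)


def write_long_csv(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Long-format CSV (sample_a, sample_b, correlation) for pairs a < b."""
    ids = matrix.sample_ids
    values = matrix.values.to_numpy()
    rows, cols = np.triu_indices(len(ids), k=1)
    pd.DataFrame(
        {
            "sample_a": [ids[r] for r in rows],
            "sample_b": [ids[c] for c in cols],
            "correlation": values[rows, cols],
        }
    ).to_csv(path, index=False)
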