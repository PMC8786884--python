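"""Reading, cleaning, normalizing and writing LC-MS peak tables.

The on-disk dialect is a plain rectangular table (CSV or a single XLSX
sheet): one row per sample, a sample identifier column, two metadata
columns (processing-stage sample type and country of origin) and then one
numeric column per compound. Peak areas are percentage-normalized so each
sample row sums to 100 and columns are conventionally sorted by descending
mean peak area across samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from cocoanet.errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: default header names of the metadata columns in the on-disk dialect
SAMPLE_ID_COL = "sample_id"
STAGE_COL = "sample-type"
ORIGIN_COL = "origin"
DEFAULT_SHEET = "lcms_data"

Format = Literal["csv", "xlsx"]


@dataclass(frozen=True)
class PeakTable:
    """Samples-by-compounds peak-area matrix with per-sample metadata.

    Attributes
    ----------
    intensities
        DataFrame indexed by sample id with one float column per compound;
        entry ``(alpha, i)`` is the peak area of compound ``i`` in sample
        ``alpha`` (relative %, dimensionless after normalization).
    stage
        Per-sample processing-stage category (e.g. unfermented, fermented,
        liquor), indexed like ``intensities``.
    origin
        Per-sample country of origin, indexed like ``intensities``.
    """

    intensities: pd.DataFrame
    stage: pd.Series
    origin: pd.Series

    def __post_init__(self) -> None:
        idx = self.intensities.index
        if not (self.stage.index.equals(idx) and self.origin.index.equals(idx)):
            raise ValidationError("stage/origin index does not match intensity rows")
        if self.stage.isna().any() or self.origin.isna().any():
            missing = sorted(
                set(idx[self.stage.isna()]) | set(idx[self.origin.isna()])
            )
            raise ValidationError(f"samples missing stage/origin labels: {missing}")
        if idx.has_duplicates:
            raise ValidationError("duplicate sample ids")
        values = self.intensities.to_numpy()
        if values.size and (values < 0).any():
            rows, cols = np.nonzero(values < 0)
            coords = [
                (idx[r], self.intensities.columns[c])
                for r, c in zip(rows[:5], cols[:5])
            ]
            raise ValidationError(f"negative peak areas at (sample, compound): {coords}")

    @property
    def sample_ids(self) -> list:
        return list(self.intensities.index)

    @property
    def compound_ids(self) -> list:
        return list(self.intensities.columns)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_compounds(self) -> int:
        return self.intensities.shape[1]

    def labels(self, attribute: str) -> pd.Series:
        """Per-sample labels for ``attribute`` in {'sample_type', 'origin'}."""
        if attribute in ("sample_type", "stage"):
            return self.stage
        if attribute == "origin":
            return self.origin
        raise ValueError(f"unknown attribute {attribute!r}")

    def equals(self, other: "PeakTable") -> bool:
        return (
            self.intensities.equals(other.intensities)
            and self.stage.equals(other.stage)
            and self.origin.equals(other.origin)
        )

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the on-disk layout (metadata columns then compounds)."""
        frame = pd.DataFrame(
            {
                SAMPLE_ID_COL: self.intensities.index,
                STAGE_COL: self.stage.to_numpy(),
                ORIGIN_COL: self.origin.to_numpy(),
            }
        )
        return pd.concat(
            [frame, self.intensities.reset_index(drop=True)], axis=1
        )


def _infer_format(path: Path, fmt: Format | None) -> Format:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return "xlsx"
    return "csv"


def read_peak_table(
    path: str | Path,
    fmt: Format | None = None,
    *,
    sheet: str = DEFAULT_SHEET,
    sample_id_col: str = SAMPLE_ID_COL,
    stage_col: str = STAGE_COL,
    origin_col: str = ORIGIN_COL,
) -> PeakTable:
    """Read a peak table from CSV or a named XLSX sheet.

    Compound column order from the file is preserved. Missing values in
    compound columns are treated as 0 (compound not detected) and logged;
    non-numeric cells raise a :class:`ValidationError` with coordinates.

    Raises
    ------
    FormatError
        If a metadata column is absent (the error names it).
    ValidationError
        On negative peak areas (with sample/compound coordinates).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "xlsx":
        raw = pd.read_excel(path, sheet_name=sheet)
    else:
        raw = pd.read_csv(path, float_precision="round_trip")

    for col in (stage_col, origin_col):
        if col not in raw.columns:
            raise FormatError(f"missing metadata column {col!r} in {path}")

    if sample_id_col in raw.columns:
        sample_ids = pd.Index(raw[sample_id_col].astype(str), name=SAMPLE_ID_COL)
        meta_cols = [sample_id_col, stage_col, origin_col]
    else:
        sample_ids = pd.Index(
            [f"sample_{k}" for k in range(len(raw))], name=SAMPLE_ID_COL
        )
        meta_cols = [stage_col, origin_col]

    compounds = raw.drop(columns=meta_cols)
    numeric = compounds.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & compounds.notna()
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        coords = [(sample_ids[r], compounds.columns[c]) for r, c in zip(rows, cols)]
        raise ValidationError(f"non-numeric peak-area cells at: {coords[:5]}")
    n_missing = int(numeric.isna().to_numpy().sum())
    if n_missing:
        logger.info("treating %d missing peak-area cells as 0", n_missing)
        numeric = numeric.fillna(0.0)
    numeric = numeric.astype(float)
    numeric.index = sample_ids

    stage = pd.Series(raw[stage_col].to_numpy(), index=sample_ids, name="stage")
    origin = pd.Series(raw[origin_col].to_numpy(), index=sample_ids, name="origin")
    return PeakTable(intensities=numeric, stage=stage, origin=origin)


def write_peak_table(
    table: PeakTable,
    path: str | Path,
    fmt: Format | None = None,
    *,
    sheet: str = DEFAULT_SHEET,
) -> None:
    """Write a peak table in the dialect :func:`read_peak_table` consumes."""
    if table.n_compounds == 0:
        raise FormatError("refusing to write a peak table with no compounds")
    path = Path(path)
    fmt = _infer_format(path, fmt)
    frame = table.to_frame()
    if fmt == "xlsx":
        # xlsx stores numbers at 15 significant digits (the Excel
        # convention); CSV round-trips bit-exactly
        frame.to_excel(path, sheet_name=sheet, index=False)
    else:
        frame.to_csv(path, index=False)


def normalize_sample_sums(table: PeakTable, total: float = 100.0) -> PeakTable:
    """Rescale every sample row so its peak areas sum to ``total``.

    This is the percentage normalization under which a peak area reads as
    the relative amount of a compound in the sample's LC-MS profile. It is
    idempotent and preserves each sample's within-profile rank order, so
    Spearman correlations between samples are unaffected.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    sums = table.intensities.sum(axis=1)
    zero = sums <= 0
    if zero.any():
        raise ValidationError(
            f"cannot normalize all-zero samples: {list(sums.index[zero])}"
        )
    scaled = table.intensities.mul(total / sums, axis=0)
    return replace(table, intensities=scaled)


def select_top_compounds(table: PeakTable, n: int) -> PeakTable:
    """Keep the ``n`` compounds with the largest mean peak area.

    Columns are (re)sorted in descending order of mean peak area across
    samples; ties keep the original column order. With ``n`` equal to the
    compound count this is a pure re-sort.
    """
    if not 1 <= n <= table.n_compounds:
        raise ValueError(
            f"n must be in [1, {table.n_compounds}], got {n}"
        )
    means = table.intensities.mean(axis=0).to_numpy()
    order = np.argsort(-means, kind="stable")[:n]
    return replace(table, intensities=table.intensities.iloc[:, order])


def write_node_attributes(table: PeakTable, path: str | Path) -> None:
    """Write the (sample_id, stage, origin) attribute CSV for Cytoscape."""
    pd.DataFrame(
        {
            SAMPLE_ID_COL: table.sample_ids,
            STAGE_COL: table.stage.to_numpy(),
            ORIGIN_COL: table.origin.to_numpy(),
        }
    ).to_csv(path, index=False)


def make_peak_table(
    intensities: np.ndarray | pd.DataFrame,
    stage: Sequence,
    origin: Sequence,
    sample_ids: Sequence | None = None,
    compound_ids: Sequence | None = None,
) -> PeakTable:
    """Convenience constructor from raw arrays and label sequences."""
    if isinstance(intensities, pd.DataFrame):
        frame = intensities.astype(float)
    else:
        arr = np.asarray(intensities, dtype=float)
        if sample_ids is None:
            sample_ids = [f"sample_{k}" for k in range(arr.shape[0])]
        if compound_ids is None:
            compound_ids = [f"compound_{k}" for k in range(arr.shape[1])]
        frame = pd.DataFrame(arr, index=list(sample_ids), columns=list(compound_ids))
    frame.index = frame.index.astype(str).rename(SAMPLE_ID_COL)
    return PeakTable(
        intensities=frame,
        stage=pd.Series(list(stage), index=frame.index, name="stage"),
        origin=pd.Series(list(origin), index=frame.index, name="origin"),
    )
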