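"""Delimited-matrix input/output and sample alignment.

Matrices travel as TSV/CSV with a header row of feature names and a
first column of sample identifiers.  Rows of the two blocks are matched
by identifier before analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("toscca")

__all__ = ["LabeledMatrix", "read_matrix", "write_matrix", "align_samples"]


@dataclass(frozen=True)
class LabeledMatrix:
    """A numeric matrix with sample identifiers and feature names."""

    values: np.ndarray
    sample_ids: tuple[str, ...]
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "feature_names", tuple(str(s) for s in self.feature_names))
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError("labels do not match matrix shape")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.feature_names)
        )


def _infer_sep(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    if path.suffix.lower() in (".tsv", ".tab", ".txt"):
        return "\t"
    return ","


def read_matrix(path: str | Path, delimiter: str | None = None) -> LabeledMatrix:
    """Read a delimited matrix: header row of feature names, first column
    of sample identifiers.

    The delimiter is inferred from the extension (``.tsv``/``.tab``/
    ``.txt`` tab, anything else comma) unless given.  Errors name the
    offending line for ragged rows, the offending row/column for a
    non-numeric cell, and reject duplicate sample identifiers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _infer_sep(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: ragged rows ({exc})") from exc
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"{path}: duplicate sample identifiers: {dups}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            row = bad[0] if len(bad) else df.index[df[col].isna()][0]
            raise ValueError(
                f"{path}: non-numeric value in row {row!r}, column {col!r}"
            )
    return LabeledMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=tuple(str(i) for i in df.index),
        feature_names=tuple(str(c) for c in df.columns),
    )


def write_matrix(path: str | Path, matrix: LabeledMatrix, delimiter: str | None = None) -> None:
    """Write a labeled matrix at 10 significant digits (round-trip safe
    to reading precision)."""
    path = Path(path)
    sep = _infer_sep(path, delimiter)
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.10g", index_label="sample_id")


def align_samples(m1: LabeledMatrix, m2: LabeledMatrix) -> tuple[LabeledMatrix, LabeledMatrix]:
    """Reorder both matrices to their common samples, preserving m1's order.

    Dropped identifiers are logged with counts; fewer than 3 shared
    samples is an error.
    """
    set2 = set(m2.sample_ids)
    common = [s for s in m1.sample_ids if s in set2]
    if not common:
        raise ValueError("no shared sample identifiers between the two matrices")
    if len(common) < 3:
        raise ValueError(f"only {len(common)} shared samples; need at least 3")
    dropped1 = len(m1.sample_ids) - len(common)
    dropped2 = len(m2.sample_ids) - len(common)
    if dropped1 or dropped2:
        logger.warning(
            "dropping unmatched samples: %d from the first matrix, %d from the second",
            dropped1,
            dropped2,
        )
    pos1 = {s: i for i, s in enumerate(m1.sample_ids)}
    pos2 = {s: i for i, s in enumerate(m2.sample_ids)}
    idx1 = [pos1[s] for s in common]
    idx2 = [pos2[s] for s in common]
    return (
        LabeledMatrix(m1.values[idx1], common, m1.feature_names),
        LabeledMatrix(m2.values[idx2], common, m2.feature_names),
    )


def weights_frame(feature_names: Sequence[str], weights: np.ndarray) -> pd.DataFrame:
    """Tidy weights table: one row per feature, one column per component."""
    k = weights.shape[1]
    df = pd.DataFrame(weights, columns=[f"component_{j + 1}" for j in range(k)])
    df.insert(0, "feature", list(feature_names))
    return df
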