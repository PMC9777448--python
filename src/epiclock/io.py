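"""Reading, writing and aligning CpG-unit beta matrices and sample sheets.

Beta matrices are delimited text with a header; missing measurements are empty
cells or NA/NaN tokens.  Internally a matrix is a samples × units pandas
DataFrame of floats in [0, 1] with NaN marking missing entries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NA_TOKENS = ["", "NA", "NaN", "nan", "na", "NAN"]

SEX_VALUES = {"F", "M", "unknown"}

__all__ = [
    "MethylationMatrix",
    "SampleSheet",
    "MatrixFormatError",
    "SampleSheetError",
    "AlignmentError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "align",
]


class MatrixFormatError(ValueError):
    """A beta matrix violates its format contract (range, duplicate ids)."""


class SampleSheetError(ValueError):
    """A sample sheet is missing required columns or has invalid values."""


class AlignmentError(ValueError):
    """Matrix and sheet share no samples."""


@dataclass
class MethylationMatrix:
    """Samples × CpG-unit beta values; NaN entries are missing measurements."""

    beta: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.beta
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate sample ids: {dups}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].tolist()
            raise MatrixFormatError(f"duplicate unit ids: {dups}")
        vals = df.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            i, j = np.argwhere(bad & ~np.isnan(vals))[0]
            raise MatrixFormatError(
                f"beta value {vals[i, j]!r} outside [0, 1] at sample "
                f"{df.index[i]!r}, unit {df.columns[j]!r}"
            )
        self.beta = df.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.beta.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.beta.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.beta.isna()

    @property
    def n_missing(self) -> int:
        return int(self.beta.isna().to_numpy().sum())

    def is_complete(self) -> bool:
        return self.n_missing == 0


@dataclass
class SampleSheet:
    """Per-sample metadata: chronological age plus optional sex/group/timepoint."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "age")
    OPTIONAL = ("sex", "group", "timepoint", "subject_id")

    def __post_init__(self) -> None:
        df = self.table
        for col in self.REQUIRED:
            if col not in df.columns:
                raise SampleSheetError(f"missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise SampleSheetError(f"duplicate sample_id values: {dups}")
        try:
            ages = pd.to_numeric(df["age"], errors="raise")
        except (ValueError, TypeError) as exc:
            raise SampleSheetError(f"non-numeric age values: {exc}") from exc
        if (ages < 0).any():
            raise SampleSheetError("negative ages are not allowed")
        df = df.copy()
        df["age"] = ages.astype(float)
        df["sample_id"] = df["sample_id"].astype(str)
        if "sex" in df.columns:
            bad = ~df["sex"].astype(str).isin(SEX_VALUES)
            if bad.any():
                df.loc[bad, "sex"] = "unknown"
        df = df.set_index(df["sample_id"].values)
        self.table = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def ages(self) -> pd.Series:
        return self.table["age"]

    def subset(self, mask_or_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[mask_or_ids].reset_index(drop=True))


def _detect_sep(path: str | Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _read_table(path: str | Path, sep: str | None) -> pd.DataFrame:
    # round_trip parsing so write/read is bit-lossless
    return pd.read_csv(
        path,
        sep=sep if sep is not None else _detect_sep(path),
        na_values=NA_TOKENS,
        keep_default_na=False,
        index_col=0,
        float_precision="round_trip",
    )


def read_beta_matrix(
    path: str | Path,
    orientation: str = "samples-in-rows",
    sep: str | None = None,
) -> MethylationMatrix:
    """Read a delimited beta matrix with a header row and an id column.

    Parameters
    ----------
    orientation:
        ``"samples-in-rows"`` (default) or ``"samples-in-columns"``; the latter
        transposes after reading.
    sep:
        Delimiter; ``None`` auto-detects (comma/tab).
    """
    if orientation not in {"samples-in-rows", "samples-in-columns"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sep)
    if orientation == "samples-in-columns":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (ValueError, TypeError) as exc:
        raise MatrixFormatError(f"{path}: non-numeric beta value: {exc}") from exc
    return MethylationMatrix(df)


def write_beta_matrix(m: MethylationMatrix, path: str | Path, sep: str = ",") -> None:
    """Write a matrix samples-in-rows; missing entries become empty cells.

    Uses round-trippable float formatting so write ∘ read is lossless.
    """
    df = m.beta.copy()
    df.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write("sample_id" + sep + sep.join(map(str, df.columns)) + "\n")
        for sid, row in zip(df.index, df.to_numpy()):
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(sid) + sep + sep.join(cells) + "\n")


def read_sample_sheet(path: str | Path, sep: str | None = None) -> SampleSheet:
    """Read a sample sheet; requires ``sample_id`` and ``age`` columns."""
    df = pd.read_csv(
        path,
        sep=sep if sep is not None else _detect_sep(path),
        na_values=NA_TOKENS,
        keep_default_na=False,
        dtype=str,
    )
    return SampleSheet(df)


def write_sample_sheet(s: SampleSheet, path: str | Path, sep: str = ",") -> None:
    s.table.to_csv(path, sep=sep, index=False)


def align(m: MethylationMatrix, s: SampleSheet) -> tuple[MethylationMatrix, SampleSheet]:
    """Restrict matrix and sheet to their shared samples, in sheet order.

    Samples present in only one input are dropped (and logged).  Idempotent:
    aligning already-aligned inputs returns them unchanged.
    """
    shared = [sid for sid in s.sample_ids if sid in set(m.sample_ids)]
    if not shared:
        raise AlignmentError("matrix and sample sheet share no samples")
    dropped_m = sorted(set(m.sample_ids) - set(shared))
    dropped_s = sorted(set(s.sample_ids) - set(shared))
    if dropped_m:
        logger.info("align: dropping %d matrix-only samples: %s", len(dropped_m), dropped_m)
    if dropped_s:
        logger.info("align: dropping %d sheet-only samples: %s", len(dropped_s), dropped_s)
    m2 = MethylationMatrix(m.beta.loc[shared])
    s2 = SampleSheet(s.table.loc[shared].reset_index(drop=True))
    return m2, s2
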