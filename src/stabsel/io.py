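"""Reading and writing the pipeline's tab-separated tables and JSON.

All tables are plain text: tab-separated with a single header line and a
shared ``participant_id`` column. Numeric output uses 10 significant
digits so reruns diff cleanly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ProteinMatrix

__all__ = [
    "read_tables",
    "read_cohort",
    "read_proteins",
    "write_table",
    "write_json",
    "file_sha256",
]

logger = logging.getLogger("stabsel")

FLOAT_FORMAT = "%.10g"
ID_COLUMN = "participant_id"


def _read_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != ID_COLUMN:
        raise ValueError(
            f"{path}: first column must be {ID_COLUMN!r}, got {df.columns[0]!r}"
        )
    dup = df[ID_COLUMN][df[ID_COLUMN].duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate participant ids: {sorted(set(dup))[:5]}")
    return df.set_index(ID_COLUMN)


def read_cohort(path) -> pd.DataFrame:
    """Read a clinical cohort table (participants x covariates)."""
    return _read_tsv(path)


def read_proteins(path, medium: str = "serum", stage: str = "raw") -> ProteinMatrix:
    """Read a protein abundance table; every cell must be numeric."""
    df = _read_tsv(path)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy()][0]
            raise ValueError(
                f"{path}: non-numeric abundance at (participant {row!r}, protein {col!r}): "
                f"{df.loc[row, col]!r}"
            )
        df[col] = coerced
    if df.isna().any().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing abundance at (participant {df.index[loc[0]]!r}, "
            f"protein {df.columns[loc[1]]!r})"
        )
    return ProteinMatrix(df.astype(float), medium=medium, stage=stage)


def read_tables(cohort_path, proteins_path, medium: str = "serum",
                stage: str = "raw") -> tuple[pd.DataFrame, ProteinMatrix]:
    """Read and align the cohort and protein tables on participant id.

    Participants present in only one table are dropped and counted in the
    log; an empty intersection is an error.
    """
    cohort = read_cohort(cohort_path)
    proteins = read_proteins(proteins_path, medium=medium, stage=stage)
    common = cohort.index.intersection(proteins.participants)
    if len(common) == 0:
        raise ValueError("no participants shared between cohort and protein tables")
    n_cohort_only = len(cohort.index.difference(common))
    n_protein_only = len(proteins.participants.difference(common))
    if n_cohort_only or n_protein_only:
        logger.info(
            "dropped unmatched participants: %d cohort-only, %d protein-only",
            n_cohort_only, n_protein_only,
        )
    proteins = ProteinMatrix(
        proteins.data.loc[common], proteins.medium, proteins.stage, proteins.meta
    )
    return cohort.loc[common], proteins


def write_table(df: pd.DataFrame, path, index: bool = True) -> Path:
    """Write a table as TSV with fixed numeric precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    if index and out.index.name is None:
        out.index.name = ID_COLUMN
    out.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
    return path


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, cls=_NumpyEncoder) + "\n")
    return path


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage as printed in cohort characteristic tables: 100*n/d, rounded.

    Used for the "n (x%)" entries of participant summary tables.
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, decimals)


def binary_summary(series: pd.Series, level) -> tuple[int, float]:
    """Count and printed percentage of one level of a binary column."""
    n = int((series == level).sum())
    return n, percent(n, int(series.notna().sum()))
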