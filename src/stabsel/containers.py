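"""Core data containers shared across the pipeline.

The pipeline moves three kinds of tabular objects around: a protein
abundance matrix (participants x proteins, relative fluorescence units),
a per-participant clinical table (a plain :class:`pandas.DataFrame`
indexed by participant id), and the assembled design matrix handed to the
penalised solver. The protein matrix and design matrix carry enough
metadata (medium, processing stage, penalty factors, provenance) that
downstream stages can verify their preconditions instead of trusting the
caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: processing stages a ProteinMatrix moves through, in order
STAGES = ("raw", "median_normalised", "standardised")


@dataclass
class ProteinMatrix:
    """Participants x proteins abundance matrix with processing state.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are participants (index = participant id), columns are
        protein names. Raw values are strictly positive abundances in
        relative fluorescence units.
    medium : str
        ``"serum"`` or ``"sputum"``.
    stage : str
        One of :data:`STAGES`; tracks which transformations have run.
    meta : dict
        Provenance: dropped columns, normalisation constants, simulation
        ground truth, conventions used.
    """

    data: pd.DataFrame
    medium: str = "serum"
    stage: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.medium not in ("serum", "sputum"):
            raise ValueError(f"medium must be 'serum' or 'sputum', got {self.medium!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")

    @property
    def participants(self) -> pd.Index:
        return self.data.index

    @property
    def proteins(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.data.copy(), self.medium, self.stage, dict(self.meta))


@dataclass
class DesignMatrix:
    """Analysis-ready design for penalised logistic regression.

    ``penalty_factors`` is the per-variable L1 multiplier: 0 marks a
    forced (never penalised) clinical covariate, 1 a penalised protein.
    """

    X: np.ndarray
    names: list[str]
    penalty_factors: np.ndarray
    y: np.ndarray
    ids: pd.Index
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.penalty_factors = np.asarray(self.penalty_factors, dtype=np.float64)
        self.y = np.asarray(self.y)
        n, p = self.X.shape
        if len(self.names) != p:
            raise ValueError("names length does not match number of columns")
        if self.penalty_factors.shape != (p,):
            raise ValueError("penalty_factors length does not match number of columns")
        if not np.all(np.isin(self.penalty_factors, (0.0, 1.0))):
            raise ValueError("penalty_factors must be 0 (forced) or 1 (penalised)")
        if self.y.shape != (n,):
            raise ValueError("outcome length does not match number of rows")
        if np.isnan(self.X).any():
            raise ValueError("design matrix contains missing values")
        classes = np.unique(self.y)
        if not np.array_equal(classes, [0, 1]) and not np.array_equal(classes, [0]) and not np.array_equal(classes, [1]):
            raise ValueError("outcome must be binary 0/1")

    @property
    def penalised(self) -> np.ndarray:
        """Boolean mask of penalised columns."""
        return self.penalty_factors > 0

    @property
    def forced_names(self) -> list[str]:
        return [nm for nm, f in zip(self.names, self.penalty_factors) if f == 0]

    @property
    def penalised_names(self) -> list[str]:
        return [nm for nm, f in zip(self.names, self.penalty_factors) if f > 0]

    def subset(self, idx: Sequence[int]) -> "DesignMatrix":
        idx = np.asarray(idx)
        return DesignMatrix(
            self.X[idx], list(self.names), self.penalty_factors.copy(),
            self.y[idx], self.ids[idx], dict(self.provenance),
        )
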