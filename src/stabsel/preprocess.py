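"""Preprocessing: normalisation, transformation, imputation, phenotypes.

The analysis-ready design is built in four steps, mirroring how
aptamer-based proteomic studies prepare their data:

1. per-sample median normalisation of the abundance matrix (removes
   multiplicative assay bias);
2. log-transform, then per-protein centring and unit scaling;
3. k-nearest-neighbour imputation of missing clinical covariates
   (granulocyte counts that define the outcome are never imputed);
4. dichotomisation of granulocyte counts into a binary phenotype, and
   assembly of the design matrix with forced (unpenalised) clinical
   covariates and penalised proteins.

Steps 1-3 are exposed both as sklearn transformers (``MedianNormalizer``,
``LogStandardizer``, ``ClinicalKNNImputer``) — whose fit/transform split
gives the frozen-model contract needed to score follow-up samples with
baseline constants — and as one-shot functions operating on
:class:`~stabsel.containers.ProteinMatrix`.

Note on step 2: the transformation is log first, then standardise.
Standardised (centred) data contains non-positive values on which a log
is undefined, so this is the only executable order; the convention and
the standardisation degrees of freedom are recorded in provenance.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics.pairwise import nan_euclidean_distances
from sklearn.utils.validation import check_is_fitted

from .containers import DesignMatrix, ProteinMatrix
from .simulate import CLINICAL_COVARIATES

__all__ = [
    "PhenotypeDefinition",
    "STANDARD_PHENOTYPES",
    "ALTERNATIVE_PHENOTYPES",
    "MedianNormalizer",
    "LogStandardizer",
    "ClinicalKNNImputer",
    "median_normalise",
    "transform_and_centre",
    "knn_impute",
    "dichotomise_phenotype",
    "assemble_design",
]

_PHENOTYPE_COLUMNS = {
    ("blood", "eosinophil"): "blood_eos",
    ("blood", "neutrophil"): "blood_neu",
    ("sputum", "eosinophil"): "sputum_eos_pct",
    ("sputum", "neutrophil"): "sputum_neu_pct",
}


@dataclass(frozen=True)
class PhenotypeDefinition:
    """A granulocyte phenotype cut-off.

    Blood phenotypes are defined on absolute counts (cells/uL), sputum
    phenotypes on the percentage of the granulocyte total; the comparator
    is always >= (value at the threshold is "high").
    """

    medium: str
    cell: str
    threshold: float
    units: str

    def __post_init__(self) -> None:
        if self.medium not in ("blood", "sputum"):
            raise ValueError(f"medium must be 'blood' or 'sputum', got {self.medium!r}")
        if self.cell not in ("eosinophil", "neutrophil"):
            raise ValueError(f"cell must be 'eosinophil' or 'neutrophil', got {self.cell!r}")
        if not self.threshold > 0:
            raise ValueError("threshold must be positive")
        expected = "cells_per_uL" if self.medium == "blood" else "percent_of_granulocytes"
        if self.units != expected:
            raise ValueError(
                f"{self.medium} phenotypes use units {expected!r}, got {self.units!r}"
            )

    @property
    def column(self) -> str:
        return _PHENOTYPE_COLUMNS[(self.medium, self.cell)]

    @property
    def name(self) -> str:
        thr = f"{self.threshold:g}".replace(".", "p")
        return f"{self.column}_ge{thr}"


#: primary clinical cut-offs: blood eosinophils >=300/uL, blood
#: neutrophils >=7500/uL, sputum eosinophils >=1.5% and sputum
#: neutrophils >=73.6% of granulocytes.
STANDARD_PHENOTYPES = {
    "blood_eosinophilic": PhenotypeDefinition("blood", "eosinophil", 300.0, "cells_per_uL"),
    "blood_neutrophilic": PhenotypeDefinition("blood", "neutrophil", 7500.0, "cells_per_uL"),
    "sputum_eosinophilic": PhenotypeDefinition("sputum", "eosinophil", 1.5, "percent_of_granulocytes"),
    "sputum_neutrophilic": PhenotypeDefinition("sputum", "neutrophil", 73.6, "percent_of_granulocytes"),
}

#: sensitivity-analysis cut-offs (>=150/uL, >=5000/uL, >=3%, >=60%).
ALTERNATIVE_PHENOTYPES = {
    "blood_eosinophilic": PhenotypeDefinition("blood", "eosinophil", 150.0, "cells_per_uL"),
    "blood_neutrophilic": PhenotypeDefinition("blood", "neutrophil", 5000.0, "cells_per_uL"),
    "sputum_eosinophilic": PhenotypeDefinition("sputum", "eosinophil", 3.0, "percent_of_granulocytes"),
    "sputum_neutrophilic": PhenotypeDefinition("sputum", "neutrophil", 60.0, "percent_of_granulocytes"),
}


def _check_positive(data: pd.DataFrame) -> None:
    if (data.to_numpy() <= 0).any() or data.isna().any().any():
        bad = np.argwhere(~(data.to_numpy() > 0))
        cells = [f"({data.index[i]}, {data.columns[j]})" for i, j in bad[:5]]
        raise ValueError(
            f"abundances must be strictly positive; offending cells: {', '.join(cells)}"
            + ("..." if len(bad) > 5 else "")
        )


class MedianNormalizer(BaseEstimator, TransformerMixin):
    """Scale every sample so its median abundance equals a reference.

    The reference is the median of per-sample medians of the fitted data,
    so no sample is designated as the anchor. Within-sample abundance
    ratios are preserved exactly. Applying the fitted transformer to new
    samples (e.g. a follow-up visit) reuses the baseline reference.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        _check_positive(X)
        self.reference_median_ = float(np.median(X.median(axis=1)))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "reference_median_")
        X = pd.DataFrame(X)
        _check_positive(X)
        scale = self.reference_median_ / X.median(axis=1)
        return X.mul(scale, axis=0)


class LogStandardizer(BaseEstimator, TransformerMixin):
    """Natural log, then per-protein centring and unit scaling.

    Zero-variance proteins (constant on the log scale in the fitted data)
    are dropped with a warning and recorded in ``dropped_``. ``ddof``
    selects the standardisation convention (1 = sample SD, the default;
    0 = population SD); the choice is surfaced in provenance downstream.
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        _check_positive(X)
        logX = np.log(X)
        sd = logX.std(axis=0, ddof=self.ddof)
        keep = sd > 1e-12
        self.dropped_ = list(logX.columns[~keep])
        if self.dropped_:
            warnings.warn(
                f"dropping {len(self.dropped_)} zero-variance protein(s): "
                f"{self.dropped_[:5]}", UserWarning,
            )
        self.columns_ = list(logX.columns[keep])
        self.mean_ = logX.loc[:, keep].mean(axis=0)
        self.scale_ = sd[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "columns_")
        X = pd.DataFrame(X)
        missing = [c for c in self.columns_ if c not in X.columns]
        if missing:
            raise ValueError(f"input lacks fitted proteins: {missing[:5]}")
        logX = np.log(X[self.columns_])
        return (logX - self.mean_) / self.scale_


def median_normalise(proteins: ProteinMatrix) -> ProteinMatrix:
    """One-shot median normalisation of a raw protein matrix."""
    norm = MedianNormalizer().fit(proteins.data)
    out = norm.transform(proteins.data)
    meta = dict(proteins.meta)
    meta["reference_median"] = norm.reference_median_
    return ProteinMatrix(out, proteins.medium, "median_normalised", meta)


def transform_and_centre(proteins: ProteinMatrix, ddof: int = 1) -> ProteinMatrix:
    """Log-transform then centre/scale a median-normalised matrix.

    Raises if the input has not been median-normalised: the pipeline's
    scale-invariance guarantee depends on the normalisation running first.
    """
    if proteins.stage != "median_normalised":
        raise ValueError(
            f"transform_and_centre expects a median-normalised matrix, got stage "
            f"{proteins.stage!r}; run median_normalise first"
        )
    std = LogStandardizer(ddof=ddof).fit(proteins.data)
    out = std.transform(proteins.data)
    meta = dict(proteins.meta)
    meta["transformation"] = {
        "order": "log, then centre and unit-scale per protein",
        "ddof": ddof,
        "dropped_zero_variance": std.dropped_,
    }
    return ProteinMatrix(out, proteins.medium, "standardised", meta)


class ClinicalKNNImputer(BaseEstimator, TransformerMixin):
    """k-nearest-neighbour imputation of clinical covariates.

    Distances are Euclidean over the standardised numeric covariates with
    pairwise-available handling (missing coordinates are skipped and the
    distance rescaled, as in ``nan_euclidean_distances``). Numeric cells
    are imputed by the mean of the ``k`` nearest donors that observe the
    column; categorical cells by majority vote among those donors (vote
    ties broken by lexicographic order). Neighbour-rank ties are broken
    by donor order after a seeded shuffle. Observed cells are never
    altered. Donors come from the fitted table, so transforming new data
    reuses baseline donors.
    """

    def __init__(self, k: int = 5, seed: int = 0, columns: Optional[list[str]] = None):
        self.k = k
        self.seed = seed
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        X = pd.DataFrame(X)
        cols = self.columns or [c for c in CLINICAL_COVARIATES if c in X.columns]
        if not cols:
            raise ValueError("no clinical covariates found to impute")
        all_missing = [c for c in cols if X[c].isna().all()]
        if all_missing:
            raise ValueError(f"column(s) entirely missing, cannot impute: {all_missing}")
        self.columns_ = cols
        self.numeric_cols_ = [c for c in cols if pd.api.types.is_numeric_dtype(X[c])]
        self.categorical_cols_ = [c for c in cols if c not in self.numeric_cols_]
        self.donors_ = X[cols].copy()
        num = self.donors_[self.numeric_cols_].astype(float)
        self.num_mean_ = num.mean()
        sd = num.std(ddof=1).replace(0.0, 1.0).fillna(1.0)
        self.num_scale_ = sd
        self.donor_std_ = ((num - self.num_mean_) / self.num_scale_).to_numpy()
        rng = np.random.default_rng(self.seed)
        self.tiebreak_rank_ = rng.permutation(len(self.donors_))
        return self

    def _impute_cell(self, col: str, order: np.ndarray, donor_pos: np.ndarray):
        donor_vals = self.donors_[col].to_numpy()
        take = donor_pos[order][: self.k]
        if len(take) < self.k:
            warnings.warn(
                f"only {len(take)} donors available for column {col!r} "
                f"(k={self.k}); using all of them", UserWarning,
            )
        vals = donor_vals[take]
        if col in self.numeric_cols_:
            return float(np.mean(vals.astype(float)))
        counts = Counter(vals)
        return sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "donors_")
        out = pd.DataFrame(X).copy()
        cols = [c for c in self.columns_ if c in out.columns]
        if not out[cols].isna().any().any():
            return out
        num = out[self.numeric_cols_].astype(float)
        query_std = ((num - self.num_mean_) / self.num_scale_).to_numpy()
        dist = nan_euclidean_distances(query_std, self.donor_std_)
        same_table = out.index.equals(self.donors_.index)
        for col in cols:
            miss_rows = np.flatnonzero(out[col].isna().to_numpy())
            if miss_rows.size == 0:
                continue
            donor_ok = ~self.donors_[col].isna().to_numpy()
            for i in miss_rows:
                ok = donor_ok.copy()
                if same_table:
                    ok[i] = False  # a row never donates to itself
                donor_pos = np.flatnonzero(ok)
                d = dist[i, donor_pos]
                if np.all(np.isnan(d)):
                    warnings.warn(
                        f"no usable distances for row {out.index[i]!r}, column "
                        f"{col!r}; falling back to marginal imputation", UserWarning,
                    )
                    vals = self.donors_[col].dropna()
                    fallback = (
                        float(vals.astype(float).mean())
                        if col in self.numeric_cols_
                        else sorted(Counter(vals).items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]
                    )
                    out.iloc[i, out.columns.get_loc(col)] = fallback
                    continue
                d = np.where(np.isnan(d), np.inf, d)
                order = np.lexsort((self.tiebreak_rank_[donor_pos], d))
                out.iloc[i, out.columns.get_loc(col)] = self._impute_cell(col, order, donor_pos)
        return out


def knn_impute(cohort: pd.DataFrame, k: int = 5, seed: int = 0,
               columns: Optional[list[str]] = None) -> pd.DataFrame:
    """Impute missing clinical covariates within one table (k donors)."""
    imp = ClinicalKNNImputer(k=k, seed=seed, columns=columns)
    return imp.fit(cohort).transform(cohort)


def dichotomise_phenotype(cohort: pd.DataFrame, definition: PhenotypeDefinition) -> pd.Series:
    """Binary high/low status from a granulocyte count or percentage.

    Status is high (1.0) iff the value is >= the threshold; a missing
    count yields a missing status, and such participants are excluded
    (and counted) when the design matrix is assembled.
    """
    col = definition.column
    if col not in cohort.columns:
        raise ValueError(
            f"cohort lacks column {col!r} required by the "
            f"{definition.medium}/{definition.cell} definition"
        )
    values = pd.to_numeric(cohort[col], errors="raise").astype(float)
    if (values.dropna() < 0).any():
        raise ValueError(f"column {col!r} contains negative values")
    status = (values >= definition.threshold).astype(float)
    status[values.isna()] = np.nan
    status.name = definition.name
    return status


#: clinical covariates forced into the model in ``full_clinical`` mode
FULL_CLINICAL_COVARIATES = list(CLINICAL_COVARIATES)

_SEX_CODES = {"male": 0.0, "female": 1.0}


def _encode_clinical(cohort: pd.DataFrame, cols: Sequence[str]) -> pd.DataFrame:
    enc = {}
    for c in cols:
        s = cohort[c]
        if c == "sex" and s.dtype == object:
            unknown = set(s.dropna().unique()) - set(_SEX_CODES)
            if unknown:
                raise ValueError(f"unrecognised sex labels: {sorted(unknown)}")
            s = s.map(_SEX_CODES)
        enc[c] = pd.to_numeric(s, errors="raise").astype(float)
    return pd.DataFrame(enc, index=cohort.index)


def assemble_design(
    cohort: pd.DataFrame,
    proteins: ProteinMatrix,
    mode: str,
    outcome: pd.Series,
) -> DesignMatrix:
    """Assemble the penalised design matrix for one phenotype.

    ``mode`` selects the forced covariates: ``"age_sex"`` forces age and
    sex only; ``"full_clinical"`` forces the full clinical covariate list.
    Forced covariates carry penalty factor 0 (never penalised), proteins
    always carry 1. Participants with a missing outcome are dropped and
    counted in provenance.
    """
    if mode == "age_sex":
        forced = ["age", "sex"]
    elif mode == "full_clinical":
        forced = list(FULL_CLINICAL_COVARIATES)
    else:
        raise ValueError(f"mode must be 'age_sex' or 'full_clinical', got {mode!r}")
    if proteins.stage != "standardised":
        raise ValueError(
            "proteins must be standardised (median_normalise + transform_and_centre) "
            f"before design assembly; got stage {proteins.stage!r}"
        )
    if proteins.shape[1] == 0:
        raise ValueError("no proteins supplied: nothing to select")
    missing_cols = [c for c in forced if c not in cohort.columns]
    if missing_cols:
        raise ValueError(f"cohort lacks forced covariates: {missing_cols}")

    ids = cohort.index.intersection(proteins.participants).intersection(outcome.index)
    outcome = outcome.loc[ids]
    keep = outcome.notna()
    n_dropped = int((~keep).sum())
    ids = ids[keep.to_numpy()]
    y = outcome.loc[ids].astype(int).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome is constant after dropping missing statuses")

    clin = _encode_clinical(cohort.loc[ids], forced)
    if clin.isna().any().any():
        bad = list(clin.columns[clin.isna().any()])
        raise ValueError(f"forced covariates contain missing values ({bad}); run knn_impute first")
    prot = proteins.data.loc[ids]

    X = np.hstack([clin.to_numpy(), prot.to_numpy()])
    names = list(clin.columns) + list(prot.columns)
    pf = np.concatenate([np.zeros(clin.shape[1]), np.ones(prot.shape[1])])
    provenance = {
        "mode": mode,
        "forced_covariates": list(clin.columns),
        "n_proteins": prot.shape[1],
        "n_participants": len(ids),
        "n_dropped_missing_outcome": n_dropped,
        "sex_encoding": dict(_SEX_CODES),
        "outcome": str(outcome.name),
        "protein_stage": proteins.stage,
        "transformation": proteins.meta.get("transformation"),
    }
    return DesignMatrix(X, names, pf, y, ids, provenance)
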