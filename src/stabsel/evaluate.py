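"""Predictive performance of selected proteins.

Predictive ability is quantified with repeated train/test splitting: the
data are split many times into stratified 80% training / 20% testing
subsets, an unpenalised logistic model is refit on each training set, and
the area under the ROC curve (AUC, Mann-Whitney formulation with ties
counted 1/2) is computed on the held-out set. The summary is the mean
AUC with a percentile 95% interval across splits.

On top of that harness sit three study-level analyses: a sequential-
addition curve (clinical covariates first, then stably selected proteins
one at a time in decreasing order of selection proportion), frozen-model
validation on follow-up samples, and a matched-subsample re-analysis that
re-runs selection on a smaller cohort whose prevalence and key covariate
means are controlled to match the full data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .containers import DesignMatrix
from .stability import (
    SelectionResult,
    calibrate,
    run_subsampling,
    stable_features,
    _stratified_take,
)

__all__ = [
    "AUCResult",
    "SequentialCurve",
    "MatchedSubsampleResult",
    "repeated_split_auc",
    "sequential_addition",
    "followup_validation",
    "matched_subsample_reanalysis",
]


@dataclass
class AUCResult:
    """Per-split test AUCs with mean and percentile 95% CI."""

    per_split_auc: np.ndarray
    mean_auc: float
    ci_low: float
    ci_high: float
    n_splits: int
    train_fraction: float
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        a = np.asarray(self.per_split_auc, dtype=float)
        if a.min() < 0.0 or a.max() > 1.0:
            raise ValueError("AUCs must lie in [0, 1]")
        if not self.ci_low <= self.mean_auc <= self.ci_high:
            raise ValueError("CI must bracket the mean AUC")

    def summary(self) -> str:
        return f"{self.mean_auc:.2f} (95% CI {self.ci_low:.2f}-{self.ci_high:.2f})"


def _summarise(aucs: np.ndarray, train_fraction: float, **notes) -> AUCResult:
    aucs = np.asarray(aucs, dtype=float)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return AUCResult(
        per_split_auc=aucs, mean_auc=float(aucs.mean()),
        ci_low=float(min(lo, aucs.mean())), ci_high=float(max(hi, aucs.mean())),
        n_splits=len(aucs), train_fraction=train_fraction, notes=dict(notes),
    )


def _fit_logistic(X_train: np.ndarray, y_train: np.ndarray) -> LogisticRegression:
    # newton-cholesky: by far the fastest exact solver for these n >> p
    # refits, and the evaluation loop performs thousands of them
    model = LogisticRegression(C=np.inf, solver="newton-cholesky", max_iter=100)
    with warnings.catch_warnings():
        # separable training splits are legitimate here; ranking is all we use
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", linalg.LinAlgWarning)
        model.fit(X_train, y_train)
    return model


def _stratified_split(
    rng: np.random.Generator, y: np.ndarray, train_fraction: float
) -> tuple[np.ndarray, np.ndarray]:
    train_idx, test_idx = [], []
    for c in np.unique(y):
        ix = np.flatnonzero(y == c)
        n_train = int(np.floor(train_fraction * len(ix)))
        n_train = min(max(n_train, 1), len(ix) - 1)
        perm = ix[rng.permutation(len(ix))]
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def repeated_split_auc(
    X,
    y,
    n_splits: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 0,
    max_redraws: int = 100,
) -> AUCResult:
    """Mean test AUC over repeated stratified train/test splits.

    Per split an unpenalised logistic model is refit on the training set
    and scored on the held-out participants; the AUC uses the
    Mann-Whitney formulation (ties count 1/2). An intercept-only model
    (zero columns) is allowed and flagged: its AUC is 0.5 by convention.
    Splits whose test set lacks a class are redrawn (logged in notes) and
    the procedure fails after ``max_redraws`` consecutive redraws.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    intercept_only = X.shape[1] == 0
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_splits)
    redraws = 0
    for s in range(n_splits):
        for attempt in range(max_redraws + 1):
            train, test = _stratified_split(rng, y, train_fraction)
            if len(np.unique(y[test])) == 2:
                break
            redraws += 1
        else:
            raise RuntimeError(
                f"test split missing a class after {max_redraws} redraws; "
                "the outcome is too imbalanced for this train_fraction"
            )
        if intercept_only:
            aucs[s] = 0.5
            continue
        model = _fit_logistic(X[train], y[train])
        scores = model.decision_function(X[test])
        aucs[s] = roc_auc_score(y[test], scores)
    notes = {"redraws": redraws}
    if intercept_only:
        notes["intercept_only"] = True
    return _summarise(aucs, train_fraction, **notes)


@dataclass
class SequentialCurve:
    """AUC as stably selected proteins are added to the clinical model."""

    steps: list[list[str]]          # variable set per step; step 0 = clinical only
    auc_at_step: list[AUCResult]

    @property
    def mean_aucs(self) -> np.ndarray:
        return np.array([r.mean_auc for r in self.auc_at_step])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, (step, res) in enumerate(zip(self.steps, self.auc_at_step)):
            added = step[-1] if k > 0 else "(clinical baseline)"
            rows.append({
                "step": k, "added": added, "n_variables": len(step),
                "mean_auc": res.mean_auc, "ci_low": res.ci_low, "ci_high": res.ci_high,
            })
        return pd.DataFrame(rows)


def sequential_addition(
    X_clinical: pd.DataFrame,
    X_proteins: pd.DataFrame,
    y,
    n_splits: int = 1000,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SequentialCurve:
    """AUC curve from clinical-only to clinical + all stable proteins.

    ``X_proteins`` columns must already be ranked (decreasing selection
    proportion); step m adds the first m of them to the clinical
    baseline. The same split seed is reused at every step so the curves
    are comparable split-by-split.
    """
    X_clinical = pd.DataFrame(X_clinical)
    X_proteins = pd.DataFrame(X_proteins)
    if X_proteins.shape[1] == 0:
        warnings.warn("no stable proteins: curve contains the clinical baseline only",
                      UserWarning)
    steps, results = [], []
    clin_names = [str(c) for c in X_clinical.columns]
    prot_names = [str(c) for c in X_proteins.columns]
    for m in range(X_proteins.shape[1] + 1):
        names = clin_names + prot_names[:m]
        Xm = np.hstack([X_clinical.to_numpy(dtype=float),
                        X_proteins.iloc[:, :m].to_numpy(dtype=float)])
        results.append(
            repeated_split_auc(Xm, y, n_splits=n_splits,
                               train_fraction=train_fraction, seed=seed)
        )
        steps.append(names)
    return SequentialCurve(steps, results)


def followup_validation(
    model,
    X_followup: pd.DataFrame,
    y_followup,
    variables: Optional[Sequence[str]] = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> AUCResult:
    """AUC of a frozen model on follow-up samples, bootstrap 95% CI.

    ``model`` is any fitted object with ``decision_function`` (e.g. the
    unpenalised logistic fit from the baseline analysis); it is NOT refit.
    ``variables`` names the columns the model expects, in order; a
    follow-up table missing any of them raises with the missing names.
    The CI bootstraps over follow-up participants (resamples with a
    single outcome class are redrawn).
    """
    X_followup = pd.DataFrame(X_followup)
    if variables is not None:
        missing = [v for v in variables if v not in X_followup.columns]
        if missing:
            raise ValueError(f"follow-up data lacks required variable(s): {missing}")
        X_followup = X_followup[list(variables)]
    y_followup = np.asarray(y_followup).astype(int)
    if len(np.unique(y_followup)) < 2:
        raise ValueError("follow-up outcome must contain both classes")
    scores = np.asarray(model.decision_function(X_followup.to_numpy(dtype=float))).ravel()
    point = roc_auc_score(y_followup, scores)
    rng = np.random.default_rng(seed)
    n = len(y_followup)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        for _ in range(1000):
            ix = rng.integers(0, n, size=n)
            if len(np.unique(y_followup[ix])) == 2:
                break
        else:
            raise RuntimeError("could not draw a bootstrap resample with both classes")
        boots[b] = roc_auc_score(y_followup[ix], scores[ix])
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return AUCResult(
        per_split_auc=np.array([point]), mean_auc=float(point),
        ci_low=float(min(lo, point)), ci_high=float(max(hi, point)),
        n_splits=1, train_fraction=1.0,
        notes={"ci": "bootstrap over follow-up participants", "n_boot": n_boot},
    )


@dataclass
class MatchedSubsampleResult:
    """Selection + evaluation re-run on a characteristic-matched subsample."""

    indices: np.ndarray
    balance: pd.DataFrame
    selection: SelectionResult
    stable: list[str]
    auc: AUCResult
    n_attempts: int


def matched_subsample_reanalysis(
    design: DesignMatrix,
    target_n: int,
    matching: Sequence[str],
    seed: int = 0,
    tolerance: float = 0.1,
    max_attempts: int = 1000,
    K: int = 1000,
    n_splits: int = 1000,
    pi_grid: Optional[np.ndarray] = None,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
) -> MatchedSubsampleResult:
    """Re-run selection and AUC evaluation on a matched subsample.

    Draws outcome-stratified subsamples of size ``target_n`` until every
    matching variable's subsample mean is within ``tolerance`` full-data
    SDs of the full-data mean (acceptance sampling); stratification pins
    the outcome prevalence to the full-data value up to rounding. The
    accepted subsample is then pushed through the full calibrated
    stability selection and the repeated-split AUC harness (forced
    covariates plus stable proteins).
    """
    n = len(design.y)
    if not 0 < target_n <= n:
        raise ValueError("target_n must lie in (0, n]")
    name_pos = {nm: j for j, nm in enumerate(design.names)}
    missing = [m for m in matching if m not in name_pos]
    if missing:
        raise ValueError(f"matching variable(s) not in design: {missing}")
    cols = [name_pos[m] for m in matching]
    full_mean = design.X[:, cols].mean(axis=0)
    full_sd = design.X[:, cols].std(axis=0, ddof=1)
    full_sd[full_sd == 0] = np.inf  # constant variables are trivially matched

    if target_n == n:
        idx, attempts = np.arange(n), 0
    else:
        class_idx = [np.flatnonzero(design.y == c) for c in (0, 1)]
        takes = _stratified_take(np.array([len(ix) for ix in class_idx]),
                                 target_n / n)
        rng = np.random.default_rng([101, seed])
        best = np.inf
        idx = None
        for attempts in range(1, max_attempts + 1):
            rows = np.sort(np.concatenate([
                ix[rng.permutation(len(ix))[:t]] for ix, t in zip(class_idx, takes)
            ]))
            z = np.abs(design.X[rows][:, cols].mean(axis=0) - full_mean) / full_sd
            worst = float(z.max()) if len(cols) else 0.0
            if worst < best:
                best = worst
            if worst <= tolerance:
                idx = rows
                break
        if idx is None:
            raise ValueError(
                f"no subsample met the matching tolerance {tolerance} in "
                f"{max_attempts} attempts (best achieved max standardised "
                f"difference: {best:.3f})"
            )
    sub = design.subset(idx)
    balance = pd.DataFrame({
        "variable": list(matching),
        "full_mean": full_mean,
        "subsample_mean": sub.X[:, cols].mean(axis=0),
        "full_sd": np.where(np.isinf(full_sd), 0.0, full_sd),
    })
    balance["std_difference"] = np.where(
        balance["full_sd"] > 0,
        np.abs(balance["subsample_mean"] - balance["full_mean"]) / balance["full_sd"],
        0.0,
    )
    res = run_subsampling(sub, K=K, seed=seed, n_lambdas=n_lambdas,
                          lambda_min_ratio=lambda_min_ratio)
    calibrate(res, pi_grid)
    stable = stable_features(res)
    keep = [j for j, nm in enumerate(sub.names)
            if design.penalty_factors[j] == 0 or nm in set(stable)]
    auc = repeated_split_auc(sub.X[:, keep], sub.y, n_splits=n_splits, seed=seed)
    return MatchedSubsampleResult(idx, balance, res, stable, auc,
                                  attempts if target_n < n else 0)
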