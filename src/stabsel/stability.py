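"""Stability selection with a binomial-null calibrated threshold.

The selection engine fits L1-penalised logistic regressions on many
random half-subsamples of the data and records, for every penalty value
lambda on a decreasing grid, how often each penalised feature enters the
model. The penalty and the selection-proportion threshold pi are then
calibrated jointly by maximising a stability score: the negative
log-likelihood of the observed selection-count pattern under the null
hypothesis that all features are selected equiprobably. Writing q(lambda)
for the average number of selected features and p for the number of
penalised features, the null count distribution is
H ~ Binomial(K, q/p); each feature falls into one of three categories —

* low:  count <= floor(K (1 - pi))
* high: count >= ceil(K pi)
* mid:  otherwise

and the score is  - sum_j log P(H in category of feature j).  A large
score means the observed pattern (some features nearly always selected,
the rest nearly never) is maximally incompatible with equiprobable,
unstable selection. Features with selection proportion >= pi* at
lambda* form the stable set.

Forced covariates (penalty factor 0) sit in every model by construction:
they are excluded from the counts, from q and from the score, and their
selection proportion is reported as exactly 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import DesignMatrix
from .lasso import lasso_path, make_lambda_grid

__all__ = [
    "SelectionResult",
    "ReproducibilityResult",
    "stability_score",
    "calibrate",
    "run_subsampling",
    "stable_features",
    "reproducibility_runs",
    "StabilitySelection",
    "default_pi_grid",
]

_PROB_FLOOR = 1e-300  # probability floor applied before taking logs


def default_pi_grid() -> np.ndarray:
    """Candidate thresholds 0.51, 0.52, ..., 0.99."""
    return np.round(np.arange(51, 100) / 100.0, 2)


# ---------------------------------------------------------------------------
# subsampling


def _stratified_take(n_class: np.ndarray, fraction: float) -> np.ndarray:
    """Per-class subsample sizes totalling floor(fraction * n).

    Largest-remainder allocation keeps the draw outcome-stratified while
    matching the overall subsample size exactly.
    """
    n = int(n_class.sum())
    n_take = int(np.floor(fraction * n))
    quota = n_take * n_class / n
    base = np.floor(quota).astype(int)
    short = n_take - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    base[order[:short]] += 1
    return base


def _subsample_counts(
    X: np.ndarray,
    y: np.ndarray,
    pf: np.ndarray,
    lambdas: np.ndarray,
    K: int,
    fraction: float,
    seed: int,
    tol: float,
    eta_tol: float,
    max_outer: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Selection counts (L x p_penalised) and q(lambda) over K subsamples."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("subsample fraction must lie in (0, 1]")
    pen = pf > 0
    classes = np.array([0, 1])
    class_idx = [np.flatnonzero(y == c) for c in classes]
    n_class = np.array([len(ix) for ix in class_idx])
    if (n_class == 0).any():
        raise ValueError("outcome must contain both classes")
    takes = _stratified_take(n_class, fraction)
    if (takes < 2).any():
        raise ValueError(
            f"a class would have fewer than 2 members in subsamples "
            f"(class sizes {n_class.tolist()}, takes {takes.tolist()}); "
            "use a larger subsample fraction"
        )
    rng = np.random.default_rng(seed)
    L = len(lambdas)
    counts = np.zeros((L, int(pen.sum())), dtype=np.int32)
    q_sum = np.zeros(L)
    for _ in range(K):
        rows = np.concatenate([
            ix[rng.permutation(len(ix))[:t]] for ix, t in zip(class_idx, takes)
        ])
        coefs, _ = lasso_path(
            X[rows], y[rows], lambdas, pf,
            tol=tol, eta_tol=eta_tol, max_outer=max_outer,
        )
        support = coefs[:, pen] != 0
        counts += support
        q_sum += support.sum(axis=1)
    return counts, q_sum / K


@dataclass
class SelectionResult:
    """Output of the subsampling stage, later annotated by calibration."""

    lambdas: np.ndarray
    K: int
    fraction: float
    feature_names: list[str]     # penalised features only
    counts: np.ndarray           # (L, p_penalised) selection counts in 0..K
    q: np.ndarray                # (L,) mean selected-support size
    seed: int
    # filled by calibrate()
    pi_grid: Optional[np.ndarray] = None
    score_surface: Optional[np.ndarray] = None
    lambda_star: Optional[float] = None
    pi_star: Optional[float] = None
    lambda_star_idx: Optional[int] = None
    pi_star_idx: Optional[int] = None
    notes: dict = field(default_factory=dict)

    @property
    def proportions(self) -> np.ndarray:
        """(L, p_penalised) selection proportions, counts / K."""
        return self.counts / self.K

    @property
    def calibrated(self) -> bool:
        return self.lambda_star is not None

    def proportions_at_star(self) -> pd.Series:
        if not self.calibrated:
            raise ValueError("result is not calibrated; run calibrate() first")
        return pd.Series(
            self.proportions[self.lambda_star_idx], index=self.feature_names,
            name="selection_proportion",
        )


def run_subsampling(
    design: DesignMatrix,
    lambdas: Optional[np.ndarray] = None,
    K: int = 1000,
    fraction: float = 0.5,
    seed: int = 0,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    tol: float = 1e-4,
    eta_tol: float = 1e-4,
    max_outer: int = 8,
) -> SelectionResult:
    """Selection counts over K outcome-stratified subsamples.

    Each iteration draws floor(fraction * n) participants without
    replacement, stratified by outcome, fits the full penalty path and
    records which penalised features have non-zero coefficients. The
    penalty grid defaults to 50 geometric points from the full-data
    lambda_max down to 1% of it.
    """
    if lambdas is None:
        lambdas = make_lambda_grid(
            design.X, design.y, design.penalty_factors,
            n_lambdas=n_lambdas, min_ratio=lambda_min_ratio,
        )
    lambdas = np.asarray(lambdas, dtype=float)
    counts, q = _subsample_counts(
        design.X, design.y, design.penalty_factors, lambdas,
        K=K, fraction=fraction, seed=seed,
        tol=tol, eta_tol=eta_tol, max_outer=max_outer,
    )
    return SelectionResult(
        lambdas=lambdas, K=K, fraction=fraction,
        feature_names=design.penalised_names, counts=counts, q=q, seed=seed,
    )


# ---------------------------------------------------------------------------
# stability score and calibration


def _category_log_probs(K: int, theta: float, pi: float) -> tuple[int, int, np.ndarray]:
    """Bounds and log-probabilities of the (low, mid, high) categories."""
    low_max = int(np.floor(K * (1.0 - pi)))
    high_min = int(np.ceil(K * pi))
    k = np.arange(K + 1)
    pmf = stats.binom.pmf(k, K, theta)
    # each category mass is summed directly from the pmf: computing the mid
    # mass as 1 - low - high would cancel catastrophically when one tail
    # carries almost all the mass
    p_low = float(pmf[: low_max + 1].sum())
    p_mid = float(pmf[low_max + 1: high_min].sum())
    p_high = float(pmf[high_min:].sum())
    probs = np.array([p_low, p_mid, p_high])
    return low_max, high_min, np.log(np.maximum(probs, _PROB_FLOOR))


def stability_score(counts: np.ndarray, K: int, q: float, pi: float) -> float:
    """Negative log-likelihood of the counts under equiprobable selection.

    ``counts`` are the selection counts of the p penalised features at one
    penalty value; ``q`` is the average selected-support size there. The
    null count distribution is Binomial(K, round(q)/p) and each feature
    contributes -log P(its category). Larger is further from the
    equiprobability (instability) null.
    """
    counts = np.asarray(counts)
    p = counts.size
    if not 0.5 < pi <= 1.0:
        raise ValueError("pi must lie in (0.5, 1]")
    if not 0 < q < p:
        raise ValueError(f"q must lie strictly between 0 and p={p}, got {q}")
    if counts.min() < 0 or counts.max() > K:
        raise ValueError("counts must lie in 0..K")
    q_int = int(np.clip(np.round(q), 1, p - 1))
    low_max, high_min, logp = _category_log_probs(K, q_int / p, pi)
    cat = np.where(counts <= low_max, 0, np.where(counts >= high_min, 2, 1))
    return float(-logp[cat].sum())


def calibrate(
    result: SelectionResult,
    pi_grid: Optional[np.ndarray] = None,
) -> tuple[float, float, np.ndarray]:
    """Choose (lambda*, pi*) maximising the stability score.

    The score surface over the penalty grid x pi grid is stored on the
    result. Grid points where q(lambda) is degenerate (zero, or the whole
    feature set) are excluded. Ties are broken toward the larger penalty
    (sparser model) and then the larger pi (more stable); a fully
    degenerate surface falls back to the sparsest pair with a warning.
    """
    pi_grid = default_pi_grid() if pi_grid is None else np.asarray(pi_grid, dtype=float)
    if pi_grid.ndim != 1 or len(pi_grid) == 0:
        raise ValueError("pi_grid must be a non-empty 1-d array")
    if not ((pi_grid > 0.5) & (pi_grid <= 1.0)).all():
        raise ValueError("pi_grid values must lie in (0.5, 1]")
    L = len(result.lambdas)
    p = len(result.feature_names)
    surface = np.full((L, len(pi_grid)), -np.inf)
    for l in range(L):
        if not 0 < result.q[l] < p:
            continue
        for m, pi in enumerate(pi_grid):
            surface[l, m] = stability_score(result.counts[l], result.K, result.q[l], pi)
    best = surface.max()
    if not np.isfinite(best):
        raise ValueError("score surface is entirely degenerate: no lambda with 0 < q < p")
    hits = np.argwhere(surface == best)
    if len(hits) == surface.size:
        warnings.warn(
            "all stability scores equal; returning the sparsest "
            "(largest lambda, largest pi) pair", UserWarning,
        )
    # smallest lambda index = largest penalty; then largest pi
    l_star = int(hits[:, 0].min())
    m_star = int(hits[hits[:, 0] == l_star, 1].max())
    result.pi_grid = pi_grid
    result.score_surface = surface
    result.lambda_star_idx = l_star
    result.pi_star_idx = m_star
    result.lambda_star = float(result.lambdas[l_star])
    result.pi_star = float(pi_grid[m_star])
    result.notes["tie_policy"] = "larger lambda, then larger pi"
    return result.lambda_star, result.pi_star, surface


def stable_features(result: SelectionResult) -> list[str]:
    """Penalised features stably selected at the calibrated pair.

    Features with selection proportion >= pi* at lambda*, in decreasing
    order of proportion (name breaks ties).
    """
    props = result.proportions_at_star()
    hit = props[props >= result.pi_star]
    order = sorted(hit.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in order]


# ---------------------------------------------------------------------------
# estimator


class StabilitySelection(BaseEstimator):
    """Stability-selection LASSO logistic regression (sklearn estimator).

    Parameters
    ----------
    n_subsamples : int
        Number of random subsamples K (default 1000).
    subsample_fraction : float
        Fraction of participants per subsample (default 0.5, drawn
        without replacement, stratified by outcome).
    n_lambdas, lambda_min_ratio : int, float
        Geometric penalty grid: ``n_lambdas`` points from the data-derived
        lambda_max down to ``lambda_min_ratio * lambda_max``.
    pi_grid : array-like or None
        Candidate stability thresholds; default 0.51..0.99 by 0.01.
    penalty_factors : array-like or None
        Per-feature L1 multipliers (0 = forced, never penalised); default
        all ones. May also be provided per-fit via ``fit(...,
        penalty_factors=...)``.
    random_state : int
        Seed for the subsample draws.
    path_tol, path_eta_tol, path_max_outer
        Solver tolerances for the subsample path fits (fast regime).

    Attributes (after fit)
    ----------------------
    lambda_grid_, selection_counts_, q_ : the subsampling outputs
        (penalised features only).
    selection_proportions_ : pandas.Series over all features at lambda*;
        forced covariates are reported as exactly 1.
    lambda_star_, pi_star_, score_surface_ : calibration outputs.
    stable_features_ : stable penalised features, by decreasing proportion.
    stable_mask_ : boolean mask over all input features (forced
        covariates included, since they sit in every model).
    """

    def __init__(
        self,
        n_subsamples: int = 1000,
        subsample_fraction: float = 0.5,
        n_lambdas: int = 50,
        lambda_min_ratio: float = 0.01,
        pi_grid: Optional[np.ndarray] = None,
        penalty_factors: Optional[np.ndarray] = None,
        random_state: int = 0,
        path_tol: float = 1e-4,
        path_eta_tol: float = 1e-4,
        path_max_outer: int = 8,
    ):
        self.n_subsamples = n_subsamples
        self.subsample_fraction = subsample_fraction
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.pi_grid = pi_grid
        self.penalty_factors = penalty_factors
        self.random_state = random_state
        self.path_tol = path_tol
        self.path_eta_tol = path_eta_tol
        self.path_max_outer = path_max_outer

    def fit(self, X, y, penalty_factors: Optional[np.ndarray] = None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(X.shape[1])], dtype=object
            )
        y = np.asarray(y)
        pf = penalty_factors if penalty_factors is not None else self.penalty_factors
        pf = np.ones(X.shape[1]) if pf is None else np.asarray(pf, dtype=float)
        names = [str(nm) for nm in self.feature_names_in_]
        design = DesignMatrix(X, names, pf, y.astype(int), pd.RangeIndex(len(y)))
        result = run_subsampling(
            design,
            K=self.n_subsamples,
            fraction=self.subsample_fraction,
            seed=self.random_state,
            n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            tol=self.path_tol,
            eta_tol=self.path_eta_tol,
            max_outer=self.path_max_outer,
        )
        calibrate(result, self.pi_grid)
        self.result_ = result
        self.lambda_grid_ = result.lambdas
        self.selection_counts_ = result.counts
        self.q_ = result.q
        self.score_surface_ = result.score_surface
        self.lambda_star_ = result.lambda_star
        self.pi_star_ = result.pi_star
        self.stable_features_ = stable_features(result)
        pen = pf > 0
        props = pd.Series(1.0, index=names, name="selection_proportion")
        props[result.feature_names] = result.proportions_at_star()
        self.selection_proportions_ = props
        stable = set(self.stable_features_)
        self.stable_mask_ = np.array(
            [(not pen[j]) or (names[j] in stable) for j in range(len(names))]
        )
        self.n_features_in_ = X.shape[1]
        return self

    def get_support(self, include_forced: bool = True) -> np.ndarray:
        check_is_fitted(self, "stable_mask_")
        if include_forced:
            return self.stable_mask_.copy()
        pf = self.result_  # penalised-only mask
        mask = self.stable_mask_.copy()
        names = [str(nm) for nm in self.feature_names_in_]
        pen_names = set(pf.feature_names)
        for j, nm in enumerate(names):
            if nm not in pen_names:
                mask[j] = False
        return mask

    def transform(self, X):
        check_is_fitted(self, "stable_mask_")
        if isinstance(X, pd.DataFrame):
            return X.loc[:, self.stable_mask_]
        return np.asarray(X)[:, self.stable_mask_]


# ---------------------------------------------------------------------------
# reproducibility across outer subsamples


@dataclass
class ReproducibilityResult:
    """Stable-selection frequencies across B outer subsamples."""

    frequency: pd.Series            # per protein: share of runs where stable
    proportions: pd.DataFrame       # (B, p) selection proportion at each run's lambda*
    stable_sets: list[list[str]]
    seeds: list[int]
    B: int
    fraction: float


def reproducibility_runs(
    design: DesignMatrix,
    B: int = 100,
    fraction: float = 0.8,
    seed: int = 0,
    K: int = 250,
    n_lambdas: int = 50,
    lambda_min_ratio: float = 0.01,
    pi_grid: Optional[np.ndarray] = None,
    seeds: Optional[Sequence[int]] = None,
) -> ReproducibilityResult:
    """Re-run the full calibrated procedure on B outer 80% subsamples.

    Each run draws an outcome-stratified subsample of floor(fraction * n)
    participants and repeats subsampling + calibration on it (with a
    reduced default K of 250 to keep 100 outer runs tractable; pass a
    larger K for the full-depth analysis). Returns the frequency with
    which each protein enters the stable set and the distribution of its
    selection proportions at the per-run calibrated penalty.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if seeds is None:
        root = np.random.default_rng([87, seed])
        seeds = [int(s) for s in root.integers(0, 2**31, size=B)]
    else:
        seeds = [int(s) for s in seeds]
        if len(seeds) != B:
            raise ValueError("seeds must have length B")
    class_idx = [np.flatnonzero(design.y == c) for c in (0, 1)]
    takes = _stratified_take(np.array([len(ix) for ix in class_idx]), fraction)
    if (takes < 2).any():
        raise ValueError("outer subsample would leave a class with < 2 members")
    prop_rows, stable_sets = [], []
    for b in range(B):
        rng = np.random.default_rng(seeds[b])
        rows = np.concatenate([
            ix[rng.permutation(len(ix))[:t]] for ix, t in zip(class_idx, takes)
        ])
        sub = design.subset(np.sort(rows))
        res = run_subsampling(
            sub, K=K, fraction=0.5, seed=seeds[b],
            n_lambdas=n_lambdas, lambda_min_ratio=lambda_min_ratio,
        )
        calibrate(res, pi_grid)
        stable_sets.append(stable_features(res))
        prop_rows.append(res.proportions_at_star())
    proportions = pd.DataFrame(prop_rows, index=pd.RangeIndex(B, name="run"))
    freq = pd.Series(0.0, index=design.penalised_names, name="stable_frequency")
    for s in stable_sets:
        freq[s] += 1.0
    freq /= B
    return ReproducibilityResult(freq, proportions, stable_sets, list(seeds), B, fraction)
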