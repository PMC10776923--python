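"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route disjoint from the package
implementation: exact rational binomial tail sums, a generic smooth
convex optimiser on the split-variable form of the penalised objective,
exhaustive concordant-pair counting for the AUC, and brute-force
all-pairs neighbour ranking for the k-NN imputer.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
from scipy import optimize


def binomial_score_oracle(counts, K: int, q: float, pi: float) -> float:
    """Stability score via exact rational binomial tail sums.

    The null is H ~ Binomial(K, q_int/p) with q_int = clip(round(q), 1,
    p-1); category masses are accumulated in exact Fraction arithmetic
    (binomial coefficients via math.comb), floored at 1e-300, and the
    score is -sum log P(category of each count).
    """
    counts = np.asarray(counts)
    p = counts.size
    q_int = int(min(max(round(q), 1), p - 1))
    theta = Fraction(q_int, p)
    low_max = math.floor(K * (1.0 - pi))
    high_min = math.ceil(K * pi)
    pmf = [
        Fraction(math.comb(K, k)) * theta**k * (1 - theta) ** (K - k)
        for k in range(K + 1)
    ]
    p_low = float(sum(pmf[: low_max + 1]))
    p_mid = float(sum(pmf[low_max + 1: high_min]))
    p_high = float(sum(pmf[high_min:]))
    floor = 1e-300
    score = 0.0
    for c in counts:
        if c <= low_max:
            prob = p_low
        elif c >= high_min:
            prob = p_high
        else:
            prob = p_mid
        score -= math.log(max(prob, floor))
    return score


def penalised_logistic_oracle(X, y, lam, penalty_factors, x0=None):
    """Minimise the penalised logistic objective with a generic solver.

    Split-variable formulation: beta = u - v with u, v >= 0 turns the L1
    term into a smooth linear one, solved with L-BFGS-B. Returns
    (objective value, coef, intercept).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    pf = np.asarray(penalty_factors, float)
    n, p = X.shape

    def fun(z):
        u, v, b0 = z[:p], z[p: 2 * p], z[-1]
        beta = u - v
        eta = b0 + X @ beta
        nll = np.mean(np.logaddexp(0.0, eta) - y * eta)
        grad_eta = (1.0 / (1.0 + np.exp(-eta)) - y) / n
        g_beta = X.T @ grad_eta
        g = np.concatenate([g_beta + lam * pf, -g_beta + lam * pf, [grad_eta.sum()]])
        return nll + lam * np.sum(pf * (u + v)), g

    z0 = np.zeros(2 * p + 1)
    if x0 is not None:
        beta0, b00 = x0
        z0[:p] = np.maximum(beta0, 0)
        z0[p: 2 * p] = np.maximum(-beta0, 0)
        z0[-1] = b00
    bounds = [(0, None)] * (2 * p) + [(None, None)]
    res = optimize.minimize(
        fun, z0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12},
    )
    beta = res.x[:p] - res.x[p: 2 * p]
    return float(res.fun), beta, float(res.x[-1])


def pair_counting_auc(y, scores) -> float:
    """AUC by exhaustive concordant-pair enumeration (ties count 1/2)."""
    y = np.asarray(y)
    scores = np.asarray(scores, float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                total += 1.0
            elif sp == sn:
                total += 0.5
    return total / (len(pos) * len(neg))


def knn_impute_oracle(frame, row_label, column, k, numeric_cols, seed=0):
    """Brute-force k-NN imputation of one cell.

    Standardises the numeric covariates (sample SD), computes pairwise-
    available Euclidean distances from the query row to every donor row
    observing ``column`` (excluding the query row itself), rescales by
    the number of shared coordinates as nan_euclidean does, and averages
    (or majority-votes) the k nearest donor values. Ties broken by the
    same seeded shuffle convention as the implementation.
    """
    import pandas as pd

    num = frame[numeric_cols].astype(float)
    std = (num - num.mean()) / num.std(ddof=1)
    query = std.loc[row_label].to_numpy()
    dists, labels = [], []
    rng = np.random.default_rng(seed)
    tiebreak = rng.permutation(len(frame))
    rank = dict(zip(frame.index, tiebreak))
    d_total = std.shape[1]
    for lab in frame.index:
        if lab == row_label or pd.isna(frame.loc[lab, column]):
            continue
        other = std.loc[lab].to_numpy()
        ok = ~np.isnan(query) & ~np.isnan(other)
        if not ok.any():
            continue
        sq = np.sum((query[ok] - other[ok]) ** 2) * d_total / ok.sum()
        dists.append(math.sqrt(sq))
        labels.append(lab)
    order = sorted(range(len(labels)), key=lambda i: (dists[i], rank[labels[i]]))
    take = [labels[i] for i in order[:k]]
    vals = frame.loc[take, column]
    if column in numeric_cols:
        return float(vals.astype(float).mean())
    from collections import Counter

    return sorted(Counter(vals).items(), key=lambda kv: (-kv[1], str(kv[0])))[0][0]
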