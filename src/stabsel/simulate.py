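"""Synthetic asthma-proteomics cohorts with known ground truth.

Real SOMAscan-style studies of granulocytic asthma phenotypes pair a
clinical table (demographics, lung function, blood/sputum granulocyte
counts) with an abundance matrix of ~1100 serum or sputum proteins in
relative fluorescence units (RFU). Access to such cohorts is controlled,
so this module generates cohorts with the same statistical skeleton:

* log-normal protein abundances with block-correlated log scale and a
  per-sample multiplicative assay scale factor (what median normalisation
  is meant to remove);
* a sparse causal support of proteins driving either a latent logistic
  disease status or negative-binomial granulocyte counts;
* clinical covariates drawn to match the marginal means/SDs typical of
  severe-asthma cohorts;
* missing-completely-at-random gaps in the clinical covariates only.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .containers import ProteinMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "CLINICAL_COVARIATES",
    "DEFAULT_CLINICAL_SPEC",
    "generate_proteome",
    "generate_outcome",
    "inject_missingness",
    "generate_cohort",
    "generate_followup",
]

#: clinical covariates eligible for missingness injection / imputation.
CLINICAL_COVARIATES = [
    "age", "sex", "bmi", "age_onset", "acq5", "fev1_pct", "fev1_fvc",
    "nasal_polyps", "ocs_dose", "pack_years", "exacerbations",
]

#: marginal distributions of the clinical covariates (means/SDs chosen to
#: match a pooled mild-moderate + severe asthma population). Gamma is used
#: for non-negative right-skewed variables so the stated mean/SD hold
#: exactly without truncation.
DEFAULT_CLINICAL_SPEC: dict[str, dict] = {
    "age": {"dist": "normal", "mean": 48.72, "sd": 14.56},
    "age_onset": {"dist": "gamma", "mean": 24.93, "sd": 17.91},
    "bmi": {"dist": "normal", "mean": 28.04, "sd": 5.78},
    "acq5": {"dist": "gamma", "mean": 1.87, "sd": 1.20},
    "fev1_pct": {"dist": "normal", "mean": 71.72, "sd": 21.89},
    "fev1_fvc": {"dist": "normal", "mean": 0.64, "sd": 0.13},
    "pack_years": {"dist": "gamma", "mean": 9.60, "sd": 15.04},
    "exacerbations": {"dist": "gamma", "mean": 1.84, "sd": 2.14},
    "ocs_dose": {"dist": "gamma", "mean": 10.69, "sd": 12.06},
    "nasal_polyps": {"dist": "bernoulli", "p": 0.272},
    "sex": {"dist": "bernoulli", "p": 0.587, "labels": ["male", "female"]},
}

#: baseline granulocyte count parameters: negative-binomial mean and
#: dispersion k (variance = mu + mu^2/k). Blood counts in cells/uL; sputum
#: counts are abstract cell tallies converted to % of granulocytes.
DEFAULT_COUNT_SPEC: dict[str, dict] = {
    "blood_eos": {"mean": 360.0, "k": 0.52},
    "blood_neu": {"mean": 4780.0, "k": 3.1},
    "sputum_eos": {"mean": 75.0, "k": 0.45},
    "sputum_neu": {"mean": 560.0, "k": 2.5},
    "sputum_other": {"mean": 365.0, "k": 2.5},
}

# distinct per-stage RNG stream tags (mixed with the master seed)
_STREAM = {"proteome": 11, "outcome": 23, "clinical": 37, "missing": 53,
           "followup": 71}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stage], int(seed)])


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the serum arm of a pooled two-cohort asthma study:
    574 participants, 1124 proteins in correlated blocks, a 10-protein
    causal support with unit log-odds effects, ~33% outcome prevalence
    and 5% missingness in clinical covariates.
    """

    n_participants: int = 574
    n_proteins: int = 1124
    n_causal: int = 10
    effect_sizes: Optional[np.ndarray] = None  # defaults to ones(n_causal)
    n_blocks: Optional[int] = None  # default: blocks of ~20 proteins
    rho: float = 0.3
    outcome_mode: str = "latent_logistic"  # or "granulocyte_counts"
    baseline_prevalence: float = 0.33
    count_target: str = "blood_eos"  # count driven by proteins in count mode
    count_spec: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COUNT_SPEC.items()})
    clinical_spec: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CLINICAL_SPEC.items()})
    missing_rate: float = 0.05
    scale_sd: float = 0.2  # SD of per-sample log scale factor
    followup_autocorr: float = 0.7
    medium: str = "serum"
    mild_cohort_fraction: float = 0.19  # share of mild-moderate-cohort participants
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants <= 0 or self.n_proteins <= 0:
            raise ValueError("n_participants and n_proteins must be positive")
        if not 0 <= self.n_causal <= self.n_proteins:
            raise ValueError("n_causal must lie in [0, n_proteins]")
        if self.effect_sizes is None:
            self.effect_sizes = np.ones(self.n_causal)
        self.effect_sizes = np.asarray(self.effect_sizes, dtype=float)
        if self.effect_sizes.shape != (self.n_causal,):
            raise ValueError(
                f"effect_sizes must have length n_causal={self.n_causal}, "
                f"got {self.effect_sizes.shape}"
            )
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(
                "within-block correlation rho must lie in [0, 1): the "
                "equicorrelated block structure is not positive definite "
                f"for rho={self.rho}"
            )
        if self.n_blocks is None:
            self.n_blocks = max(1, self.n_proteins // 20)
        if self.n_blocks < 1 or self.n_blocks > self.n_proteins:
            raise ValueError("n_blocks must lie in [1, n_proteins]")
        if self.outcome_mode not in ("latent_logistic", "granulocyte_counts"):
            raise ValueError(f"unknown outcome_mode {self.outcome_mode!r}")
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0.0 <= self.followup_autocorr <= 1.0:
            raise ValueError("followup_autocorr must lie in [0, 1]")
        if self.count_target not in DEFAULT_COUNT_SPEC or self.count_target == "sputum_other":
            raise ValueError(f"count_target must be a granulocyte count, got {self.count_target!r}")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    cohort: pd.DataFrame
    proteins: ProteinMatrix
    true_support: list[str]
    true_coefficients: np.ndarray  # full-length p vector
    latent_scores: pd.Series


def _block_assignment(p: int, n_blocks: int) -> np.ndarray:
    """Contiguous near-equal blocks; returns per-protein block index."""
    sizes = np.full(n_blocks, p // n_blocks)
    sizes[: p % n_blocks] += 1
    return np.repeat(np.arange(n_blocks), sizes)


def _participant_ids(n: int) -> pd.Index:
    return pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")


def generate_proteome(config: SimulationConfig) -> ProteinMatrix:
    """Draw the raw protein abundance matrix.

    Log-abundances are multivariate normal with an equicorrelated block
    structure (correlation ``rho`` within each of ``n_blocks`` blocks),
    protein-specific location/scale, and a per-sample log-normal assay
    scale factor of SD ``scale_sd`` that multiplies every protein of a
    sample. Returns a raw-stage :class:`ProteinMatrix` whose ``meta``
    carries the generative constants needed to reconstruct the latent
    standardised signal (used by :func:`generate_outcome` and
    :func:`generate_followup`).
    """
    rng = _rng(config.seed, "proteome")
    n, p = config.n_participants, config.n_proteins
    blocks = _block_assignment(p, config.n_blocks)
    eps = rng.standard_normal((n, p))
    shared = rng.standard_normal((n, config.n_blocks))
    z = math.sqrt(1.0 - config.rho) * eps + math.sqrt(config.rho) * shared[:, blocks]
    mu = rng.normal(7.0, 1.0, size=p)            # log-RFU locations
    sigma = rng.uniform(0.2, 0.6, size=p)        # log-RFU scales
    log_scale = rng.normal(0.0, config.scale_sd, size=n)
    log_abund = mu[None, :] + sigma[None, :] * z + log_scale[:, None]
    ids = _participant_ids(n)
    names = [f"prot{j:04d}" for j in range(p)]
    data = pd.DataFrame(np.exp(log_abund), index=ids, columns=names)
    meta = {
        "blocks": blocks,
        "mu": mu,
        "sigma": sigma,
        "sample_log_scale": pd.Series(log_scale, index=ids),
        "seed": config.seed,
    }
    return ProteinMatrix(data, medium=config.medium, stage="raw", meta=meta)


def _latent_signal(proteins: ProteinMatrix) -> np.ndarray:
    """Standardised log-abundance with the assay scale factor removed.

    The disease model acts on the biological signal, not on the per-sample
    assay artifact, so the stored scale factors are subtracted before
    column standardisation.
    """
    logA = np.log(proteins.data.to_numpy())
    scale = proteins.meta.get("sample_log_scale")
    if scale is not None:
        logA = logA - np.asarray(scale)[:, None]
    logA = logA - logA.mean(axis=0)
    sd = logA.std(axis=0)
    sd[sd == 0] = 1.0
    return logA / sd


def _causal_indices(config: SimulationConfig) -> np.ndarray:
    rng = _rng(config.seed, "outcome")
    return np.sort(rng.choice(config.n_proteins, size=config.n_causal, replace=False))


def _draw_clinical(config: SimulationConfig, ids: pd.Index) -> pd.DataFrame:
    rng = _rng(config.seed, "clinical")
    n = len(ids)
    cols: dict[str, np.ndarray] = {}
    # sorted iteration: the draw order (hence the RNG stream) must not depend
    # on dict insertion order, or a config round-tripped through YAML would
    # generate a different cohort
    for name in sorted(config.clinical_spec):
        spec = config.clinical_spec[name]
        dist = spec["dist"]
        if dist == "normal":
            cols[name] = rng.normal(spec["mean"], spec["sd"], size=n)
        elif dist == "gamma":
            m, s = spec["mean"], spec["sd"]
            shape = (m / s) ** 2
            cols[name] = rng.gamma(shape, s * s / m, size=n)
        elif dist == "bernoulli":
            draw = (rng.random(n) < spec["p"]).astype(int)
            labels = spec.get("labels")
            cols[name] = np.array([labels[d] for d in draw]) if labels else draw
        else:
            raise ValueError(f"unknown clinical distribution {dist!r} for {name}")
    order = [c for c in CLINICAL_COVARIATES if c in cols]
    order += [c for c in sorted(cols) if c not in order]
    df = pd.DataFrame(cols, index=ids)[order]
    n_mild = int(round(config.mild_cohort_fraction * n))
    cohort_lbl = np.array(["severe"] * n, dtype=object)
    mild_idx = rng.choice(n, size=n_mild, replace=False)
    cohort_lbl[mild_idx] = "mild_moderate"
    df["cohort"] = cohort_lbl
    df["visit"] = "baseline"
    return df


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, k: float) -> np.ndarray:
    """Negative binomial with mean ``mean`` and dispersion ``k``."""
    mean = np.asarray(mean, dtype=float)
    prob = k / (k + mean)
    return rng.negative_binomial(k, prob).astype(float)


def generate_outcome(proteins: ProteinMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Draw the clinical table with outcome for a generated proteome.

    In ``latent_logistic`` mode a binary ``status`` column is drawn from
    Bernoulli(sigmoid(alpha + X beta)) where alpha = logit(baseline
    prevalence) and X is the latent standardised causal signal. In
    ``granulocyte_counts`` mode the targeted granulocyte count is drawn
    from a negative binomial whose log-mean is linear in the causal
    proteins; all other counts are null draws. Sputum percentages are the
    eosinophil/neutrophil share of the total granulocyte tally. The
    latent linear predictor is returned in column ``latent_score``.
    """
    if proteins.shape != (config.n_participants, config.n_proteins):
        raise ValueError("proteins shape does not match config")
    if config.n_causal > 0 and config.effect_sizes.size == 0:
        raise ValueError("n_causal > 0 but effect_sizes is empty")
    rng = _rng(config.seed, "outcome")
    causal = np.sort(rng.choice(config.n_proteins, size=config.n_causal, replace=False))
    signal = _latent_signal(proteins)
    eta = signal[:, causal] @ config.effect_sizes if config.n_causal else np.zeros(len(proteins.data))

    cohort = _draw_clinical(config, proteins.participants)
    cohort["latent_score"] = eta

    counts: dict[str, np.ndarray] = {}
    for name in sorted(config.count_spec):  # draw order independent of dict order
        spec = config.count_spec[name]
        log_mean = np.log(spec["mean"]) * np.ones(len(eta))
        if config.outcome_mode == "granulocyte_counts" and name == config.count_target:
            log_mean = log_mean + eta
        counts[name] = _nb_draw(rng, np.exp(log_mean), spec["k"])
    gran_total = counts["sputum_eos"] + counts["sputum_neu"] + counts["sputum_other"]
    gran_total = np.maximum(gran_total, 1.0)
    cohort["blood_eos"] = counts["blood_eos"]
    cohort["blood_neu"] = counts["blood_neu"]
    cohort["sputum_eos_pct"] = 100.0 * counts["sputum_eos"] / gran_total
    cohort["sputum_neu_pct"] = 100.0 * counts["sputum_neu"] / gran_total

    if config.outcome_mode == "latent_logistic":
        alpha = math.log(config.baseline_prevalence / (1.0 - config.baseline_prevalence))
        prob = 1.0 / (1.0 + np.exp(-(alpha + eta)))
        cohort["status"] = (rng.random(len(eta)) < prob).astype(int)
    return cohort


def inject_missingness(
    cohort: pd.DataFrame,
    rate: float,
    seed: int,
    columns: Optional[list[str]] = None,
) -> pd.DataFrame:
    """Set a random ``rate`` fraction of eligible clinical cells missing.

    Missingness is completely at random and touches only clinical
    covariates: outcome/status, granulocyte counts and labels are never
    eligible.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    out = cohort.copy()
    if columns is None:
        columns = [c for c in CLINICAL_COVARIATES if c in out.columns]
    else:
        bad = set(columns) - set(CLINICAL_COVARIATES)
        if bad:
            raise ValueError(f"only clinical covariates may be made missing, not {sorted(bad)}")
    if rate == 0.0 or not columns:
        return out
    rng = _rng(seed, "missing")
    mask = rng.random((len(out), len(columns))) < rate
    for j, col in enumerate(columns):
        if mask[:, j].any():
            if out[col].dtype == object:
                out.loc[mask[:, j], col] = None
            else:
                out[col] = out[col].astype(float)
                out.loc[mask[:, j], col] = np.nan
    return out


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full generator: proteome, outcome, clinical missingness."""
    proteins = generate_proteome(config)
    cohort = generate_outcome(proteins, config)
    cohort = inject_missingness(cohort, config.missing_rate, config.seed)
    causal = _causal_indices(config)
    names = list(proteins.proteins)
    support = [names[j] for j in causal]
    coef = np.zeros(config.n_proteins)
    coef[causal] = config.effect_sizes
    return SyntheticCohort(
        cohort=cohort,
        proteins=proteins,
        true_support=support,
        true_coefficients=coef,
        latent_scores=cohort["latent_score"],
    )


def generate_followup(
    sc: SyntheticCohort,
    config: SimulationConfig,
    n_followup: int = 62,
    seed: Optional[int] = None,
) -> ProteinMatrix:
    """Redraw protein noise for a follow-up visit of a participant subset.

    The latent standardised log-signal z is redrawn around the baseline
    value with autocorrelation ``config.followup_autocorr``; locations,
    scales and block structure are those of the baseline draw, and fresh
    per-sample assay scale factors are applied. Mild-cohort participants
    are preferred, emulating a short-interval repeat visit arm.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, "followup")
    meta = sc.proteins.meta
    for key in ("mu", "sigma", "sample_log_scale"):
        if key not in meta:
            raise ValueError("proteins must come from generate_proteome (meta missing)")
    a = config.followup_autocorr
    cohort = sc.cohort
    mild = cohort.index[cohort["cohort"] == "mild_moderate"]
    if len(mild) >= n_followup:
        chosen = mild[np.sort(rng.choice(len(mild), size=n_followup, replace=False))]
    else:
        chosen = cohort.index[: n_followup]
    pos = sc.proteins.participants.get_indexer(chosen)

    logA = np.log(sc.proteins.data.to_numpy()[pos])
    mu, sigma = meta["mu"], meta["sigma"]
    base_scale = np.asarray(meta["sample_log_scale"])[pos]
    z = (logA - base_scale[:, None] - mu[None, :]) / sigma[None, :]
    eps = rng.standard_normal(z.shape)
    z_new = a * z + math.sqrt(1.0 - a * a) * eps
    new_scale = rng.normal(0.0, config.scale_sd, size=len(pos))
    data = pd.DataFrame(
        np.exp(mu[None, :] + sigma[None, :] * z_new + new_scale[:, None]),
        index=chosen, columns=sc.proteins.proteins,
    )
    new_meta = dict(meta)
    new_meta["sample_log_scale"] = pd.Series(new_scale, index=chosen)
    new_meta["visit"] = "followup"
    return ProteinMatrix(data, medium=sc.proteins.medium, stage="raw", meta=new_meta)
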