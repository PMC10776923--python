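"""End-to-end orchestration: simulate/read -> preprocess -> select -> evaluate.

A single :class:`PipelineConfig` (YAML-serialisable, lossless round-trip)
drives the whole analysis. Every random stage derives its own seed from
the master seed and the stage name, so stages are independently
reproducible, and the run directory ends with a ``manifest.json``
recording the config echo, per-stage seeds and SHA-256 hashes of every
output file. Manifests contain no timestamps: two runs of the same config
are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import ProteinMatrix
from .evaluate import (
    followup_validation,
    matched_subsample_reanalysis,
    sequential_addition,
    _fit_logistic,
)
from .io import file_sha256, read_tables, write_json, write_table
from .preprocess import (
    ALTERNATIVE_PHENOTYPES,
    ClinicalKNNImputer,
    LogStandardizer,
    MedianNormalizer,
    PhenotypeDefinition,
    STANDARD_PHENOTYPES,
    assemble_design,
    dichotomise_phenotype,
)
from .simulate import SimulationConfig, generate_cohort, generate_followup
from .stability import calibrate, reproducibility_runs, run_subsampling, stable_features

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "stage_seed"]

logger = logging.getLogger("stabsel")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and config echo."""

    def __init__(self, stage: str, config: "PipelineConfig", cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}\nconfig: {config.to_dict()}")
        self.stage = stage
        self.cause = cause


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed: hash of the stage name and master seed."""
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Everything one reproducible run needs.

    Either ``simulation`` (a :class:`SimulationConfig`) or the pair
    ``cohort_path``/``proteins_path`` provides the input data. Phenotypes
    are analysed for every entry of ``phenotypes`` crossed with every
    adjustment mode in ``modes``; in latent-outcome simulations the
    simulated binary status is analysed directly when
    ``use_latent_status`` is set.
    """

    out_dir: str = "stabsel_run"
    seed: int = 0
    # input
    simulation: Optional[SimulationConfig] = None
    cohort_path: Optional[str] = None
    proteins_path: Optional[str] = None
    medium: str = "serum"
    # preprocessing
    knn_k: int = 5
    ddof: int = 1
    # analyses
    use_latent_status: bool = True
    phenotypes: list = field(default_factory=list)  # list[PhenotypeDefinition]
    modes: list = field(default_factory=lambda: ["age_sex", "full_clinical"])
    # selection
    K: int = 1000
    subsample_fraction: float = 0.5
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    # evaluation
    n_splits: int = 1000
    train_fraction: float = 0.8
    # optional re-analyses
    reproducibility_B: int = 0
    reproducibility_K: int = 250
    followup: bool = False
    n_followup: int = 62
    matched_subsample_n: int = 0
    matching_variables: list = field(default_factory=lambda: ["age", "sex"])

    def __post_init__(self) -> None:
        if self.simulation is None and (self.cohort_path is None or self.proteins_path is None):
            raise ValueError("provide either a simulation config or cohort/protein paths")
        bad = [m for m in self.modes if m not in ("age_sex", "full_clinical")]
        if bad:
            raise ValueError(f"unknown adjustment mode(s): {bad}")

    # -- lossless (de)serialisation -----------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["effect_sizes"] = [float(v) for v in self.simulation.effect_sizes]
            d["simulation"] = sim
        d["phenotypes"] = [dataclasses.asdict(p) for p in self.phenotypes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulation") is not None:
            sim = dict(d["simulation"])
            if sim.get("effect_sizes") is not None:
                sim["effect_sizes"] = np.asarray(sim["effect_sizes"], dtype=float)
            d["simulation"] = SimulationConfig(**sim)
        d["phenotypes"] = [PhenotypeDefinition(**p) for p in d.get("phenotypes", [])]
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def default_phenotype_battery(cls) -> list:
        """Primary plus alternative cut-offs: 2 per cell type and medium."""
        return list(STANDARD_PHENOTYPES.values()) + list(ALTERNATIVE_PHENOTYPES.values())


def _prevalence_guard(outcome: pd.Series, label: str) -> bool:
    vals = outcome.dropna()
    if vals.nunique() < 2:
        raise ValueError(f"outcome {label!r} is constant; cannot analyse")
    return True


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured analysis end to end; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {},
        "files": {},
        "analyses": {},
    }
    files = manifest["files"]

    def record(path: Path) -> None:
        files[str(path.relative_to(out))] = file_sha256(path)

    # ---- input ------------------------------------------------------------
    stage = "input"
    try:
        if config.simulation is not None:
            sc = generate_cohort(config.simulation)
            cohort, proteins = sc.cohort, sc.proteins
            record(write_table(cohort, out / "cohort.tsv"))
            record(write_table(proteins.data, out / "proteins.tsv"))
            record(write_json({
                "true_support": sc.true_support,
                "true_coefficients": {
                    nm: float(c) for nm, c in zip(proteins.proteins, sc.true_coefficients) if c != 0
                },
                "simulation": manifest["config"]["simulation"],
            }, out / "truth.json"))
        else:
            sc = None
            cohort, proteins = read_tables(
                config.cohort_path, config.proteins_path, medium=config.medium
            )
    except Exception as e:  # noqa: BLE001 - wrap with stage context
        raise PipelineError(stage, config, e) from e

    # ---- preprocessing ----------------------------------------------------
    stage = "preprocess"
    try:
        normalizer = MedianNormalizer().fit(proteins.data)
        standardizer = LogStandardizer(ddof=config.ddof).fit(
            normalizer.transform(proteins.data)
        )
        prot_std = ProteinMatrix(
            standardizer.transform(normalizer.transform(proteins.data)),
            proteins.medium, "standardised",
            {**proteins.meta,
             "reference_median": normalizer.reference_median_,
             "transformation": {
                 "order": "log, then centre and unit-scale per protein",
                 "ddof": config.ddof,
                 "dropped_zero_variance": standardizer.dropped_,
             }},
        )
        imputer = ClinicalKNNImputer(k=config.knn_k,
                                     seed=stage_seed(config.seed, "impute"))
        manifest["stage_seeds"]["impute"] = stage_seed(config.seed, "impute")
        cohort_imp = imputer.fit(cohort).transform(cohort)
        record(write_table(cohort_imp, out / "cohort_imputed.tsv"))
        record(write_table(prot_std.data, out / "proteins_standardised.tsv"))
        record(write_json({
            "reference_median": normalizer.reference_median_,
            "transformation": prot_std.meta["transformation"],
            "knn_k": config.knn_k,
        }, out / "preprocess_provenance.json"))
    except Exception as e:
        raise PipelineError(stage, config, e) from e

    # ---- analyses ---------------------------------------------------------
    analyses: list[tuple[str, pd.Series]] = []
    if config.use_latent_status and "status" in cohort_imp.columns:
        analyses.append(("status", cohort_imp["status"].astype(float)))
    for ph in config.phenotypes:
        analyses.append((ph.name, dichotomise_phenotype(cohort_imp, ph)))

    for label, outcome in analyses:
        for mode in config.modes:
            akey = f"{label}__{mode}"
            stage = f"select[{akey}]"
            try:
                _prevalence_guard(outcome, label)
                design = assemble_design(cohort_imp, prot_std, mode, outcome)
                sel_seed = stage_seed(config.seed, f"select:{akey}")
                manifest["stage_seeds"][f"select:{akey}"] = sel_seed
                result = run_subsampling(
                    design, K=config.K, fraction=config.subsample_fraction,
                    seed=sel_seed, n_lambdas=config.n_lambdas,
                    lambda_min_ratio=config.lambda_min_ratio,
                )
                calibrate(result)
                stable = stable_features(result)
                props = result.proportions_at_star().sort_values(ascending=False)
                sel_tab = pd.DataFrame({
                    "feature": props.index,
                    "selection_proportion": props.to_numpy(),
                    "stable": [nm in set(stable) for nm in props.index],
                })
                record(write_table(sel_tab, out / f"selection_{akey}.tsv", index=False))
                record(write_json({
                    "lambda_star": result.lambda_star,
                    "pi_star": result.pi_star,
                    "K": result.K,
                    "fraction": result.fraction,
                    "seed": result.seed,
                    "lambda_grid": result.lambdas,
                    "q": result.q,
                    "stable_features": stable,
                    "n_stable": len(stable),
                    "design_provenance": design.provenance,
                }, out / f"calibration_{akey}.json"))
            except Exception as e:
                raise PipelineError(stage, config, e) from e

            stage = f"evaluate[{akey}]"
            try:
                eval_seed = stage_seed(config.seed, f"evaluate:{akey}")
                manifest["stage_seeds"][f"evaluate:{akey}"] = eval_seed
                clin = pd.DataFrame(
                    design.X[:, ~design.penalised],
                    columns=design.forced_names, index=design.ids,
                )
                prot_ranked = pd.DataFrame(
                    design.X[:, [design.names.index(nm) for nm in stable]],
                    columns=stable, index=design.ids,
                )
                curve = sequential_addition(
                    clin, prot_ranked, design.y,
                    n_splits=config.n_splits,
                    train_fraction=config.train_fraction, seed=eval_seed,
                )
                record(write_table(curve.to_frame(), out / f"auc_{akey}.tsv", index=False))
                summary = {
                    "clinical_only": curve.auc_at_step[0].mean_auc,
                    "final": curve.auc_at_step[-1].mean_auc,
                    "final_ci": [curve.auc_at_step[-1].ci_low, curve.auc_at_step[-1].ci_high],
                    "n_stable": len(stable),
                    "stable_features": stable,
                }
                manifest["analyses"][akey] = summary
            except Exception as e:
                raise PipelineError(stage, config, e) from e

            # optional deeper analyses run once, on the adjusted model
            if mode != "full_clinical":
                continue
            if config.reproducibility_B > 0:
                stage = f"reproducibility[{akey}]"
                try:
                    rep_seed = stage_seed(config.seed, f"repro:{akey}")
                    manifest["stage_seeds"][f"repro:{akey}"] = rep_seed
                    rep = reproducibility_runs(
                        design, B=config.reproducibility_B,
                        seed=rep_seed, K=config.reproducibility_K,
                        n_lambdas=config.n_lambdas,
                        lambda_min_ratio=config.lambda_min_ratio,
                    )
                    record(write_table(
                        rep.frequency.sort_values(ascending=False).to_frame(),
                        out / f"reproducibility_{akey}.tsv",
                    ))
                except Exception as e:
                    raise PipelineError(stage, config, e) from e
            if config.followup and sc is not None and label == "status" and stable:
                stage = f"followup[{akey}]"
                try:
                    fu_seed = stage_seed(config.seed, f"followup:{akey}")
                    manifest["stage_seeds"][f"followup:{akey}"] = fu_seed
                    fu_prot = generate_followup(
                        sc, config.simulation, n_followup=config.n_followup, seed=fu_seed
                    )
                    fu_std = standardizer.transform(normalizer.transform(fu_prot.data))
                    variables = design.forced_names + stable
                    Xb = pd.concat([clin, prot_ranked], axis=1)
                    model = _fit_logistic(Xb.to_numpy(dtype=float), design.y)
                    fu_clin = clin.loc[clin.index.intersection(fu_std.index)]
                    fu_ids = fu_clin.index
                    Xf = pd.concat([fu_clin, fu_std.loc[fu_ids, stable]], axis=1)
                    yf = outcome.loc[fu_ids].astype(int)
                    res = followup_validation(
                        model, Xf, yf, variables=variables, seed=fu_seed
                    )
                    manifest["analyses"][akey]["followup_auc"] = res.mean_auc
                    manifest["analyses"][akey]["followup_ci"] = [res.ci_low, res.ci_high]
                except Exception as e:
                    raise PipelineError(stage, config, e) from e
            if config.matched_subsample_n > 0:
                stage = f"matched_subsample[{akey}]"
                try:
                    ms_seed = stage_seed(config.seed, f"matched:{akey}")
                    manifest["stage_seeds"][f"matched:{akey}"] = ms_seed
                    ms = matched_subsample_reanalysis(
                        design, config.matched_subsample_n,
                        config.matching_variables, seed=ms_seed,
                        K=config.K, n_splits=config.n_splits,
                        n_lambdas=config.n_lambdas,
                        lambda_min_ratio=config.lambda_min_ratio,
                    )
                    record(write_table(ms.balance, out / f"matched_balance_{akey}.tsv", index=False))
                    manifest["analyses"][akey]["matched_subsample"] = {
                        "n": int(config.matched_subsample_n),
                        "n_stable": len(ms.stable),
                        "stable_features": ms.stable,
                        "mean_auc": ms.auc.mean_auc,
                    }
                except Exception as e:
                    raise PipelineError(stage, config, e) from e

    record(config.to_yaml(out / "config.yaml"))
    write_json(manifest, out / "manifest.json")
    return manifest
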