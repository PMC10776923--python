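"""Preprocessing: normalisation, transformation, imputation, phenotypes."""

import math

import numpy as np
import pandas as pd
import pytest

from stabsel import (
    ClinicalKNNImputer,
    PhenotypeDefinition,
    ProteinMatrix,
    STANDARD_PHENOTYPES,
    assemble_design,
    dichotomise_phenotype,
    knn_impute,
    median_normalise,
    transform_and_centre,
)
from stabsel.preprocess import FULL_CLINICAL_COVARIATES

from oracles import knn_impute_oracle


def _pm(values, **kw):
    data = pd.DataFrame(np.asarray(values, dtype=float),
                        index=[f"P{i}" for i in range(len(values))])
    data.columns = [f"prot{j}" for j in range(data.shape[1])]
    return ProteinMatrix(data, **kw)


class TestMedianNormalise:
    def test_equal_medians_is_fixed_point(self):
        pm = _pm([[1, 2, 3], [3, 2, 1], [2, 1, 3]])
        out = median_normalise(pm)
        np.testing.assert_allclose(out.data.to_numpy(), pm.data.to_numpy())
        assert out.stage == "median_normalised"

    def test_doubling_one_sample_is_undone(self):
        # scaling the largest-median sample leaves the reference (median of
        # per-sample medians) unchanged, so normalisation removes the factor
        rng = np.random.default_rng(0)
        base = rng.uniform(1, 10, size=(5, 9))
        top = int(np.argmax(np.median(base, axis=1)))
        scaled = base.copy()
        scaled[top] *= 2.0
        a = median_normalise(_pm(base)).data.to_numpy()
        b = median_normalise(_pm(scaled)).data.to_numpy()
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_three_by_three_worked_example(self):
        # rows {1,2,4}, {2,4,8}, {3,6,12}: sample medians 2, 4, 6; the
        # reference is their median, 4, so scale factors are 2, 1, 2/3 and
        # every row becomes {2,4,8}
        pm = _pm([[1, 2, 4], [2, 4, 8], [3, 6, 12]])
        out = median_normalise(pm)
        np.testing.assert_allclose(out.data.median(axis=1), [4.0, 4.0, 4.0])
        np.testing.assert_allclose(out.data.to_numpy(),
                                   np.tile([2.0, 4.0, 8.0], (3, 1)))

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        pm = _pm(rng.lognormal(size=(6, 11)))
        once = median_normalise(pm)
        twice = median_normalise(once)
        np.testing.assert_allclose(once.data.to_numpy(), twice.data.to_numpy(),
                                   rtol=1e-12)

    def test_non_positive_cell_is_named(self):
        pm = _pm([[1, 2], [3, 4]])
        pm.data.iloc[1, 0] = -1.0
        with pytest.raises(ValueError, match=r"\(P1, prot0\)"):
            median_normalise(pm)


class TestTransformAndCentre:
    def test_requires_median_normalised_input(self):
        with pytest.raises(ValueError, match="median-normalised"):
            transform_and_centre(_pm([[1, 2], [3, 4]], stage="raw"))

    def test_log_then_standardise_population_convention(self):
        e = math.e
        pm = _pm([[1], [e], [e**2], [e**3]], stage="median_normalised")
        out = transform_and_centre(pm, ddof=0)
        np.testing.assert_allclose(
            out.data.iloc[:, 0], [-1.3416408, -0.4472136, 0.4472136, 1.3416408],
            atol=1e-6,
        )
        assert out.meta["transformation"]["ddof"] == 0

    def test_log_then_standardise_sample_convention(self):
        # same column under the default sample-SD (ddof=1) convention:
        # log gives {0,1,2,3}, mean 1.5, sd sqrt(5/3)
        e = math.e
        pm = _pm([[1], [e], [e**2], [e**3]], stage="median_normalised")
        out = transform_and_centre(pm)  # ddof=1 default
        sd = math.sqrt(5.0 / 3.0)
        expected = (np.array([0.0, 1, 2, 3]) - 1.5) / sd
        np.testing.assert_allclose(out.data.iloc[:, 0], expected, atol=1e-12)
        assert out.meta["transformation"]["ddof"] == 1

    def test_zero_variance_column_dropped_with_warning(self):
        pm = _pm([[1, 2], [1, 4], [1, 8]], stage="median_normalised")
        with pytest.warns(UserWarning, match="zero-variance"):
            out = transform_and_centre(pm)
        assert list(out.data.columns) == ["prot1"]
        assert out.meta["transformation"]["dropped_zero_variance"] == ["prot0"]

    def test_columns_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(2)
        pm = median_normalise(_pm(rng.lognormal(size=(30, 7))))
        out = transform_and_centre(pm)
        assert out.data.mean().abs().max() < 1e-8
        assert (out.data.std(ddof=1) - 1).abs().max() < 1e-8

    def test_pipeline_invariant_to_per_sample_scaling(self):
        rng = np.random.default_rng(3)
        base = rng.lognormal(size=(12, 6))
        scaled = base * rng.uniform(0.5, 2.0, size=(12, 1))
        a = transform_and_centre(median_normalise(_pm(base)))
        b = transform_and_centre(median_normalise(_pm(scaled)))
        np.testing.assert_allclose(a.data.to_numpy(), b.data.to_numpy(), atol=1e-10)


class TestKNNImpute:
    def _table(self, n=40, miss=None, seed=4):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame({
            "age": rng.normal(50, 10, n),
            "bmi": rng.normal(27, 4, n),
            "acq5": rng.normal(2, 1, n),
            "sex": rng.choice(["male", "female"], n),
        }, index=[f"P{i}" for i in range(n)])
        if miss:
            for row, col in miss:
                df.loc[row, col] = np.nan if col != "sex" else None
        return df

    def test_no_missing_is_identity(self):
        df = self._table()
        pd.testing.assert_frame_equal(knn_impute(df, k=5), df)

    def test_numeric_cell_matches_bruteforce_oracle(self):
        df = self._table(miss=[("P3", "age"), ("P17", "bmi")])
        out = knn_impute(df, k=5, seed=0)
        for row, col in [("P3", "age"), ("P17", "bmi")]:
            expected = knn_impute_oracle(df, row, col, 5,
                                         ["age", "bmi", "acq5"], seed=0)
            assert out.loc[row, col] == pytest.approx(expected)

    def test_categorical_vote_matches_bruteforce_oracle(self):
        df = self._table(miss=[("P8", "sex")], seed=6)
        out = knn_impute(df, k=5, seed=0)
        expected = knn_impute_oracle(df, "P8", "sex", 5,
                                     ["age", "bmi", "acq5"], seed=0)
        assert out.loc["P8", "sex"] == expected

    def test_majority_vote_on_constructed_donors(self):
        # query at the origin; 5 nearest donors have sex female 4:1
        df = pd.DataFrame({
            "age": [0.0, 0.1, -0.1, 0.2, -0.2, 0.15, 5, 6, 7],
            "bmi": [0.0, 0.1, -0.1, 0.2, -0.2, -0.15, 5, 6, 7],
            "sex": [None, "female", "female", "female", "female", "male",
                    "male", "male", "male"],
        }, index=[f"P{i}" for i in range(9)])
        out = knn_impute(df, k=5)
        assert out.loc["P0", "sex"] == "female"

    def test_observed_cells_never_altered(self):
        df = self._table(miss=[("P3", "age")])
        out = knn_impute(df, k=5)
        observed = df["age"].notna()
        pd.testing.assert_series_equal(out.loc[observed, "age"],
                                       df.loc[observed, "age"])

    def test_entirely_missing_column_rejected(self):
        df = self._table()
        df["age"] = np.nan
        with pytest.raises(ValueError, match="entirely missing"):
            knn_impute(df, k=5)

    def test_fewer_donors_than_k_warns_and_uses_all(self):
        df = self._table(n=4, miss=[("P0", "age")])
        with pytest.warns(UserWarning, match="donors"):
            out = knn_impute(df, k=5)
        assert out.loc["P0", "age"] == pytest.approx(df["age"].dropna().mean())

    def test_frozen_donors_for_new_data(self):
        base = self._table(seed=7)
        imp = ClinicalKNNImputer(k=3, columns=["age", "bmi", "acq5", "sex"]).fit(base)
        new = self._table(n=5, seed=8)
        new.loc["P2", "age"] = np.nan
        out = imp.transform(new)
        assert not out["age"].isna().any()


class TestPhenotypes:
    def test_blood_eosinophil_threshold_is_inclusive(self):
        cohort = pd.DataFrame({"blood_eos": [300.0, 299.9, np.nan]})
        status = dichotomise_phenotype(cohort, STANDARD_PHENOTYPES["blood_eosinophilic"])
        assert status.iloc[0] == 1.0
        assert status.iloc[1] == 0.0
        assert np.isnan(status.iloc[2])

    def test_sputum_neutrophil_threshold_is_inclusive(self):
        cohort = pd.DataFrame({"sputum_neu_pct": [73.6, 73.5999]})
        status = dichotomise_phenotype(cohort, STANDARD_PHENOTYPES["sputum_neutrophilic"])
        assert list(status) == [1.0, 0.0]

    def test_monotone_in_underlying_count(self):
        counts = np.sort(np.random.default_rng(5).uniform(0, 600, 50))
        cohort = pd.DataFrame({"blood_eos": counts})
        status = dichotomise_phenotype(cohort, STANDARD_PHENOTYPES["blood_eosinophilic"])
        assert (np.diff(status) >= 0).all()

    def test_negative_counts_rejected(self):
        cohort = pd.DataFrame({"blood_eos": [-5.0, 200.0]})
        with pytest.raises(ValueError, match="negative"):
            dichotomise_phenotype(cohort, STANDARD_PHENOTYPES["blood_eosinophilic"])

    def test_units_medium_pairing_enforced(self):
        with pytest.raises(ValueError, match="units"):
            PhenotypeDefinition("blood", "eosinophil", 300, "percent_of_granulocytes")
        with pytest.raises(ValueError, match="units"):
            PhenotypeDefinition("sputum", "eosinophil", 1.5, "cells_per_uL")
        with pytest.raises(ValueError, match="threshold"):
            PhenotypeDefinition("blood", "eosinophil", 0.0, "cells_per_uL")

    def test_missing_column_reported(self):
        with pytest.raises(ValueError, match="sputum_eos_pct"):
            dichotomise_phenotype(pd.DataFrame({"blood_eos": [1.0]}),
                                  STANDARD_PHENOTYPES["sputum_eosinophilic"])


class TestAssembleDesign:
    @pytest.fixture()
    def prepared(self, small_signal_cohort):
        config, sc = small_signal_cohort
        proteins = transform_and_centre(median_normalise(sc.proteins))
        return sc.cohort, proteins

    def test_age_sex_mode_forces_exactly_two(self, prepared):
        cohort, proteins = prepared
        design = assemble_design(cohort, proteins, "age_sex", cohort["status"])
        assert (design.penalty_factors == 0).sum() == 2
        assert design.forced_names == ["age", "sex"]
        assert (design.penalty_factors[2:] == 1).all()

    def test_full_clinical_mode_forces_eleven(self, prepared):
        cohort, proteins = prepared
        design = assemble_design(cohort, proteins, "full_clinical", cohort["status"])
        assert design.forced_names == FULL_CLINICAL_COVARIATES
        assert (design.penalty_factors == 0).sum() == 11

    def test_missing_outcomes_dropped_and_counted(self, prepared):
        cohort, proteins = prepared
        outcome = cohort["status"].astype(float).copy()
        outcome.iloc[:7] = np.nan
        design = assemble_design(cohort, proteins, "age_sex", outcome)
        assert design.provenance["n_dropped_missing_outcome"] == 7
        assert design.X.shape[0] == len(cohort) - 7

    def test_no_proteins_rejected(self, prepared):
        cohort, proteins = prepared
        empty = ProteinMatrix(proteins.data.iloc[:, :0], stage="standardised")
        with pytest.raises(ValueError, match="nothing to select"):
            assemble_design(cohort, empty, "age_sex", cohort["status"])

    def test_constant_outcome_rejected(self, prepared):
        cohort, proteins = prepared
        constant = pd.Series(1.0, index=cohort.index)
        with pytest.raises(ValueError, match="constant"):
            assemble_design(cohort, proteins, "age_sex", constant)

    def test_unstandardised_proteins_rejected(self, small_signal_cohort):
        config, sc = small_signal_cohort
        with pytest.raises(ValueError, match="standardised"):
            assemble_design(sc.cohort, sc.proteins, "age_sex", sc.cohort["status"])
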