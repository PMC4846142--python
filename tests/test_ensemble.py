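"""Resampled ensemble, sensitivities, ROC/AUC, top-variable selection."""

import numpy as np
import pytest

import steatnet as sn
from steatnet.ann import AnnConfig
from steatnet.cohort import Cohort, FishRecord
from steatnet.ensemble import (FULL_MODEL_VARIABLES, FeatureSpec,
                               SensitivityTable, design_matrix, pooled_roc,
                               roc_curve, run_ensemble, select_top_variables,
                               sensitivity)


def auc_oracle(scores, labels):
    """Brute-force concordant-pair (Mann-Whitney) statistic."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += (p > n) + 0.5 * (p == n)
    return total / (len(pos) * len(neg))


class TestDesignMatrix:
    def test_listwise_exclusion_over_selected_features(self, study_cohort):
        spec = FeatureSpec()
        X, y, ids, excluded = design_matrix(study_cohort, spec)
        assert len(excluded) == 1  # the single CK-less fish
        assert len(X) == 38 and not np.isnan(X).any()
        # dropping CK from the spec brings the fish back
        spec2 = FeatureSpec(variables=tuple(v for v in spec.variables if v != "CK"))
        X2, _, _, excluded2 = design_matrix(study_cohort, spec2)
        assert len(X2) == 39 and excluded2 == []

    def test_binary_target_coding(self, study_cohort):
        _, y, _, _ = design_matrix(study_cohort, FeatureSpec())
        assert set(np.unique(y)) == {0.0, 1.0}

    def test_vet_score_target_rescaled(self, study_cohort):
        _, y, _, _ = design_matrix(
            study_cohort, FeatureSpec(target="vet_score"))
        assert y.min() >= 0.0 and y.max() <= 1.0

    def test_duplicate_variable_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            FeatureSpec(variables=("TP", "TP"))


class TestRunEnsemble:
    def test_reproducible_end_to_end(self, study_cohort, study_ensemble):
        again = run_ensemble(study_cohort, base_seed=1)
        assert again.to_dict() == study_ensemble.to_dict()
        a = pooled_roc(again)
        b = pooled_roc(study_ensemble)
        assert a.auc == b.auc and np.array_equal(a.tpr, b.tpr)

    def test_train_fraction_and_class_coverage(self, study_ensemble):
        n = len(study_ensemble.y)
        for run in study_ensemble.models:
            assert len(run.train_idx) == pytest.approx(0.7 * n, abs=1.5)
            assert np.ptp(study_ensemble.y[run.train_idx]) > 0
            assert len(np.intersect1d(run.train_idx, run.test_idx)) == 0

    def test_cv_predictions_only_from_excluding_models(self, study_ensemble):
        y_true, y_pred, idx = study_ensemble.pooled_cv_predictions()
        # recompute the pooled average by hand
        n = len(study_ensemble.y)
        sums, counts = np.zeros(n), np.zeros(n)
        for run in study_ensemble.models:
            assert set(run.test_idx).isdisjoint(run.train_idx)
            sums[run.test_idx] += run.cv_pred
            counts[run.test_idx] += 1
        mask = counts > 0
        assert np.allclose(y_pred, (sums[mask] / counts[mask]))

    def test_fit_exceeds_cv_in_expectation(self, study_cohort):
        fits, cvs = [], []
        for s in range(5):
            res = run_ensemble(study_cohort, base_seed=100 + s, n_models=10)
            fits.append(res.fit_r2[0])
            cvs.append(res.cv_r2[0])
        assert np.mean(fits) > np.mean(cvs)

    def test_target_leakage_sanity(self, study_cohort):
        """Feeding the target in as a feature must drive both fit and CV
        R-squared to ~1 — a wiring check on the resampling machinery."""
        spec = FeatureSpec(variables=("TP", "vet_score"), target="vet_score")
        res = run_ensemble(study_cohort, spec, n_models=5, base_seed=0)
        assert res.fit_r2[0] > 0.9
        assert res.cv_r2[0] > 0.9

    def test_pure_noise_cv_near_zero(self):
        cvs = []
        for s in range(8):
            rng = np.random.default_rng(s)
            records = [
                FishRecord(f"f{i}", "male" if i % 2 else "female", 40.0, 1.5,
                           0.0 if i < 20 else 2.0,
                           analytes={"TP": float(rng.normal(4, 1) + 3),
                                     "K": float(rng.normal(4, 1) + 3),
                                     "Na": float(rng.normal(150, 10))})
                for i in range(40)
            ]
            cohort = Cohort(records)
            spec = FeatureSpec(variables=("TP", "K", "Na"))
            res = run_ensemble(cohort, spec, n_models=10, base_seed=s)
            cvs.append(res.cv_r2[0])
        assert abs(np.mean(cvs)) < 0.15

    def test_single_class_cohort_rejected(self):
        records = [FishRecord(f"f{i}", "male", 40.0, 1.5, 0.0,
                              analytes={"TP": 4.0 + i * 0.01})
                   for i in range(12)]
        with pytest.raises(ValueError, match="single health class"):
            run_ensemble(Cohort(records), FeatureSpec(variables=("TP",)))

    def test_unstratified_draws_keep_both_classes(self, study_cohort):
        res = run_ensemble(study_cohort, n_models=5, base_seed=0,
                           stratified=False)
        for run in res.models:
            assert np.ptp(res.y[run.train_idx]) > 0


class TestRoc:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.7, 0.4], [1, 1, 0, 0])
        assert roc.auc == 1.0

    def test_hand_counted_example(self):
        # concordant pairs: 3 of 4
        roc = roc_curve([0.9, 0.4, 0.7, 0.2], [1, 1, 0, 0])
        assert roc.auc == pytest.approx(0.75)

    def test_all_tied_scores_give_half(self):
        roc = roc_curve([0.5] * 6, [1, 1, 1, 0, 0, 0])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            roc_curve([0.1, 0.9], [1, 1])

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            roc = roc_curve(scores, labels)
            assert abs(roc.auc - auc_oracle(scores, labels)) < 1e-12

    def test_label_flip_antisymmetry(self):
        rng = np.random.default_rng(11)
        scores = rng.random(30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = roc_curve(scores, labels).auc
        b = roc_curve(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_curve_monotone_and_bounded(self, study_ensemble):
        roc = pooled_roc(study_ensemble)
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()
        assert 0.0 <= roc.auc <= 1.0

    def test_auc_se_is_per_model_dispersion(self, study_ensemble):
        import sklearn.metrics as skm
        roc = pooled_roc(study_ensemble)
        per = []
        for run in study_ensemble.models:
            yt = study_ensemble.y[run.test_idx]
            if len(yt) >= 2 and np.ptp(yt) > 0:
                f, t, _ = skm.roc_curve(yt, run.cv_pred)
                per.append(skm.auc(f, t))
        assert roc.auc_se == pytest.approx(np.std(per, ddof=1))


class TestSensitivity:
    def test_disconnected_input_zero(self, study_ensemble):
        import copy
        res = copy.deepcopy(study_ensemble)
        j = res.spec.variables.index("K")
        for run in res.models:
            run.model.w1[j, :] = 0.0
        sens = sensitivity(res)
        assert sens.mean[j] == 0.0

    def test_degenerate_feature_flagged(self, study_cohort):
        import copy
        res = copy.deepcopy(
            run_ensemble(study_cohort, n_models=3, base_seed=2))
        res.X[:, 0] = 5.0  # constant feature: zero observed range
        sens = sensitivity(res)
        assert res.spec.variables[0] in sens.degenerate
        assert np.isfinite(sens.mean).all()

    def test_positive_delta_required(self, study_ensemble):
        with pytest.raises(ValueError, match="delta"):
            sensitivity(study_ensemble, delta=0.0)

    def test_ranking_sorted_by_mean(self, study_ensemble):
        sens = sensitivity(study_ensemble)
        df = sens.to_frame()
        assert (np.diff(df["sensitivity_mean"]) <= 1e-15).all()


class TestSelectTopVariables:
    def study_like_table(self):
        # ordering mirrors the study's importance plot
        vars_ = ("AST", "CK", "GLU", "Ca", "PHOS", "TP", "ALB", "GLOB", "K",
                 "Na", "age", "total_length")
        means = {"total_length": 0.9, "TP": 0.8, "ALB": 0.7, "Ca": 0.6,
                 "Na": 0.5, "age": 0.45, "GLOB": 0.3, "PHOS": 0.25,
                 "K": 0.2, "GLU": 0.15, "AST": 0.1, "CK": 0.05}
        m = np.array([means[v] for v in vars_])
        return SensitivityTable(vars_, m, np.zeros_like(m), 0.05)

    def test_top_four_plus_length_non_lethal(self):
        spec = select_top_variables(self.study_like_table(), k=4)
        assert set(spec.variables) == {"Ca", "Na", "TP", "ALB", "total_length"}
        assert "age" not in spec.variables

    def test_age_restored_when_lethal_allowed(self):
        spec = select_top_variables(self.study_like_table(), k=4,
                                    non_lethal=False)
        assert "age" in spec.variables

    def test_k_equals_all_candidates_is_identity(self):
        table = self.study_like_table()
        chem = [v for v in table.variables if v in sn.ANALYTE_CODES]
        spec = select_top_variables(table, k=len(chem))
        assert set(spec.variables) == set(chem) | {"total_length"}

    def test_boundary_tie_warns_and_breaks_lexicographically(self):
        vars_ = ("TP", "ALB", "Na")
        m = np.array([0.5, 0.3, 0.3])
        table = SensitivityTable(vars_, m, np.zeros(3), 0.05)
        with pytest.warns(UserWarning, match="tie"):
            spec = select_top_variables(table, k=2)
        assert set(spec.variables) == {"TP", "ALB"}  # ALB < Na lexicographic

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            select_top_variables(self.study_like_table(), k=11)
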