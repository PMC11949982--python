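"""Feature assembly, SMOTE, the cross-validated experiment and ROC inference."""

import numpy as np
import pandas as pd
import pytest

from osahrv import osa_classifier as oc
from osahrv.osa_classifier import (ExperimentSpec, benjamini_hochberg,
                                   build_feature_table, compare_models,
                                   delong_test, run_experiment,
                                   smote_oversample, subject_features)
from osahrv.synthetic_cohort import CohortSpec, generate_cohort
from . import oracles


class TestFeatureTable:
    def test_shape_and_columns(self, small_feature_table):
        table = small_feature_table
        assert len(table) <= 32
        assert len(table) >= 28            # few, if any, exclusions expected
        assert len(oc.FEATURE_SETS["all"]) == 41
        for col in oc.FEATURE_SETS["all"]:
            assert col in table.columns
        assert len(oc.HRV_COLUMNS) == 34
        assert not table[oc.FEATURE_SETS["all"]].isna().any().any()

    def test_hrv_columns_are_segment_means(self, small_cohort):
        """A subject's SDNN cell equals the mean of its six per-segment
        SDNN values."""
        from osahrv.rri_preprocess import correct_rri, select_segments
        subj = small_cohort[0]
        row = subject_features(subj)
        segs = [correct_rri(s) for s in select_segments(subj.rri_hours)]
        per_seg = [oc.segment_features(s.values)["SDNN"] for s in segs]
        assert row["SDNN"] == pytest.approx(np.mean(per_seg))

    def test_gender_encoding(self, small_cohort, small_feature_table):
        genders = {s.id: s.gender for s in small_cohort}
        for _, row in small_feature_table.iterrows():
            assert row["Gender"] == (1.0 if genders[row["id"]] == "male" else 0.0)

    def test_ineligible_subject_logged_not_raised(self, small_cohort):
        """A subject whose every 15-min window is artifact-laden lands in
        the exclusion log, not in the table."""
        import copy
        bad = copy.deepcopy(small_cohort[0])
        bad.id = "bad-000"
        rng = np.random.default_rng(0)
        for hour in bad.rri_hours:
            idx = rng.choice(len(hour.values), size=int(0.06 * len(hour.values)),
                             replace=False)
            hour.values[idx] *= 1.5
        table, exclusions = build_feature_table([bad, small_cohort[1]])
        assert "bad-000" not in table["id"].tolist()
        assert exclusions.iloc[0]["id"] == "bad-000"
        assert exclusions.iloc[0]["reason"] == "poor quality"


class TestSmote:
    def test_synthetic_points_lie_on_segments(self):
        """With two mutual-neighbor minority points A and B every synthetic
        row is A + u (B - A), u in [0, 1]."""
        A, B = np.array([0.0, 0.0]), np.array([2.0, 1.0])
        X = np.vstack([A, B, np.full((6, 2), 10.0) + np.arange(6)[:, None]])
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0])
        Xo, yo, synth = smote_oversample(X, y, k=5, seed=0)
        assert np.array_equal(Xo[:8], X) and np.array_equal(yo[:8], y)
        new = Xo[synth]
        assert (yo[synth] == 1).all()
        direction = B - A
        for p in new:
            u = np.dot(p - A, direction) / np.dot(direction, direction)
            assert -1e-9 <= u <= 1 + 1e-9
            assert np.linalg.norm(p - (A + u * direction)) < 1e-9

    def test_unbalanced_clinical_class_sizes_equalized(self):
        """Class sizes 47/63/70/111 are all resampled to 111."""
        rng = np.random.default_rng(1)
        sizes = {"normal": 47, "mild": 63, "moderate": 70, "severe": 111}
        X = rng.normal(size=(sum(sizes.values()), 5))
        y = np.concatenate([np.full(n, c) for c, n in sizes.items()])
        _, yo, synth = smote_oversample(X, y, k=5, seed=2)
        counts = pd.Series(yo).value_counts()
        assert (counts == 111).all()
        assert synth.sum() == 4 * 111 - sum(sizes.values())

    def test_balanced_input_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4))
        y = np.repeat([0, 1], 10)
        Xo, yo, synth = smote_oversample(X, y, seed=0)
        assert np.array_equal(Xo, X) and np.array_equal(yo, y)
        assert not synth.any()

    def test_small_class_reduces_k_with_warning(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(13, 3))
        y = np.array([0] * 10 + [1] * 3)
        with pytest.warns(UserWarning, match="using k=2"):
            _, yo, _ = smote_oversample(X, y, k=5, seed=0)
        assert (yo == 1).sum() == 10


class TestExperiment:
    @staticmethod
    def _spec(**kw):
        kw.setdefault("bootstrap_reps", 100)
        return ExperimentSpec(**kw)

    def test_separable_features_reach_perfect_auroc(self, small_feature_table):
        table = small_feature_table.copy()
        sep = {"normal-to-mild": 0.0, "moderate-to-severe": 5.0}
        table["T90"] = table["binary"].map(sep) + np.random.default_rng(0).uniform(
            0, 1, len(table))
        rep = run_experiment(table, self._spec(feature_set="spo2", task="binary",
                                               cv_folds=4))
        assert rep.auroc["binary"] == 1.0
        assert rep.ci["binary"][1] == 1.0

    def test_seeded_determinism(self, small_feature_table):
        spec = self._spec(task="binary", cv_folds=4, seed=7)
        a = run_experiment(small_feature_table, spec)
        b = run_experiment(small_feature_table, spec)
        assert a.auroc == b.auroc and a.ci == b.ci
        assert np.array_equal(a.oof_scores, b.oof_scores)
        assert a.importances.equals(b.importances)

    def test_permuted_labels_collapse_to_chance(self, small_feature_table):
        """Null-model calibration: permuting labels across 20 seeds gives a
        mean binary AUROC indistinguishable from 0.5."""
        aurocs = []
        for s in range(20):
            table = small_feature_table.copy()
            rng = np.random.default_rng(s)
            table["binary"] = rng.permutation(table["binary"].to_numpy())
            if table["binary"].nunique() < 2:
                continue
            rep = run_experiment(table, self._spec(task="binary", cv_folds=4,
                                                   seed=s))
            aurocs.append(rep.auroc["binary"])
        assert 0.45 <= np.mean(aurocs) <= 0.55

    def test_smote_applied_to_training_folds_only(self, small_feature_table,
                                                  monkeypatch):
        """Structural no-leakage proof: every SMOTE call inside the CV sees
        exactly the training-fold rows, and each subject receives exactly
        one out-of-fold prediction computed on its raw feature row."""
        calls = []
        real = oc.smote_oversample

        def spy(X, y, k=5, seed=0):
            calls.append(len(X))
            return real(X, y, k=k, seed=seed)

        monkeypatch.setattr(oc, "smote_oversample", spy)
        n = len(small_feature_table)
        folds = 4
        rep = run_experiment(small_feature_table,
                             self._spec(task="binary", cv_folds=folds))
        cv_calls = calls[:folds]
        assert len(calls) == folds + 1          # folds + full-data importance fit
        assert sum(cv_calls) == (folds - 1) * n  # each subject in folds-1 train sets
        assert all(c < n for c in cv_calls)      # never the whole table
        assert rep.oof_scores.shape[0] == n
        assert np.all(rep.oof_scores.sum(axis=1) > 0)  # every subject scored once

    def test_importances_sum_to_100(self, small_feature_table):
        rep = run_experiment(small_feature_table,
                             self._spec(task="binary", cv_folds=4))
        assert rep.importances["pct"].sum() == pytest.approx(100.0, abs=1e-6)
        assert (rep.ci["binary"][0] <= rep.auroc["binary"] <= rep.ci["binary"][1])

    def test_informative_features_rank_top(self):
        """Importance sanity on a cohort where only the desaturation burden
        and the slow cyclic RR oscillation separate the classes.

        The white-noise SD is compensated so total RR variance is flat
        across classes and the oscillation shows up as slow-oscillation
        structure.  The oscillation produces a *family* of correlated HRV
        readouts that share impurity credit, so the checks are: T90 ranks
        in the top 3; VLFabs in the top 10; no anthropometric column (pure
        noise in this construction) reaches the top 20; and T90 ranks first
        when the forest sees only oximetry + anthropometric features."""
        from dataclasses import replace
        from osahrv.synthetic_cohort import DEFAULT_EFFECTS, SEVERITY_CLASSES
        ref = DEFAULT_EFFECTS["mild"]
        amps = {"normal": 10.0, "mild": 16.0, "moderate": 26.0, "severe": 36.0}
        rates = {"normal": 0.5, "mild": 2.0, "moderate": 15.0, "severe": 30.0}
        effects = {}
        for cls in SEVERITY_CLASSES:
            amp = amps[cls]
            effects[cls] = replace(
                ref, ahi_range=DEFAULT_EFFECTS[cls].ahi_range,
                cyclic_amp_ms=amp,
                white_sd_ms=float(np.sqrt(898.0 - 0.52 * amp**2)),
                desat_rate_per_hour=rates[cls], desat_depth_pct=12.0)
        cohort = generate_cohort(CohortSpec(n_per_class=10, seed=5,
                                            severity_effects=effects))
        table, _ = build_feature_table(cohort)
        rep_all = run_experiment(table, self._spec(task="binary", cv_folds=4))
        imp = rep_all.importances
        assert "T90" in imp.head(3)["feature"].tolist()
        assert "VLFabs" in imp.head(10)["feature"].tolist()
        assert not set(imp.head(20)["feature"]) & set(oc.ANTHRO_COLUMNS)
        rep_spo2 = run_experiment(table, self._spec(feature_set="spo2",
                                                    task="binary", cv_folds=4))
        assert rep_spo2.importances.iloc[0]["feature"] == "T90"


class TestRocInference:
    def test_auroc_equals_mann_whitney_identity(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        s = rng.normal(size=40)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, s) == pytest.approx(oracles.brute_auroc(y, s),
                                                    abs=1e-12)

    def test_delong_matches_structural_components_brute_force(self):
        """DeLong variance on a 30-subject toy score set equals the naive
        O(n^2) placement-kernel computation to 1e-10."""
        rng = np.random.default_rng(7)
        y = np.array([1] * 14 + [0] * 16)
        sa = rng.normal(size=30) + y
        sb = 0.5 * sa + rng.normal(size=30)
        delta, z, p = delong_test(y, sa, sb)

        auc_a, v10_a, v01_a = oracles.brute_delong_components(y, sa)
        auc_b, v10_b, v01_b = oracles.brute_delong_components(y, sb)
        assert delta == pytest.approx(auc_a - auc_b, abs=1e-10)
        m, n = 14, 16
        s10 = np.cov(np.vstack([v10_a, v10_b]))
        s01 = np.cov(np.vstack([v01_a, v01_b]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        assert z == pytest.approx((auc_a - auc_b) / np.sqrt(var), abs=1e-10)

    def test_identical_scores_give_p_one(self):
        y = np.array([0, 1] * 15)
        s = np.random.default_rng(8).normal(size=30)
        delta, _, p = delong_test(y, s, s)
        assert delta == 0.0 and p == 1.0

    def test_monotone_transform_leaves_auroc_and_test_unchanged(self):
        y = np.array([0, 1] * 15)
        s = np.random.default_rng(9).normal(size=30)
        delta, _, p = delong_test(y, s, np.exp(s))
        assert delta == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        p = np.array([0.001, 0.02, 0.03, 0.04, 0.2, 0.9])
        ours = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_compare_models_same_subjects(self, small_feature_table):
        spec_a = ExperimentSpec(feature_set="all", task="binary", cv_folds=4,
                                bootstrap_reps=50)
        spec_b = ExperimentSpec(feature_set="spo2", task="binary", cv_folds=4,
                                bootstrap_reps=50)
        rep_a = run_experiment(small_feature_table, spec_a)
        rep_b = run_experiment(small_feature_table, spec_b)
        delta, p = compare_models(rep_a, rep_b)
        assert 0.0 <= p <= 1.0
        assert delta == pytest.approx(
            rep_a.auroc["binary"] - rep_b.auroc["binary"], abs=1e-12)
        rep_c = run_experiment(small_feature_table.iloc[:-2], spec_a)
        with pytest.raises(ValueError):
            compare_models(rep_a, rep_c)
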