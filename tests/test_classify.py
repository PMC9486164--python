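"""Feature extraction, confusion metrics, SVM behaviour, clinical correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from dcfmri.degcen import DCMap
from dcfmri.classify import (extract_features, metrics_from_confusion,
                             svm_classify, correlate_clinical)


def make_map(values, subject_id="s"):
    values = np.asarray(values, float)
    return DCMap(values=values, mask=np.ones(values.shape, bool),
                 kind="zscored_smoothed", r_threshold=0.25, affine=np.eye(4),
                 subject_id=subject_id)


class TestMetrics:
    def test_reported_sensitivity_specificity_from_printed_counts(self):
        """168/198 patients and 185/234 controls correct -> 84.85% / 79.06%."""
        acc, sens, spec = metrics_from_confusion(tp=168, fn=30, tn=185, fp=49)
        assert round(100 * sens, 2) == 84.85
        assert round(100 * spec, 2) == 79.06

    def test_accuracy_is_ratio_of_correct_to_total(self):
        acc, _, _ = metrics_from_confusion(tp=168, fn=30, tn=185, fp=49)
        assert acc == pytest.approx(353 / 432)
        assert round(100 * acc, 2) == 81.71

    def test_perfect_classification(self):
        assert metrics_from_confusion(10, 0, 10, 0) == (1.0, 1.0, 1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(0, 0, 5, 5)

    @given(tp=st.integers(0, 500), fn=st.integers(0, 500),
           tn=st.integers(0, 500), fp=st.integers(0, 500))
    @settings(derandomize=True, deadline=None, max_examples=200)
    def test_invariants_on_random_tables(self, tp, fn, tn, fp):
        assume(tp + fn >= 1 and tn + fp >= 1)
        acc, sens, spec = metrics_from_confusion(tp, fn, tn, fp)
        assert sens == tp / (tp + fn)
        assert spec == tn / (tn + fp)
        assert acc == (tp + tn) / (tp + fn + tn + fp)
        assert 0 <= min(acc, sens, spec) and max(acc, sens, spec) <= 1
        # accuracy is a convex combination of sensitivity and specificity
        w = (tp + fn) / (tp + fn + tn + fp)
        assert acc == pytest.approx(w * sens + (1 - w) * spec)

    def test_label_swap_exchanges_sensitivity_and_specificity(self, rng):
        tp, fn, tn, fp = rng.integers(1, 50, size=4)
        _, sens, spec = metrics_from_confusion(tp, fn, tn, fp)
        _, sens2, spec2 = metrics_from_confusion(tn, fp, tp, fn)
        assert sens2 == spec and spec2 == sens


class TestFeatures:
    def test_singleton_mask_picks_voxel_value(self):
        m = make_map(np.arange(8.0).reshape(2, 2, 2))
        roi = np.zeros((2, 2, 2), bool)
        roi[1, 0, 1] = True
        feats = extract_features([m], {"point": roi})
        assert feats.loc["s", "point"] == 5.0

    def test_constant_map_gives_constant_feature(self):
        m = make_map(np.full((3, 3, 3), 2.5))
        roi = np.zeros((3, 3, 3), bool)
        roi[0:2, 1, 1] = True
        feats = extract_features([m], {"roi": roi})
        assert feats.loc["s", "roi"] == 2.5

    def test_empty_mask_names_roi(self):
        m = make_map(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="bad_roi"):
            extract_features([m], {"bad_roi": np.zeros((2, 2, 2), bool)})


class TestSVM:
    def _clouds(self, rng, n=20, sep=6.0):
        X = pd.DataFrame(np.vstack([rng.standard_normal((n, 2)),
                                    rng.standard_normal((n, 2)) + sep / np.sqrt(2)]),
                         columns=["a", "b"])
        y = np.array(["patient"] * n + ["control"] * n)
        return X, y

    def test_separated_clouds_high_accuracy(self, rng):
        X, y = self._clouds(rng)
        rep = svm_classify(X, y, cv_scheme="stratified-5fold",
                           C_grid=(1.0, 16.0), gamma_grid=(0.125, 0.5), seed=1)
        assert rep.accuracy >= 0.95
        assert rep.n_subjects == 40

    def test_deterministic_given_seed(self, rng):
        X, y = self._clouds(rng, sep=1.5)
        a = svm_classify(X, y, cv_scheme="stratified-5fold",
                         C_grid=(1.0,), gamma_grid=(0.25,), seed=7)
        b = svm_classify(X, y, cv_scheme="stratified-5fold",
                         C_grid=(1.0,), gamma_grid=(0.25,), seed=7)
        assert (a.tp, a.fn, a.tn, a.fp) == (b.tp, b.fn, b.tn, b.fp)

    def test_constant_features_fall_back_to_majority_class(self, caplog):
        X = pd.DataFrame(np.ones((20, 2)), columns=["a", "b"])
        y = np.array(["patient"] * 12 + ["control"] * 8)
        import logging
        with caplog.at_level(logging.WARNING, logger="dcfmri.classify"):
            rep = svm_classify(X, y, seed=0)
        assert rep.accuracy == pytest.approx(12 / 20)
        assert "majority" in caplog.text

    def test_too_few_subjects_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((6, 2)))
        y = np.array(["patient"] * 3 + ["control"] * 3)
        with pytest.raises(ValueError, match="8"):
            svm_classify(X, y)

    def test_loocv_scheme_runs(self, rng):
        X, y = self._clouds(rng, n=6)
        rep = svm_classify(X, y, cv_scheme="loocv",
                           C_grid=(1.0,), gamma_grid=(0.25,), seed=0)
        assert rep.accuracy >= 0.9
        assert "loocv" in rep.cv_scheme

    def test_paper_style_flag_changes_scheme_label_only_in_classify(self, rng):
        X, y = self._clouds(rng)
        rep = svm_classify(X, y, cv_scheme="stratified-5fold",
                           C_grid=(1.0, 16.0), gamma_grid=(0.125,), seed=2,
                           paper_style=True)
        assert "paper-style" in rep.cv_scheme
        assert rep.accuracy >= 0.95


class TestClinicalCorrelation:
    def _pheno(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "id": [f"p{i}" for i in range(n)],
            "group": ["patient"] * n,
            "hrsd17": rng.integers(17, 35, n).astype(float),
            "duration_months": rng.uniform(2, 60, n),
        })

    def test_feature_equal_to_score_correlates_perfectly(self):
        pheno = self._pheno()
        feats = pd.DataFrame({"roi": pheno["hrsd17"].to_numpy(float)},
                             index=pd.Index(pheno["id"], name="id"))
        tab = correlate_clinical(feats, pheno, variables=("hrsd17",))
        row = tab.iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p_uncorrected < 1e-10

    def test_null_false_positive_rate_calibrated(self):
        """Independent feature and score: p<0.05 in ~5% of repetitions."""
        rng = np.random.default_rng(4)
        n, reps = 50, 1000
        ids = pd.Index([f"p{i}" for i in range(n)], name="id")
        hits = 0
        for _ in range(reps):
            pheno = pd.DataFrame({"id": ids, "group": ["patient"] * n,
                                  "hrsd17": rng.standard_normal(n)})
            feats = pd.DataFrame({"roi": rng.standard_normal(n)}, index=ids)
            tab = correlate_clinical(feats, pheno, variables=("hrsd17",))
            hits += tab.iloc[0].p_uncorrected < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_two_patients_rejected(self):
        pheno = self._pheno(n=2)
        feats = pd.DataFrame({"roi": [1.0, 2.0]},
                             index=pd.Index(pheno["id"], name="id"))
        with pytest.raises(ValueError, match=">= 3"):
            correlate_clinical(feats, pheno, variables=("hrsd17",))

    def test_zero_variance_rejected(self):
        pheno = self._pheno(n=10)
        feats = pd.DataFrame({"roi": np.ones(10)},
                             index=pd.Index(pheno["id"], name="id"))
        with pytest.raises(ValueError, match="variance"):
            correlate_clinical(feats, pheno, variables=("hrsd17",))
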