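"""Trait computation, naive-Bayes training/scoring, and cohort evaluation."""

import math

import numpy as np
import pandas as pd
import pytest

import smmip_msi as sm
from smmip_msi.classifier import (
    MSI_H,
    MSS,
    MSIClassifier,
    allelic_bias_p,
    deletion_frequency,
)


class TestDeletionFrequency:
    @pytest.mark.parametrize(
        "hist,ref,expected",
        [
            ({10: 85, 9: 10, 8: 5}, 10, 0.15),
            ({10: 100}, 10, 0.0),
            # insertion reads stay in the denominator but are not deletions
            ({11: 5, 10: 80, 9: 15}, 10, 0.15),
        ],
    )
    def test_examples(self, hist, ref, expected):
        assert deletion_frequency(hist, ref) == pytest.approx(expected)

    def test_empty_histogram_undefined(self):
        with pytest.raises(ValueError):
            deletion_frequency({}, 10)


class TestAllelicBias:
    def test_strong_bias_significant(self):
        # deletions exclusively on the ref allele
        p = allelic_bias_p([[40, 10], [0, 50]])
        assert p is not None and p < 0.05

    def test_homozygous_sample_absent(self):
        assert allelic_bias_p([[90, 8], [1, 1]]) is None

    def test_proportional_deletions_uninformative(self):
        assert allelic_bias_p([[10, 40], [10, 40]]) == pytest.approx(1.0)

    def test_heterozygosity_floor(self):
        # 20% minor fraction but fewer than 5 minor reads
        assert allelic_bias_p([[12, 4], [2, 2]]) is None


def _frame(rows):
    return pd.DataFrame(rows).astype(float)


def _training_frame(n_h=6, n_s=6, seed=0):
    """Well-separated synthetic summaries for two markers."""
    rng = np.random.default_rng(seed)
    rows, y = [], []
    for _ in range(n_h):
        rows.append(
            {"M1:d": rng.uniform(0.25, 0.5), "M2:d": rng.uniform(0.2, 0.4),
             "M1:p": rng.uniform(0, 0.01), "M2:p": rng.uniform(0, 0.01)}
        )
        y.append(MSI_H)
    for _ in range(n_s):
        rows.append(
            {"M1:d": rng.uniform(0.0, 0.05), "M2:d": rng.uniform(0.0, 0.05),
             "M1:p": rng.uniform(0.2, 1.0), "M2:p": rng.uniform(0.2, 1.0)}
        )
        y.append(MSS)
    return _frame(rows), y


class TestTraining:
    def test_laplace_smoothed_trait_probability(self):
        # 45 of 50 MSI-H positive, kappa=1 -> 46/52
        rng = np.random.default_rng(1)
        rows, y = [], []
        for i in range(50):
            d = 0.5 if i < 45 else 0.0
            rows.append({"M1:d": d})
            y.append(MSI_H)
        for _ in range(10):
            rows.append({"M1:d": rng.uniform(0, 0.1)})
            y.append(MSS)
        clf = MSIClassifier().fit(_frame(rows), y)
        assert clf.p_d_[MSI_H]["M1"] == pytest.approx(46 / 52)

    def test_threshold_is_mss_95th_percentile(self):
        rows = [{"M1:d": 0.4}, {"M1:d": 0.5}]
        y = [MSI_H, MSI_H]
        for k in range(1, 21):
            rows.append({"M1:d": round(0.01 * k, 2)})
            y.append(MSS)
        clf = MSIClassifier().fit(_frame(rows), y)
        assert clf.thresholds_["M1"] == pytest.approx(0.1905)

    def test_relabeling_swaps_probability_tables(self):
        # identical d-value multisets in both classes keep the learned
        # thresholds invariant under relabeling, isolating the estimator's
        # class symmetry (the B trait carries the class signal here)
        rng = np.random.default_rng(8)
        d_vals = rng.uniform(0, 0.3, size=8)
        rows, y = [], []
        for cls in (MSI_H, MSS):
            for d in d_vals:
                rows.append(
                    {"M1:d": d,
                     "M1:p": rng.uniform(0, 0.04) if cls == MSI_H else rng.uniform(0.1, 1)}
                )
                y.append(cls)
        swap = {MSI_H: MSS, MSS: MSI_H}
        a = MSIClassifier().fit(_frame(rows), y)
        b = MSIClassifier().fit(_frame(rows), [swap[l] for l in y])
        assert a.thresholds_ == b.thresholds_
        assert a.p_d_[MSI_H] == b.p_d_[MSS] and a.p_d_[MSS] == b.p_d_[MSI_H]
        assert a.p_b_[MSI_H] == b.p_b_[MSS] and a.p_b_[MSS] == b.p_b_[MSI_H]

    def test_single_class_rejected(self):
        X, _ = _training_frame()
        with pytest.raises(ValueError):
            MSIClassifier().fit(X, [MSI_H] * len(X))

    def test_missing_mss_deletion_frequency_rejected(self):
        X, y = _training_frame()
        X.loc[X.index[-1], "M1:d"] = np.nan
        with pytest.raises(ValueError, match="MSS"):
            MSIClassifier().fit(X, y)

    def test_unobserved_bias_trait_flagged_uninformative(self):
        X, y = _training_frame()
        X["M2:p"] = np.nan
        clf = MSIClassifier().fit(X, y)
        assert clf.uninformative_b_markers_ == ["M2"]
        assert clf.p_b_[MSI_H]["M2"] == clf.p_b_[MSS]["M2"] == 0.5


class TestDichotomize:
    @pytest.fixture()
    def clf(self):
        X, y = _training_frame()
        clf = MSIClassifier().fit(X, y)
        clf.thresholds_["M1"] = 0.10
        return clf

    def test_deletion_trait_strict_greater(self, clf):
        row = pd.Series({"M1:d": 0.20, "M1:p": np.nan, "M2:d": np.nan, "M2:p": np.nan})
        assert clf.dichotomize(row)["M1"] == (1, None)
        row["M1:d"] = 0.10  # exactly the threshold: D = 0 by convention
        assert clf.dichotomize(row)["M1"][0] == 0

    def test_bias_trait_cut_at_05(self, clf):
        row = pd.Series({"M1:d": 0.0, "M1:p": 0.04, "M2:d": np.nan, "M2:p": 0.5})
        traits = clf.dichotomize(row)
        assert traits["M1"][1] == 1
        assert traits["M2"] == (None, 0)


class TestScoring:
    def _prior_only_clf(self):
        clf = MSIClassifier()
        clf.markers_ = ["M1"]
        clf.classes_ = np.array([MSI_H, MSS], dtype=object)
        clf.thresholds_ = {"M1": 0.1}
        clf.p_d_ = {MSI_H: {"M1": 0.5}, MSS: {"M1": 0.5}}
        clf.p_b_ = {MSI_H: {"M1": 0.5}, MSS: {"M1": 0.5}}
        clf.n_per_class_ = {MSI_H: 2, MSS: 2}
        clf.uninformative_b_markers_ = []
        return clf

    def test_prior_only_score(self):
        clf = self._prior_only_clf()
        X = _frame([{"M1:d": 0.05, "M1:p": np.nan}])
        score = clf.decision_function(X)[0]
        assert score == pytest.approx(math.log10(0.15 / 0.85), abs=1e-9)
        assert clf.predict(X)[0] == MSS

    def test_single_informative_marker(self):
        clf = self._prior_only_clf()
        clf.p_d_ = {MSI_H: {"M1": 0.9}, MSS: {"M1": 0.05}}
        X = _frame([{"M1:d": 0.5, "M1:p": np.nan}])
        score = clf.decision_function(X)[0]
        assert score == pytest.approx(math.log10(0.15 * 0.9 / (0.85 * 0.05)), abs=1e-9)
        assert score == pytest.approx(0.502, abs=5e-4)
        assert clf.predict(X)[0] == MSI_H

    def test_marker_order_irrelevant(self):
        X, y = _training_frame()
        clf = MSIClassifier().fit(X, y)
        rev = X[list(reversed(X.columns))]
        assert np.allclose(clf.decision_function(X), clf.decision_function(rev))

    def test_all_traits_missing_unscorable(self):
        X, y = _training_frame()
        clf = MSIClassifier().fit(X, y)
        bad = _frame([{"M1:d": np.nan, "M1:p": np.nan, "M2:d": np.nan, "M2:p": np.nan}])
        with pytest.raises(ValueError, match="unscorable"):
            clf.decision_function(bad)

    def test_score_restricted_to_marker_intersection_warns(self):
        X, y = _training_frame()
        clf = MSIClassifier().fit(X, y)
        X1 = X[["M1:d", "M1:p"]]
        with pytest.warns(UserWarning, match="restricted"):
            scores = clf.decision_function(X1)
        assert len(scores) == len(X)

    def test_prior_sensitivity_constant_shift(self):
        X, y = _training_frame()
        a = MSIClassifier(prior_mss=0.85).fit(X, y)
        b = MSIClassifier(prior_mss=0.5).fit(X, y)
        shift = a.decision_function(X) - b.decision_function(X)
        assert np.allclose(shift, math.log10(0.15 / 0.85))

    def test_deletion_monotonicity_across_threshold(self):
        # raising d_m across its threshold never lowers the score when the
        # deletion trait favors MSI-H
        X, y = _training_frame()
        clf = MSIClassifier().fit(X, y)
        assert clf.p_d_[MSI_H]["M1"] > clf.p_d_[MSS]["M1"]
        lo = X.iloc[[0]].copy()
        hi = lo.copy()
        lo["M1:d"] = clf.thresholds_["M1"] - 0.01
        hi["M1:d"] = clf.thresholds_["M1"] + 0.01
        assert clf.decision_function(hi)[0] >= clf.decision_function(lo)[0]


class TestCohort:
    def test_reclassification_of_training_cohort_is_perfect(self, trained_cohort):
        res = sm.classify_samples(
            trained_cohort["clf"], trained_cohort["summaries"]
        )
        ev = sm.evaluate(res, trained_cohort["truth"].labels)
        assert ev["sensitivity"] == 1.0 and ev["specificity"] == 1.0

    def test_parameter_recovery_at_large_n(self):
        # trained P(D=1|class) approaches the generator's trait probabilities
        # as the training cohort grows; summaries drawn directly from the
        # trait-level model for speed
        rng = np.random.default_rng(42)
        true_p = {"M1": (0.9, 0.01), "M2": (0.7, 0.02)}
        n = 300
        rows, y = [], []
        for cls, idx in ((MSI_H, 0), (MSS, 1)):
            for _ in range(n):
                row = {}
                for m, probs in true_p.items():
                    positive = rng.random() < probs[idx]
                    row[f"{m}:d"] = 0.5 if positive else 0.0
                    row[f"{m}:p"] = np.nan
                rows.append(row)
                y.append(cls)
        clf = MSIClassifier().fit(_frame(rows), y)
        for m, (ph, ps) in true_p.items():
            # MSS positives are rare enough that the learned threshold sits
            # below the positive d value, so D=1 coincides with the latent
            # trait and the smoothed estimates approach the truth
            assert clf.thresholds_[m] < 0.5
            assert clf.p_d_[MSI_H][m] == pytest.approx(ph, abs=0.05)
            assert clf.p_d_[MSS][m] == pytest.approx(ps, abs=0.05)

    def test_evaluate_reports_exact_cis(self):
        from smmip_msi.classifier import ClassificationResult

        results = [
            ClassificationResult(f"h{i}", 1.0, MSI_H, {}, 6) for i in range(51)
        ] + [ClassificationResult(f"s{i}", -1.0, MSS, {}, 6) for i in range(47)]
        labels = {r.sample_id: r.call for r in results}
        ev = sm.evaluate(results, labels)
        assert ev["sensitivity"] == 1.0 and ev["specificity"] == 1.0
        assert round(ev["sensitivity_ci"][0], 3) == 0.930
        assert round(ev["specificity_ci"][0], 3) == 0.925

    def test_evaluate_mixed_accuracy(self):
        from smmip_msi.classifier import ClassificationResult

        results = [
            ClassificationResult(f"h{i}", 1.0 if i else -1.0, MSI_H if i else MSS, {}, 6)
            for i in range(10)
        ]
        labels = {r.sample_id: MSI_H for r in results}
        with pytest.warns(UserWarning, match="specificity undefined"):
            ev = sm.evaluate(results, labels)
        assert ev["sensitivity"] == pytest.approx(0.9)
        assert ev["specificity"] is None
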