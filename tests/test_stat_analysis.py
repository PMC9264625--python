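import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_hyp
from scipy.stats import mannwhitneyu

import facesym as fs
from facesym.mesh_core import RaterPanel


def _panel(ratings):
    r = np.asarray(ratings)
    return RaterPanel(subjects=[f"s{i}" for i in range(r.shape[0])],
                      raters=[f"r{j}" for j in range(r.shape[1])],
                      ratings=r)


class TestConsensus:
    def test_unanimous(self):
        res = fs.consensus_labels(_panel([[1] * 10]))
        assert res.labels["s0"] == "symmetric"
        assert res.agreement["s0"] == 1.0

    def test_seven_of_ten_retained(self):
        """7/10 agreement meets the 70% bound and is retained."""
        res = fs.consensus_labels(_panel([[1] * 7 + [0] * 3]))
        assert res.labels["s0"] == "symmetric"
        assert "s0" in res.retained

    def test_six_of_ten_excluded(self):
        res = fs.consensus_labels(_panel([[1] * 6 + [0] * 4]))
        assert res.labels["s0"] == "excluded"
        assert res.retained == []

    def test_asymmetric_majority(self):
        res = fs.consensus_labels(_panel([[0] * 8 + [1] * 2]))
        assert res.retained_binary()["s0"] == 0

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError, match="shape|empty"):
            fs.consensus_labels(_panel(np.zeros((0, 10))))


def fleiss_kappa_oracle(ratings):
    """Spreadsheet-style evaluation of Fleiss' kappa for 2 categories."""
    r = np.asarray(ratings)
    n_sub, n_rat = r.shape
    counts = np.column_stack([n_rat - r.sum(axis=1), r.sum(axis=1)])
    p_i = (np.sum(counts * (counts - 1), axis=1)) / (n_rat * (n_rat - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n_sub * n_rat)
    pe = np.sum(p_j ** 2)
    return (p_bar - pe) / (1.0 - pe)


class TestFleissKappa:
    def test_perfect_agreement_mixed_categories(self):
        assert fs.fleiss_kappa(_panel([[1] * 10, [0] * 10])) == pytest.approx(1.0)

    def test_even_split_is_negative(self):
        """Each subject split 5/5: observed agreement below chance."""
        panel = _panel([[1] * 5 + [0] * 5] * 4)
        kappa = fs.fleiss_kappa(panel)
        assert kappa < 0
        assert kappa == pytest.approx(fleiss_kappa_oracle(panel.ratings), abs=1e-12)

    def test_matches_hand_oracle_on_fixture(self):
        """Hand-built 10-subject panel: agreement with the direct formula to
        1e-12."""
        rng = np.random.default_rng(123)
        ratings = (rng.random((10, 10)) < 0.7).astype(int)
        panel = _panel(ratings)
        assert fs.fleiss_kappa(panel) == pytest.approx(
            fleiss_kappa_oracle(ratings), abs=1e-12)

    def test_single_category_warns_one(self):
        with pytest.warns(UserWarning, match="single category"):
            assert fs.fleiss_kappa(_panel([[1, 1], [1, 1]])) == 1.0

    def test_single_rater_rejected(self):
        with pytest.raises(ValueError, match="2 raters"):
            fs.fleiss_kappa(_panel([[1], [0]]))


class TestTTests:
    def test_identical_groups(self):
        res = fs.independent_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_whole_face_groups_significant(self, variant):
        """Symmetric vs asymmetric whole-face summaries (n=222/45) separate
        at p < 0.001."""
        res = fs.t_test_from_summary(81.23, 10.66, 222, 66.91, 13.17, 45,
                                     variant=variant)
        assert res.p < 0.001

    @pytest.mark.parametrize("variant", ["pooled", "welch"])
    def test_central_forehead_not_significant(self, variant):
        res = fs.t_test_from_summary(95.32, 6.67, 222, 93.74, 8.51, 45,
                                     variant=variant)
        assert res.p > 0.05

    def test_swap_negates_t_preserves_p(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(0, 1, 30), rng.normal(0.5, 1.2, 25)
        a = fs.independent_t_test(x, y)
        b = fs.independent_t_test(y, x)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_raw_data_matches_summary_entry_point(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(80, 10, 40), rng.normal(70, 12, 20)
        raw = fs.independent_t_test(x, y)
        summ = fs.t_test_from_summary(x.mean(), x.std(ddof=1), len(x),
                                      y.mean(), y.std(ddof=1), len(y))
        assert raw.t == pytest.approx(summ.t)
        assert raw.p == pytest.approx(summ.p)


def auc_pair_counting_oracle(scores, labels):
    """Concordant/discordant pair counting with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        res = fs.roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc == 1.0
        assert res.sensitivity_at_cutoff == 1.0
        assert res.specificity_at_cutoff == 1.0
        assert 3 < res.cutoff <= 10

    def test_hand_fixture_pair_counting(self):
        """Six-point fixture: AUC equals the pair-counting oracle exactly."""
        scores = [1, 2, 3, 4, 5, 6]
        labels = [0, 0, 1, 0, 1, 1]
        res = fs.roc_analysis(scores, labels)
        assert res.auc == pytest.approx(
            auc_pair_counting_oracle(scores, labels), abs=1e-12)
        assert res.auc == pytest.approx(8 / 9)

    def test_random_labels_auc_near_half(self):
        rng = np.random.default_rng(2024)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        res = fs.roc_analysis(scores, labels)
        assert abs(res.auc - 0.5) < 0.03

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st_hyp.integers(min_value=0, max_value=10_000))
    def test_auc_equals_normalized_mannwhitney(self, seed):
        """AUC identically equals U / (n_pos * n_neg), ties half-credited."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        scores = rng.integers(0, 8, size=n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=n)
        if labels.sum() in (0, n):
            labels[0] = 1 - labels[0]
        res = fs.roc_analysis(scores, labels)
        u = mannwhitneyu(scores[labels == 1], scores[labels == 0],
                         alternative="two-sided").statistic
        n1, n0 = int(labels.sum()), int(n - labels.sum())
        assert res.auc == pytest.approx(u / (n1 * n0), abs=1e-12)

    def test_threshold_arrays_monotone(self):
        rng = np.random.default_rng(3)
        res = fs.roc_analysis(rng.normal(size=100), rng.integers(0, 2, 100))
        assert (np.diff(res.sensitivity) <= 1e-12).all()
        assert (np.diff(res.specificity) >= -1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fs.roc_analysis([1, 2, 3], [1, 1, 1])


class TestPredictiveValues:
    def test_perfect_test(self):
        assert fs.predictive_values(1.0, 1.0, 10, 10) == (1.0, 1.0)

    def test_reported_operating_point(self):
        """sens 0.76 / spec 0.71 at 222 symmetric vs 45 asymmetric gives a
        positive predictive value that rounds to 0.93."""
        ppv, npv = fs.predictive_values(0.76, 0.71, 222, 45)
        assert round(ppv, 2) == 0.93

    def test_uninformative_balanced(self):
        ppv, npv = fs.predictive_values(0.5, 0.5, 100, 100)
        assert ppv == pytest.approx(0.5)
        assert npv == pytest.approx(0.5)

    def test_bayes_identity_margins(self):
        """The implied confusion table recovers the class margins."""
        sens, spec, n_pos, n_neg = 0.8, 0.65, 120, 60
        tp, fp = sens * n_pos, (1 - spec) * n_neg
        tn, fn = spec * n_neg, (1 - sens) * n_pos
        assert tp + fn == pytest.approx(n_pos)
        assert tn + fp == pytest.approx(n_neg)
        ppv, npv = fs.predictive_values(sens, spec, n_pos, n_neg)
        assert ppv == pytest.approx(tp / (tp + fp))
        assert npv == pytest.approx(tn / (tn + fn))


class TestPearson:
    def test_identity_line(self):
        x = np.arange(10.0)
        r, _ = fs.pearson_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_negative_affine(self):
        x = np.arange(10.0)
        r, _ = fs.pearson_correlation(x, -2 * x + 3)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        r, _ = fs.pearson_correlation(x, y)
        oracle = (np.mean(x * y) - x.mean() * y.mean()) / (
            x.std() * y.std())
        assert r == pytest.approx(oracle, abs=1e-12)
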