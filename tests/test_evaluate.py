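"""Ranking and classification performance measures."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, norm

from cipasim.errors import UndefinedMeasureError
from cipasim.evaluate import (
    ZERO_PROTECTION,
    draw_panel,
    evaluate_panel,
    likelihood_ratios,
    mean_classification_error,
    pairwise_correct_rate,
    roc_analysis,
    roc_auc,
)
from cipasim.synthetic import SyntheticPanelSpec, generate_score_panel
from cipasim.thresholds import ScoreDistribution, Thresholds


def _trapezoid_auc(scores, positive):
    """Oracle: trapezoidal integration of the empirical ROC curve, with
    the lower-score-is-positive direction convention."""
    scores = np.asarray(scores, float)
    positive = np.asarray(positive, bool)
    cuts = np.concatenate([[-np.inf], np.sort(np.unique(scores)), [np.inf]])
    tpr = [np.mean(scores[positive] <= c) for c in cuts]
    fpr = [np.mean(scores[~positive] <= c) for c in cuts]
    return float(np.trapezoid(tpr, fpr))


def _panel(values, labels, n=1, jitter=0.0, seed=0):
    rng = np.random.default_rng(seed)
    return [
        ScoreDistribution(
            f"d{i}",
            np.full(n, v) + (rng.normal(0, jitter, n) if jitter else 0.0),
            lab)
        for i, (v, lab) in enumerate(zip(values, labels))
    ]


class TestDrawPanel:
    def test_point_masses_and_seed_determinism(self):
        dists = _panel([0.02, 0.06, 0.10], ["high", "intermediate", "low"])
        p1 = draw_panel(dists, seed=1)
        assert np.array_equal(p1, [0.02, 0.06, 0.10])
        dists2 = generate_score_panel(SyntheticPanelSpec(seed=2))
        assert np.array_equal(draw_panel(dists2, 7), draw_panel(dists2, 7))

    def test_resamples_reproduce_source_distribution(self):
        rng = np.random.default_rng(0)
        d = ScoreDistribution("x", rng.normal(0.06, 0.01, 4000), "low")
        draws = np.array([draw_panel([d], s)[0] for s in range(5000)])
        assert ks_2samp(draws, d.scores).statistic < 0.05


class TestRocAuc:
    def test_perfect_separation_and_all_ties(self):
        assert roc_auc([0.01, 0.02, 0.9, 0.8],
                       [True, True, False, False]) == 1.0
        assert roc_auc([0.5, 0.5, 0.5, 0.5],
                       [True, True, False, False]) == 0.5

    def test_hand_counted_example(self):
        # positives {0.03, 0.07}, negatives {0.05, 0.09}: 3 of 4 pairs
        # concordant
        assert roc_auc([0.03, 0.07, 0.05, 0.09],
                       [True, True, False, False]) == 0.75

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedMeasureError):
            roc_auc([0.1, 0.2], [True, True])

    @pytest.mark.parametrize("seed", range(5))
    def test_pair_counting_equals_trapezoid_and_sklearn(self, seed):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(seed)
        for _ in range(20):
            n = rng.integers(4, 30)
            scores = np.round(rng.normal(0, 1, n), 2)  # force some ties
            positive = rng.random(n) < 0.5
            if positive.all() or not positive.any():
                continue
            ours = roc_auc(scores, positive)
            assert ours == pytest.approx(_trapezoid_auc(scores, positive),
                                         abs=1e-12)
            assert ours == pytest.approx(
                roc_auc_score(positive, -scores), abs=1e-12)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 20)
        positive = rng.random(20) < 0.5
        assert roc_auc(scores, positive) == pytest.approx(
            1.0 - roc_auc(scores, ~positive), abs=1e-12)


class TestRocAnalysis:
    def test_point_mass_perfect_separation(self):
        dists = _panel([0.02, 0.03, 0.06, 0.10, 0.11],
                       ["high", "high", "intermediate", "low", "low"])
        rec = roc_analysis(dists, "ROC1", n_iter=100, seed=0)
        assert (rec.median, rec.ci_low, rec.ci_high) == (1.0, 1.0, 1.0)

    def test_groupings_differ(self):
        panel = generate_score_panel(SyntheticPanelSpec(seed=5))
        r1 = roc_analysis(panel, "ROC1", n_iter=500, seed=1)
        r2 = roc_analysis(panel, "ROC2", n_iter=500, seed=1)
        assert 0.5 < r1.median <= 1.0 and 0.5 < r2.median <= 1.0

    def test_single_class_grouping_is_undefined(self):
        dists = _panel([0.02, 0.04], ["high", "intermediate"])
        with pytest.raises(UndefinedMeasureError):
            roc_analysis(dists, "ROC1", n_iter=10, seed=0)


class TestPairwise:
    def test_ordered_and_reversed_point_masses(self):
        labs = ["high", "intermediate", "low"]
        assert pairwise_correct_rate(
            _panel([0.02, 0.06, 0.10], labs), 50, 0).median == 1.0
        assert pairwise_correct_rate(
            _panel([0.10, 0.06, 0.02], labs), 50, 0).median == 0.0

    def test_three_drug_hand_enumeration(self):
        # pairs: (H,I): 0.05<0.04 wrong; (H,L): 0.05<0.08 right;
        # (I,L): 0.04<0.08 right -> 2/3
        dists = _panel([0.05, 0.04, 0.08], ["high", "intermediate", "low"])
        rec = pairwise_correct_rate(dists, 20, 0)
        assert rec.median == pytest.approx(2.0 / 3.0)


class TestLikelihoodRatios:
    TH = Thresholds(t1=0.05, t2=0.02)

    @staticmethod
    def _exact_panel(n_pos, n_pos_correct, n_neg, n_neg_correct):
        """Point-mass drugs realizing exact per-iteration sens/spec at
        the t1 cut (0.05): positives below the cut count as detected."""
        dists = []
        for i in range(n_pos):
            v = 0.04 if i < n_pos_correct else 0.06
            dists.append(ScoreDistribution(f"p{i}", np.full(1, v), "high"))
        for i in range(n_neg):
            v = 0.06 if i < n_neg_correct else 0.04
            dists.append(ScoreDistribution(f"n{i}", np.full(1, v), "low"))
        return dists

    def test_closed_form_sens08_spec08(self):
        # sens 0.8, spec 0.8 -> LR+ = 4.0, LR- = 0.25, exactly
        dists = self._exact_panel(10, 8, 10, 8)
        lrp, lrn = likelihood_ratios(dists, self.TH, "t1", n_iter=200, seed=0)
        assert lrp.median == pytest.approx(4.0, abs=1e-9)
        assert lrn.median == pytest.approx(0.25, abs=1e-9)

    def test_protection_magnitude_for_perfect_specificity(self):
        # sens 0.75, spec 1 -> LR+ = 0.75/1e-6 = 7.5e5 under protection
        dists = self._exact_panel(4, 3, 10, 10)
        lrp, _ = likelihood_ratios(dists, self.TH, "t1", n_iter=200, seed=1)
        assert lrp.median == pytest.approx(7.5e5, rel=1e-9)

    def test_protection_magnitude_for_perfect_sensitivity(self):
        # sens 1, spec 0.885 -> LR- = 1e-6/0.885 = 1.13e-6 under protection
        dists = self._exact_panel(5, 5, 200, 177)
        _, lrn = likelihood_ratios(dists, self.TH, "t1", n_iter=200, seed=2)
        assert lrn.median == pytest.approx(1e-6 / 0.885, rel=1e-9)

    def test_lr_informative_without_protection_when_no_zero_cells(self):
        dists = self._exact_panel(10, 9, 10, 9)
        lrp, lrn = likelihood_ratios(dists, self.TH, "t1", n_iter=200, seed=3,
                                     protection=0.0)
        assert lrp.median == pytest.approx(9.0) and lrn.median < 1.0


class TestMeanClassificationError:
    TH = Thresholds(t1=0.08, t2=0.05)

    def test_perfectly_banded_panel_has_zero_error(self):
        dists = _panel([0.03, 0.06, 0.10], ["high", "intermediate", "low"])
        assert mean_classification_error(dists, self.TH, 100, 0).median == 0.0

    def test_one_partially_misplaced_drug_arithmetic(self):
        # 15 perfect drugs plus one with exactly 75% off-category mass
        dists = _panel([0.03] * 5 + [0.06] * 5 + [0.10] * 5,
                       ["high"] * 5 + ["intermediate"] * 5 + ["low"] * 5,
                       n=400)
        off = np.concatenate([np.full(300, 0.09), np.full(100, 0.06)])
        dists.append(ScoreDistribution("stray", off, "intermediate"))
        rec = mean_classification_error(dists, self.TH, n_iter=4000, seed=4)
        # expected error = off-category mass / n_drugs = 0.75/16
        assert rec.mean == pytest.approx(0.75 / 16.0, abs=0.005)
        # per-iteration error is 0 or 1/16; the stray drug misses with
        # probability 0.75, so the median iteration errs on it
        assert rec.median == pytest.approx(1.0 / 16.0, abs=1e-9)

    def test_matches_gaussian_tail_mass_oracle(self):
        spec = SyntheticPanelSpec(
            score_means={"high": 0.045, "intermediate": 0.065, "low": 0.085},
            score_sds={"high": 0.01, "intermediate": 0.01, "low": 0.01},
            n_samples=4000, seed=6)
        panel = generate_score_panel(spec)
        th = Thresholds(t1=0.075, t2=0.055)
        expected = 0.0
        for cat, n in spec.n_drugs.items():
            mu, sd = spec.score_means[cat], spec.score_sds[cat]
            p_high = norm.cdf((th.t2 - mu) / sd)
            p_low = 1.0 - norm.cdf((th.t1 - mu) / sd)
            p_int = 1.0 - p_high - p_low
            correct = {"high": p_high, "intermediate": p_int, "low": p_low}[cat]
            expected += n * (1.0 - correct)
        expected /= sum(spec.n_drugs.values())
        rec = mean_classification_error(panel, th, n_iter=6000, seed=7)
        assert rec.mean == pytest.approx(expected, abs=0.01)


class TestReport:
    def test_evaluate_panel_is_deterministic_and_complete(self):
        panel = generate_score_panel(SyntheticPanelSpec(seed=8))
        th = Thresholds(t1=0.075, t2=0.05)
        r1 = evaluate_panel(panel, th, n_iter=300, seed=5)
        r2 = evaluate_panel(panel, th, n_iter=300, seed=5)
        assert set(r1.records) == {
            "auc_roc1", "auc_roc2", "pairwise_correct", "lr_pos_t1",
            "lr_neg_t1", "lr_pos_t2", "lr_neg_t2", "mean_class_error"}
        for m in r1.records:
            assert r1[m].median == r2[m].median
            assert r1[m].ci_low <= r1[m].median <= r1[m].ci_high

    def test_medians_stable_when_widening_iterations(self):
        panel = generate_score_panel(SyntheticPanelSpec(seed=9))
        th = Thresholds(t1=0.075, t2=0.05)
        small = evaluate_panel(panel, th, n_iter=1000, seed=6)
        big = evaluate_panel(panel, th, n_iter=10_000, seed=6)
        for m in ("auc_roc1", "auc_roc2", "pairwise_correct",
                  "mean_class_error"):
            assert big[m].median == pytest.approx(small[m].median, abs=0.02)
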