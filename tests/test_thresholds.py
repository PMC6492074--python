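"""Ordinal-regression thresholds, classification and leave-one-out CV."""

import numpy as np
import pytest
from scipy.stats import norm

from cipasim.errors import FitError
from cipasim.thresholds import (
    OrdinalThresholdClassifier,
    ScoreDistribution,
    Thresholds,
    category_fractions,
    classify_score,
    classify_scores,
    fit_ordinal_thresholds,
    loo_cross_validate,
)
from cipasim.synthetic import SyntheticPanelSpec, generate_score_panel


def _point_mass_panel(values=(0.02, 0.06, 0.10), n=200, jitter=1e-4, seed=0):
    """Three tightly concentrated groups at the given scores."""
    rng = np.random.default_rng(seed)
    cats = ("high", "intermediate", "low")
    return [
        ScoreDistribution(f"{c}_{k}", v + rng.normal(0, jitter, n), c)
        for v, c in zip(values, cats)
        for k in range(2)
    ]


class TestOrdinalFit:
    def test_separated_groups_bracket_thresholds(self):
        th = fit_ordinal_thresholds(_point_mass_panel())
        assert 0.02 < th.t2 < 0.06
        assert 0.06 < th.t1 < 0.10

    def test_missing_category_is_fit_error(self):
        panel = [d for d in _point_mass_panel() if d.risk_label != "low"]
        with pytest.raises(FitError, match="categor"):
            fit_ordinal_thresholds(panel)

    def test_scale_equivariance(self):
        panel = generate_score_panel(SyntheticPanelSpec(seed=3))
        th = fit_ordinal_thresholds(panel)
        c = 7.3
        scaled = [ScoreDistribution(d.drug, c * d.scores, d.risk_label)
                  for d in panel]
        th_c = fit_ordinal_thresholds(scaled)
        assert th_c.t1 == pytest.approx(c * th.t1, rel=1e-6)
        assert th_c.t2 == pytest.approx(c * th.t2, rel=1e-6)

    def test_thresholds_follow_labels_not_drug_identity(self):
        # swapping the label assignment on a symmetric panel moves the
        # thresholds with the labels
        rng = np.random.default_rng(1)
        lo, mid, hi = 0.02, 0.06, 0.10
        mk = lambda name, mu, lab: ScoreDistribution(
            name, rng.normal(mu, 0.004, 300), lab)
        panel_a = [mk("d1", lo, "high"), mk("d2", mid, "intermediate"),
                   mk("d3", hi, "low"), mk("d4", lo, "high"),
                   mk("d5", mid, "intermediate"), mk("d6", hi, "low")]
        th_a = fit_ordinal_thresholds(panel_a)
        # permute which drug carries which label (data identical per label)
        panel_b = [mk("d1", lo, "high"), mk("d5", mid, "intermediate"),
                   mk("d6", hi, "low"), mk("d4", lo, "high"),
                   mk("d2", mid, "intermediate"), mk("d3", hi, "low")]
        th_b = fit_ordinal_thresholds(panel_b)
        assert th_b.t1 == pytest.approx(th_a.t1, rel=0.05)
        assert th_b.t2 == pytest.approx(th_a.t2, rel=0.05)

    def test_matches_statsmodels_ordered_model_on_unweighted_data(self):
        # independent oracle: statsmodels' proportional-odds fit on the
        # same pooled (equal-size, hence unweighted) data
        from statsmodels.miscmodels.ordinal_model import OrderedModel
        import pandas as pd

        panel = generate_score_panel(SyntheticPanelSpec(
            n_drugs={"high": 2, "intermediate": 2, "low": 2},
            n_samples=400, seed=9))
        scores = np.concatenate([d.scores for d in panel])
        labels = np.concatenate([[d.risk_label] * len(d.scores)
                                 for d in panel])
        codes = pd.Categorical(labels, categories=["high", "intermediate",
                                                   "low"], ordered=True)
        sm_fit = OrderedModel(codes.codes, scores[:, None],
                              distr="logit").fit(method="bfgs", disp=False)
        beta = float(sm_fit.params[0])   # >0: lower score = higher risk
        a0 = float(sm_fit.params[1])
        a1 = a0 + np.exp(float(sm_fit.params[2]))
        th = fit_ordinal_thresholds(panel)
        assert th.t2 == pytest.approx(a0 / beta, rel=1e-3)
        assert th.t1 == pytest.approx(a1 / beta, rel=1e-3)

    def test_estimator_api(self):
        est = OrdinalThresholdClassifier()
        assert est.get_params()["tol"] == 1e-8
        panel = _point_mass_panel()
        X = np.concatenate([d.scores for d in panel])
        y = np.concatenate([[d.risk_label] * len(d.scores) for d in panel])
        est.fit(X, y)
        assert est.t2_ < est.t1_
        preds = est.predict([0.01, 0.08, 0.2])
        assert list(preds) == ["high", "intermediate", "low"]


class TestClassification:
    TH = Thresholds(t1=0.0689, t2=0.0579)

    @pytest.mark.parametrize("score,expected", [
        (0.050, "high"),
        (0.065, "intermediate"),
        (0.075, "low"),
        (0.0689, "intermediate"),  # boundary tie -> intermediate
        (0.0579, "intermediate"),
    ])
    def test_classify_against_frozen_thresholds(self, score, expected):
        assert classify_score(score, self.TH) == expected

    def test_vectorized_matches_scalar(self):
        s = np.linspace(0.02, 0.12, 101)
        vec = classify_scores(s, self.TH)
        assert all(vec[i] == classify_score(s[i], self.TH)
                   for i in range(len(s)))

    def test_fractions_partition_and_edge_cases(self):
        th = Thresholds(t1=0.08, t2=0.05)
        below = ScoreDistribution("x", np.full(100, 0.01), "high")
        assert category_fractions(below, th) == (1.0, 0.0, 0.0)
        inside = ScoreDistribution("y", np.linspace(0.051, 0.079, 100))
        assert category_fractions(inside, th) == (0.0, 1.0, 0.0)

    def test_fractions_match_analytic_gaussian_mass(self):
        th = Thresholds(t1=0.08, t2=0.05)
        mu, sd, n = 0.06, 0.01, 2000
        rng = np.random.default_rng(8)
        d = ScoreDistribution("g", rng.normal(mu, sd, n))
        fh, fi, fl = category_fractions(d, th)
        p_high = norm.cdf((th.t2 - mu) / sd)
        p_low = 1 - norm.cdf((th.t1 - mu) / sd)
        # binomial sampling error at n=2000 is ~3 sd(p)/sqrt(n) < 0.03
        assert fh == pytest.approx(p_high, abs=0.03)
        assert fl == pytest.approx(p_low, abs=0.03)
        assert fh + fi + fl == 1.0


class TestLeaveOneOut:
    def test_perfectly_separated_panel_has_zero_error(self):
        panel = _point_mass_panel()
        report = loo_cross_validate(panel, n_iter=200, seed=0)
        assert report["mean_class_error"].median == 0.0
        assert report["auc_roc1"].median == 1.0

    def test_misplaced_drug_contributes_full_mass_at_frozen_thresholds(self):
        # with thresholds frozen, a drug whose entire distribution sits in
        # the wrong category adds exactly 1/n_drugs to the error
        from cipasim.evaluate import mean_classification_error

        panel = _point_mass_panel()
        th = fit_ordinal_thresholds(panel)
        bad = ScoreDistribution("bad_low", np.full(200, 0.021), "low")
        rec = mean_classification_error(panel + [bad], th, n_iter=200, seed=0)
        assert rec.median == pytest.approx(1.0 / 7.0, abs=1e-9)

    def test_matches_brute_force_recomputation(self):
        # 28-drug overlapping panel; oracle re-implements the per-fold
        # resampled classification error with plain loops
        panel = generate_score_panel(SyntheticPanelSpec(
            n_drugs={"high": 10, "intermediate": 9, "low": 9},
            score_means={"high": 0.045, "intermediate": 0.060, "low": 0.075},
            score_sds={"high": 0.008, "intermediate": 0.008, "low": 0.008},
            n_samples=300, seed=4))
        n_iter = 2000
        report = loo_cross_validate(panel, n_iter=n_iter, seed=11)
        per_drug_th = {
            d.drug: fit_ordinal_thresholds(panel[:i] + panel[i + 1:])
            for i, d in enumerate(panel)
        }
        rng = np.random.default_rng(123)
        errs = []
        for _ in range(n_iter):
            wrong = 0
            for d in panel:
                s = d.scores[rng.integers(len(d.scores))]
                wrong += classify_score(s, per_drug_th[d.drug]) != d.risk_label
            errs.append(wrong / len(panel))
        assert report["mean_class_error"].median == pytest.approx(
            np.median(errs), abs=0.02)

    def test_small_panel_rejected(self):
        with pytest.raises(FitError):
            loo_cross_validate(_point_mass_panel()[:2], n_iter=10, seed=0)
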