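"""Prespecified ranking and classification performance measures.

Every measure is evaluated on panels drawn by independent sampling (with
replacement, one score per drug per iteration, default 10,000 iterations)
from the per-drug torsade-metric-score distributions, and summarized as
median with 2.5/97.5-percentile confidence interval:

* ROC1 AUC — probability of ranking a high-or-intermediate-risk drug
  above (score lower than) a low-risk drug; ROC2 AUC — high vs the rest.
* Pairwise comparison correct rate — concordance across all three
  categories without combining.
* LR+/LR- at both thresholds — sensitivity/(1-specificity) and
  (1-sensitivity)/specificity of threshold classification, with zero
  probabilities protected at 1e-6 before forming the ratios.
* Mean classification error — mean over drugs of the 0/1
  misclassification of the drawn score against the true category.

The direction convention is fixed globally: lower torsade metric score =
higher predicted risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import UndefinedMeasureError
from .thresholds import ScoreDistribution, Thresholds, classify_scores

__all__ = [
    "MEASURE_IDS",
    "ZERO_PROTECTION",
    "MeasureRecord",
    "PerformanceReport",
    "draw_panel",
    "roc_auc",
    "roc_analysis",
    "pairwise_correct_rate",
    "likelihood_ratios",
    "mean_classification_error",
    "evaluate_panel",
]

MEASURE_IDS = (
    "auc_roc1", "auc_roc2", "pairwise_correct",
    "lr_pos_t1", "lr_neg_t1", "lr_pos_t2", "lr_neg_t2",
    "mean_class_error",
)

#: Substituted for any zero probability before forming likelihood ratios;
#: reproduces finite magnitudes (e.g. 0.75/1e-6 = 7.5e5) where the raw
#: ratio would be infinite or zero.
ZERO_PROTECTION = 1e-6


@dataclass
class MeasureRecord:
    measure_id: str
    median: float
    ci_low: float
    ci_high: float
    n_resamples: int
    mean: float = float("nan")  # expectation across resamples

    def __post_init__(self):
        if not (self.ci_low <= self.median <= self.ci_high):
            raise UndefinedMeasureError(
                f"{self.measure_id}: inconsistent summary "
                f"({self.ci_low}, {self.median}, {self.ci_high})"
            )


@dataclass
class PerformanceReport:
    """Median + 95% CI of every prespecified measure."""

    records: dict[str, MeasureRecord] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __getitem__(self, measure_id: str) -> MeasureRecord:
        return self.records[measure_id]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"measure_id": r.measure_id, "median": r.median,
              "ci_low": r.ci_low, "ci_high": r.ci_high,
              "n_resamples": r.n_resamples}
             for r in self.records.values()]
        )

    def to_dict(self) -> dict:
        return {
            "measures": {
                m: {"median": r.median, "ci_low": r.ci_low,
                    "ci_high": r.ci_high, "n_resamples": r.n_resamples}
                for m, r in self.records.items()
            },
            "meta": {k: v for k, v in self.meta.items()},
        }


def _summarize(measure_id: str, values: np.ndarray) -> MeasureRecord:
    return MeasureRecord(
        measure_id=measure_id,
        median=float(np.median(values)),
        ci_low=float(np.percentile(values, 2.5)),
        ci_high=float(np.percentile(values, 97.5)),
        n_resamples=len(values),
        mean=float(np.mean(values)),
    )


def draw_panel(dists: list[ScoreDistribution], seed) -> np.ndarray:
    """One uniformly-resampled score per drug (seeded, reproducible)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return np.array([d.scores[rng.integers(len(d.scores))] for d in dists])


def _sample_matrix(dists, n_iter, rng) -> np.ndarray:
    """(n_iter, n_drugs) matrix of independent with-replacement draws."""
    cols = [d.scores[rng.integers(len(d.scores), size=n_iter)] for d in dists]
    return np.column_stack(cols)


def roc_auc(scores, positive) -> float:
    """AUC by pair counting (Mann-Whitney form), ties 0.5.

    Equals the probability that a positive (riskier) drug's score is
    LOWER than a negative drug's score.
    """
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos, neg = scores[positive], scores[~positive]
    if len(pos) == 0 or len(neg) == 0:
        raise UndefinedMeasureError("ROC needs both a positive and a negative class")
    diff = pos[:, None] - neg[None, :]
    return float(np.mean((diff < 0) + 0.5 * (diff == 0)))


def _auc_rows(samples, pos_cols, neg_cols):
    p = samples[:, pos_cols][:, :, None]
    q = samples[:, neg_cols][:, None, :]
    return np.mean((p < q) + 0.5 * (p == q), axis=(1, 2))


def _labels(dists):
    labels = [d.risk_label for d in dists]
    if any(lab is None for lab in labels):
        raise UndefinedMeasureError("every drug needs a risk label")
    return np.array(labels)


def roc_analysis(
    dists: list[ScoreDistribution],
    grouping: str = "ROC1",
    n_iter: int = 10_000,
    seed: int = 0,
) -> MeasureRecord:
    """Distribution of the ROC AUC across resampled panels.

    ``grouping="ROC1"``: positives = high or intermediate vs low;
    ``"ROC2"``: positives = high vs intermediate-or-low.
    """
    labels = _labels(dists)
    if grouping.upper() == "ROC1":
        positive = np.isin(labels, ("high", "intermediate"))
    elif grouping.upper() == "ROC2":
        positive = labels == "high"
    else:
        raise UndefinedMeasureError(f"unknown ROC grouping {grouping!r}")
    if positive.all() or not positive.any():
        raise UndefinedMeasureError(f"{grouping} grouping yields a single class")
    rng = np.random.default_rng(seed)
    samples = _sample_matrix(dists, n_iter, rng)
    aucs = _auc_rows(samples, np.flatnonzero(positive), np.flatnonzero(~positive))
    return _summarize(f"auc_{grouping.lower()}", aucs)


def pairwise_correct_rate(
    dists: list[ScoreDistribution],
    n_iter: int = 10_000,
    seed: int = 0,
) -> MeasureRecord:
    """Fraction of cross-category drug pairs ranked concordantly with risk
    order (higher risk => lower score), ties 0.5, across resampled panels."""
    labels = _labels(dists)
    order = {"high": 0, "intermediate": 1, "low": 2}
    ranks = np.array([order[lab] for lab in labels])
    riskier, safer = [], []
    n = len(dists)
    for i in range(n):
        for j in range(n):
            if ranks[i] < ranks[j]:
                riskier.append(i)
                safer.append(j)
    if not riskier:
        raise UndefinedMeasureError("no cross-category pairs in panel")
    rng = np.random.default_rng(seed)
    samples = _sample_matrix(dists, n_iter, rng)
    a = samples[:, riskier]
    b = samples[:, safer]
    rate = np.mean((a < b) + 0.5 * (a == b), axis=1)
    return _summarize("pairwise_correct", rate)


def _threshold_arrays(dists, th: Thresholds | Mapping[str, Thresholds]):
    if isinstance(th, Thresholds):
        t1 = np.full(len(dists), th.t1)
        t2 = np.full(len(dists), th.t2)
    else:
        t1 = np.array([th[d.drug].t1 for d in dists])
        t2 = np.array([th[d.drug].t2 for d in dists])
    return t1, t2


def likelihood_ratios(
    dists: list[ScoreDistribution],
    th: Thresholds | Mapping[str, Thresholds],
    which: str = "t1",
    n_iter: int = 10_000,
    seed: int = 0,
    protection: float = ZERO_PROTECTION,
):
    """LR+ and LR- of threshold classification across resampled panels.

    ``which="t1"``: positives = high-or-intermediate risk, test positive =
    score <= t1. ``which="t2"``: positives = high risk, test positive =
    score < t2 (boundary ties classify intermediate). ``th`` may be one
    frozen Thresholds or a per-drug mapping (leave-one-out evaluation).

    Returns ``(lr_pos_record, lr_neg_record)``.
    """
    labels = _labels(dists)
    t1, t2 = _threshold_arrays(dists, th)
    if which == "t1":
        truth = np.isin(labels, ("high", "intermediate"))
        cut, below_incl = t1, True
    elif which == "t2":
        truth = labels == "high"
        cut, below_incl = t2, False
    else:
        raise UndefinedMeasureError(f"unknown threshold selector {which!r}")
    if truth.all() or not truth.any():
        raise UndefinedMeasureError(f"{which} grouping yields a single class")
    rng = np.random.default_rng(seed)
    samples = _sample_matrix(dists, n_iter, rng)
    test_pos = samples <= cut if below_incl else samples < cut
    sens = np.mean(test_pos[:, truth], axis=1)
    spec = np.mean(~test_pos[:, ~truth], axis=1)
    sens_p = np.maximum(sens, protection)
    spec_p = np.maximum(spec, protection)
    fpr_p = np.maximum(1.0 - spec, protection)
    fnr_p = np.maximum(1.0 - sens, protection)
    lr_pos = sens_p / fpr_p
    lr_neg = fnr_p / spec_p
    return (_summarize(f"lr_pos_{which}", lr_pos),
            _summarize(f"lr_neg_{which}", lr_neg))


def mean_classification_error(
    dists: list[ScoreDistribution],
    th: Thresholds | Mapping[str, Thresholds],
    n_iter: int = 10_000,
    seed: int = 0,
) -> MeasureRecord:
    """Mean over drugs of the 0/1 misclassification of the drawn score
    against the true category, across resampled panels. Equivalently (in
    expectation) the mean off-category probability mass per drug."""
    labels = _labels(dists)
    t1, t2 = _threshold_arrays(dists, th)
    rng = np.random.default_rng(seed)
    samples = _sample_matrix(dists, n_iter, rng)
    pred_high = samples < t2
    pred_low = samples > t1
    pred_int = ~pred_high & ~pred_low
    truth = np.array([{"high": 0, "intermediate": 1, "low": 2}[lab]
                      for lab in labels])
    correct = np.where(truth == 0, pred_high,
                       np.where(truth == 1, pred_int, pred_low))
    err = 1.0 - np.mean(correct, axis=1)
    return _summarize("mean_class_error", err)


def evaluate_panel(
    dists: list[ScoreDistribution],
    th: Thresholds | Mapping[str, Thresholds],
    n_iter: int = 10_000,
    seed: int = 0,
) -> PerformanceReport:
    """All eight prespecified measures for one panel and one set of
    (frozen or per-drug) thresholds."""
    seeds = np.random.SeedSequence(seed).generate_state(6)
    report = PerformanceReport(meta={"n_iter": n_iter, "seed": seed})
    report.records["auc_roc1"] = roc_analysis(dists, "ROC1", n_iter, seeds[0])
    report.records["auc_roc2"] = roc_analysis(dists, "ROC2", n_iter, seeds[1])
    report.records["pairwise_correct"] = pairwise_correct_rate(
        dists, n_iter, seeds[2])
    lrp1, lrn1 = likelihood_ratios(dists, th, "t1", n_iter, seeds[3])
    lrp2, lrn2 = likelihood_ratios(dists, th, "t2", n_iter, seeds[4])
    report.records["lr_pos_t1"] = lrp1
    report.records["lr_neg_t1"] = lrn1
    report.records["lr_pos_t2"] = lrp2
    report.records["lr_neg_t2"] = lrn2
    report.records["mean_class_error"] = mean_classification_error(
        dists, th, n_iter, seeds[5])
    return report
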