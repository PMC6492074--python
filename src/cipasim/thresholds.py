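"""Ordinal-regression risk thresholds on the torsade metric score axis.

A proportional-odds cumulative-logit model with the score as single
covariate is fit to the pooled per-drug score distributions (each drug's
samples weighted 1/n so drugs contribute equally). With categories
ordered high < intermediate < low along the score axis,

    P(category <= k | s) = sigmoid(alpha_k - beta * s),   beta > 0,

and the two classification thresholds are the scores where adjacent
cumulative probabilities equal 0.5: t2 = alpha_0/beta (high vs the rest)
and t1 = alpha_1/beta (low vs the rest), with t2 < t1 because lower
score = higher risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import ConfigurationError, FitError
from .pharm import RISK_CATEGORIES

__all__ = [
    "ScoreDistribution",
    "Thresholds",
    "OrdinalThresholdClassifier",
    "fit_ordinal_thresholds",
    "classify_score",
    "classify_scores",
    "category_fractions",
    "loo_cross_validate",
]

log = logging.getLogger(__name__)

_CAT_INDEX = {c: i for i, c in enumerate(RISK_CATEGORIES)}


@dataclass
class ScoreDistribution:
    """Bootstrap torsade metric scores of one drug (default 2000 values)."""

    drug: str
    scores: np.ndarray
    risk_label: str | None = None

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size == 0:
            raise ConfigurationError(f"{self.drug}: empty score distribution")
        if not np.all(np.isfinite(self.scores)):
            raise ConfigurationError(f"{self.drug}: non-finite scores")
        if self.risk_label is not None and self.risk_label not in RISK_CATEGORIES:
            raise ConfigurationError(f"{self.drug}: bad risk label {self.risk_label!r}")

    def median(self) -> float:
        return float(np.median(self.scores))


@dataclass(frozen=True)
class Thresholds:
    """The two cut points (uC/uF): t2 < t1, lower score = higher risk."""

    t1: float  # separates low from intermediate/high
    t2: float  # separates high from intermediate/low

    def __post_init__(self):
        if not self.t2 < self.t1:
            raise ConfigurationError("require t2 < t1 (lower score = higher risk)")


class OrdinalThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Proportional-odds ordinal regression of risk category on score.

    scikit-learn style: ``fit(X, y, sample_weight)`` with X the scores
    (shape ``(n,)`` or ``(n, 1)``) and y risk labels (strings from
    ``("high", "intermediate", "low")`` or codes 0/1/2 in that order).
    Scores are standardized internally, which makes the fitted thresholds
    exactly scale-equivariant.

    Fitted attributes: ``t1_``, ``t2_``, ``slope_`` (on the original score
    scale), ``intercepts_``, ``nll_``, ``converged_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 1000):
        self.tol = tol
        self.max_iter = max_iter

    @staticmethod
    def _encode(y):
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            try:
                return np.array([_CAT_INDEX[str(v)] for v in y])
            except KeyError as err:
                raise FitError(f"unknown risk label {err}") from None
        return y.astype(int)

    def fit(self, X, y, sample_weight=None):
        s = np.asarray(X, dtype=float).reshape(-1)
        k = self._encode(y)
        if s.shape != k.shape:
            raise FitError("scores and labels differ in length")
        if set(np.unique(k)) != {0, 1, 2}:
            raise FitError("ordinal fit requires all three risk categories")
        w = (np.ones_like(s) if sample_weight is None
             else np.asarray(sample_weight, dtype=float).reshape(-1))
        w = w / w.sum()

        mu, sd = float(np.mean(s)), float(np.std(s))
        if sd == 0:
            raise FitError("degenerate scores: zero variance")
        z = (s - mu) / sd

        is0 = k == 0
        is1 = k == 1

        def nll(theta):
            a0, gap, logb = theta
            a1 = a0 + np.exp(gap)
            b = np.exp(logb)
            c0 = expit(a0 - b * z)
            c1 = expit(a1 - b * z)
            p = np.where(is0, c0, np.where(is1, c1 - c0, 1.0 - c1))
            return -np.sum(w * np.log(np.clip(p, 1e-300, None)))

        # moment-based start: logistic slope ~ 1.7/sd on standardized scale
        m0 = float(np.median(z[is0])) if is0.any() else -1.0
        m2 = float(np.median(z[k == 2]))
        b0 = 1.7
        theta0 = np.array([b0 * (m0 + 0.5), np.log(max(b0 * (m2 - m0), 0.1)),
                           np.log(b0)])
        res = minimize(nll, theta0, method="Nelder-Mead",
                       options={"xatol": self.tol, "fatol": self.tol,
                                "maxiter": self.max_iter * 10})
        res = minimize(nll, res.x, method="BFGS",
                       options={"gtol": self.tol, "maxiter": self.max_iter})
        a0, gap, logb = res.x
        a1 = a0 + np.exp(gap)
        b = np.exp(logb)
        self.converged_ = bool(np.isfinite(res.fun))
        if not self.converged_:
            raise FitError(f"ordinal fit failed to converge: {res.message}")
        # map standardized cut points back to the score scale
        self.t2_ = mu + sd * a0 / b
        self.t1_ = mu + sd * a1 / b
        self.slope_ = b / sd
        self.intercepts_ = (a0 - b * (-mu / sd), a1 - b * (-mu / sd))
        self.nll_ = float(res.fun)
        self.classes_ = np.array(RISK_CATEGORIES)
        return self

    @property
    def thresholds_(self) -> Thresholds:
        return Thresholds(t1=float(self.t1_), t2=float(self.t2_))

    def predict(self, X):
        return classify_scores(np.asarray(X, dtype=float).reshape(-1),
                               self.thresholds_)


def fit_ordinal_thresholds(
    training: list[ScoreDistribution],
    use_medians: bool = False,
    tol: float = 1e-8,
) -> Thresholds:
    """Fit the two risk thresholds from labeled training distributions.

    Pools every drug's samples with weight 1/n (drugs contribute equally);
    ``use_medians=True`` switches to one median score per drug instead of
    the full distributions.
    """
    labels = {d.risk_label for d in training}
    if not labels.issuperset(RISK_CATEGORIES):
        raise FitError(
            f"training panel missing categories: {set(RISK_CATEGORIES) - labels}"
        )
    xs, ys, ws = [], [], []
    for d in training:
        if use_medians:
            xs.append([d.median()])
            ws.append([1.0])
            ys.append([d.risk_label])
        else:
            xs.append(d.scores)
            ws.append(np.full(len(d.scores), 1.0 / len(d.scores)))
            ys.append([d.risk_label] * len(d.scores))
    est = OrdinalThresholdClassifier(tol=tol).fit(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(ws)
    )
    return est.thresholds_


def classify_score(score: float, th: Thresholds) -> str:
    """high below t2, low above t1, intermediate in between (boundary ties
    go to intermediate)."""
    if score < th.t2:
        return "high"
    if score > th.t1:
        return "low"
    return "intermediate"


def classify_scores(scores, th: Thresholds) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    out = np.full(s.shape, "intermediate", dtype=object)
    out[s < th.t2] = "high"
    out[s > th.t1] = "low"
    return out.astype(str)


def category_fractions(dist: ScoreDistribution, th: Thresholds):
    """Fractions of the distribution classified (high, intermediate, low);
    an exact partition summing to 1."""
    s = dist.scores
    n = len(s)
    n_high = int(np.sum(s < th.t2))
    n_low = int(np.sum(s > th.t1))
    return (n_high / n, (n - n_high - n_low) / n, n_low / n)


def loo_cross_validate(
    panel: list[ScoreDistribution],
    n_iter: int = 10_000,
    seed: int = 0,
    use_medians: bool = False,
):
    """Leave-one-out cross-validation of threshold classification.

    For each drug the thresholds are refit on the remaining drugs and the
    held-out drug is classified with them; the classification measures
    (likelihood ratios, mean classification error) aggregate the held-out
    results, while the ranking measures (ROC AUCs, pairwise comparison)
    use the full panel's score distributions. Folds whose training part
    misses a category are skipped with a warning and reported in the
    returned report's ``meta``.
    """
    from .evaluate import evaluate_panel  # local import to avoid a cycle

    if len(panel) < 3:
        raise FitError("need at least 3 drugs for leave-one-out")
    per_drug_th = {}
    skipped = []
    for i, held in enumerate(panel):
        rest = panel[:i] + panel[i + 1:]
        try:
            per_drug_th[held.drug] = fit_ordinal_thresholds(
                rest, use_medians=use_medians)
        except FitError as err:
            log.warning("LOO fold for %s skipped: %s", held.drug, err)
            skipped.append(held.drug)
    kept = [d for d in panel if d.drug in per_drug_th]
    report = evaluate_panel(kept, per_drug_th, n_iter=n_iter, seed=seed)
    report.meta["loo_skipped"] = skipped
    report.meta["n_drugs"] = len(kept)
    return report
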