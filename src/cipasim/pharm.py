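"""Concentration–response pharmacology: Hill block, fitting, bootstrap UQ.

Non-hERG drug effects are summarized by the Hill equation

    block(C) = 1 / (1 + (IC50 / C)**h)

with half-inhibition concentration IC50 (nM) and Hill coefficient h; a
current's conductance is multiplied by ``1 - block(C)``. hERG effects are
carried through untouched as the five dynamic binding parameters. The
bootstrap resamples cells with replacement and refits, propagating
patch-clamp variability into per-drug parameter sample sets for
uncertainty quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import ConfigurationError, FitError
from .models import SCALABLE_CURRENTS, DrugExposure, HergDynamicParams, INERT_HERG

__all__ = [
    "RISK_CATEGORIES",
    "NO_BLOCK",
    "ChannelBlock",
    "DrugRecord",
    "CellResponse",
    "DrugSampleSet",
    "hill_block_fraction",
    "mean_block_over_range",
    "HillCurveFitter",
    "fit_hill",
    "bootstrap_hill_samples",
    "assemble_sample_set",
    "exposure_at",
]

#: Ordinal TdP risk categories, most to least dangerous.
RISK_CATEGORIES = ("high", "intermediate", "low")

#: Currents a ChannelBlock may address.
BLOCKABLE_CURRENTS = SCALABLE_CURRENTS


@dataclass(frozen=True)
class ChannelBlock:
    """Hill-equation block of one current. ``ic50_nM = inf`` encodes
    'no measurable block'."""

    current_id: str
    ic50_nM: float
    hill: float = 1.0

    def __post_init__(self):
        if self.current_id not in BLOCKABLE_CURRENTS:
            raise ConfigurationError(
                f"current {self.current_id!r} not blockable; one of {BLOCKABLE_CURRENTS}"
            )
        if not self.ic50_nM > 0:
            raise ConfigurationError("ic50 must be > 0 (inf for no block)")
        if not self.hill > 0:
            raise ConfigurationError("Hill coefficient must be > 0")


def NO_BLOCK(current_id: str) -> ChannelBlock:
    """Sentinel block record meaning 'no measurable block'."""
    return ChannelBlock(current_id, math.inf, 1.0)


@dataclass(frozen=True)
class DrugRecord:
    """One drug's block parameters, free Cmax and (optional) risk label."""

    name: str
    cmax_nM: float
    herg: HergDynamicParams = INERT_HERG
    blocks: Mapping[str, ChannelBlock] = field(default_factory=dict)
    risk_label: str | None = None

    def __post_init__(self):
        if not self.cmax_nM > 0:
            raise ConfigurationError(f"drug {self.name!r}: cmax must be > 0")
        for cur, blk in self.blocks.items():
            if blk.current_id != cur:
                raise ConfigurationError(
                    f"drug {self.name!r}: block keyed {cur} targets {blk.current_id}"
                )
        if self.risk_label is not None and self.risk_label not in RISK_CATEGORIES:
            raise ConfigurationError(
                f"drug {self.name!r}: risk label must be one of {RISK_CATEGORIES}"
            )


@dataclass(frozen=True)
class CellResponse:
    """One patch-clamp observation: fractional block of one current in one
    cell at one concentration."""

    drug: str
    cell_id: str
    concentration_nM: float
    fractional_block: float
    current_id: str = ""

    def __post_init__(self):
        if not self.concentration_nM > 0:
            raise ConfigurationError("response concentration must be > 0")


@dataclass
class DrugSampleSet:
    """Joint parameter samples for one drug, one row per UQ replicate."""

    drug: str
    samples: list[tuple[HergDynamicParams, dict[str, ChannelBlock]]]

    def __len__(self):
        return len(self.samples)


def hill_block_fraction(conc_nM, block: ChannelBlock):
    """Fractional block in [0, 1] at concentration ``conc_nM`` (scalar or
    array); 0 at zero concentration and for the no-block sentinel."""
    conc = np.asarray(conc_nM, dtype=float)
    if np.any(conc < 0):
        raise ConfigurationError("concentration must be >= 0")
    if not np.isfinite(block.ic50_nM):
        return np.zeros_like(conc) if conc.ndim else 0.0
    with np.errstate(divide="ignore", over="ignore"):
        frac = np.where(conc > 0,
                        1.0 / (1.0 + (block.ic50_nM / np.maximum(conc, 1e-300))
                               ** block.hill),
                        0.0)
    return frac if conc.ndim else float(frac)


def mean_block_over_range(
    block: ChannelBlock,
    cmax_nM: float,
    lo_mult: float = 1.0,
    hi_mult: float = 4.0,
    n_grid: int = 10,
) -> float:
    """Mean fractional block over a log-spaced concentration grid spanning
    ``[lo_mult, hi_mult] x Cmax`` (the span used to report mean block%)."""
    if not lo_mult < hi_mult:
        raise ConfigurationError("require lo_mult < hi_mult")
    grid = np.geomspace(lo_mult * cmax_nM, hi_mult * cmax_nM, n_grid)
    return float(np.mean(hill_block_fraction(grid, block)))


def exposure_at(record: DrugRecord, concentration_nM: float) -> DrugExposure:
    """Resolve a drug record at one concentration into model-level effects."""
    scale = {
        cur: 1.0 - float(hill_block_fraction(concentration_nM, blk))
        for cur, blk in record.blocks.items()
        if np.isfinite(blk.ic50_nM)
    }
    return DrugExposure(concentration_nM=concentration_nM,
                        herg=record.herg, scale=scale)


class HillCurveFitter(BaseEstimator, RegressorMixin):
    """Least-squares Hill-equation fit of fractional block vs concentration.

    scikit-learn style estimator: ``fit(X, y)`` with X the concentrations
    (nM, shape ``(n,)`` or ``(n, 1)``) and y the fractional block in
    [0, 1]. The IC50 is optimized on a log10 scale; the Hill coefficient
    is constrained to ``hill_bounds`` (default (0, 5]) because
    unconstrained fits on noisy sparse data are unstable.

    Fitted attributes: ``ic50_`` (nM, ``inf`` when responses show no
    measurable block), ``hill_``, ``rmse_``, ``n_obs_``, ``converged_``.
    """

    #: responses all below this level are treated as 'no measurable block'
    NO_BLOCK_LEVEL = 0.01

    def __init__(self, hill_bounds=(1e-3, 5.0), max_nfev=200):
        self.hill_bounds = hill_bounds
        self.max_nfev = max_nfev

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if X.shape != y.shape:
            raise FitError("concentrations and responses differ in length")
        if np.any(X <= 0):
            raise FitError("concentrations must be > 0")
        if len(np.unique(X)) < 2:
            raise FitError(
                "Hill fit underdetermined: need >= 2 distinct concentrations"
            )
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        self.n_obs_ = len(y)
        if np.all(y <= self.NO_BLOCK_LEVEL):
            self.ic50_ = math.inf
            self.hill_ = 1.0
            self.rmse_ = float(np.sqrt(np.mean(y ** 2)))
            self.converged_ = True
            return self

        # initial IC50: concentration where the response crosses 0.5,
        # else extrapolate from the largest observed block
        order = np.argsort(X)
        xs, ys = X[order], y[order]
        if ys.max() >= 0.5:
            i = int(np.argmax(ys >= 0.5))
            ic50_0 = xs[i]
        else:
            ic50_0 = xs[-1] * (1.0 - ys.max()) / max(ys.max(), 1e-3)
        theta0 = np.array([math.log10(ic50_0), 1.0])
        lo = np.array([-12.0, self.hill_bounds[0]])
        hi = np.array([18.0, self.hill_bounds[1]])

        def resid(theta):
            ic50, h = 10.0 ** theta[0], theta[1]
            return 1.0 / (1.0 + (ic50 / X) ** h) - y

        sol = least_squares(resid, np.clip(theta0, lo, hi), bounds=(lo, hi),
                            max_nfev=self.max_nfev)
        if not sol.success:
            raise FitError(f"Hill fit did not converge: {sol.message}")
        self.ic50_ = float(10.0 ** sol.x[0])
        self.hill_ = float(sol.x[1])
        self.rmse_ = float(np.sqrt(np.mean(sol.fun ** 2)))
        self.converged_ = True
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        if not np.isfinite(self.ic50_):
            return np.zeros_like(X)
        return 1.0 / (1.0 + (self.ic50_ / X) ** self.hill_)

    def to_block(self, current_id: str) -> ChannelBlock:
        return ChannelBlock(current_id, self.ic50_, self.hill_)


def _as_arrays(data: Iterable[CellResponse]):
    data = list(data)
    if not data:
        raise FitError("no concentration-response data supplied")
    conc = np.array([r.concentration_nM for r in data])
    frac = np.array([r.fractional_block for r in data])
    cells = np.array([r.cell_id for r in data])
    return data, conc, frac, cells


def fit_hill(data: Iterable[CellResponse], current_id: str = "INaL"):
    """Fit one drug+current concentration-response panel.

    Returns ``(ChannelBlock, diagnostics)`` where diagnostics reports the
    residual summary and sample size.
    """
    _, conc, frac, _ = _as_arrays(data)
    est = HillCurveFitter().fit(conc, frac)
    diag = {"rmse": est.rmse_, "n_obs": est.n_obs_, "converged": est.converged_}
    return est.to_block(current_id), diag


def bootstrap_hill_samples(
    data: Iterable[CellResponse],
    n: int,
    seed: int,
    current_id: str = "INaL",
    max_redraws: int = 50,
) -> list[ChannelBlock]:
    """Nonparametric bootstrap of the Hill fit, resampling cells.

    Cells (not individual points) are drawn with replacement, preserving
    within-cell correlation; each replicate is refit. Replicates whose fit
    fails are redrawn, up to ``max_redraws`` consecutive failures.
    """
    data, conc, frac, cells = _as_arrays(data)
    cell_ids = np.unique(cells)
    by_cell = {c: np.flatnonzero(cells == c) for c in cell_ids}
    rng = np.random.default_rng(seed)
    out: list[ChannelBlock] = []
    failures = 0
    while len(out) < n:
        chosen = rng.choice(cell_ids, size=len(cell_ids), replace=True)
        idx = np.concatenate([by_cell[c] for c in chosen])
        try:
            est = HillCurveFitter().fit(conc[idx], frac[idx])
        except FitError:
            failures += 1
            if failures > max_redraws:
                raise FitError(
                    f"bootstrap exceeded {max_redraws} consecutive failed refits"
                )
            continue
        failures = 0
        out.append(est.to_block(current_id))
    return out


def assemble_sample_set(
    drug: DrugRecord,
    herg_samples: Sequence[HergDynamicParams] = (),
    block_samples: Mapping[str, Sequence[ChannelBlock]] | None = None,
    n: int = 2000,
    seed: int = 0,
    precomputed: DrugSampleSet | None = None,
) -> DrugSampleSet:
    """Build the per-drug joint parameter sample set for UQ.

    Channels are sampled independently (they are measured in separate
    experiments): each joint sample pairs an independent draw (with
    replacement) from the hERG samples with one from each per-current
    block collection. A channel with no samples falls back to the drug
    record's point estimate. If ``precomputed`` is supplied, its first
    ``n`` rows are passed through unchanged.
    """
    if precomputed is not None:
        if n > len(precomputed):
            raise ConfigurationError(
                f"requested {n} samples but precomputed set has {len(precomputed)}"
            )
        return DrugSampleSet(drug.name, list(precomputed.samples[:n]))

    block_samples = block_samples or {}
    rng = np.random.default_rng(seed)
    herg_pool = list(herg_samples) if len(herg_samples) else [drug.herg]
    pools: dict[str, list[ChannelBlock]] = {}
    currents = set(drug.blocks) | set(block_samples)
    for cur in sorted(currents):
        pool = list(block_samples.get(cur, ()))
        if not pool:
            pool = [drug.blocks[cur]]
        pools[cur] = pool

    samples = []
    for _ in range(n):
        herg = herg_pool[rng.integers(len(herg_pool))]
        blocks = {cur: pool[rng.integers(len(pool))]
                  for cur, pool in pools.items()}
        samples.append((herg, blocks))
    return DrugSampleSet(drug.name, samples)
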