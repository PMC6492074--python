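"""Synthetic data generators: everything needed to exercise the pipeline
without external data.

Three layers of realism:

* :func:`make_toy_model` — the registered 3-variable AP caricature
  (see :mod:`cipasim.models.toy`) for fast end-to-end runs.
* :func:`generate_patch_clamp_panel` — per-cell concentration-response
  points from known Hill parameters with truncated Gaussian noise,
  emulating patch-clamp block-potency panels.
* :func:`generate_score_panel` — Gaussian torsade-metric-score
  distributions with category-level means/sds, giving closed-form
  off-category masses once thresholds are chosen.

Every generator is a pure function of its seed and spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .models import HergDynamicParams
from .pharm import (
    RISK_CATEGORIES,
    CellResponse,
    ChannelBlock,
    DrugRecord,
    hill_block_fraction,
)
from .thresholds import ScoreDistribution

__all__ = [
    "SyntheticPanelSpec",
    "make_toy_model",
    "generate_patch_clamp_panel",
    "generate_score_panel",
    "generate_toy_drug_panel",
    "jitter_herg_samples",
]


def make_toy_model():
    """Return the registered toy model spec (registering it on first use)."""
    from .models import get_model
    from .models import toy  # noqa: F401  (import registers the model)

    return get_model("toy")


def generate_patch_clamp_panel(
    true_params: Mapping[tuple[str, str], ChannelBlock] | ChannelBlock,
    n_cells: int = 8,
    concs: Sequence[float] | None = None,
    noise_sd: float = 0.05,
    seed: int = 0,
    drug: str = "drugA",
) -> list[CellResponse]:
    """Per-cell fractional-block observations from known Hill curves.

    ``true_params`` maps ``(drug, current)`` to the generating
    :class:`ChannelBlock` (a bare block is shorthand for one drug/current).
    Responses are the Hill curve plus additive Gaussian noise of sd
    ``noise_sd``, truncated to [0, 1]. Default concentrations: 5 points
    log-spaced over 0.1-10x IC50, the span a potency experiment would use.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise_sd must be >= 0")
    if isinstance(true_params, ChannelBlock):
        true_params = {(drug, true_params.current_id): true_params}
    rng = np.random.default_rng(seed)
    out: list[CellResponse] = []
    for (drug_name, current), block in true_params.items():
        if concs is None:
            if not np.isfinite(block.ic50_nM):
                c_grid = np.geomspace(1.0, 1e4, 5)
            else:
                c_grid = np.geomspace(0.1 * block.ic50_nM, 10 * block.ic50_nM, 5)
        else:
            c_grid = np.asarray(concs, dtype=float)
        truth = hill_block_fraction(c_grid, block)
        for cell in range(n_cells):
            noisy = truth + rng.normal(0.0, noise_sd, size=len(c_grid))
            noisy = np.clip(noisy, 0.0, 1.0)
            for c, fb in zip(c_grid, noisy):
                out.append(CellResponse(
                    drug=drug_name, cell_id=f"cell{cell:02d}",
                    concentration_nM=float(c), fractional_block=float(fb),
                    current_id=current,
                ))
    return out


@dataclass(frozen=True)
class SyntheticPanelSpec:
    """Recipe for a multi-drug panel of Gaussian score distributions."""

    n_drugs: Mapping[str, int] = field(
        default_factory=lambda: {"high": 4, "intermediate": 4, "low": 4})
    score_means: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.030, "intermediate": 0.062,
                                 "low": 0.085})
    score_sds: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.006, "intermediate": 0.006,
                                 "low": 0.006})
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self):
        m = self.score_means
        if not m["high"] < m["intermediate"] < m["low"]:
            raise ConfigurationError(
                "category means must be ordered high < intermediate < low")
        if any(sd <= 0 for sd in self.score_sds.values()):
            raise ConfigurationError("score sds must be > 0")


def generate_score_panel(spec: SyntheticPanelSpec) -> list[ScoreDistribution]:
    """Gaussian score distributions per drug with category-level
    means/sds; off-category masses are then normal tail integrals."""
    rng = np.random.default_rng(spec.seed)
    dists = []
    for cat in RISK_CATEGORIES:
        for i in range(spec.n_drugs.get(cat, 0)):
            scores = rng.normal(spec.score_means[cat], spec.score_sds[cat],
                                size=spec.n_samples)
            dists.append(ScoreDistribution(f"{cat}_{i + 1}", scores, cat))
    return dists


def jitter_herg_samples(
    herg: HergDynamicParams,
    n: int,
    rel_sd: float = 0.15,
    seed: int = 0,
) -> list[HergDynamicParams]:
    """Lognormal jitter of the five dynamic hERG parameters.

    Emulates the sampling variability of the binding-parameter fit when
    the raw voltage-clamp sweeps (and hence a real bootstrap) are not
    available; rate/potency parameters get multiplicative lognormal noise
    of relative sd ``rel_sd``, the trapping voltage additive Gaussian
    noise of 2 mV.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(HergDynamicParams(
            kmax=herg.kmax * rng.lognormal(0.0, rel_sd),
            ku=herg.ku * rng.lognormal(0.0, rel_sd),
            n=herg.n,
            halfmax=herg.halfmax * rng.lognormal(0.0, rel_sd),
            vhalf=herg.vhalf + rng.normal(0.0, 2.0),
        ))
    return out


# hERG parameters below put the toy model's steady drug occupancy b* at
# roughly 0.5 / 0.25 / 0.05 at Cmax for the three categories, which maps
# (through the toy qNet closed form) onto well-separated score bands.
_CATEGORY_KMAX = {"high": 10000.0, "intermediate": 3300.0, "low": 520.0}


def generate_toy_drug_panel(
    n_per_category: Mapping[str, int] | int = 4,
    seed: int = 0,
    cmax_nM: float = 100.0,
    potency_jitter: float = 0.25,
    p_multichannel: float = 0.3,
) -> list[DrugRecord]:
    """Drug records with known risk structure for the toy model.

    hERG potency (Kmax) sets the category; lognormal jitter of relative
    sd ``potency_jitter`` individualizes drugs; a minority of drugs get
    additional INaL or ICaL block, mimicking multichannel pharmacology.
    """
    if isinstance(n_per_category, int):
        n_per_category = {c: n_per_category for c in RISK_CATEGORIES}
    rng = np.random.default_rng(seed)
    panel = []
    for cat in RISK_CATEGORIES:
        for i in range(n_per_category.get(cat, 0)):
            kmax = _CATEGORY_KMAX[cat] * rng.lognormal(0.0, potency_jitter)
            herg = HergDynamicParams(kmax=kmax, ku=0.1, n=1.0,
                                     halfmax=1.0e6, vhalf=-10.0)
            blocks = {}
            if rng.random() < p_multichannel:
                cur = "INaL" if rng.random() < 0.5 else "ICaL"
                blocks[cur] = ChannelBlock(
                    cur, float(rng.uniform(5, 50) * cmax_nM), 1.0)
            panel.append(DrugRecord(
                name=f"{cat}_drug_{i + 1}", cmax_nM=cmax_nM, herg=herg,
                blocks=blocks, risk_label=cat,
            ))
    return panel
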