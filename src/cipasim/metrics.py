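"""Per-beat electrophysiological metrics and the torsade metric score.

qNet is the time integral over one paced beat of the net current

    Inet = ICaL + INaL + IKr + IKs + IK1 + Ito      (uA/uF)

in uC/uF; lower qNet means less repolarization reserve and higher
torsade-de-pointes liability. The torsade metric score is the mean qNet
across simulations at 1-4x the drug's maximum free therapeutic plasma
concentration (Cmax).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CipasimError, ConfigurationError
from .models import (
    ApTrace,
    PacingProtocol,
    run_to_steady_state,
)
from .pharm import DrugRecord, exposure_at

__all__ = [
    "QNET_CURRENTS",
    "BeatMetrics",
    "TorsadeScore",
    "EngineConfig",
    "qnet",
    "apd",
    "diastolic_ca",
    "detect_depolarization_failure",
    "torsade_metric_score",
    "score_samples",
    "DepolarizationFailure",
    "RepolarizationFailure",
]

#: Currents entering the net charge; INa is excluded (its role is the
#: depolarization-failure mechanism, not the integral).
QNET_CURRENTS = ("ICaL", "INaL", "IKr", "IKs", "IK1", "Ito")

#: Peak membrane potential below this after the stimulus = failed upstroke.
DEPOL_THRESHOLD_MV = 0.0


class DepolarizationFailure(CipasimError):
    """The beat never depolarized (e.g. near-total INa block)."""


class RepolarizationFailure(CipasimError):
    """The beat never repolarized to the requested APD level."""


def qnet(trace: ApTrace) -> float:
    """Net charge (uC/uF) carried by the six qNet currents over one beat,
    trapezoidal rule on the trace grid."""
    for cur in QNET_CURRENTS:
        if cur not in trace.currents:
            raise ConfigurationError(f"trace lacks required current {cur}")
    inet = np.zeros_like(trace.time_ms)
    for cur in QNET_CURRENTS:
        inet = inet + trace.currents[cur]
    return float(np.trapezoid(inet, trace.time_ms)) / 1000.0


def _upstroke_index(trace: ApTrace) -> int:
    dv = np.diff(trace.v_mV) / np.diff(trace.time_ms)
    return int(np.argmax(dv))


def detect_depolarization_failure(trace: ApTrace) -> bool:
    """True iff the peak membrane potential after the stimulus stays below
    :data:`DEPOL_THRESHOLD_MV`."""
    return bool(np.max(trace.v_mV) < DEPOL_THRESHOLD_MV)


def apd(trace: ApTrace, level: float) -> float:
    """Action-potential duration at ``level`` % repolarization (ms).

    Measured from the time of maximum upstroke velocity to the crossing of
    ``peak - level% * amplitude`` (linear interpolation between samples),
    with the pre-upstroke minimum as the amplitude baseline.
    """
    if level not in (50, 90):
        raise ConfigurationError("APD level must be 50 or 90")
    if detect_depolarization_failure(trace):
        raise DepolarizationFailure("no upstroke: peak V below threshold")
    t, v = trace.time_ms, trace.v_mV
    iu = _upstroke_index(trace)
    t_up = t[iu + 1]
    v_base = float(np.min(v[: iu + 1])) if iu > 0 else float(v[0])
    post = slice(iu + 1, None)
    ipk = iu + 1 + int(np.argmax(v[post]))
    v_peak = float(v[ipk])
    v_thr = v_peak - (level / 100.0) * (v_peak - v_base)
    below = np.flatnonzero(v[ipk:] < v_thr)
    if len(below) == 0:
        raise RepolarizationFailure(f"no {level}% repolarization before beat end")
    j = ipk + below[0]
    # linear interpolation across the crossing interval [j-1, j]
    frac = (v[j - 1] - v_thr) / (v[j - 1] - v[j])
    t_cross = t[j - 1] + frac * (t[j] - t[j - 1])
    return float(t_cross - t_up)


def diastolic_ca(trace: ApTrace) -> float:
    """Minimum intracellular calcium over the beat (mM)."""
    return float(np.min(trace.cai_mM))


@dataclass
class BeatMetrics:
    """All per-beat metrics; qNet is defined iff no failure flag is set."""

    qnet: float
    apd90: float
    apd50: float
    diastolic_ca: float
    depol_failure: bool = False
    repol_failure: bool = False

    @classmethod
    def from_trace(cls, trace: ApTrace) -> "BeatMetrics":
        depol = repol = False
        apd90 = apd50 = np.nan
        try:
            apd90 = apd(trace, 90)
            apd50 = apd(trace, 50)
        except DepolarizationFailure:
            depol = True
        except RepolarizationFailure:
            repol = True
        q = qnet(trace) if not (depol or repol) else np.nan
        return cls(
            qnet=q,
            apd90=apd90,
            apd50=apd50,
            diastolic_ca=diastolic_ca(trace),
            depol_failure=depol,
            repol_failure=repol,
        )


@dataclass(frozen=True)
class EngineConfig:
    """Simulation configuration shared by all metric computations."""

    model_id: str = "cipaordv1.0"
    protocol: PacingProtocol = PacingProtocol()
    dt_ms: float | None = None
    record_dt_ms: float | None = None
    multiples: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0)


@dataclass
class TorsadeScore:
    """Torsade metric score of one drug for one joint parameter sample:
    mean qNet over the Cmax multiples, undefined (NaN) if any
    concentration fails to depolarize or repolarize."""

    drug: str
    score: float
    per_concentration_qnet: dict[float, float] = field(default_factory=dict)
    n_failures: int = 0
    per_concentration_metrics: dict[float, BeatMetrics] = field(default_factory=dict)


def torsade_metric_score(
    drug: DrugRecord,
    params: tuple | None = None,
    engine: EngineConfig = EngineConfig(),
) -> TorsadeScore:
    """Mean qNet across 1-4x Cmax for one joint parameter sample.

    ``params`` is one ``(HergDynamicParams, {current: ChannelBlock})``
    sample from a :class:`~cipasim.pharm.DrugSampleSet`; ``None`` uses the
    drug record's point estimates. A sample with any failing concentration
    yields an undefined (NaN) score with ``n_failures`` reported.
    """
    if params is not None:
        herg, blocks = params
        drug = DrugRecord(drug.name, drug.cmax_nM, herg=herg, blocks=blocks,
                          risk_label=drug.risk_label)
    per_q: dict[float, float] = {}
    per_m: dict[float, BeatMetrics] = {}
    n_fail = 0
    for mult in engine.multiples:
        conc = mult * drug.cmax_nM
        exposure = exposure_at(drug, conc)
        try:
            trace = run_to_steady_state(
                engine.model_id, engine.protocol, exposure,
                dt_ms=engine.dt_ms, record_dt_ms=engine.record_dt_ms,
            )
        except CipasimError as err:
            raise type(err)(f"{err} at {mult}x Cmax of {drug.name}") from err
        m = BeatMetrics.from_trace(trace)
        per_m[mult] = m
        per_q[mult] = m.qnet
        if m.depol_failure or m.repol_failure:
            n_fail += 1
    vals = np.array(list(per_q.values()))
    score = float(np.mean(vals)) if n_fail == 0 else float("nan")
    return TorsadeScore(drug.name, score, per_q, n_fail, per_m)


def score_samples(drug, sample_set, engine: EngineConfig = EngineConfig()):
    """Torsade metric scores for every joint sample of one drug.

    Returns ``(scores, n_failed_samples)`` where ``scores`` holds only the
    defined values (samples with a failing concentration are excluded and
    counted — they are reported, not silently dropped).
    """
    scores = []
    n_failed = 0
    for params in sample_set.samples:
        ts = torsade_metric_score(drug, params, engine)
        if np.isnan(ts.score):
            n_failed += 1
        else:
            scores.append(ts.score)
    return np.array(scores), n_failed
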