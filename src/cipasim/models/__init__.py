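"""Paced ventricular action-potential models behind a common interface.

Two models are registered:

``"cipaordv1.0"``
    An endocardial human ventricular myocyte model of the optimized
    O'Hara–Rudy family, with the rapid delayed-rectifier current IKr
    replaced by a Markov scheme carrying dynamic drug binding/trapping
    (five drug parameters: association scale Kmax, unbinding rate Ku,
    Hill-like exponent n, potency term halfmax, trapping voltage Vhalf).

``"toy"``
    A three-variable action-potential caricature with analytically known
    responses, used for fast pipeline and statistics testing.

Any model registers its state layout, initial condition and a compiled
simulator, so the metric / uncertainty-quantification / statistics layers
are model-agnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from ..errors import ConfigurationError, SimulationError

__all__ = [
    "CURRENT_IDS",
    "SCALABLE_CURRENTS",
    "HergDynamicParams",
    "DrugExposure",
    "PacingProtocol",
    "ModelState",
    "ApTrace",
    "ModelSpec",
    "register_model",
    "get_model",
    "available_models",
    "initial_state",
    "simulate_paced",
    "run_to_steady_state",
]

log = logging.getLogger(__name__)

#: Currents every model must report, in the order used by packed arrays.
CURRENT_IDS = ("IKr", "INaL", "ICaL", "INa", "IKs", "IK1", "Ito")

#: Currents that accept static conductance scaling from Hill-type block.
#: IKr is deliberately absent: drug effects on IKr enter only through the
#: dynamic binding parameters.
SCALABLE_CURRENTS = ("INaL", "INa", "ICaL", "IKs", "IK1", "Ito")


@dataclass(frozen=True)
class HergDynamicParams:
    """Five dynamic drug–hERG interaction parameters.

    Parameters
    ----------
    kmax : float
        Dimensionless scale of the maximum drug association rate.
    ku : float
        Unbinding rate from the open-bound state, 1/ms.
    n : float
        Hill-like exponent of the concentration dependence of binding.
    halfmax : float
        Potency term in the binding rate, units nM**n.
    vhalf : float
        Half-activation voltage (mV) of drug release from the trapped
        (closed-bound) state.
    """

    kmax: float = 0.0
    ku: float = 1.0
    n: float = 1.0
    halfmax: float = 1.0
    vhalf: float = -1.0

    def __post_init__(self):
        if self.kmax < 0 or self.ku < 0:
            raise ConfigurationError("hERG rate-type parameters must be >= 0")
        if self.n <= 0:
            raise ConfigurationError("hERG exponent n must be > 0")
        if self.halfmax <= 0:
            raise ConfigurationError("hERG halfmax must be > 0")

    def binding_rate(self, concentration_nM: float) -> float:
        """Drug association rate (1/ms) at a given free concentration."""
        if concentration_nM <= 0 or self.kmax == 0:
            return 0.0
        dn = concentration_nM ** self.n
        return self.kmax * self.ku * dn / (dn + self.halfmax)


#: Inert binding parameters: zero association whatever the concentration.
INERT_HERG = HergDynamicParams(kmax=0.0, ku=1.0, n=1.0, halfmax=1.0, vhalf=-1.0)


@dataclass(frozen=True)
class DrugExposure:
    """A drug at one free concentration, resolved to model-level effects.

    ``scale`` maps current ids (subset of :data:`SCALABLE_CURRENTS`) to
    conductance multipliers in [0, 1] already evaluated at
    ``concentration_nM``; hERG effects stay dynamic via ``herg``.
    """

    concentration_nM: float = 0.0
    herg: HergDynamicParams = INERT_HERG
    scale: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.concentration_nM < 0:
            raise ConfigurationError("exposure concentration must be >= 0")
        for cur, s in self.scale.items():
            if cur not in SCALABLE_CURRENTS:
                raise ConfigurationError(
                    f"current {cur!r} does not accept static conductance scaling"
                )
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(f"conductance multiplier for {cur} outside [0,1]")

    def pack(self) -> np.ndarray:
        """Pack effects into the flat array consumed by compiled simulators."""
        kon = self.herg.binding_rate(self.concentration_nM)
        out = np.ones(9)
        out[0] = kon
        out[1] = self.herg.ku
        out[2] = self.herg.vhalf
        for i, cur in enumerate(SCALABLE_CURRENTS):
            out[3 + i] = self.scale.get(cur, 1.0)
        return out


NO_DRUG = DrugExposure()


@dataclass(frozen=True)
class PacingProtocol:
    """Periodic current-clamp stimulation.

    Defaults follow standard proarrhythmia-simulation practice: cycle
    length 2000 ms, stimulus -80 uA/uF for 0.5 ms, 1000 beats to reach
    the paced steady state.
    """

    cycle_length_ms: float = 2000.0
    n_beats: int = 1000
    stimulus_amplitude: float = -80.0  # uA/uF
    stimulus_duration_ms: float = 0.5
    output_beat_index: int | None = None  # 1-based; None = last beat

    def __post_init__(self):
        if not self.cycle_length_ms > self.stimulus_duration_ms > 0:
            raise ConfigurationError("require cycle_length > stimulus_duration > 0")
        if self.n_beats < 1:
            raise ConfigurationError("n_beats must be >= 1")
        if self.output_beat_index is not None and not (
            1 <= self.output_beat_index <= self.n_beats
        ):
            raise ConfigurationError("output_beat_index outside [1, n_beats]")


@dataclass
class ModelState:
    """Full state vector of a registered model, with named entries."""

    model_id: str
    names: tuple[str, ...]
    values: np.ndarray

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def copy(self) -> "ModelState":
        return ModelState(self.model_id, self.names, self.values.copy())


@dataclass
class ApTrace:
    """One paced beat: membrane potential, currents and intracellular Ca.

    ``currents`` holds one series per id in :data:`CURRENT_IDS`,
    outward-positive, in uA/uF. ``meta`` carries provenance (model id,
    drug context, convergence diagnostics, occupancy-conservation error).
    """

    time_ms: np.ndarray
    v_mV: np.ndarray
    currents: dict[str, np.ndarray]
    cai_mM: np.ndarray
    cycle_length_ms: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.time_ms)
        if np.any(np.diff(self.time_ms) <= 0):
            raise ConfigurationError("trace time grid must be strictly increasing")
        for cur in CURRENT_IDS:
            if cur not in self.currents or len(self.currents[cur]) != n:
                raise ConfigurationError(f"trace is missing or mis-sized current {cur}")
        if len(self.v_mV) != n or len(self.cai_mM) != n:
            raise ConfigurationError("trace series lengths disagree")

    def to_frame(self):
        import pandas as pd

        data = {"time_ms": self.time_ms, "v_mV": self.v_mV}
        for cur in CURRENT_IDS:
            data[cur] = self.currents[cur]
        data["cai_mM"] = self.cai_mM
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, cycle_length_ms=None) -> "ApTrace":
        import pandas as pd

        df = pd.read_csv(path)
        t = df["time_ms"].to_numpy(float)
        if cycle_length_ms is None:
            cycle_length_ms = float(t[-1] - t[0])
        return cls(
            time_ms=t,
            v_mV=df["v_mV"].to_numpy(float),
            currents={c: df[c].to_numpy(float) for c in CURRENT_IDS},
            cai_mM=df["cai_mM"].to_numpy(float),
            cycle_length_ms=cycle_length_ms,
        )


@dataclass(frozen=True)
class ModelSpec:
    """Registration record: state layout, initial condition, simulator.

    ``simulate`` is a compiled function with the uniform signature
    ``(y0, pack, cl, n_beats, rec_beat, dt, stim_amp, stim_dur, rec_stride)``
    returning ``(status, t, v, currents(7,n), cai, occ_sum, y_end,
    y_last_beat_start)`` where ``status`` is 0 on success and 1 when the
    integration produced non-finite values.
    """

    model_id: str
    state_names: tuple[str, ...]
    initial_values: np.ndarray
    simulate: Callable
    default_dt_ms: float
    default_record_dt_ms: float
    description: str = ""


_REGISTRY: dict[str, ModelSpec] = {}


def register_model(spec: ModelSpec) -> ModelSpec:
    _REGISTRY[spec.model_id] = spec
    return spec


def available_models() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def get_model(model_id: str) -> ModelSpec:
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise ConfigurationError(
            f"unknown model {model_id!r}; registered models: {available_models()}"
        ) from None


def initial_state(model_id: str) -> ModelState:
    """Published resting/initial condition of a registered model."""
    spec = get_model(model_id)
    return ModelState(model_id, spec.state_names, spec.initial_values.copy())


def _run(spec, y0, protocol, drug, dt, record_dt, rec_beat):
    pack = drug.pack()
    rec_stride = max(1, int(round(record_dt / dt)))
    out = spec.simulate(
        np.ascontiguousarray(y0, dtype=np.float64),
        pack,
        float(protocol.cycle_length_ms),
        int(protocol.n_beats),
        int(rec_beat),
        float(dt),
        float(protocol.stimulus_amplitude),
        float(protocol.stimulus_duration_ms),
        int(rec_stride),
    )
    status, t, v, cur, cai, occ, y_end, y_prev = out
    if status != 0:
        raise SimulationError(
            f"integration of model {spec.model_id!r} produced non-finite state",
            concentration_nM=drug.concentration_nM,
        )
    occ_err = float(np.max(np.abs(occ - 1.0)))
    currents = {cid: cur[i] for i, cid in enumerate(CURRENT_IDS)}
    trace = ApTrace(
        time_ms=t,
        v_mV=v,
        currents=currents,
        cai_mM=cai,
        cycle_length_ms=protocol.cycle_length_ms,
        meta={
            "model_id": spec.model_id,
            "concentration_nM": drug.concentration_nM,
            "dt_ms": dt,
            "occupancy_max_abs_error": occ_err,
        },
    )
    return trace, y_end, y_prev


def simulate_paced(
    state: ModelState,
    protocol: PacingProtocol,
    drug: DrugExposure = NO_DRUG,
    dt_ms: float | None = None,
    record_dt_ms: float | None = None,
    return_state: bool = False,
):
    """Integrate ``protocol.n_beats`` paced beats from ``state``.

    Returns the :class:`ApTrace` of the output beat (by default the last
    one). Drug effects enter only via the dynamic hERG parameters and the
    static conductance multipliers carried by ``drug``.
    """
    spec = get_model(state.model_id)
    if len(state.values) != len(spec.state_names):
        raise ConfigurationError("state vector length does not match model layout")
    dt = spec.default_dt_ms if dt_ms is None else float(dt_ms)
    rdt = spec.default_record_dt_ms if record_dt_ms is None else float(record_dt_ms)
    rec_beat = (protocol.output_beat_index or protocol.n_beats) - 1
    trace, y_end, _ = _run(spec, state.values, protocol, drug, dt, rdt, rec_beat)
    if return_state:
        return trace, ModelState(state.model_id, spec.state_names, y_end)
    return trace


def run_to_steady_state(
    model_id: str,
    protocol: PacingProtocol,
    drug: DrugExposure = NO_DRUG,
    start: ModelState | None = None,
    dt_ms: float | None = None,
    record_dt_ms: float | None = None,
):
    """Pace for ``protocol.n_beats`` beats and return the final beat.

    The trace's ``meta["beat_convergence"]`` records the maximum relative
    state-variable change across the final beat (state at the start vs the
    end of the last cycle), a cheap diagnostic of pacing convergence.
    """
    spec = get_model(model_id)
    y0 = (start.values if start is not None else spec.initial_values)
    dt = spec.default_dt_ms if dt_ms is None else float(dt_ms)
    rdt = spec.default_record_dt_ms if record_dt_ms is None else float(record_dt_ms)
    trace, y_end, y_prev = _run(
        spec, y0, protocol, drug, dt, rdt, protocol.n_beats - 1
    )
    denom = np.maximum(np.abs(y_prev), 1e-12)
    conv = float(np.max(np.abs(y_end - y_prev) / denom))
    trace.meta["beat_convergence"] = conv
    trace.meta["final_state"] = ModelState(model_id, spec.state_names, y_end)
    log.info(
        "run_to_steady_state(%s, conc=%.4g nM): %d beats, convergence %.3e",
        model_id, drug.concentration_nM, protocol.n_beats, conv,
    )
    return trace


# Register built-in models on import.
from . import ord as _ord  # noqa: E402,F401
from . import toy as _toy  # noqa: E402,F401
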