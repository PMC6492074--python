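"""Three-variable action-potential caricature with analytic responses.

States: membrane potential ``v``, a repolarization phase variable ``w``
(1 at the plateau, relaxing to 0 with time constant ``TAU0*(1+KAPPA*b)``)
and the fraction ``b`` of hERG channels occupied by drug. All three ODEs
are linear with piecewise-constant coefficients, so the paced periodic
solution — and hence qNet — has a closed form (:func:`closed_form_qnet`).

Drug coupling mirrors the production model: the five dynamic hERG
parameters set the binding rate ``kon = Kmax*Ku*D^n/(D^n+halfmax)`` and
unbinding ``Ku`` (occupancy ``b -> kon/(kon+Ku)``), while Hill-type block
of the other currents scales their conductances. Blocking INa scales the
upstroke drive, so near-total INa block produces depolarization failure.
qNet is strictly decreasing in ``b``, giving the built-in monotone
score-vs-potency response used by the property tests.

A beat integrates in well under 10 ms, which is what makes the full
pipeline (uncertainty quantification, thresholds, performance measures)
testable at desk scale.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import ModelSpec, register_model

VREST = -88.0   # mV
AMP = 128.0     # mV, plateau amplitude at w = 1
TAUV = 0.5      # ms, membrane relaxation
TAU0 = 250.0    # ms, repolarization time constant, drug free
KAPPA = 0.5     # relative APD prolongation at full hERG occupancy
R0 = 20.0       # 1/ms, upstroke drive during the stimulus
STIM_THRESHOLD = 5.0  # uA/uF, minimum |amplitude| that fires the cell

G_KR = 0.20
G_KS = 0.05
G_K1 = 0.12
G_TO = 0.03
G_CAL = 0.08
G_NAL = 0.04
G_NA = 5.0      # display scale of the (non-qNet) fast sodium current
CA0 = 1.0e-4    # mM, diastolic intracellular calcium
CA1 = 4.0e-4    # mM, calcium transient amplitude at w = 1

STATE_NAMES = ("v", "w", "b")


@njit(cache=True)
def _simulate(y0, pack, cl, n_beats, rec_beat, dt, stim_amp, stim_dur, rec_stride):
    kon = pack[0]
    ku = pack[1]
    s_nal = pack[3]
    s_na = pack[4]
    s_cal = pack[5]
    s_ks = pack[6]
    s_k1 = pack[7]
    s_to = pack[8]

    spb = int(round(cl / dt))
    dt = cl / spb
    nrec = spb // rec_stride + 1
    total = n_beats * spb

    t_rec = np.empty(nrec)
    v_rec = np.empty(nrec)
    cur_rec = np.empty((7, nrec))
    cai_rec = np.empty(nrec)
    occ_rec = np.empty(nrec)
    y = y0.copy()
    y_prev = y0.copy()
    status = 0

    fires = math.fabs(stim_amp) >= STIM_THRESHOLD
    rec_lo = rec_beat * spb
    rec_hi = rec_lo + spb

    for step in range(total + 1):
        v = y[0]
        w = y[1]
        b = y[2]
        t_in_beat = (step % spb) * dt if step < total else 0.0
        stim_on = fires and step < total and t_in_beat < stim_dur

        IKr = G_KR * (1.0 - b) * w
        IKs = G_KS * s_ks * w
        IK1 = G_K1 * s_k1 * w
        Ito = G_TO * s_to * w
        ICaL = -G_CAL * s_cal * w
        INaL = -G_NAL * s_nal * w
        INa = -G_NA * s_na * (1.0 - w) if stim_on else 0.0

        if rec_lo <= step <= rec_hi and (step - rec_lo) % rec_stride == 0:
            k = (step - rec_lo) // rec_stride
            if k < nrec:
                t_rec[k] = (step - rec_lo) * dt
                v_rec[k] = v
                cur_rec[0, k] = IKr
                cur_rec[1, k] = INaL
                cur_rec[2, k] = ICaL
                cur_rec[3, k] = INa
                cur_rec[4, k] = IKs
                cur_rec[5, k] = IK1
                cur_rec[6, k] = Ito
                cai_rec[k] = CA0 + CA1 * w
                occ_rec[k] = b + (1.0 - b)  # bound + free hERG occupancy
                if not (v == v):
                    status = 1
                    break

        if step == total:
            break
        if step == (n_beats - 1) * spb:
            y_prev = y.copy()

        # exact exponential updates (linear ODEs, coefficients frozen per step)
        lam_b = kon + ku
        if lam_b > 0.0:
            b_inf = kon / lam_b
            b_new = b_inf + (b - b_inf) * math.exp(-lam_b * dt)
        else:
            b_new = b
        drive = R0 * s_na if stim_on else 0.0
        lam_w = drive + 1.0 / (TAU0 * (1.0 + KAPPA * b))
        w_inf = drive / lam_w
        w_new = w_inf + (w - w_inf) * math.exp(-lam_w * dt)
        v_inf = VREST + AMP * w
        v_new = v_inf + (v - v_inf) * math.exp(-dt / TAUV)

        y[0] = v_new
        y[1] = w_new
        y[2] = b_new

    return status, t_rec, v_rec, cur_rec, cai_rec, occ_rec, y, y_prev


INITIAL_VALUES = np.array([VREST, 0.0, 0.0])


SPEC = register_model(ModelSpec(
    model_id="toy",
    state_names=STATE_NAMES,
    initial_values=INITIAL_VALUES,
    simulate=_simulate,
    default_dt_ms=0.1,
    default_record_dt_ms=0.5,
    description="3-variable AP caricature with closed-form qNet",
))


def steady_occupancy(kon: float, ku: float) -> float:
    """Periodic steady-state hERG drug occupancy ``b* = kon/(kon+ku)``."""
    lam = kon + ku
    return kon / lam if lam > 0 else 0.0


def closed_form_qnet(
    b: float = 0.0,
    scale: dict | None = None,
    cycle_length_ms: float = 2000.0,
    stim_duration_ms: float = 0.5,
    s_na: float = 1.0,
) -> float:
    """Exact qNet (uC/uF) of the paced periodic solution of the toy model.

    ``b`` is the (steady) hERG occupancy and ``scale`` the static
    conductance multipliers as used by :class:`~cipasim.models.DrugExposure`.
    """
    scale = scale or {}
    s = {c: scale.get(c, 1.0) for c in ("INaL", "ICaL", "IKs", "IK1", "Ito")}
    tau = TAU0 * (1.0 + KAPPA * b)
    drive = R0 * s_na
    lam1 = drive + 1.0 / tau
    w_inf = drive / lam1
    e1 = math.exp(-lam1 * stim_duration_ms)
    e2 = math.exp(-(cycle_length_ms - stim_duration_ms) / tau)
    w_peak = w_inf * (1.0 - e1) / (1.0 - e1 * e2)
    w0 = w_peak * e2
    int_stim = w_inf * stim_duration_ms + (w0 - w_inf) * (1.0 - e1) / lam1
    int_decay = w_peak * tau * (1.0 - e2)
    int_w = int_stim + int_decay
    g_net = (G_KR * (1.0 - b) + G_KS * s["IKs"] + G_K1 * s["IK1"]
             + G_TO * s["Ito"] - G_CAL * s["ICaL"] - G_NAL * s["INaL"])
    return g_net * int_w / 1000.0
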