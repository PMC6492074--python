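"""Optimized O'Hara–Rudy endocardial myocyte model with dynamic hERG drug binding.

The base electrophysiology is the published human endocardial ventricular
ORd formulation (41 states: voltage, 8 ionic concentrations, Hodgkin–Huxley
gates, CaMK and SR-release states), with the delayed-rectifier scaling
factors of the CiPA-optimized variant applied to INaL, ICaL, IKr, IKs and
IK1. The Hodgkin–Huxley IKr is replaced by a 9-state Markov scheme:

    closed row       C1 <-> C2 <-> O
    inactivated row  IC1 <-> IC2 <-> IO    (vertical pairs C*<->IC*, O<->IO)
    drug-bound       O <-> Obound, IO <-> IObound, both <-> Cbound (trapped)

Drug effects enter via five dynamic parameters (Kmax, Ku, n, halfmax,
Vhalf): association to the open/inactivated-open states at rate
``Kmax*Ku*D^n/(D^n+halfmax)``, first-order unbinding at ``Ku`` (scaled by
the inactivation equilibrium for the inactivated-bound state, i.e. the
drug unbinds more slowly while the channel is inactivated — trapping), and
voltage-dependent escape from the trapped closed-bound state governed by
``Vhalf``. Non-hERG drug effects are static conductance multipliers.

Integration: forward Euler for voltage, concentrations and Markov states
(Markov sub-stepped 4x), exact exponential (Rush–Larsen) updates for all
Hodgkin–Huxley gates. Default step 0.01 ms; the qNet metric is stable to
<0.1% under step halving (checked in the test suite).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from . import ModelSpec, register_model

# physical constants
F = 96485.0
R = 8314.0
T = 310.0
FRT = F / (R * T)

# geometry (ORd cell)
L_CELL = 0.01
RAD = 0.0011
VCELL = 1000.0 * 3.14 * RAD * RAD * L_CELL
AGEO = 2.0 * 3.14 * RAD * RAD + 2.0 * 3.14 * RAD * L_CELL
ACAP = 2.0 * AGEO
VMYO = 0.68 * VCELL
VNSR = 0.0552 * VCELL
VJSR = 0.0048 * VCELL
VSS = 0.02 * VCELL

# extracellular milieu (mM)
NAO = 140.0
CAO = 1.8
KO = 5.4

# delayed-rectifier / depolarizing-current rescaling of the optimized variant
SC_NAL = 2.661
SC_CAL = 1.007
SC_KR = 1.013
SC_KS = 1.870
SC_K1 = 1.698

# hERG Markov rate constants: rate = A*exp(B*v) * q**((37-20)/10)
_QPOW = 1.7
HERG_RATES = {
    # closed row: C1<->C2, C2<->O
    "a_c1c2": (0.0264, 4.631e-05, 4.843),
    "b_c1c2": (4.986e-06, -0.004226, 4.23),
    "a_c2o": (0.001214, 0.008516, 4.962),
    "b_c2o": (1.854e-05, -0.04641, 3.769),
    # inactivated row: IC1<->IC2, IC2<->IO
    "a_ic1ic2": (0.0007868, 1.535e-08, 4.942),
    "b_ic1ic2": (5.455e-06, -0.1688, 4.156),
    "a_ic2io": (0.005509, 7.771e-09, 4.22),
    "b_ic2io": (0.001416, -0.02877, 1.459),
    # inactivation columns: C1, C2, O
    "a_inac_c1": (0.4492, 0.008595, 5.0),
    "a_inac_c2": (0.3181, 3.613e-08, 4.663),
    "a_inac_o": (0.149, 0.004668, 2.412),
    "b_inac_c1": (0.01241, 0.1725, 5.568),
    "b_inac_c2": (0.3226, -0.0006575, 5.0),
    "b_inac_o": (0.008978, -0.02215, 5.682),
}


def _ab(name):
    a, b, q = HERG_RATES[name]
    return a * q ** _QPOW, b


A_C1C2, B_C1C2 = _ab("a_c1c2")
A2_C1C2, B2_C1C2 = _ab("b_c1c2")
A_C2O, B_C2O = _ab("a_c2o")
A2_C2O, B2_C2O = _ab("b_c2o")
A_I12, B_I12 = _ab("a_ic1ic2")
A2_I12, B2_I12 = _ab("b_ic1ic2")
A_I2O, B_I2O = _ab("a_ic2io")
A2_I2O, B2_I2O = _ab("b_ic2io")
AIN1, BIN1 = _ab("a_inac_c1")
AIN2, BIN2 = _ab("a_inac_c2")
AINO, BINO = _ab("a_inac_o")
BRE1, CRE1 = _ab("b_inac_c1")
BRE2, CRE2 = _ab("b_inac_c2")
BREO, CREO = _ab("b_inac_o")

KT_TRAP = 3.5e-5  # 1/ms, trapping rate between bound states
GKR = 0.046 * SC_KR

STATE_NAMES = (
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "hf", "hs", "j", "hsp", "jp", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xs1", "xs2", "xk1", "Jrelnp", "Jrelp", "CaMKt",
    "IC1", "IC2", "C1", "C2", "O", "IO", "IObound", "Obound", "Cbound",
)

NV = len(STATE_NAMES)  # 48


@njit(cache=True, inline="always")
def _rexp(u):
    # u / (exp(u) - 1), continuous through u = 0
    if -1e-7 < u < 1e-7:
        return 1.0 - 0.5 * u
    return u / math.expm1(u)


@njit(cache=True)
def _simulate(y0, pack, cl, n_beats, rec_beat, dt, stim_amp, stim_dur, rec_stride):
    kon = pack[0]
    ku = pack[1]
    vhalf = pack[2]
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

    rec_lo = rec_beat * spb
    rec_hi = rec_lo + spb

    for step in range(total + 1):
        v = y[0]
        nai = y[1]; nass = y[2]; ki = y[3]; kss = y[4]
        cai = y[5]; cass = y[6]; cansr = y[7]; cajsr = y[8]
        m = y[9]; hf = y[10]; hs = y[11]; jj = y[12]; hsp = y[13]; jp = y[14]
        mL = y[15]; hL = y[16]; hLp = y[17]
        a = y[18]; iF = y[19]; iS = y[20]; ap = y[21]; iFp = y[22]; iSp = y[23]
        d = y[24]; ff = y[25]; fs = y[26]; fcaf = y[27]; fcas = y[28]
        jca = y[29]; nca = y[30]; ffp = y[31]; fcafp = y[32]
        xs1 = y[33]; xs2 = y[34]; xk1 = y[35]
        Jrelnp = y[36]; Jrelp = y[37]; CaMKt = y[38]

        t_in_beat = (step % spb) * dt if step < total else 0.0
        istim = stim_amp if (step < total and t_in_beat < stim_dur) else 0.0

        # reversal potentials
        ENa = (1.0 / FRT) * math.log(NAO / nai)
        EK = (1.0 / FRT) * math.log(KO / ki)
        EKs = (1.0 / FRT) * math.log((KO + 0.01833 * NAO) / (ki + 0.01833 * nai))
        vfrt = v * FRT
        vffrt = v * F * FRT

        # CaMK
        CaMKb = 0.05 * (1.0 - CaMKt) / (1.0 + 0.0015 / cass)
        CaMKa = CaMKb + CaMKt
        fphos = 1.0 / (1.0 + 0.15 / CaMKa)

        # INa (fast)
        mss = 1.0 / (1.0 + math.exp(-(v + 39.57) / 9.871))
        tm = 1.0 / (6.765 * math.exp((v + 11.64) / 34.77)
                    + 8.552 * math.exp(-(v + 77.42) / 5.955))
        hss = 1.0 / (1.0 + math.exp((v + 82.90) / 6.086))
        thf = 1.0 / (1.432e-5 * math.exp(-(v + 1.196) / 6.285)
                     + 6.149 * math.exp((v + 0.5096) / 20.27))
        ths = 1.0 / (0.009794 * math.exp(-(v + 17.95) / 28.05)
                     + 0.3343 * math.exp((v + 5.730) / 56.66))
        h = 0.99 * hf + 0.01 * hs
        jss = hss
        tj = 2.038 + 1.0 / (0.02136 * math.exp(-(v + 100.6) / 8.281)
                            + 0.3052 * math.exp((v + 0.9941) / 38.45))
        hssp = 1.0 / (1.0 + math.exp((v + 89.1) / 6.086))
        thsp = 3.0 * ths
        hp = 0.99 * hf + 0.01 * hsp
        tjp = 1.46 * tj
        INa = (s_na * 75.0 * (v - ENa) * m ** 3
               * ((1.0 - fphos) * h * jj + fphos * hp * jp))

        # INaL
        mLss = 1.0 / (1.0 + math.exp(-(v + 42.85) / 5.264))
        tmL = tm
        hLss = 1.0 / (1.0 + math.exp((v + 87.61) / 7.488))
        thL = 200.0
        hLssp = 1.0 / (1.0 + math.exp((v + 93.81) / 7.488))
        thLp = 3.0 * thL
        GNaL = 0.0075 * SC_NAL * s_nal
        INaL = GNaL * (v - ENa) * mL * ((1.0 - fphos) * hL + fphos * hLp)

        # Ito (endo: no epicardial delta factor)
        ass = 1.0 / (1.0 + math.exp(-(v - 14.34) / 14.82))
        ta = 1.0515 / (1.0 / (1.2089 * (1.0 + math.exp(-(v - 18.4099) / 29.3814)))
                       + 3.5 / (1.0 + math.exp((v + 100.0) / 29.3814)))
        iss = 1.0 / (1.0 + math.exp((v + 43.94) / 5.711))
        tiF = 4.562 + 1.0 / (0.3933 * math.exp(-(v + 100.0) / 100.0)
                             + 0.08004 * math.exp((v + 50.0) / 16.59))
        tiS = 23.62 + 1.0 / (0.001416 * math.exp(-(v + 96.52) / 59.05)
                             + 1.780e-8 * math.exp((v + 114.1) / 8.079))
        AiF = 1.0 / (1.0 + math.exp((v - 213.6) / 151.2))
        AiS = 1.0 - AiF
        ii = AiF * iF + AiS * iS
        assp = 1.0 / (1.0 + math.exp(-(v - 24.34) / 14.82))
        dti_dev = 1.354 + 1.0e-4 / (math.exp((v - 167.4) / 15.89)
                                    + math.exp(-(v - 12.23) / 0.2154))
        dti_rec = 1.0 - 0.5 / (1.0 + math.exp((v + 70.0) / 20.0))
        tiFp = dti_dev * dti_rec * tiF
        tiSp = dti_dev * dti_rec * tiS
        iip = AiF * iFp + AiS * iSp
        Gto = 0.02 * s_to
        Ito = Gto * (v - EK) * ((1.0 - fphos) * a * ii + fphos * ap * iip)

        # ICaL / ICaNa / ICaK
        dss = 1.0 / (1.0 + math.exp(-(v + 3.940) / 4.230))
        td = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
        fss = 1.0 / (1.0 + math.exp((v + 19.58) / 3.696))
        tff = 7.0 + 1.0 / (0.0045 * math.exp(-(v + 20.0) / 10.0)
                           + 0.0045 * math.exp((v + 20.0) / 10.0))
        tfs = 1000.0 + 1.0 / (0.000035 * math.exp(-(v + 5.0) / 4.0)
                              + 0.000035 * math.exp((v + 5.0) / 6.0))
        f = 0.6 * ff + 0.4 * fs
        fcass_inf = fss
        tfcaf = 7.0 + 1.0 / (0.04 * math.exp(-(v - 4.0) / 7.0)
                             + 0.04 * math.exp((v - 4.0) / 7.0))
        tfcas = 100.0 + 1.0 / (0.00012 * math.exp(-v / 3.0)
                               + 0.00012 * math.exp(v / 7.0))
        Afcaf = 0.3 + 0.6 / (1.0 + math.exp((v - 10.0) / 10.0))
        Afcas = 1.0 - Afcaf
        fca = Afcaf * fcaf + Afcas * fcas
        tjca = 75.0
        tffp = 2.5 * tff
        fp = 0.6 * ffp + 0.4 * fs
        tfcafp = 2.5 * tfcaf
        fcap = Afcaf * fcafp + Afcas * fcas
        km2n = jca * 1.0
        anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / cass) ** 4)
        u2 = 2.0 * vfrt
        r2 = _rexp(u2)
        r1 = _rexp(vfrt)
        PhiCaL = 2.0 * F * r2 * (cass * math.exp(u2) - 0.341 * CAO)
        PhiCaNa = F * r1 * (0.75 * nass * math.exp(vfrt) - 0.75 * NAO)
        PhiCaK = F * r1 * (0.75 * kss * math.exp(vfrt) - 0.75 * KO)
        PCa = 0.0001 * SC_CAL * s_cal
        PCap = 1.1 * PCa
        PCaNa = 0.00125 * PCa
        PCaK = 3.574e-4 * PCa
        PCaNap = 0.00125 * PCap
        PCaKp = 3.574e-4 * PCap
        gate_np = d * (f * (1.0 - nca) + jca * fca * nca)
        gate_p = d * (fp * (1.0 - nca) + jca * fcap * nca)
        ICaL = (1.0 - fphos) * PCa * PhiCaL * gate_np + fphos * PCap * PhiCaL * gate_p
        ICaNa = ((1.0 - fphos) * PCaNa * PhiCaNa * gate_np
                 + fphos * PCaNap * PhiCaNa * gate_p)
        ICaK = ((1.0 - fphos) * PCaK * PhiCaK * gate_np
                + fphos * PCaKp * PhiCaK * gate_p)

        # IKr via Markov open probability
        O = y[43]
        IKr = GKR * math.sqrt(KO / 5.4) * O * (v - EK)

        # IKs
        xs1ss = 1.0 / (1.0 + math.exp(-(v + 11.60) / 8.932))
        txs1 = 817.3 + 1.0 / (2.326e-4 * math.exp((v + 48.28) / 17.80)
                              + 0.001292 * math.exp(-(v + 210.0) / 230.0))
        xs2ss = xs1ss
        txs2 = 1.0 / (0.01 * math.exp((v - 50.0) / 20.0)
                      + 0.0193 * math.exp(-(v + 66.54) / 31.0))
        KsCa = 1.0 + 0.6 / (1.0 + (3.8e-5 / cai) ** 1.4)
        IKs = 0.0034 * SC_KS * s_ks * KsCa * xs1 * xs2 * (v - EKs)

        # IK1
        xk1ss = 1.0 / (1.0 + math.exp(-(v + 2.5538 * KO + 144.59)
                                      / (1.5692 * KO + 3.8115)))
        txk1 = 122.2 / (math.exp(-(v + 127.2) / 20.36)
                        + math.exp((v + 236.8) / 69.33))
        rk1 = 1.0 / (1.0 + math.exp((v + 105.8 - 2.6 * KO) / 9.493))
        IK1 = 0.1908 * SC_K1 * s_k1 * math.sqrt(KO) * rk1 * xk1 * (v - EK)

        # INaCa (myoplasmic and subspace components)
        kna1 = 15.0; kna2 = 5.0; kna3 = 88.12
        kasymm = 12.5; wna = 6.0e4; wca = 6.0e4; wnaca = 5.0e3
        kcaon = 1.5e6; kcaoff = 5.0e3
        qna = 0.5224; qca = 0.1670
        hca = math.exp(qca * vfrt)
        hna = math.exp(qna * vfrt)
        # myoplasmic
        h1 = 1.0 + nai / kna3 * (1.0 + hna)
        h2 = (nai * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + nai / kna1 * (1.0 + nai / kna2)
        h5 = nai * nai / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        h7 = 1.0 + NAO / kna3 * (1.0 + 1.0 / hna)
        h8 = NAO / (kna3 * hna * h7)
        h9 = 1.0 / h7
        h10 = kasymm + 1.0 + NAO / kna1 * (1.0 + NAO / kna2)
        h11 = NAO * NAO / (h10 * kna1 * kna2)
        h12 = 1.0 / h10
        k1 = h12 * CAO * kcaon
        k2 = kcaoff
        k3p = h9 * wca
        k3pp = h8 * wnaca
        k3 = k3p + k3pp
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k5 = kcaoff
        k6 = h6 * cai * kcaon
        k7 = h5 * h2 * wna
        k8 = h8 * h11 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        KmCaAct = 150.0e-6
        allo = 1.0 / (1.0 + (KmCaAct / cai) ** 2)
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        Gncx = 0.0008
        INaCa_i = 0.8 * Gncx * allo * (JncxNa + 2.0 * JncxCa)
        # subspace
        h1 = 1.0 + nass / kna3 * (1.0 + hna)
        h2 = (nass * hna) / (kna3 * h1)
        h3 = 1.0 / h1
        h4 = 1.0 + nass / kna1 * (1.0 + nass / kna2)
        h5 = nass * nass / (h4 * kna1 * kna2)
        h6 = 1.0 / h4
        k4p = h3 * wca / hca
        k4pp = h2 * wnaca
        k4 = k4p + k4pp
        k6 = h6 * cass * kcaon
        k7 = h5 * h2 * wna
        x1 = k2 * k4 * (k7 + k6) + k5 * k7 * (k2 + k3)
        x2 = k1 * k7 * (k4 + k5) + k4 * k6 * (k1 + k8)
        x3 = k1 * k3 * (k7 + k6) + k8 * k6 * (k2 + k3)
        x4 = k2 * k8 * (k4 + k5) + k3 * k5 * (k1 + k8)
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        allo_ss = 1.0 / (1.0 + (KmCaAct / cass) ** 2)
        JncxNa = 3.0 * (E4 * k7 - E1 * k8) + E3 * k4pp - E2 * k3pp
        JncxCa = E2 * k2 - E1 * k1
        INaCa_ss = 0.2 * Gncx * allo_ss * (JncxNa + 2.0 * JncxCa)

        # INaK
        k1p = 949.5; k1m = 182.4; k2p = 687.2; k2m = 39.4
        k3pp_ = 1899.0; k3m = 79300.0; k4pp_ = 639.0; k4m = 40.0
        Knai = 9.073 * math.exp(-0.1550 * vfrt / 3.0)
        Knao = 27.78 * math.exp((1.0 + 0.1550) * vfrt / 3.0)
        Kki = 0.5; Kko = 0.3582
        MgADP = 0.05; MgATP = 9.8; Kmgatp = 1.698e-7
        H = 1.0e-7; eP = 4.2; Khp = 1.698e-7; Knap = 224.0; Kxkur = 292.0
        P = eP / (1.0 + H / Khp + nai / Knap + ki / Kxkur)
        a1 = (k1p * (nai / Knai) ** 3
              / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
        b1 = k1m * MgADP
        a2 = k2p
        b2 = (k2m * (NAO / Knao) ** 3
              / ((1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0))
        a3 = (k3pp_ * (KO / Kko) ** 2
              / ((1.0 + NAO / Knao) ** 3 + (1.0 + KO / Kko) ** 2 - 1.0))
        b3 = k3m * P * H / (1.0 + MgATP / Kmgatp)
        a4 = k4pp_ * MgATP / Kmgatp / (1.0 + MgATP / Kmgatp)
        b4 = (k4m * (ki / Kki) ** 2
              / ((1.0 + nai / Knai) ** 3 + (1.0 + ki / Kki) ** 2 - 1.0))
        x1 = a4 * a1 * a2 + b2 * b4 * b3 + a2 * b4 * b3 + b3 * a1 * a2
        x2 = b2 * b1 * b4 + a1 * a2 * a3 + a3 * b1 * b4 + a2 * a3 * b4
        x3 = a2 * a3 * a4 + b3 * b2 * b1 + b2 * b1 * a4 + a3 * a4 * b1
        x4 = b4 * b3 * b2 + a3 * a4 * a1 + b2 * a4 * a1 + b3 * b1 * a4
        E1 = x1 / (x1 + x2 + x3 + x4)
        E2 = x2 / (x1 + x2 + x3 + x4)
        E3 = x3 / (x1 + x2 + x3 + x4)
        E4 = x4 / (x1 + x2 + x3 + x4)
        JnakNa = 3.0 * (E1 * a3 - E2 * b3)
        JnakK = 2.0 * (E4 * b1 - E3 * a1)
        INaK = 30.0 * (JnakNa + JnakK)

        # background and pump currents
        xkb = 1.0 / (1.0 + math.exp(-(v - 14.48) / 18.34))
        IKb = 0.003 * xkb * (v - EK)
        INab = 3.75e-10 * F * r1 * (nai * math.exp(vfrt) - NAO)
        ICab = 2.5e-8 * 2.0 * F * r2 * (cai * math.exp(u2) - 0.341 * CAO)
        IpCa = 0.0005 * cai / (0.0005 + cai)

        # diffusion and SR fluxes
        JdiffNa = (nass - nai) / 2.0
        JdiffK = (kss - ki) / 2.0
        Jdiff = (cass - cai) / 0.2
        bt = 4.75
        a_rel = 0.5 * bt
        Jrel_inf = a_rel * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        tau_rel = bt / (1.0 + 0.0123 / cajsr)
        if tau_rel < 0.001:
            tau_rel = 0.001
        btp = 1.25 * bt
        a_relp = 0.5 * btp
        Jrel_infp = a_relp * (-ICaL) / (1.0 + (1.5 / cajsr) ** 8)
        tau_relp = btp / (1.0 + 0.0123 / cajsr)
        if tau_relp < 0.001:
            tau_relp = 0.001
        Jrel = (1.0 - fphos) * Jrelnp + fphos * Jrelp
        Jupnp = 0.004375 * cai / (cai + 0.00092)
        Jupp = 2.75 * 0.004375 * cai / (cai + 0.00092 - 0.00017)
        Jleak = 0.0039375 * cansr / 15.0
        Jup = (1.0 - fphos) * Jupnp + fphos * Jupp - Jleak
        Jtr = (cansr - cajsr) / 100.0

        # record
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
                cai_rec[k] = cai
                occ = 0.0
                for q in range(39, 48):
                    occ += y[q]
                occ_rec[k] = occ
                if not (v == v) or math.fabs(v) > 1.0e3:
                    status = 1
                    break

        if step == total:
            break
        if step == (n_beats - 1) * spb:
            y_prev = y.copy()

        # membrane potential (forward Euler)
        Itot = (INa + INaL + Ito + ICaL + ICaNa + ICaK + IKr + IKs + IK1
                + INaCa_i + INaCa_ss + INaK + INab + IKb + IpCa + ICab + istim)
        y[0] = v - dt * Itot

        # concentrations (forward Euler)
        y[1] = nai + dt * (-(INa + INaL + 3.0 * INaCa_i + 3.0 * INaK + INab)
                           * ACAP / (F * VMYO) + JdiffNa * VSS / VMYO)
        y[2] = nass + dt * (-(ICaNa + 3.0 * INaCa_ss) * ACAP / (F * VSS) - JdiffNa)
        y[3] = ki + dt * (-(Ito + IKr + IKs + IK1 + IKb + istim - 2.0 * INaK)
                          * ACAP / (F * VMYO) + JdiffK * VSS / VMYO)
        y[4] = kss + dt * (-ICaK * ACAP / (F * VSS) - JdiffK)
        Bcai = 1.0 / (1.0 + 0.05 * 0.00238 / (0.00238 + cai) ** 2
                      + 0.07 * 0.0005 / (0.0005 + cai) ** 2)
        y[5] = cai + dt * Bcai * (
            -(IpCa + ICab - 2.0 * INaCa_i) * ACAP / (2.0 * F * VMYO)
            - Jup * VNSR / VMYO + Jdiff * VSS / VMYO)
        Bcass = 1.0 / (1.0 + 0.047 * 0.00087 / (0.00087 + cass) ** 2
                       + 1.124 * 0.0087 / (0.0087 + cass) ** 2)
        y[6] = cass + dt * Bcass * (
            -(ICaL - 2.0 * INaCa_ss) * ACAP / (2.0 * F * VSS)
            + Jrel * VJSR / VSS - Jdiff)
        y[7] = cansr + dt * (Jup - Jtr * VJSR / VNSR)
        Bcajsr = 1.0 / (1.0 + 10.0 * 0.8 / (0.8 + cajsr) ** 2)
        y[8] = cajsr + dt * Bcajsr * (Jtr - Jrel)

        # Hodgkin-Huxley gates (Rush-Larsen exact exponential updates)
        y[9] = mss + (m - mss) * math.exp(-dt / tm)
        y[10] = hss + (hf - hss) * math.exp(-dt / thf)
        y[11] = hss + (hs - hss) * math.exp(-dt / ths)
        y[12] = jss + (jj - jss) * math.exp(-dt / tj)
        y[13] = hssp + (hsp - hssp) * math.exp(-dt / thsp)
        y[14] = jss + (jp - jss) * math.exp(-dt / tjp)
        y[15] = mLss + (mL - mLss) * math.exp(-dt / tmL)
        y[16] = hLss + (hL - hLss) * math.exp(-dt / thL)
        y[17] = hLssp + (hLp - hLssp) * math.exp(-dt / thLp)
        y[18] = ass + (a - ass) * math.exp(-dt / ta)
        y[19] = iss + (iF - iss) * math.exp(-dt / tiF)
        y[20] = iss + (iS - iss) * math.exp(-dt / tiS)
        y[21] = assp + (ap - assp) * math.exp(-dt / ta)
        y[22] = iss + (iFp - iss) * math.exp(-dt / tiFp)
        y[23] = iss + (iSp - iss) * math.exp(-dt / tiSp)
        y[24] = dss + (d - dss) * math.exp(-dt / td)
        y[25] = fss + (ff - fss) * math.exp(-dt / tff)
        y[26] = fss + (fs - fss) * math.exp(-dt / tfs)
        y[27] = fcass_inf + (fcaf - fcass_inf) * math.exp(-dt / tfcaf)
        y[28] = fcass_inf + (fcas - fcass_inf) * math.exp(-dt / tfcas)
        y[29] = fcass_inf + (jca - fcass_inf) * math.exp(-dt / tjca)
        y[30] = nca + dt * (anca * 1000.0 - nca * km2n)
        y[31] = fss + (ffp - fss) * math.exp(-dt / tffp)
        y[32] = fcass_inf + (fcafp - fcass_inf) * math.exp(-dt / tfcafp)
        y[33] = xs1ss + (xs1 - xs1ss) * math.exp(-dt / txs1)
        y[34] = xs2ss + (xs2 - xs2ss) * math.exp(-dt / txs2)
        y[35] = xk1ss + (xk1 - xk1ss) * math.exp(-dt / txk1)
        y[36] = Jrel_inf + (Jrelnp - Jrel_inf) * math.exp(-dt / tau_rel)
        y[37] = Jrel_infp + (Jrelp - Jrel_infp) * math.exp(-dt / tau_relp)
        y[38] = CaMKt + dt * (0.05 * CaMKb * (CaMKb + CaMKt) - 0.00068 * CaMKt)

        # hERG Markov scheme (forward Euler, 4 substeps); conservation holds
        # exactly because every flux appears once with each sign
        a12c = A_C1C2 * math.exp(B_C1C2 * v)
        b12c = A2_C1C2 * math.exp(B2_C1C2 * v)
        a2oc = A_C2O * math.exp(B_C2O * v)
        b2oc = A2_C2O * math.exp(B2_C2O * v)
        a12i = A_I12 * math.exp(B_I12 * v)
        b12i = A2_I12 * math.exp(B2_I12 * v)
        a2oi = A_I2O * math.exp(B_I2O * v)
        b2oi = A2_I2O * math.exp(B2_I2O * v)
        ain1 = AIN1 * math.exp(BIN1 * v)
        bin1 = BRE1 * math.exp(CRE1 * v)
        ain2 = AIN2 * math.exp(BIN2 * v)
        bin2 = BRE2 * math.exp(CRE2 * v)
        aino = AINO * math.exp(BINO * v)
        bino = BREO * math.exp(CREO * v)
        ku_io = ku * bino / aino  # trapping: slower unbinding while inactivated
        krel = KT_TRAP / (1.0 + math.exp(-(v - vhalf) / 6.789))
        dtm = dt / 4.0
        for _ in range(4):
            IC1 = y[39]; IC2 = y[40]; C1 = y[41]; C2 = y[42]
            O_ = y[43]; IO = y[44]; IOb = y[45]; Ob = y[46]; Cb = y[47]
            f_c12 = a12c * C1 - b12c * C2
            f_c2o = a2oc * C2 - b2oc * O_
            f_i12 = a12i * IC1 - b12i * IC2
            f_i2o = a2oi * IC2 - b2oi * IO
            f_in1 = ain1 * C1 - bin1 * IC1
            f_in2 = ain2 * C2 - bin2 * IC2
            f_ino = aino * O_ - bino * IO
            f_bo = kon * O_ - ku * Ob
            f_bio = kon * IO - ku_io * IOb
            f_tro = KT_TRAP * Ob - krel * Cb
            f_trio = KT_TRAP * IOb - krel * Cb
            y[39] = IC1 + dtm * (f_in1 - f_i12)
            y[40] = IC2 + dtm * (f_in2 + f_i12 - f_i2o)
            y[41] = C1 + dtm * (-f_c12 - f_in1)
            y[42] = C2 + dtm * (f_c12 - f_c2o - f_in2)
            y[43] = O_ + dtm * (f_c2o - f_ino - f_bo)
            y[44] = IO + dtm * (f_ino + f_i2o - f_bio)
            y[45] = IOb + dtm * (f_bio - f_trio)
            y[46] = Ob + dtm * (f_bo - f_tro)
            y[47] = Cb + dtm * (f_tro + f_trio)

    return status, t_rec, v_rec, cur_rec, cai_rec, occ_rec, y, y_prev


# Paced resting state: the model's own drug-free steady state after 1000
# beats at cycle length 2000 ms (stimulus -80 uA/uF for 0.5 ms), stored as
# the initial-condition table. Regenerate with
# ``python -m cipasim.models.ord`` after any change to the equations.
INITIAL_VALUES = np.array([
    -8.80099297904034e+01,  # v
     6.44609287120855e+00,  # nai
     6.44615186353979e+00,  # nass
     1.45485014205131e+02,  # ki
     1.45484997325003e+02,  # kss
     7.40857775462649e-05,  # cai
     7.26195590523925e-05,  # cass
     1.36940046492090e+00,  # cansr
     1.36981852446713e+00,  # cajsr
     7.33819512329475e-03,  # m
     6.98385261739008e-01,  # hf
     6.98385166880206e-01,  # hs
     6.98384535692295e-01,  # j
     4.55341169344468e-01,  # hsp
     6.98384041864607e-01,  # jp
     1.87974920040000e-04,  # mL
     5.13242231254226e-01,  # hL
     3.07666194414468e-01,  # hLp
     1.00055131519175e-03,  # a
     9.99554858930758e-01,  # iF
     8.71082187856269e-01,  # iS
     5.09807765380747e-04,  # ap
     9.99554858974729e-01,  # iFp
     9.04844163931315e-01,  # iSp
     2.33632227928304e-09,  # d
     9.99999990896319e-01,  # ff
     9.71524887171258e-01,  # fs
     9.99999990896320e-01,  # fcaf
     9.99999977705252e-01,  # fcas
     9.99999990837744e-01,  # jca
     1.50480847382756e-03,  # nca
     9.99999990896259e-01,  # ffp
     9.99999990896262e-01,  # fcafp
     1.32159796921613e-01,  # xs1
     1.92614880203311e-04,  # xs2
     9.96757259729809e-01,  # xk1
     1.41245496807282e-07,  # Jrelnp
     1.76555834343501e-07,  # Jrelp
     3.19685145649733e-03,  # CaMKt
     9.99546605768072e-01,  # IC1
     6.83669820491437e-05,  # IC2
     1.80346594422944e-08,  # C1
     8.30820119997873e-05,  # C2
     2.20221491456473e-04,  # O
     8.17057134490924e-05,  # IO
     0.00000000000000e+00,  # IObound
     0.00000000000000e+00,  # Obound
     0.00000000000000e+00,  # Cbound
])


SPEC = register_model(ModelSpec(
    model_id="cipaordv1.0",
    state_names=STATE_NAMES,
    initial_values=INITIAL_VALUES,
    simulate=_simulate,
    default_dt_ms=0.01,
    default_record_dt_ms=1.0,
    description="Optimized ORd endocardial myocyte with dynamic hERG drug binding",
))


def _regenerate_initial_values(n_beats=1000):  # pragma: no cover - maintenance tool
    """Re-pace the drug-free model and print an initial-condition table."""
    from . import PacingProtocol, run_to_steady_state

    proto = PacingProtocol(n_beats=n_beats)
    trace = run_to_steady_state("cipaordv1.0", proto)
    y = trace.meta["final_state"].values
    for name, val in zip(STATE_NAMES, y):
        print(f"    {val: .14e},  # {name}")
    print("convergence:", trace.meta["beat_convergence"])


if __name__ == "__main__":  # pragma: no cover
    _regenerate_initial_values()
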