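"""Courtemanche–Ramirez–Nattel (1998) human atrial membrane model.

Reference right-hand side plus fast table-driven integration kernels.

The model has 21 states laid out as::

    0  V      transmembrane voltage            mV
    1  m      INa activation
    2  h      INa fast inactivation
    3  j      INa slow inactivation
    4  oa     Ito activation
    5  oi     Ito inactivation
    6  ua     IKur activation
    7  ui     IKur inactivation
    8  xr     IKr activation
    9  xs     IKs activation
    10 d      ICaL activation
    11 f      ICaL voltage inactivation
    12 fca    ICaL calcium inactivation
    13 u      RyR activation
    14 v      RyR inactivation
    15 w      RyR voltage inactivation
    16 Nai    intracellular sodium             mM
    17 Ki     intracellular potassium          mM
    18 Cai    intracellular calcium            mM
    19 Caup   network SR (uptake) calcium      mM
    20 Carel  junctional SR (release) calcium  mM

Maximal conductances/fluxes are passed as a 13-vector ``cond`` (see
``COND_NAMES``); entry ``gKur`` is a dimensionless multiplier on the
voltage-dependent ultrarapid conductance.  Chronic-AF electrical
remodeling (Courtemanche et al. 1999) is applied on top of the control
values: Ito −50%, ICaL −70%, IK1 +100%.

Two integration paths are provided and must agree to discretisation
error: ``derivatives`` (plain NumPy, the readable reference used by
tests and oracles) and the numba kernels (Rush–Larsen for gates,
forward Euler for voltage and concentrations, with all voltage-dependent
quantities pre-tabulated on a 0.02 mV grid).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .errors import ValidationError

N_STATES = 21

# physical constants
R_GAS = 8.3143      # J/(mol*K)
TEMP = 310.0        # K
FARADAY = 96.4867   # C/mmol
RTF = R_GAS * TEMP / FARADAY

CM = 100.0          # pF
V_CELL = 20100.0    # um^3
V_I = 13668.0
V_UP = 1109.52
V_REL = 96.48

KO = 5.4            # mM
NAO = 140.0
CAO = 1.8

# buffers / SR
TRPN_MAX = 0.070
KM_TRPN = 0.0005
CMDN_MAX = 0.050
KM_CMDN = 0.00238
CSQN_MAX = 10.0
KM_CSQN = 0.8
CA_UP_MAX = 15.0
K_REL = 30.0
K_UP = 0.00092
TAU_TR = 180.0
TAU_U = 8.0
TAU_FCA = 2.0

SIGMA_NAK = (math.exp(NAO / 67.3) - 1.0) / 7.0
KM_NAI = 10.0
KM_KO = 1.5
KM_NA_NCX = 87.5
KM_CA_NCX = 1.38
KSAT_NCX = 0.1
GAMMA_NCX = 0.35
NAO3 = NAO ** 3
NCX_DENOM = (KM_NA_NCX ** 3 + NAO3) * (KM_CA_NCX + CAO)

COND_NAMES = (
    "gNa", "gCaL", "gto", "gKur", "gKr", "gKs", "gK1",
    "gNaK", "gNaCa", "gCaP", "gup", "gbCa", "gbNa",
)

#: control (sinus-rhythm) maximal conductances/fluxes, order of COND_NAMES.
#: gKur is a multiplier on the voltage-dependent expression; gNaK/gNaCa/gCaP
#: are the pump/exchanger maxima (pA/pF except gNaCa), gup the SERCA maximum
#: (mM/ms).
CONTROL_COND = np.array([
    7.8,          # gNa        nS/pF
    0.12375,      # gCaL       nS/pF
    0.1652,       # gto        nS/pF
    1.0,          # gKur       multiplier
    0.029411765,  # gKr        nS/pF
    0.12941176,   # gKs        nS/pF
    0.09,         # gK1        nS/pF
    0.59933874,   # INaK max   pA/pF
    1600.0,       # INaCa max  pA/pF
    0.275,        # ICaP max   pA/pF
    0.005,        # Iup max    mM/ms
    0.001131,     # gbCa       nS/pF
    0.0006744375, # gbNa       nS/pF
])

#: chronic-AF ionic remodeling multipliers (Courtemanche et al. 1999).
AF_REMODEL = {"gto": 0.5, "gCaL": 0.3, "gK1": 2.0}


def af_baseline_cond() -> np.ndarray:
    """Chronic-AF remodeled maximal conductances (the baseline AF cell)."""
    cond = CONTROL_COND.copy()
    for name, factor in AF_REMODEL.items():
        cond[COND_NAMES.index(name)] *= factor
    return cond


def initial_state() -> np.ndarray:
    """Published control resting state; adequate start for all variants."""
    return np.array([
        -81.18,      # V
        2.908e-3,    # m
        9.649e-1,    # h
        9.775e-1,    # j
        3.043e-2,    # oa
        9.992e-1,    # oi
        4.966e-3,    # ua
        9.986e-1,    # ui
        3.296e-5,    # xr
        1.869e-2,    # xs
        1.367e-4,    # d
        9.996e-1,    # f
        7.755e-1,    # fca
        0.0,         # u
        1.0,         # v
        9.992e-1,    # w
        1.117e1,     # Nai
        1.390e2,     # Ki
        1.013e-4,    # Cai
        1.488,       # Caup
        1.488,       # Carel
    ])


def _safe_div(num, den, lim):
    """num/den with the removable-singularity limit substituted at den≈0."""
    return lim if abs(den) < 1e-10 else num / den


def gate_rates(v: float) -> dict:
    """Steady states and time constants (ms) of the 12 voltage-dependent gates."""
    out = {}

    # INa (Luo-Rudy style alpha/beta)
    a_m = _safe_div(0.32 * (v + 47.13), 1.0 - math.exp(-0.1 * (v + 47.13)), 3.2)
    b_m = 0.08 * math.exp(-v / 11.0)
    if v >= -40.0:
        a_h = 0.0
        b_h = 1.0 / (0.13 * (1.0 + math.exp(-(v + 10.66) / 11.1)))
        a_j = 0.0
        b_j = 0.3 * math.exp(-2.535e-7 * v) / (1.0 + math.exp(-0.1 * (v + 32.0)))
    else:
        a_h = 0.135 * math.exp(-(v + 80.0) / 6.8)
        b_h = 3.56 * math.exp(0.079 * v) + 3.1e5 * math.exp(0.35 * v)
        a_j = ((-1.2714e5 * math.exp(0.2444 * v) - 3.474e-5 * math.exp(-0.04391 * v))
               * (v + 37.78) / (1.0 + math.exp(0.311 * (v + 79.23))))
        b_j = 0.1212 * math.exp(-0.01052 * v) / (1.0 + math.exp(-0.1378 * (v + 40.14)))
    for name, a, b in (("m", a_m, b_m), ("h", a_h, b_h), ("j", a_j, b_j)):
        out[name] = (a / (a + b), 1.0 / (a + b))

    kq10 = 3.0
    # Ito
    a_oa = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_oa = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    out["oa"] = (1.0 / (1.0 + math.exp(-(v + 20.47) / 17.54)),
                 1.0 / ((a_oa + b_oa) * kq10))
    a_oi = 1.0 / (18.53 + math.exp((v + 113.7) / 10.95))
    b_oi = 1.0 / (35.56 + math.exp(-(v + 1.26) / 7.44))
    out["oi"] = (1.0 / (1.0 + math.exp((v + 43.1) / 5.3)),
                 1.0 / ((a_oi + b_oi) * kq10))

    # IKur
    a_ua = 0.65 / (math.exp(-(v + 10.0) / 8.5) + math.exp(-(v - 30.0) / 59.0))
    b_ua = 0.65 / (2.5 + math.exp((v + 82.0) / 17.0))
    out["ua"] = (1.0 / (1.0 + math.exp(-(v + 30.3) / 9.6)),
                 1.0 / ((a_ua + b_ua) * kq10))
    a_ui = 1.0 / (21.0 + math.exp(-(v - 185.0) / 28.0))
    b_ui = math.exp((v - 158.0) / 16.0)
    out["ui"] = (1.0 / (1.0 + math.exp((v - 99.45) / 27.48)),
                 1.0 / ((a_ui + b_ui) * kq10))

    # IKr / IKs
    a_xr = _safe_div(0.0003 * (v + 14.1), 1.0 - math.exp(-(v + 14.1) / 5.0), 0.0015)
    b_xr = _safe_div(7.3898e-5 * (v - 3.3328),
                     math.exp((v - 3.3328) / 5.1237) - 1.0, 3.7862e-4)
    out["xr"] = (1.0 / (1.0 + math.exp(-(v + 14.1) / 6.5)), 1.0 / (a_xr + b_xr))
    a_xs = _safe_div(4e-5 * (v - 19.9), 1.0 - math.exp(-(v - 19.9) / 17.0), 6.8e-4)
    b_xs = _safe_div(3.5e-5 * (v - 19.9), math.exp((v - 19.9) / 9.0) - 1.0, 3.15e-4)
    out["xs"] = ((1.0 + math.exp(-(v - 19.9) / 12.7)) ** -0.5,
                 0.5 / (a_xs + b_xs))

    # ICaL
    e_d = math.exp(-(v + 10.0) / 6.24)
    tau_d = _safe_div((1.0 - e_d), 0.035 * (v + 10.0) * (1.0 + e_d), 2.2898)
    out["d"] = (1.0 / (1.0 + math.exp(-(v + 10.0) / 8.0)), tau_d)
    out["f"] = (1.0 / (1.0 + math.exp((v + 28.0) / 6.9)),
                9.0 / (0.0197 * math.exp(-(0.0337 ** 2) * (v + 10.0) ** 2) + 0.02))

    # RyR voltage gate
    e_w = math.exp(-(v - 7.9) / 5.0)
    tau_w = _safe_div(6.0 * (1.0 - e_w), (1.0 + 0.3 * e_w) * (v - 7.9), 6.0 / 1.3)
    out["w"] = (1.0 - 1.0 / (1.0 + math.exp(-(v - 40.0) / 17.0)), tau_w)
    return out


def currents(state: np.ndarray, cond: np.ndarray) -> dict:
    """All membrane currents (pA/pF) and SR fluxes (mM/ms) at a state."""
    (v, m, h, j, oa, oi, ua, ui, xr, xs, d, f, fca,
     u, vv, w, nai, ki, cai, caup, carel) = state

    ena = RTF * math.log(NAO / nai)
    ek = RTF * math.log(KO / ki)
    eca = 0.5 * RTF * math.log(CAO / cai)

    i = {}
    i["INa"] = cond[0] * m ** 3 * h * j * (v - ena)
    i["IK1"] = cond[6] * (v - ek) / (1.0 + math.exp(0.07 * (v + 80.0)))
    i["Ito"] = cond[2] * oa ** 3 * oi * (v - ek)
    gkur = cond[3] * (0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0)))
    i["IKur"] = gkur * ua ** 3 * ui * (v - ek)
    i["IKr"] = cond[4] * xr * (v - ek) / (1.0 + math.exp((v + 15.0) / 22.4))
    i["IKs"] = cond[5] * xs ** 2 * (v - ek)
    i["ICaL"] = cond[1] * d * f * fca * (v - 65.0)

    fnak = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                  + 0.0365 * SIGMA_NAK * math.exp(-v / RTF))
    i["INaK"] = (cond[7] * fnak * KO / (KO + KM_KO)
                 / (1.0 + (KM_NAI / nai) ** 1.5))
    e1 = math.exp(GAMMA_NCX * v / RTF)
    e2 = math.exp((GAMMA_NCX - 1.0) * v / RTF)
    i["INaCa"] = (cond[8] * (e1 * nai ** 3 * CAO - e2 * NAO ** 3 * cai)
                  / ((KM_NA_NCX ** 3 + NAO ** 3) * (KM_CA_NCX + CAO)
                     * (1.0 + KSAT_NCX * e2)))
    i["ICaP"] = cond[9] * cai / (0.0005 + cai)
    i["IbNa"] = cond[12] * (v - ena)
    i["IbCa"] = cond[11] * (v - eca)

    i["Iup"] = cond[10] / (1.0 + K_UP / cai)
    i["Iupleak"] = cond[10] * caup / CA_UP_MAX
    i["Itr"] = (caup - carel) / TAU_TR
    i["Irel"] = K_REL * u ** 2 * vv * w * (carel - cai)
    return i


def derivatives(state: np.ndarray, cond: np.ndarray, stim: float = 0.0) -> np.ndarray:
    """Reference d(state)/dt.

    Parameters
    ----------
    state : (21,) array satisfying the state invariants.
    cond : (13,) maximal conductance vector (see ``COND_NAMES``).
    stim : external stimulus current density (pA/pF, depolarizing positive).
    """
    if not np.all(np.isfinite(state)):
        bad = int(np.flatnonzero(~np.isfinite(state))[0])
        raise FloatingPointError(f"non-finite state variable index {bad}")
    if np.any(state[1:16] < -1e-9) or np.any(state[1:16] > 1.0 + 1e-9):
        bad = 1 + int(np.flatnonzero((state[1:16] < -1e-9)
                                     | (state[1:16] > 1.0 + 1e-9))[0])
        raise ValidationError(f"gating variable index {bad} outside [0, 1]")

    v = state[0]
    cai, carel = state[18], state[20]
    i = currents(state, cond)
    d = np.empty(N_STATES)

    i_ion = (i["INa"] + i["IK1"] + i["Ito"] + i["IKur"] + i["IKr"] + i["IKs"]
             + i["ICaL"] + i["INaK"] + i["INaCa"] + i["ICaP"] + i["IbNa"]
             + i["IbCa"])
    d[0] = -(i_ion - stim)

    rates = gate_rates(v)
    for idx, name in ((1, "m"), (2, "h"), (3, "j"), (4, "oa"), (5, "oi"),
                      (6, "ua"), (7, "ui"), (8, "xr"), (9, "xs"), (10, "d"),
                      (11, "f"), (15, "w")):
        inf, tau = rates[name]
        d[idx] = (inf - state[idx]) / tau

    fca_inf = 1.0 / (1.0 + cai / 0.00035)
    d[12] = (fca_inf - state[12]) / TAU_FCA

    fn = 1e3 * (1e-15 * V_REL * i["Irel"]
                - 1e-15 / (2.0 * FARADAY) * (0.5 * i["ICaL"] - 0.2 * i["INaCa"]) * CM)
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    d[13] = (u_inf - state[13]) / TAU_U
    d[14] = (v_inf - state[14]) / tau_v

    d[16] = (-3.0 * i["INaK"] - 3.0 * i["INaCa"] - i["IbNa"] - i["INa"]) * CM / (FARADAY * V_I)
    d[17] = (2.0 * i["INaK"] - i["IK1"] - i["Ito"] - i["IKur"] - i["IKr"]
             - i["IKs"]) * CM / (FARADAY * V_I)

    b1 = ((2.0 * i["INaCa"] - i["ICaP"] - i["ICaL"] - i["IbCa"]) * CM
          / (2.0 * FARADAY * V_I)
          + (V_UP * (i["Iupleak"] - i["Iup"]) + i["Irel"] * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
    d[18] = b1 / b2
    d[19] = i["Iup"] - i["Iupleak"] - i["Itr"] * V_REL / V_UP
    d[20] = ((i["Itr"] - i["Irel"])
             / (1.0 + CSQN_MAX * KM_CSQN / (carel + KM_CSQN) ** 2))
    return d


# ---------------------------------------------------------------------------
# Table-driven kernels
# ---------------------------------------------------------------------------
# Columns of the lookup table, tabulated on a uniform voltage grid:
#   0..23  (inf, exp(-dt/tau)) for the 12 voltage gates in the order
#          m h j oa oi ua ui xr xs d f w
#   24     IK1 rectification factor 1/(1+exp(0.07(V+80)))
#   25     gKur(V) voltage-dependent conductance
#   26     IKr rectification 1/(1+exp((V+15)/22.4))
#   27     INaK voltage factor fNaK
#   28     exp(gamma V F/RT)
#   29     exp((gamma-1) V F/RT)
N_TAB = 30
GATE_IDX = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 15)

TAB_VMIN = -110.0
TAB_VMAX = 70.0
TAB_DV = 0.02


def build_tables(dt: float) -> np.ndarray:
    """Tabulate voltage-dependent model quantities for step size ``dt`` (ms)."""
    vgrid = np.arange(TAB_VMIN, TAB_VMAX + TAB_DV / 2, TAB_DV)
    tab = np.empty((vgrid.size, N_TAB))
    names = ("m", "h", "j", "oa", "oi", "ua", "ui", "xr", "xs", "d", "f", "w")
    for k, v in enumerate(vgrid):
        rates = gate_rates(v)
        for g, name in enumerate(names):
            inf, tau = rates[name]
            tab[k, 2 * g] = inf
            tab[k, 2 * g + 1] = math.exp(-dt / tau)
        tab[k, 24] = 1.0 / (1.0 + math.exp(0.07 * (v + 80.0)))
        tab[k, 25] = 0.005 + 0.05 / (1.0 + math.exp(-(v - 15.0) / 13.0))
        tab[k, 26] = 1.0 / (1.0 + math.exp((v + 15.0) / 22.4))
        tab[k, 27] = 1.0 / (1.0 + 0.1245 * math.exp(-0.1 * v / RTF)
                            + 0.0365 * SIGMA_NAK * math.exp(-v / RTF))
        tab[k, 28] = math.exp(GAMMA_NCX * v / RTF)
        tab[k, 29] = math.exp((GAMMA_NCX - 1.0) * v / RTF)
    return tab


@njit(cache=True, inline="always", fastmath=True)
def _react_node(s, k, dt, cond, tab, exp_dt_fca, exp_dt_u, istim):
    """One Rush–Larsen/Euler reaction step of node row k. Returns dV."""
    v = s[k, 0]
    # table lookup with linear interpolation; clamp to grid
    x = (v - TAB_VMIN) / TAB_DV
    if x < 0.0:
        x = 0.0
    elif x > tab.shape[0] - 1.001:
        x = tab.shape[0] - 1.001
    i0 = int(x)
    wgt = x - i0

    nai = s[k, 16]
    ki = s[k, 17]
    cai = s[k, 18]
    caup = s[k, 19]
    carel = s[k, 20]

    ena = RTF * math.log(NAO / nai)
    ek = RTF * math.log(KO / ki)
    eca = 0.5 * RTF * math.log(CAO / cai)

    t24 = tab[i0, 24] + wgt * (tab[i0 + 1, 24] - tab[i0, 24])
    t25 = tab[i0, 25] + wgt * (tab[i0 + 1, 25] - tab[i0, 25])
    t26 = tab[i0, 26] + wgt * (tab[i0 + 1, 26] - tab[i0, 26])
    t27 = tab[i0, 27] + wgt * (tab[i0 + 1, 27] - tab[i0, 27])
    t28 = tab[i0, 28] + wgt * (tab[i0 + 1, 28] - tab[i0, 28])
    t29 = tab[i0, 29] + wgt * (tab[i0 + 1, 29] - tab[i0, 29])

    m_ = s[k, 1]
    ina = cond[0] * m_ * m_ * m_ * s[k, 2] * s[k, 3] * (v - ena)
    ik1 = cond[6] * (v - ek) * t24
    oa_ = s[k, 4]
    ito = cond[2] * oa_ * oa_ * oa_ * s[k, 5] * (v - ek)
    ua_ = s[k, 6]
    ikur = cond[3] * t25 * ua_ * ua_ * ua_ * s[k, 7] * (v - ek)
    ikr = cond[4] * s[k, 8] * (v - ek) * t26
    iks = cond[5] * s[k, 9] * s[k, 9] * (v - ek)
    ical = cond[1] * s[k, 10] * s[k, 11] * s[k, 12] * (v - 65.0)
    rna = KM_NAI / nai
    inak = cond[7] * t27 * KO / (KO + KM_KO) / (1.0 + rna * math.sqrt(rna))
    nai3 = nai * nai * nai
    inaca = (cond[8] * (t28 * nai3 * CAO - t29 * NAO3 * cai)
             / ((KM_NA_NCX ** 3 + NAO ** 3) * (KM_CA_NCX + CAO)
                * (1.0 + KSAT_NCX * t29)))
    icap = cond[9] * cai / (0.0005 + cai)
    ibna = cond[12] * (v - ena)
    ibca = cond[11] * (v - eca)

    iup = cond[10] / (1.0 + K_UP / cai)
    iupleak = cond[10] * caup / CA_UP_MAX
    itr = (caup - carel) / TAU_TR
    u_ = s[k, 13]
    irel = K_REL * u_ * u_ * s[k, 14] * s[k, 15] * (carel - cai)

    # voltage gates: Rush–Larsen using tabulated inf and exp(-dt/tau)
    for g in range(12):
        inf = tab[i0, 2 * g] + wgt * (tab[i0 + 1, 2 * g] - tab[i0, 2 * g])
        ex = tab[i0, 2 * g + 1] + wgt * (tab[i0 + 1, 2 * g + 1] - tab[i0, 2 * g + 1])
        idx = GATE_IDX[g]
        s[k, idx] = inf + (s[k, idx] - inf) * ex

    # calcium/flux-dependent gates
    fca_inf = 1.0 / (1.0 + cai / 0.00035)
    s[k, 12] = fca_inf + (s[k, 12] - fca_inf) * exp_dt_fca
    fn = 1e3 * (1e-15 * V_REL * irel
                - 1e-15 / (2.0 * FARADAY) * (0.5 * ical - 0.2 * inaca) * CM)
    u_inf = 1.0 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    v_inf = 1.0 - 1.0 / (1.0 + math.exp(-(fn - 6.835e-14) / 13.67e-16))
    tau_v = 1.91 + 2.09 / (1.0 + math.exp(-(fn - 3.4175e-13) / 13.67e-16))
    s[k, 13] = u_inf + (s[k, 13] - u_inf) * exp_dt_u
    s[k, 14] = v_inf + (s[k, 14] - v_inf) * math.exp(-dt / tau_v)

    # concentrations: forward Euler
    s[k, 16] = nai + dt * ((-3.0 * inak - 3.0 * inaca - ibna - ina) * CM
                           / (FARADAY * V_I))
    s[k, 17] = ki + dt * ((2.0 * inak - ik1 - ito - ikur - ikr - iks) * CM
                          / (FARADAY * V_I))
    b1 = ((2.0 * inaca - icap - ical - ibca) * CM / (2.0 * FARADAY * V_I)
          + (V_UP * (iupleak - iup) + irel * V_REL) / V_I)
    b2 = (1.0 + TRPN_MAX * KM_TRPN / (cai + KM_TRPN) ** 2
          + CMDN_MAX * KM_CMDN / (cai + KM_CMDN) ** 2)
    s[k, 18] = cai + dt * b1 / b2
    s[k, 19] = caup + dt * (iup - iupleak - itr * V_REL / V_UP)
    s[k, 20] = carel + dt * ((itr - irel)
                             / (1.0 + CSQN_MAX * KM_CSQN / (carel + KM_CSQN) ** 2))

    i_ion = (ina + ik1 + ito + ikur + ikr + iks + ical + inak + inaca + icap
             + ibna + ibca)
    return dt * (istim - i_ion)


@njit(cache=True, fastmath=True)
def run_cell(state, dt, n_steps, cond, tab, stim_start, stim_period_steps,
             stim_dur_steps, stim_amp, record_every):
    """Paced single-cell run; records V every ``record_every`` steps.

    ``state`` (1, 21) is advanced in place; returns the voltage trace
    including the initial sample.
    """
    n_rec = n_steps // record_every + 1
    out = np.empty(n_rec)
    out[0] = state[0, 0]
    exp_dt_fca = math.exp(-dt / TAU_FCA)
    exp_dt_u = math.exp(-dt / TAU_U)
    for n in range(n_steps):
        ph = (n - stim_start) % stim_period_steps if n >= stim_start else -1
        istim = stim_amp if 0 <= ph < stim_dur_steps else 0.0
        dv = _react_node(state, 0, dt, cond, tab, exp_dt_fca, exp_dt_u, istim)
        state[0, 0] += dv
        if (n + 1) % record_every == 0:
            out[(n + 1) // record_every] = state[0, 0]
    return out


@njit(cache=True, fastmath=True)
def run_tissue(states, dt, n_steps, cond0, cond1, switch_step, tab, dcoef,
               lap_indptr, lap_indices, lap_data, stim_amp, stim_nodes,
               stim_start_step, stim_end_step, frame_every, frames):
    """Monodomain loop: reaction (Rush–Larsen/Euler) then explicit diffusion.

    ``cond0`` applies before ``switch_step``, ``cond1`` after (conductance
    block).  ``lap_*`` is the CSR discrete Laplacian (units cm^-2); ``dcoef``
    in cm^2/ms.  One optional stimulus episode over boolean ``stim_nodes``.
    Frames of V are written into ``frames`` every ``frame_every`` steps
    (frame 0 is the state on entry).  Returns the step index of the first
    non-finite voltage, or -1 on success.
    """
    n_nodes = states.shape[0]
    exp_dt_fca = math.exp(-dt / TAU_FCA)
    exp_dt_u = math.exp(-dt / TAU_U)
    dv = np.empty(n_nodes)
    frames[0, :] = states[:, 0]
    for n in range(n_steps):
        cond = cond0 if n < switch_step else cond1
        stim_on = stim_start_step <= n < stim_end_step
        for k in range(n_nodes):
            istim = stim_amp if (stim_on and stim_nodes[k]) else 0.0
            dv[k] = _react_node(states, k, dt, cond, tab, exp_dt_fca,
                                exp_dt_u, istim)
        # diffusion on the pre-reaction voltage field (Godunov split uses the
        # updated V; Laplacian evaluated on current V column)
        for k in range(n_nodes):
            acc = 0.0
            for p in range(lap_indptr[k], lap_indptr[k + 1]):
                acc += lap_data[p] * states[lap_indices[p], 0]
            dv[k] += dt * dcoef * acc
        ok = True
        for k in range(n_nodes):
            states[k, 0] += dv[k]
            if not np.isfinite(states[k, 0]):
                ok = False
        if not ok:
            return n
        if (n + 1) % frame_every == 0:
            f = (n + 1) // frame_every
            if f < frames.shape[0]:
                frames[f, :] = states[:, 0]
    return -1
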