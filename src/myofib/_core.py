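"""Compiled numerical core.

Everything here is numba ``@njit`` code operating on flat float64 arrays:
the myocyte/fibroblast state vector, the packed parameter vector (see
:mod:`myofib.params`), and the trace buffers.  The public modules wrap these
functions with typed, validated interfaces.

State vector layout (myocyte block, then 3 slots per fibroblast):

====  ==========================================================
 0    V_myo (mV)
 1-12 HH gates: m h j d f f2 fCass r s xr1 xr2 xs
13-16 RyR occupancies: R O I RI
17-21 Na_i K_i Ca_i Ca_ss Ca_SR (mM)
22    CaTnC (uM)
23    N_xb
24    l1 (CE strain, L_max units)
25    l2 (parallel-block strain)
26    frozen CaTnC off-rate (ms^-1; negative = clamp not engaged)
27+3i V_cf, r_Kv, s_Kv of fibroblast i
====  ==========================================================
"""

import math

import numpy as np
from numba import njit

from .params import P

# one integer module constant per packed parameter (P_g_Na, P_k_rel, ...)
# so the compiled kernels can index the parameter vector
globals().update({f"P_{_k}": _v for _k, _v in P.items()})

# state indices
IV = 0
IM, IH, IJ, ID, IF, IF2, IFCASS, IR, IS, IXR1, IXR2, IXS = range(1, 13)
IRYR_R, IRYR_O, IRYR_I, IRYR_RI = 13, 14, 15, 16
INAI, IKI, ICAI, ICASS, ICASR = 17, 18, 19, 20, 21
ICATNC, INXB, IL1, IL2, IKOFF = 22, 23, 24, 25, 26
NMYO = 27
NFBSTATE = 3

N_GATES = 12

# current indices (CurrentSet order)
CUR_CAL, CUR_BCA, CUR_K1, CUR_TO, CUR_KR, CUR_KS, CUR_PK, \
    CUR_NA, CUR_BNA, CUR_PCA, CUR_NAK, CUR_NACA = range(12)
N_CURRENTS = 12

# trace channel indices
CH_V, CH_CAI, CH_CASR, CH_CASS, CH_CATNC, CH_NXB, CH_FMYO, \
    CH_L1, CH_L2, CH_KOFF, CH_OFFFLUX, CH_ORYR = range(12)
NCH_BASE = 12
NCH_PER_FB = 2   # V_cf, i_MS

RGAS = 8314.472
FARADAY = 96485.3415
TEMP = 310.0
RTONF = RGAS * TEMP / FARADAY  # ~26.71 mV


# ---------------------------------------------------------------------------
# TP06 sarcolemmal currents
# ---------------------------------------------------------------------------

@njit(cache=True)
def tp06_currents(y, p, out):
    """All sarcolemmal currents (pA/pF) at the instantaneous state."""
    V = y[IV]
    na_i = y[INAI]
    k_i = y[IKI]
    ca_i = y[ICAI]
    ca_ss = y[ICASS]

    k_o = p[P_K_o]
    na_o = p[P_Na_o]
    ca_o = p[P_Ca_o]

    e_k = RTONF * math.log(k_o / k_i)
    e_na = RTONF * math.log(na_o / na_i)
    e_ca = 0.5 * RTONF * math.log(ca_o / ca_i)
    e_ks = RTONF * math.log((k_o + p[P_p_KNa] * na_o)
                            / (k_i + p[P_p_KNa] * na_i))

    # fast Na+
    out[CUR_NA] = (p[P_g_Na] * y[IM] ** 3 * y[IH] * y[IJ] * (V - e_na))
    out[CUR_BNA] = p[P_g_bNa] * (V - e_na)

    # L-type Ca2+ (GHK-like TP06 driving term, centred at +15 mV)
    vshift = V - 15.0
    expo = math.exp(2.0 * vshift / RTONF)
    if abs(vshift) < 1e-6:
        # series limit of vshift * (...) / (exp - 1)
        drive = RTONF / 2.0 * (0.25 * ca_ss * expo - ca_o)
    else:
        drive = vshift * (0.25 * ca_ss * expo - ca_o) / (expo - 1.0)
    g_cal = p[P_g_CaL] * p[P_ical_mult]
    out[CUR_CAL] = (g_cal * y[ID] * y[IF] * y[IF2] * y[IFCASS]
                    * 4.0 * FARADAY / RTONF * drive)
    out[CUR_BCA] = p[P_g_bCa] * (V - e_ca)

    # K+ currents
    dvk = V - e_k
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (dvk - 200.0)))
    b_k1 = ((3.0 * math.exp(0.0002 * (dvk + 100.0)) + math.exp(0.1 * (dvk - 10.0)))
            / (1.0 + math.exp(-0.5 * dvk)))
    out[CUR_K1] = p[P_g_K1] * math.sqrt(k_o / 5.4) * a_k1 / (a_k1 + b_k1) * dvk
    out[CUR_TO] = p[P_g_to] * y[IR] * y[IS] * dvk
    out[CUR_KR] = (p[P_g_Kr] * p[P_ikr_mult] * math.sqrt(k_o / 5.4)
                   * y[IXR1] * y[IXR2] * dvk)
    out[CUR_KS] = p[P_g_Ks] * p[P_iks_mult] * y[IXS] * y[IXS] * (V - e_ks)
    out[CUR_PK] = p[P_g_pK] * dvk / (1.0 + math.exp((25.0 - V) / 5.98))

    # pumps and exchangers
    out[CUR_PCA] = p[P_g_pCa] * ca_i / (ca_i + p[P_k_pCa])
    out[CUR_NAK] = (p[P_P_NaK] * k_o * na_i
                    / ((k_o + p[P_K_mK]) * (na_i + p[P_K_mNa])
                       * (1.0 + 0.1245 * math.exp(-0.1 * V / RTONF)
                          + 0.0353 * math.exp(-V / RTONF))))
    gam = p[P_gamma_NaCa]
    out[CUR_NACA] = (p[P_k_NaCa]
                     * (math.exp(gam * V / RTONF) * na_i ** 3 * ca_o
                        - math.exp((gam - 1.0) * V / RTONF) * na_o ** 3 * ca_i
                        * p[P_alpha_NaCa])
                     / ((p[P_K_mNai] ** 3 + na_o ** 3) * (p[P_K_mCa] + ca_o)
                        * (1.0 + p[P_k_sat]
                           * math.exp((gam - 1.0) * V / RTONF))))
    return out[CUR_NA] + out[CUR_BNA] + out[CUR_CAL] + out[CUR_BCA] \
        + out[CUR_K1] + out[CUR_TO] + out[CUR_KR] + out[CUR_KS] \
        + out[CUR_PK] + out[CUR_PCA] + out[CUR_NAK] + out[CUR_NACA]


@njit(cache=True)
def tp06_gate_inf_tau(V, ca_ss, inf, tau):
    """Steady states and time constants of the 12 TP06 HH gates."""
    # m
    inf[0] = 1.0 / (1.0 + math.exp((-56.86 - V) / 9.03)) ** 2
    am = 1.0 / (1.0 + math.exp((-60.0 - V) / 5.0))
    bm = 0.1 / (1.0 + math.exp((V + 35.0) / 5.0)) \
        + 0.1 / (1.0 + math.exp((V - 50.0) / 200.0))
    tau[0] = am * bm
    # h
    inf[1] = 1.0 / (1.0 + math.exp((V + 71.55) / 7.43)) ** 2
    if V >= -40.0:
        ah = 0.0
        bh = 0.77 / (0.13 * (1.0 + math.exp(-(V + 10.66) / 11.1)))
    else:
        ah = 0.057 * math.exp(-(V + 80.0) / 6.8)
        bh = 2.7 * math.exp(0.079 * V) + 3.1e5 * math.exp(0.3485 * V)
    tau[1] = 1.0 / (ah + bh)
    # j
    inf[2] = inf[1]
    if V >= -40.0:
        aj = 0.0
        bj = 0.6 * math.exp(0.057 * V) / (1.0 + math.exp(-0.1 * (V + 32.0)))
    else:
        aj = ((-2.5428e4 * math.exp(0.2444 * V) - 6.948e-6 * math.exp(-0.04391 * V))
              * (V + 37.78) / (1.0 + math.exp(0.311 * (V + 79.23))))
        bj = 0.02424 * math.exp(-0.01052 * V) \
            / (1.0 + math.exp(-0.1378 * (V + 40.14)))
    tau[2] = 1.0 / (aj + bj)
    # d
    inf[3] = 1.0 / (1.0 + math.exp((-8.0 - V) / 7.5))
    ad = 1.4 / (1.0 + math.exp((-35.0 - V) / 13.0)) + 0.25
    bd = 1.4 / (1.0 + math.exp((V + 5.0) / 5.0))
    gd = 1.0 / (1.0 + math.exp((50.0 - V) / 20.0))
    tau[3] = ad * bd + gd
    # f
    inf[4] = 1.0 / (1.0 + math.exp((V + 20.0) / 7.0))
    tau[4] = (1102.5 * math.exp(-((V + 27.0) ** 2) / 225.0)
              + 200.0 / (1.0 + math.exp((13.0 - V) / 10.0))
              + 180.0 / (1.0 + math.exp((V + 30.0) / 10.0)) + 20.0)
    # f2
    inf[5] = 0.67 / (1.0 + math.exp((V + 35.0) / 7.0)) + 0.33
    tau[5] = (562.0 * math.exp(-((V + 27.0) ** 2) / 240.0)
              + 31.0 / (1.0 + math.exp((25.0 - V) / 10.0))
              + 80.0 / (1.0 + math.exp((V + 30.0) / 10.0)))
    # fCass
    css = (ca_ss / 0.05) ** 2
    inf[6] = 0.6 / (1.0 + css) + 0.4
    tau[6] = 80.0 / (1.0 + css) + 2.0
    # r
    inf[7] = 1.0 / (1.0 + math.exp((20.0 - V) / 6.0))
    tau[7] = 9.5 * math.exp(-((V + 40.0) ** 2) / 1800.0) + 0.8
    # s (epicardial)
    inf[8] = 1.0 / (1.0 + math.exp((V + 20.0) / 5.0))
    tau[8] = (85.0 * math.exp(-((V + 45.0) ** 2) / 320.0)
              + 5.0 / (1.0 + math.exp((V - 20.0) / 5.0)) + 3.0)
    # xr1
    inf[9] = 1.0 / (1.0 + math.exp((-26.0 - V) / 7.0))
    axr1 = 450.0 / (1.0 + math.exp((-45.0 - V) / 10.0))
    bxr1 = 6.0 / (1.0 + math.exp((V + 30.0) / 11.5))
    tau[9] = axr1 * bxr1
    # xr2
    inf[10] = 1.0 / (1.0 + math.exp((V + 88.0) / 24.0))
    axr2 = 3.0 / (1.0 + math.exp((-60.0 - V) / 20.0))
    bxr2 = 1.12 / (1.0 + math.exp((V - 60.0) / 20.0))
    tau[10] = axr2 * bxr2
    # xs
    inf[11] = 1.0 / (1.0 + math.exp((-5.0 - V) / 14.0))
    axs = 1400.0 / math.sqrt(1.0 + math.exp((5.0 - V) / 6.0))
    bxs = 1.0 / (1.0 + math.exp((V - 35.0) / 15.0))
    tau[11] = axs * bxs + 80.0


# ---------------------------------------------------------------------------
# RyR ring and SR fluxes
# ---------------------------------------------------------------------------

@njit(cache=True)
def ryr_rates(ca_ss, ca_sr, ca_i, p):
    """SR-load-modulated opening/inactivation rates of the RyR ring.

    Opening combines the fast subspace-Ca trigger (CICR proper) with a
    store-overload-induced term: a sharp luminal-load threshold sensitised
    by bulk cytosolic Ca.  The latter is the route for spontaneous release
    between stimuli, ignited when an overloaded SR coincides with the
    elevated cytosolic Ca maintained by Ca-TnC dissociation during
    relaxation."""
    k_casr = p[P_ryr_max_sr] - (p[P_ryr_max_sr] - p[P_ryr_min_sr]) \
        / (1.0 + (p[P_ryr_ec50_sr] / ca_sr) ** 2)
    a = p[P_ryr_ko_ca] / (k_casr * k_casr) * ca_ss * ca_ss   # R->O, RI->I
    xl = (ca_sr / p[P_ryr_k_load]) ** p[P_ryr_h_load]
    xc = (ca_i / p[P_ryr_k_cyt]) ** p[P_ryr_h_cyt]
    a += p[P_ryr_g_ig] * (xl / (1.0 + xl)) * (xc / (1.0 + xc))
    b = p[P_ryr_ki_ca] * k_casr * ca_ss                      # O->I, R->RI
    return a, b, p[P_ryr_kom], p[P_ryr_kim]


@njit(cache=True)
def ryr_derivs(y, p, d4):
    """Time derivatives of the RyR occupancies; returns I_rel (mM/ms)."""
    a, b, kom, kim = ryr_rates(y[ICASS], y[ICASR], y[ICAI], p)
    r_, o_, i_, ri = y[IRYR_R], y[IRYR_O], y[IRYR_I], y[IRYR_RI]
    d4[0] = kom * o_ + kim * ri - (a + b) * r_
    d4[1] = a * r_ + kim * i_ - (kom + b) * o_
    d4[2] = b * o_ + a * ri - (kim + kom) * i_
    d4[3] = kom * i_ + b * r_ - (kim + a) * ri
    return p[P_k_rel] * o_ * (y[ICASR] - y[ICASS])


@njit(cache=True)
def ryr_implicit_step(y, p, dt):
    """Backward-Euler update of the RyR ring (exactly conserves the sum)."""
    a, b, kom, kim = ryr_rates(y[ICASS], y[ICASR], y[ICAI], p)
    m = np.empty((4, 4))
    m[0, 0] = 1.0 + dt * (a + b)
    m[0, 1] = -dt * kom
    m[0, 2] = 0.0
    m[0, 3] = -dt * kim
    m[1, 0] = -dt * a
    m[1, 1] = 1.0 + dt * (kom + b)
    m[1, 2] = -dt * kim
    m[1, 3] = 0.0
    m[2, 0] = 0.0
    m[2, 1] = -dt * b
    m[2, 2] = 1.0 + dt * (kim + kom)
    m[2, 3] = -dt * a
    m[3, 0] = -dt * b
    m[3, 1] = 0.0
    m[3, 2] = -dt * kom
    m[3, 3] = 1.0 + dt * (kim + a)
    rhs = np.empty(4)
    rhs[0] = y[IRYR_R]
    rhs[1] = y[IRYR_O]
    rhs[2] = y[IRYR_I]
    rhs[3] = y[IRYR_RI]
    # Gaussian elimination with partial pivoting (4x4)
    for col in range(3):
        piv = col
        big = abs(m[col, col])
        for row in range(col + 1, 4):
            if abs(m[row, col]) > big:
                big = abs(m[row, col])
                piv = row
        if piv != col:
            for k in range(4):
                tmp = m[col, k]
                m[col, k] = m[piv, k]
                m[piv, k] = tmp
            tmp = rhs[col]
            rhs[col] = rhs[piv]
            rhs[piv] = tmp
        for row in range(col + 1, 4):
            fac = m[row, col] / m[col, col]
            for k in range(col, 4):
                m[row, k] -= fac * m[col, k]
            rhs[row] -= fac * rhs[col]
    x3 = rhs[3] / m[3, 3]
    x2 = (rhs[2] - m[2, 3] * x3) / m[2, 2]
    x1 = (rhs[1] - m[1, 2] * x2 - m[1, 3] * x3) / m[1, 1]
    x0 = (rhs[0] - m[0, 1] * x1 - m[0, 2] * x2 - m[0, 3] * x3) / m[0, 0]
    y[IRYR_R] = x0
    y[IRYR_O] = x1
    y[IRYR_I] = x2
    y[IRYR_RI] = x3


@njit(cache=True)
def sr_fluxes(y, p):
    """(I_up, I_leak, I_xfer) per TP06, with the SERCA multiplier on I_up."""
    ca_i = y[ICAI]
    i_up = p[P_serca_mult] * p[P_V_max_up] \
        / (1.0 + (p[P_K_up] / ca_i) ** 2) if ca_i > 0.0 else 0.0
    i_leak = p[P_V_leak] * (y[ICASR] - ca_i)
    i_xfer = p[P_V_xfer] * (y[ICASS] - ca_i)
    return i_up, i_leak, i_xfer


# ---------------------------------------------------------------------------
# mechanics
# ---------------------------------------------------------------------------

@njit(cache=True)
def elastic_force(alpha, beta, strain):
    return beta * (math.exp(alpha * strain) - 1.0)


@njit(cache=True)
def fv_factor(v, p):
    """Hill force-velocity factor P(v); P(0)=1, monotone increasing,
    zero at -v_max, capped for lengthening."""
    vmax = p[P_v_max]
    if v <= -vmax:
        return 0.0
    if v < 0.0:
        a = p[P_hill_a]
        return (1.0 + v / vmax) / (1.0 - v / (a * vmax))
    pl = p[P_p_len_max]
    return 1.0 + (pl - 1.0) * v / (v + p[P_len_b])


@njit(cache=True)
def overlap(s, p):
    """Thin/thick filament overlap vs sarcomere length fraction (ascending limb)."""
    x = (s - p[P_ov_s0]) / (p[P_ov_s1] - p[P_ov_s0])
    if x < 0.0:
        return 0.0
    if x > 1.0:
        return 1.0
    return x


@njit(cache=True)
def f_ce(n_xb, v, p):
    return p[P_F_xb_max] * n_xb * fv_factor(v, p)


@njit(cache=True)
def solve_balance(y, p):
    """Per-step force balance of the isometric preparation.

    Returns (v1, v2, F_XSE, converged).  The parallel-block velocity
    follows directly from VS2: v2 - v1 = R/mu2 with
    R = F_XSE - F_PE - n*F_PEfb - F_SE; v1 then solves the contractile
    chain balance F_CE(v1) + mu1*v1 = F_SE + R by safeguarded Newton
    (the left side is strictly increasing in v1, so the root is unique).
    """
    l1 = y[IL1]
    l2 = y[IL2]
    n_xb = y[INXB]
    l3 = l2 - l1
    lx = p[P_L_prep] - p[P_block_slack] - l2
    f_xse = elastic_force(p[P_alpha_XSE], p[P_beta_XSE], lx)
    f_pe = elastic_force(p[P_alpha_PE], p[P_beta_PE], l2)
    f_se = elastic_force(p[P_alpha_SE], p[P_beta_SE], l3)
    n_mech = p[P_n_fb] * p[P_mech_fb_on]
    f_fb = elastic_force(p[P_alpha_fb], p[P_beta_fb], l2)
    resid = f_xse - f_pe - n_mech * f_fb - f_se
    target = f_se + resid
    mu1 = p[P_mu_VS1]
    tol = p[P_balance_tol]

    # bracket the root of g(v) = F_CE(v) + mu1*v - target
    vmax = p[P_v_max]
    lo = -vmax * 0.999999
    hi = vmax
    glo = f_ce(n_xb, lo, p) + mu1 * lo - target
    ghi = f_ce(n_xb, hi, p) + mu1 * hi - target
    it = 0
    while glo > 0.0 and it < 60:
        lo *= 2.0
        glo = f_ce(n_xb, lo, p) + mu1 * lo - target
        it += 1
    it = 0
    while ghi < 0.0 and it < 60:
        hi *= 2.0
        ghi = f_ce(n_xb, hi, p) + mu1 * hi - target
        it += 1
    if glo > 0.0 or ghi < 0.0:
        return 0.0, 0.0, f_xse, False

    v = 0.5 * (lo + hi)
    converged = False
    for _ in range(100):
        g = f_ce(n_xb, v, p) + mu1 * v - target
        if abs(g) < tol:
            converged = True
            break
        if g > 0.0:
            hi = v
        else:
            lo = v
        # numerical Newton step, safeguarded by the bracket
        h = 1e-9
        dg = (f_ce(n_xb, v + h, p) + mu1 * (v + h)
              - f_ce(n_xb, v - h, p) - mu1 * (v - h)) / (2.0 * h)
        if dg > 0.0:
            vn = v - g / dg
            if lo < vn < hi:
                v = vn
            else:
                v = 0.5 * (lo + hi)
        else:
            v = 0.5 * (lo + hi)
    v2 = v + resid / p[P_mu_VS2]
    return v, v2, f_xse, converged


@njit(cache=True)
def catnc_off_rate(catnc, n_xb, p):
    """Cooperative CaTnC off-rate: decreasing in both CaTnC and N_xb."""
    pi_n = p[P_pi_min] + (1.0 - p[P_pi_min]) * math.exp(-p[P_k_N] * n_xb)
    return p[P_k_off0] * math.exp(-p[P_k_A] * catnc) * pi_n


@njit(cache=True)
def catnc_derivative(catnc, ca_i, n_xb, p, frozen_off):
    """dCaTnC/dt (uM/ms); if frozen_off >= 0 the off-rate is clamped there."""
    k_off = frozen_off if frozen_off >= 0.0 else catnc_off_rate(catnc, n_xb, p)
    return p[P_a_on] * ca_i * (p[P_A_tot] - catnc) - k_off * catnc


@njit(cache=True)
def xb_derivative(n_xb, catnc, s, v, p):
    """dN_xb/dt with length-dependent attachment and velocity-dependent
    detachment; keeps N_xb inside [0, 1]."""
    perm = (catnc / p[P_A_tot]) ** p[P_perm_exp]
    att = p[P_k_on_xb] * perm * overlap(s, p) * (1.0 - n_xb)
    det = p[P_k_off_xb] * (1.0 + p[P_xb_v_sens] * abs(v)) * n_xb
    return att - det


# ---------------------------------------------------------------------------
# fibroblast membrane
# ---------------------------------------------------------------------------

@njit(cache=True)
def fb_current_sum(vf, r, s, p, cur4):
    """MacCannell four-current sum (pA/pF): i_Kv, i_K1, i_NaK, i_bNa."""
    e_k = RTONF * math.log(p[P_f_Ko] / p[P_f_Ki])
    e_na = RTONF * math.log(p[P_f_Nao] / p[P_f_Nai])
    dvk = vf - e_k
    cur4[0] = p[P_fg_Kv] * r * s * dvk
    a_k1 = 0.1 / (1.0 + math.exp(0.06 * (dvk - 200.0)))
    b_k1 = ((3.0 * math.exp(0.0002 * (dvk + 100.0)) + math.exp(0.1 * (dvk - 10.0)))
            / (1.0 + math.exp(-0.5 * dvk)))
    cur4[1] = p[P_fg_K1] * a_k1 / (a_k1 + b_k1) * dvk
    nai = p[P_f_Nai]
    cur4[2] = (p[P_f_INaK_max]
               * (p[P_f_Ko] / (p[P_f_Ko] + p[P_f_KmK]))
               * (nai ** 1.5 / (nai ** 1.5 + p[P_f_KmNa] ** 1.5))
               * (vf - p[P_f_VrevNaK]) / (vf - p[P_f_BNaK]))
    cur4[3] = p[P_fg_bNa] * (vf - e_na)
    return cur4[0] + cur4[1] + cur4[2] + cur4[3]


@njit(cache=True)
def fb_gate_inf_tau(vf):
    r_inf = 1.0 / (1.0 + math.exp(-(vf + 20.0) / 11.0))
    tau_r = 20.3 + 138.0 * math.exp(-((vf + 20.0) / 25.9) ** 2)
    s_inf = 1.0 / (1.0 + math.exp((vf + 23.0) / 7.0))
    tau_s = 1574.0 + 5268.0 * math.exp(-((vf + 23.0) / 22.7) ** 2)
    return r_inf, tau_r, s_inf, tau_s


@njit(cache=True)
def msc_vrev(ell, p):
    """Reversal potential (mV) at fibroblast length fraction ``ell``."""
    lo = p[P_ms_len_lo]
    hi = p[P_ms_len_hi]
    if ell < lo:
        ell = lo
    elif ell > hi:
        ell = hi
    frac = (ell - lo) / (hi - lo)
    return p[P_ms_vrev_short] + frac * (p[P_ms_vrev_long] - p[P_ms_vrev_short])


@njit(cache=True)
def msc_current(vf, ell, dl, p):
    """i_MS (pA): g_max * a(dl) * (V_cf - V_rev(ell)); negative depolarises."""
    a = 1.0 + p[P_ms_a_slope] * dl
    if a < 0.05:
        a = 0.05
    return p[P_ms_gmax] * a * (vf - msc_vrev(ell, p))


# ---------------------------------------------------------------------------
# stimulus
# ---------------------------------------------------------------------------

@njit(cache=True)
def stimulus(t, p):
    """Inward rectangular stimulus (pA/pF, returned with negative sign)."""
    period = p[P_pace_period]
    tin = t % period
    if tin < p[P_stim_dur]:
        return -p[P_stim_amp]
    return 0.0


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

@njit(cache=True)
def integrate(y, p, t0, n_steps, dt, steps_per_out, times, chans):
    """Advance the coupled system ``n_steps`` of size ``dt`` from ``t0``.

    ``times``/``chans`` are preallocated output buffers sampled every
    ``steps_per_out`` steps (including step 0).  Returns (status, t_fail):
    status 0 = ok, 1 = mechanics solver failure, 2 = non-finite state.
    """
    nfb = int(p[P_n_fb])
    mode2 = p[P_ms_on] > 0.5
    g_gap = p[P_g_gap]
    c_myo = p[P_C_myo]
    c_mf = p[P_C_mf]
    cur = np.empty(N_CURRENTS)
    fcur = np.empty(4)
    ginf = np.empty(N_GATES)
    gtau = np.empty(N_GATES)
    iout = 0
    t = t0
    for step in range(n_steps + 1):
        # --- mechanics balance at current state
        v1, v2, f_xse, ok = solve_balance(y, p)
        if not ok:
            return 1, t
        s_frac = p[P_block_slack] + y[IL1]
        ell_fb = p[P_L_prep] + (y[IL2] - p[P_l2_init])
        dl_fb = y[IL2] - p[P_l2_init]

        # --- clamp bookkeeping (freeze the CaTnC off-rate at clamp_time)
        if p[P_clamp_on] > 0.5 and t >= p[P_clamp_time] and y[IKOFF] < 0.0:
            y[IKOFF] = catnc_off_rate(y[ICATNC], y[INXB], p)
        k_off_eff = y[IKOFF] if y[IKOFF] >= 0.0 else \
            catnc_off_rate(y[ICATNC], y[INXB], p)

        # --- record
        if step % steps_per_out == 0 and iout < times.shape[0]:
            times[iout] = t
            chans[CH_V, iout] = y[IV]
            chans[CH_CAI, iout] = y[ICAI]
            chans[CH_CASR, iout] = y[ICASR]
            chans[CH_CASS, iout] = y[ICASS]
            chans[CH_CATNC, iout] = y[ICATNC]
            chans[CH_NXB, iout] = y[INXB]
            chans[CH_FMYO, iout] = f_xse / p[P_F_norm]
            chans[CH_L1, iout] = y[IL1]
            chans[CH_L2, iout] = y[IL2]
            chans[CH_KOFF, iout] = k_off_eff
            chans[CH_OFFFLUX, iout] = k_off_eff * y[ICATNC]
            chans[CH_ORYR, iout] = y[IRYR_O]
            for i in range(nfb):
                vf = y[NMYO + NFBSTATE * i]
                chans[NCH_BASE + NCH_PER_FB * i, iout] = vf
                chans[NCH_BASE + NCH_PER_FB * i + 1, iout] = \
                    msc_current(vf, ell_fb, dl_fb, p) if mode2 else 0.0
            iout += 1
        if step == n_steps:
            break

        # --- myocyte membrane currents
        i_sum = tp06_currents(y, p, cur)
        i_stim = stimulus(t, p)
        gap_sum = 0.0
        for i in range(nfb):
            gap_sum += g_gap * (y[IV] - y[NMYO + NFBSTATE * i])
        dv = -(i_sum + i_stim + gap_sum / c_myo)

        # --- Ca2+ subsystem
        i_up, i_leak, i_xfer = sr_fluxes(y, p)
        i_rel = p[P_k_rel] * y[IRYR_O] * (y[ICASR] - y[ICASS])
        d_catnc = catnc_derivative(y[ICATNC], y[ICAI], y[INXB], p, y[IKOFF])

        vc = p[P_V_c]
        vsr = p[P_V_sr]
        vss = p[P_V_ss]
        # TP06 convention: Cm in uF with these volumes; with currents in
        # pA/pF the flux factor is Cm(=0.185 uF)/(2 Vc F)
        cap_uf = c_myo * 1e-3
        bufc = 1.0 / (1.0 + p[P_buf_c] * p[P_K_buf_c]
                      / (y[ICAI] + p[P_K_buf_c]) ** 2)
        d_cai = bufc * ((i_leak - i_up) * vsr / vc + i_xfer
                        - (cur[CUR_BCA] + cur[CUR_PCA] - 2.0 * cur[CUR_NACA])
                        * cap_uf / (2.0 * vc * FARADAY)
                        - d_catnc * 1e-3)
        bufss = 1.0 / (1.0 + p[P_buf_ss] * p[P_K_buf_ss]
                       / (y[ICASS] + p[P_K_buf_ss]) ** 2)
        d_cass = bufss * (-i_xfer * vc / vss + i_rel * vsr / vss
                          - cur[CUR_CAL] * cap_uf / (2.0 * vss * FARADAY))
        bufsr = 1.0 / (1.0 + p[P_buf_sr] * p[P_K_buf_sr]
                       / (y[ICASR] + p[P_K_buf_sr]) ** 2)
        d_casr = bufsr * (i_up - i_leak - i_rel)
        d_nai = -(cur[CUR_NA] + cur[CUR_BNA]
                  + 3.0 * cur[CUR_NAK] + 3.0 * cur[CUR_NACA]) \
            * cap_uf / (vc * FARADAY)
        d_ki = -(cur[CUR_K1] + cur[CUR_TO] + cur[CUR_KR] + cur[CUR_KS]
                 + cur[CUR_PK] - 2.0 * cur[CUR_NAK] + i_stim) \
            * cap_uf / (vc * FARADAY)

        # --- mechanics derivatives
        d_nxb = xb_derivative(y[INXB], y[ICATNC], s_frac, v1, p)

        # --- fibroblasts
        for i in range(nfb):
            base = NMYO + NFBSTATE * i
            vf = y[base]
            icf = fb_current_sum(vf, y[base + 1], y[base + 2], p, fcur)
            extra = g_gap * (vf - y[IV])
            if mode2:
                extra += msc_current(vf, ell_fb, dl_fb, p)
            dvf = -(icf + extra / c_mf)
            r_inf, tau_r, s_inf, tau_s = fb_gate_inf_tau(vf)
            y[base] = vf + dt * dvf
            y[base + 1] = r_inf + (y[base + 1] - r_inf) * math.exp(-dt / tau_r)
            y[base + 2] = s_inf + (y[base + 2] - s_inf) * math.exp(-dt / tau_s)

        # --- myocyte gate update (Rush-Larsen)
        tp06_gate_inf_tau(y[IV], y[ICASS], ginf, gtau)
        for g in range(N_GATES):
            y[1 + g] = ginf[g] + (y[1 + g] - ginf[g]) * math.exp(-dt / gtau[g])

        # --- RyR semi-implicit update
        ryr_implicit_step(y, p, dt)

        # --- explicit updates
        y[IV] += dt * dv
        y[INAI] += dt * d_nai
        y[IKI] += dt * d_ki
        y[ICAI] += dt * d_cai
        y[ICASS] += dt * d_cass
        y[ICASR] += dt * d_casr
        y[ICATNC] += dt * d_catnc
        y[INXB] += dt * d_nxb
        if y[INXB] < 0.0:
            y[INXB] = 0.0
        elif y[INXB] > 1.0:
            y[INXB] = 1.0
        if y[ICATNC] < 0.0:
            y[ICATNC] = 0.0
        y[IL1] += dt * v1
        y[IL2] += dt * v2
        t = t0 + (step + 1) * dt
        if not (math.isfinite(y[IV]) and math.isfinite(y[ICAI])):
            return 2, t
    return 0, t
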