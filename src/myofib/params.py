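"""Parameter sets for the coupled myocyte-fibroblast electromechanical model.

All electrophysiological quantities use the conventional cardiac units:
millivolts, milliseconds, millimolar (micromolar for Ca-troponin C),
picoamperes per picofarad for sarcolemmal currents, nanosiemens for
junctional and mechanosensitive conductances.  Mechanical strains are
dimensionless fractions of ``L_max`` (the preparation length of maximal
active isometric force; one ``L_max`` corresponds to a sarcomere length of
2.23 um) and forces are normalised to the peak steady-state isometric force
of the uncoupled myocyte at 90 % ``L_max``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Optional

import numpy as np

__all__ = [
    "MyocyteEPParams",
    "MechParams",
    "FibroblastParams",
    "PacingProtocol",
    "SolverOptions",
    "EnsembleConfig",
    "default_params",
    "pack_params",
    "load_param_file",
    "PARAM_FILE_VERSION",
]

PARAM_FILE_VERSION = "1"

MODE_SINGLE = 0
MODE_MODEL1 = 1
MODE_MODEL2 = 2

_MODE_NAMES = {"single": MODE_SINGLE, "model1": MODE_MODEL1, "model2": MODE_MODEL2}


@dataclass
class MyocyteEPParams:
    """Sarcolemmal and Ca2+-handling parameters of the ventricular myocyte.

    Defaults follow the published TP06 epicardial parameter set, with the
    L-type Ca2+ conductance scale anchored at 5e-5 (F*s)^-1 and the
    ryanodine-receptor ring described by a Shannon-style four-state scheme.
    The TP06 generalised cytosolic buffer is split into dynamic Ca-TnC
    (owned by the mechanics block) plus a residual instantaneous buffer so
    that total buffering capacity is preserved.
    """

    # maximal conductances (pA/pF per mV unless noted)
    g_Na: float = 14.838
    g_K1: float = 5.405
    g_to: float = 0.294
    g_Kr: float = 0.153
    g_Ks: float = 0.392
    p_KNa: float = 0.03
    g_CaL: float = 5.0e-5          # L-type scale, (F*s)^-1
    g_bNa: float = 0.00029
    g_bCa: float = 0.000592
    g_pCa: float = 0.1238
    k_pCa: float = 0.0005
    g_pK: float = 0.0146
    # Na/K pump and Na/Ca exchanger
    P_NaK: float = 2.724
    K_mK: float = 1.0
    K_mNa: float = 40.0
    k_NaCa: float = 1000.0
    gamma_NaCa: float = 0.35
    K_mCa: float = 1.38
    K_mNai: float = 87.5
    k_sat: float = 0.1
    alpha_NaCa: float = 2.5
    # fixed extracellular milieu
    K_o: float = 5.4
    Na_o: float = 140.0
    Ca_o: float = 2.0
    # membrane
    C_myo: float = 185.0           # pF
    # SR / cytosol Ca2+ translocation
    V_max_up: float = 0.009
    K_up: float = 0.00025
    V_leak: float = 0.00036
    V_xfer: float = 0.0038
    # RyR release (Shannon-style R/O/I/RI ring driven by Ca_ss and Ca_SR)
    k_rel: float = 0.12            # ms^-1, I_rel = k_rel * O * (Ca_SR - Ca_ss)
    ryr_ko_ca: float = 0.6         # mM^-2 ms^-1
    ryr_ki_ca: float = 0.10        # mM^-1 ms^-1
    ryr_kom: float = 0.06          # ms^-1
    ryr_kim: float = 0.005         # ms^-1
    ryr_ec50_sr: float = 1.5       # mM, SR-load sensor midpoint
    ryr_max_sr: float = 2.5
    ryr_min_sr: float = 1.0
    # store-overload-induced opening (luminal regulation): extra opening
    # rate g_ig * S_load(Ca_SR) * S_cyt(Ca_ss) with Hill sensors
    ryr_g_ig: float = 15.0         # ms^-1
    ryr_k_load: float = 3.85       # mM, luminal ignition threshold
    ryr_k_cyt: float = 1.5e-3      # mM, cytosolic sensitisation midpoint
    ryr_h_load: float = 20.0       # Hill steepness of the luminal sensor
    ryr_h_cyt: float = 4.0         # Hill steepness of the cytosolic sensor
    # buffering (residual instantaneous cytosolic buffer after the TnC split)
    buf_c: float = 0.13            # mM (TP06 total 0.20 minus 0.07 mM TnC sites)
    K_buf_c: float = 0.001
    buf_sr: float = 10.0
    K_buf_sr: float = 0.3
    buf_ss: float = 0.4
    K_buf_ss: float = 0.00025
    # compartment volumes (TP06 convention)
    V_c: float = 0.016404
    V_sr: float = 0.001094
    V_ss: float = 0.00005468
    # multipliers (dimensionless scalings applied to the baseline values)
    ical_mult: float = 1.0
    ikr_mult: float = 1.0
    iks_mult: float = 1.0
    serca_mult: float = 1.0

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite EP parameter: {name}")
        if self.C_myo <= 0:
            raise ValueError("C_myo must be positive")
        for name in ("g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "g_CaL",
                     "ical_mult", "ikr_mult", "iks_mult", "serca_mult"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class MechParams:
    """Mechanics of the preparation: Ca-TnC, cross-bridges and rheology.

    The rheological scheme is: an external series elastic element (XSE) in
    series with a parallel block made of the passive element PE, the ``n``
    fibroblast elastic elements PEfb, and the contractile chain (contractile
    element CE with parallel viscosity VS1, in series with the internal
    elastic element SE with parallel viscosity VS2).  Strains ``l1`` (CE),
    ``l2`` (parallel block) and ``l3 = l2 - l1`` (SE) are measured in units
    of ``L_max`` above slack.  Elastic forces are exponential,
    ``F = beta * (exp(alpha * l) - 1)``; the fibroblast pair
    (``alpha2fb``, ``beta2fb``) equals the PE pair by default.

    The Ca-TnC off-rate carries the cooperative cross-bridge dependence:
    ``k_off = k_off0 * exp(-k_A * CaTnC) * pi(N_xb)`` with ``pi`` strictly
    decreasing in the attached cross-bridge fraction ``N_xb``.
    """

    A_tot: float = 70.0            # uM, total troponin-C regulatory sites
    a_on: float = 40.0             # mM^-1 ms^-1, Ca binding on-rate
    k_off0: float = 0.12           # ms^-1, base Ca-TnC off-rate
    k_A: float = 0.010             # uM^-1, CaTnC self-cooperativity
    pi_min: float = 0.10           # floor of the cross-bridge factor pi(N_xb)
    k_N: float = 6.0               # steepness of pi(N_xb)
    # cross-bridge kinetics
    k_on_xb: float = 0.12          # ms^-1, attachment scale
    k_off_xb: float = 0.040        # ms^-1, base detachment
    xb_v_sens: float = 1000.0      # (L_max/ms)^-1, detachment velocity sensitivity
    perm_exp: float = 1.6          # exponent of the CaTnC->attachment drive
    F_xb_max: float = 3.0          # normalised CE force at N_xb=1, P(v)=1
    # force-velocity shape
    v_max: float = 0.0015          # L_max/ms, unloaded shortening velocity
    hill_a: float = 0.35           # Hill curvature (a/F0)
    p_len_max: float = 1.5         # lengthening force cap
    len_b: float = 0.0002          # L_max/ms, lengthening saturation scale
    # overlap (length-dependent activation), sarcomere fraction of L_max
    ov_s0: float = 0.60
    ov_s1: float = 0.92
    # elastic coefficients (normalised force units / strain in L_max units)
    alpha_PE: float = 15.0
    beta_PE: float = 0.010
    alpha2fb: float = 15.0
    beta2fb: float = 0.010
    alpha_SE: float = 60.0
    beta_SE: float = 0.040
    alpha_XSE: float = 200.0
    beta_XSE: float = 0.050
    mu_VS1: float = 10.0           # normalised force per (L_max/ms)
    mu_VS2: float = 5.0
    # geometry
    block_slack: float = 0.76      # parallel-block slack length, fraction of L_max
    L_max_um: float = 2.23         # sarcomere length at L_max, um
    # normalisation constant: peak steady-state isometric force of the
    # uncoupled myocyte at 90 % L_max (filled by calibration, see data file)
    F_norm: float = 1.328270

    def validate(self) -> None:
        for name, value in asdict(self).items():
            if not math.isfinite(value):
                raise ValueError(f"non-finite mechanics parameter: {name}")
        for name in ("A_tot", "a_on", "k_off0", "k_on_xb", "k_off_xb",
                     "alpha_PE", "beta_PE", "alpha2fb", "beta2fb",
                     "alpha_SE", "beta_SE", "alpha_XSE", "beta_XSE",
                     "mu_VS1", "mu_VS2", "F_norm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class FibroblastParams:
    """Active fibroblast membrane (MacCannell-style) plus the
    length-dependent mechanosensitive current.

    The mechanosensitive current is
    ``i_MS = g_max * a(dl) * (V_cf - V_rev(l))`` with an affine deformation
    factor ``a(dl) = 1 + a_slope * dl`` (``dl`` relative to the run's
    initial length) and an affine reversal potential spanning
    [-38, -30] mV over the 80-90 % ``L_max`` working range.  By default the
    more negative endpoint (-38 mV) is assigned to the *long* end of the
    range (``stretch_rev_negative = True``); flipping the switch assigns it
    to the short end.
    """

    C_mf: float = 6.3              # pF
    g_Kv: float = 0.25             # nS/pF, delayed rectifier
    g_K1: float = 0.4822           # nS/pF, inward rectifier
    I_NaK_max: float = 2.002       # pA/pF
    K_mK: float = 1.0
    K_mNa: float = 11.0
    V_rev_NaK: float = -150.0      # mV
    B_NaK: float = -200.0          # mV
    g_bNa: float = 0.0095          # nS/pF
    K_i: float = 129.4349          # mM, held fixed
    Na_i: float = 8.5547           # mM, held fixed
    K_o: float = 5.4
    Na_o: float = 140.0
    # mechanosensitive current
    g_max: float = 8.0             # nS at zero deformation
    a_slope: float = 8.0           # per unit strain (L_max units)
    V_rev_lo: float = -38.0        # mV, more negative endpoint
    V_rev_hi: float = -30.0        # mV, less negative endpoint
    length_lo: float = 0.80        # fraction of L_max
    length_hi: float = 0.90
    stretch_rev_negative: bool = True  # -38 mV at length_hi if True
    # multipliers used by the sensitivity protocols
    gmax_mult: float = 1.0
    vrev_mult: float = 1.0         # scales both reversal endpoints

    def validate(self) -> None:
        if self.C_mf <= 0:
            raise ValueError("C_mf must be positive")
        if self.g_max < 0:
            raise ValueError("g_max must be non-negative")
        if not self.V_rev_lo < self.V_rev_hi:
            raise ValueError("V_rev_lo must be below V_rev_hi")
        if not self.length_lo < self.length_hi:
            raise ValueError("degenerate working length range")


@dataclass
class PacingProtocol:
    """Rectangular-pulse pacing.  Pulse onsets at t = 0, period, 2*period..."""

    frequency_hz: float = 1.0
    amplitude: float = 52.0        # pA/pF, inward (depolarising)
    duration: float = 1.0          # ms

    @property
    def period(self) -> float:
        if self.frequency_hz <= 0:
            raise ValueError("pacing frequency must be positive")
        return 1000.0 / self.frequency_hz

    def validate(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("pacing frequency must be positive")
        if self.duration <= 0 or self.duration >= self.period:
            raise ValueError("pulse duration must lie inside the pacing period")


@dataclass
class SolverOptions:
    """Fixed-step hybrid integrator settings.

    ``dt`` is the integration step (Rush-Larsen for gates, semi-implicit
    RyR ring, forward Euler elsewhere); halving ``dt`` is the convergence
    check.  ``balance_tol`` bounds the per-step force-balance root solve.
    """

    dt: float = 0.02               # ms
    output_dt: float = 1.0         # ms
    balance_tol: float = 1e-10

    def validate(self) -> None:
        if self.dt <= 0 or self.output_dt <= 0:
            raise ValueError("solver steps must be positive")
        if self.output_dt < self.dt:
            raise ValueError("output_dt must be >= dt")


@dataclass
class EnsembleConfig:
    """Full specification of one run of the coupled preparation."""

    mode: str = "model2"           # single | model1 | model2
    n: int = 0                     # number of attached fibroblasts
    g_gap: float = 0.0             # nS per junction
    initial_length: float = 0.90   # fraction of L_max
    duration: float = 5000.0       # ms
    pacing: PacingProtocol = field(default_factory=PacingProtocol)
    solver: SolverOptions = field(default_factory=SolverOptions)
    ep: MyocyteEPParams = field(default_factory=MyocyteEPParams)
    mech: MechParams = field(default_factory=MechParams)
    fb: FibroblastParams = field(default_factory=FibroblastParams)
    clamp_time: Optional[float] = None   # ms; freeze the CaTnC off-rate there
    record_currents: bool = False

    def validate(self) -> None:
        if self.mode not in _MODE_NAMES:
            raise ValueError(f"unknown mode {self.mode!r}; valid: single, model1, model2")
        if self.n < 0:
            raise ValueError("n must be >= 0 (valid range 0-10)")
        if self.mode == "single" and self.n != 0:
            raise ValueError("mode 'single' forces n = 0")
        if self.g_gap < 0:
            raise ValueError("g_gap must be >= 0 nS")
        if not (0.7 < self.initial_length <= 1.0):
            raise ValueError("initial_length must lie in (0.7, 1.0] of L_max")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.clamp_time is not None and not (0 <= self.clamp_time <= self.duration):
            raise ValueError("clamp_time outside the run")
        self.pacing.validate()
        self.solver.validate()
        self.ep.validate()
        self.mech.validate()
        self.fb.validate()

    @property
    def mode_id(self) -> int:
        return _MODE_NAMES[self.mode]


# ---------------------------------------------------------------------------
# kernel parameter vector layout
# ---------------------------------------------------------------------------
# The compiled integrator receives all scalars in a flat float64 vector.
_names = [
    # TP06 EP
    "g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "p_KNa", "g_CaL",
    "g_bNa", "g_bCa", "g_pCa", "k_pCa", "g_pK",
    "P_NaK", "K_mK", "K_mNa",
    "k_NaCa", "gamma_NaCa", "K_mCa", "K_mNai", "k_sat", "alpha_NaCa",
    "K_o", "Na_o", "Ca_o", "C_myo",
    "V_max_up", "K_up", "V_leak", "V_xfer",
    "k_rel", "ryr_ko_ca", "ryr_ki_ca", "ryr_kom", "ryr_kim",
    "ryr_ec50_sr", "ryr_max_sr", "ryr_min_sr",
    "ryr_g_ig", "ryr_k_load", "ryr_k_cyt", "ryr_h_load", "ryr_h_cyt",
    "buf_c", "K_buf_c", "buf_sr", "K_buf_sr", "buf_ss", "K_buf_ss",
    "V_c", "V_sr", "V_ss",
    "ical_mult", "ikr_mult", "iks_mult", "serca_mult",
    # stimulus / pacing
    "stim_amp", "stim_dur", "pace_period",
    # ensemble
    "n_fb", "g_gap", "mode", "L_prep", "clamp_time", "clamp_on",
    # mechanics
    "A_tot", "a_on", "k_off0", "k_A", "pi_min", "k_N",
    "k_on_xb", "k_off_xb", "xb_v_sens", "perm_exp", "F_xb_max",
    "v_max", "hill_a", "p_len_max", "len_b",
    "ov_s0", "ov_s1",
    "alpha_PE", "beta_PE", "alpha_fb", "beta_fb",
    "alpha_SE", "beta_SE", "alpha_XSE", "beta_XSE",
    "mu_VS1", "mu_VS2", "block_slack", "F_norm",
    "mech_fb_on",                  # 1 in model2: PEfb terms present
    "l2_init",                     # parallel-block strain at run start
    # fibroblast membrane
    "C_mf", "fg_Kv", "fg_K1", "f_INaK_max", "f_KmK", "f_KmNa",
    "f_VrevNaK", "f_BNaK", "fg_bNa", "f_Ki", "f_Nai", "f_Ko", "f_Nao",
    "ms_gmax", "ms_a_slope", "ms_vrev_short", "ms_vrev_long",
    "ms_len_lo", "ms_len_hi", "ms_on",
    "balance_tol",
]
P = {name: i for i, name in enumerate(_names)}
N_PARAMS = len(_names)


def pack_params(cfg: EnsembleConfig) -> np.ndarray:
    """Flatten a validated :class:`EnsembleConfig` into the kernel vector."""
    cfg.validate()
    ep, me, fb = cfg.ep, cfg.mech, cfg.fb
    v = np.zeros(N_PARAMS)

    def put(name, value):
        v[P[name]] = value

    for name in ("g_Na", "g_K1", "g_to", "g_Kr", "g_Ks", "p_KNa", "g_CaL",
                 "g_bNa", "g_bCa", "g_pCa", "k_pCa", "g_pK",
                 "P_NaK", "K_mK", "K_mNa",
                 "k_NaCa", "gamma_NaCa", "K_mCa", "K_mNai", "k_sat",
                 "alpha_NaCa", "K_o", "Na_o", "Ca_o", "C_myo",
                 "V_max_up", "K_up", "V_leak", "V_xfer",
                 "k_rel", "ryr_ko_ca", "ryr_ki_ca", "ryr_kom", "ryr_kim",
                 "ryr_ec50_sr", "ryr_max_sr", "ryr_min_sr",
                 "ryr_g_ig", "ryr_k_load", "ryr_k_cyt", "ryr_h_load",
                 "ryr_h_cyt",
                 "buf_c", "K_buf_c", "buf_sr", "K_buf_sr", "buf_ss",
                 "K_buf_ss", "V_c", "V_sr", "V_ss",
                 "ical_mult", "ikr_mult", "iks_mult", "serca_mult"):
        put(name, getattr(ep, name))

    put("stim_amp", cfg.pacing.amplitude)
    put("stim_dur", cfg.pacing.duration)
    put("pace_period", cfg.pacing.period)

    put("n_fb", 0 if cfg.mode == "single" else cfg.n)
    put("g_gap", cfg.g_gap)
    put("mode", cfg.mode_id)
    put("L_prep", cfg.initial_length)
    put("clamp_time", -1.0 if cfg.clamp_time is None else cfg.clamp_time)
    put("clamp_on", 0.0 if cfg.clamp_time is None else 1.0)

    for name in ("A_tot", "a_on", "k_off0", "k_A", "pi_min", "k_N",
                 "k_on_xb", "k_off_xb", "xb_v_sens", "perm_exp", "F_xb_max",
                 "v_max", "hill_a", "p_len_max", "len_b", "ov_s0", "ov_s1",
                 "alpha_PE", "beta_PE", "alpha_SE", "beta_SE",
                 "alpha_XSE", "beta_XSE", "mu_VS1", "mu_VS2",
                 "block_slack", "F_norm"):
        put(name, getattr(me, name))
    put("alpha_fb", me.alpha2fb)
    put("beta_fb", me.beta2fb)
    put("mech_fb_on", 1.0 if cfg.mode == "model2" else 0.0)
    put("l2_init", 0.0)  # overwritten by the simulator from the initial state

    put("C_mf", fb.C_mf)
    put("fg_Kv", fb.g_Kv)
    put("fg_K1", fb.g_K1)
    put("f_INaK_max", fb.I_NaK_max)
    put("f_KmK", fb.K_mK)
    put("f_KmNa", fb.K_mNa)
    put("f_VrevNaK", fb.V_rev_NaK)
    put("f_BNaK", fb.B_NaK)
    put("fg_bNa", fb.g_bNa)
    put("f_Ki", fb.K_i)
    put("f_Nai", fb.Na_i)
    put("f_Ko", fb.K_o)
    put("f_Nao", fb.Na_o)
    put("ms_gmax", fb.g_max * fb.gmax_mult)
    put("ms_a_slope", fb.a_slope)
    lo = fb.V_rev_lo * fb.vrev_mult
    hi = fb.V_rev_hi * fb.vrev_mult
    if fb.stretch_rev_negative:
        vrev_short, vrev_long = hi, lo
    else:
        vrev_short, vrev_long = lo, hi
    put("ms_vrev_short", vrev_short)
    put("ms_vrev_long", vrev_long)
    put("ms_len_lo", fb.length_lo)
    put("ms_len_hi", fb.length_hi)
    put("ms_on", 1.0 if cfg.mode == "model2" else 0.0)
    put("balance_tol", cfg.solver.balance_tol)
    return v


# ---------------------------------------------------------------------------
# packaged defaults
# ---------------------------------------------------------------------------

def _data_text(filename: str) -> str:
    return resources.files("myofib").joinpath("data", filename).read_text()


def load_param_file(text: Optional[str] = None) -> EnsembleConfig:
    """Build an :class:`EnsembleConfig` from a JSON parameter document.

    With no argument, loads the packaged default parameter file (which
    carries the calibrated mechanics/RyR/mechanosensitive values).
    """
    if text is None:
        text = _data_text("default_params.json")
    doc = json.loads(text)
    if doc.get("version") != PARAM_FILE_VERSION:
        raise ValueError("unsupported parameter-file version")
    cfg = EnsembleConfig(
        ep=MyocyteEPParams(**doc.get("ep", {})),
        mech=MechParams(**doc.get("mech", {})),
        fb=FibroblastParams(**doc.get("fb", {})),
    )
    cfg.validate()
    return cfg


def default_params() -> EnsembleConfig:
    """The packaged default configuration (calibrated parameter values)."""
    return load_param_file()


def dump_param_file(cfg: EnsembleConfig) -> str:
    doc = {
        "version": PARAM_FILE_VERSION,
        "ep": asdict(cfg.ep),
        "mech": asdict(cfg.mech),
        "fb": asdict(cfg.fb),
    }
    return json.dumps(doc, indent=1)
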