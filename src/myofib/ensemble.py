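"""Assembly and integration of the coupled myocyte-fibroblast system.

The preparation couples one human ventricular myocyte (TP06-style
electrophysiology plus an Ekaterinburg-style mechanics block) with ``n``
identical fibroblasts through ohmic gap junctions; in ``model2`` mode the
fibroblasts additionally load the myocyte elastically and carry a
length-dependent mechanosensitive current.  ``model1`` keeps only the
electrical coupling; ``single`` is the uncoupled myocyte.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np

from . import _core as core
from .params import EnsembleConfig, pack_params, P, default_params

__all__ = [
    "SimulationTrace",
    "SolverError",
    "initial_state",
    "simulate",
    "run_to_steady_state",
    "ensemble_rhs",
    "beat_metrics",
]

TRACE_SCHEMA_VERSION = "1"

# TP06 published initial conditions (quiescent epicardial myocyte)
_TP06_INIT = {
    "V": -85.23, "m": 0.00172, "h": 0.7444, "j": 0.7045, "d": 3.373e-5,
    "f": 0.7888, "f2": 0.9755, "fcass": 0.9953, "r": 2.42e-8, "s": 0.999998,
    "xr1": 0.00621, "xr2": 0.4712, "xs": 0.0095,
    "Na_i": 8.604, "K_i": 136.89, "Ca_i": 0.000126, "Ca_ss": 0.00036,
    "Ca_SR": 3.64,
}


class SolverError(RuntimeError):
    """Integration failure, carrying the failure time and state snapshot."""

    def __init__(self, message: str, t: float, state: np.ndarray):
        super().__init__(f"{message} at t = {t:.3f} ms")
        self.t = t
        self.state = state


@dataclass
class SimulationTrace:
    """Uniformly sampled record of a run.

    ``channels`` maps channel name -> 1-D array on the common time grid.
    Forces are normalised, potentials in mV, concentrations mM (CaTnC uM),
    strains in L_max units.
    """

    time: np.ndarray
    channels: dict
    config: EnsembleConfig
    schema_version: str = TRACE_SCHEMA_VERSION

    @property
    def n_fb(self) -> int:
        return 0 if self.config.mode == "single" else self.config.n

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    @property
    def output_dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"time": self.time, **self.channels})

    def slice(self, t0: float, t1: float) -> "SimulationTrace":
        m = (self.time >= t0) & (self.time <= t1)
        return SimulationTrace(self.time[m],
                               {k: v[m] for k, v in self.channels.items()},
                               self.config, self.schema_version)


CHANNEL_UNITS = {
    "V_myo": "mV", "Ca_i": "mM", "Ca_SR": "mM", "Ca_ss": "mM",
    "CaTnC": "uM", "N_xb": "1", "F_myo": "norm", "l1": "L_max",
    "l2": "L_max", "k_off": "1/ms", "catnc_off_flux": "uM/ms",
    "ryr_open": "1",
}


def _channel_names(n_fb: int):
    names = ["V_myo", "Ca_i", "Ca_SR", "Ca_ss", "CaTnC", "N_xb", "F_myo",
             "l1", "l2", "k_off", "catnc_off_flux", "ryr_open"]
    for i in range(n_fb):
        names.append(f"V_cf_{i + 1}")
        names.append(f"i_MS_{i + 1}")
    return names


def channel_units(name: str) -> str:
    if name in CHANNEL_UNITS:
        return CHANNEL_UNITS[name]
    if name.startswith("V_cf"):
        return "mV"
    if name.startswith("i_MS"):
        return "pA"
    if name == "time":
        return "ms"
    raise KeyError(name)


# ---------------------------------------------------------------------------
# initial conditions
# ---------------------------------------------------------------------------

def _passive_l2(p: np.ndarray) -> float:
    """Static passive balance: F_XSE(L - slack - l2) = F_PE + n*F_PEfb, l3 = 0."""
    n_mech = p[P["n_fb"]] * p[P["mech_fb_on"]]

    def h(l2):
        lx = p[P["L_prep"]] - p[P["block_slack"]] - l2
        return (core.elastic_force(p[P["alpha_XSE"]], p[P["beta_XSE"]], lx)
                - core.elastic_force(p[P["alpha_PE"]], p[P["beta_PE"]], l2)
                - n_mech * core.elastic_force(p[P["alpha_fb"]], p[P["beta_fb"]], l2))

    lo, hi = -0.3, p[P["L_prep"]] - p[P["block_slack"]] + 0.3
    if h(lo) < 0 or h(hi) > 0:
        raise SolverError("no passive balance root in bracket", 0.0, p)
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fb_rest_state(cfg: EnsembleConfig, with_ms: Optional[bool] = None) -> np.ndarray:
    """Resting (V_cf, r, s) of an isolated fibroblast by bisection on
    the total-membrane-current root in [-90, 0] mV."""
    p = pack_params(cfg)
    if with_ms is None:
        with_ms = cfg.mode == "model2"
    cur4 = np.empty(4)

    def net(v):
        r_inf, _, s_inf, _ = core.fb_gate_inf_tau(v)
        total = core.fb_current_sum(v, r_inf, s_inf, p, cur4)
        if with_ms:
            total += core.msc_current(v, cfg.initial_length, 0.0, p) / cfg.fb.C_mf
        return total

    lo, hi = -90.0, 0.0
    if net(lo) > 0 or net(hi) < 0:
        raise RuntimeError("no fibroblast resting root in [-90, 0] mV")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if net(mid) < 0:
            lo = mid
        else:
            hi = mid
    v = 0.5 * (lo + hi)
    r_inf, _, s_inf, _ = core.fb_gate_inf_tau(v)
    return np.array([v, r_inf, s_inf])


def _load_snapshots() -> dict:
    try:
        text = resources.files("myofib").joinpath(
            "data", "initial_states.json").read_text()
    except FileNotFoundError:
        return {}
    return json.loads(text)


_SNAPSHOTS_CACHE: Optional[dict] = None


def initial_state(cfg: EnsembleConfig) -> np.ndarray:
    """Initial full state: packaged pre-paced myocyte snapshot for the
    configured length when available (cold TP06 quiescent state otherwise),
    passive mechanical balance, fibroblasts at their isolated rest."""
    global _SNAPSHOTS_CACHE
    if _SNAPSHOTS_CACHE is None:
        _SNAPSHOTS_CACHE = _load_snapshots()
    cfg.validate()
    n_fb = 0 if cfg.mode == "single" else cfg.n
    y = np.zeros(core.NMYO + core.NFBSTATE * n_fb)

    key = f"{cfg.initial_length:.2f}"
    snap = _SNAPSHOTS_CACHE.get(key)
    if snap is not None:
        y[:core.NMYO] = np.asarray(snap, dtype=float)
    else:
        t = _TP06_INIT
        y[core.IV] = t["V"]
        for i, g in enumerate(["m", "h", "j", "d", "f", "f2", "fcass",
                               "r", "s", "xr1", "xr2", "xs"]):
            y[1 + i] = t[g]
        y[core.IRYR_R] = 0.98
        y[core.IRYR_O] = 0.0
        y[core.IRYR_I] = 0.0
        y[core.IRYR_RI] = 0.02
        y[core.INAI] = t["Na_i"]
        y[core.IKI] = t["K_i"]
        y[core.ICAI] = t["Ca_i"]
        y[core.ICASS] = t["Ca_ss"]
        y[core.ICASR] = t["Ca_SR"]
        y[core.ICATNC] = 3.0
        y[core.INXB] = 0.0
    # mechanics: passive balance for THIS ensemble (depends on n in model2)
    p = pack_params(cfg)
    l2 = _passive_l2(p)
    y[core.IL1] = l2
    y[core.IL2] = l2
    y[core.IKOFF] = -1.0
    if n_fb:
        fb = fb_rest_state(cfg)
        for i in range(n_fb):
            y[core.NMYO + 3 * i: core.NMYO + 3 * i + 3] = fb
    return y


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _prepare(cfg: EnsembleConfig, y0: Optional[np.ndarray]):
    cfg.validate()
    if y0 is None:
        y0 = initial_state(cfg)
    y = np.array(y0, dtype=float)
    n_fb = 0 if cfg.mode == "single" else cfg.n
    expect = core.NMYO + core.NFBSTATE * n_fb
    if y.size != expect:
        raise ValueError(
            f"state dimension {y.size} does not match ensemble "
            f"(myocyte + {n_fb} fibroblasts requires {expect})")
    p = pack_params(cfg)
    p[P["l2_init"]] = y[core.IL2]
    return y, p, n_fb


def simulate(cfg: EnsembleConfig, y0: Optional[np.ndarray] = None,
             return_state: bool = False):
    """Integrate the configured run and return a :class:`SimulationTrace`.

    Deterministic given the configuration (there is no randomness anywhere
    in the model).  ``y0`` overrides the packaged initial state, e.g. to
    continue a previous run from its final state.
    """
    y, p, n_fb = _prepare(cfg, y0)
    dt = cfg.solver.dt
    n_steps = int(round(cfg.duration / dt))
    spo = max(1, int(round(cfg.solver.output_dt / dt)))
    n_out = n_steps // spo + 1
    times = np.empty(n_out)
    chans = np.empty((core.NCH_BASE + core.NCH_PER_FB * n_fb, n_out))
    try:
        status, t_end = core.integrate(y, p, 0.0, n_steps, dt, spo, times,
                                       chans)
    except (ZeroDivisionError, FloatingPointError, ValueError) as err:
        raise SolverError(f"numerical failure ({err})", float("nan"), y) \
            from err
    if status == 1:
        raise SolverError("mechanics force-balance solver failure", t_end, y)
    if status == 2:
        raise SolverError("non-finite state", t_end, y)
    names = _channel_names(n_fb)
    trace = SimulationTrace(times, {nm: chans[i] for i, nm in enumerate(names)},
                            cfg)
    if return_state:
        return trace, y
    return trace


def ensemble_rhs(t: float, y: np.ndarray, cfg: EnsembleConfig) -> np.ndarray:
    """Full derivative vector of the coupled system at (t, y).

    Reference (non-compiled) assembly of the same equations the integrator
    uses; intended for inspection and invariant tests.  Gate derivatives are
    the plain HH forms (gate_inf - gate)/tau.
    """
    cfg.validate()
    n_fb = 0 if cfg.mode == "single" else cfg.n
    expect = core.NMYO + core.NFBSTATE * n_fb
    if y.size != expect:
        raise ValueError("state dimension mismatch")
    p = pack_params(cfg)
    p[P["l2_init"]] = y[core.IL2]  # rhs treats current l2 as the reference
    d = np.zeros_like(y)
    cur = np.empty(core.N_CURRENTS)
    i_sum = core.tp06_currents(y, p, cur)
    i_stim = core.stimulus(t, p)
    gap = 0.0
    for i in range(n_fb):
        gap += cfg.g_gap * (y[core.IV] - y[core.NMYO + 3 * i])
    d[core.IV] = -(i_sum + i_stim + gap / cfg.ep.C_myo)

    ginf = np.empty(core.N_GATES)
    gtau = np.empty(core.N_GATES)
    core.tp06_gate_inf_tau(y[core.IV], y[core.ICASS], ginf, gtau)
    d[1:13] = (ginf - y[1:13]) / gtau

    d4 = np.empty(4)
    i_rel = core.ryr_derivs(y, p, d4)
    d[core.IRYR_R:core.IRYR_RI + 1] = d4

    i_up, i_leak, i_xfer = core.sr_fluxes(y, p)
    v1, v2, f_xse, ok = core.solve_balance(y, p)
    if not ok:
        raise SolverError("mechanics force-balance solver failure", t, y)
    s_frac = cfg.mech.block_slack + y[core.IL1]
    d_catnc = core.catnc_derivative(y[core.ICATNC], y[core.ICAI],
                                    y[core.INXB], p, y[core.IKOFF])
    cap_uf = cfg.ep.C_myo * 1e-3
    vc, vsr, vss = cfg.ep.V_c, cfg.ep.V_sr, cfg.ep.V_ss
    F = core.FARADAY
    bufc = 1.0 / (1.0 + cfg.ep.buf_c * cfg.ep.K_buf_c
                  / (y[core.ICAI] + cfg.ep.K_buf_c) ** 2)
    d[core.ICAI] = bufc * ((i_leak - i_up) * vsr / vc + i_xfer
                           - (cur[core.CUR_BCA] + cur[core.CUR_PCA]
                              - 2 * cur[core.CUR_NACA]) * cap_uf / (2 * vc * F)
                           - d_catnc * 1e-3)
    bufss = 1.0 / (1.0 + cfg.ep.buf_ss * cfg.ep.K_buf_ss
                   / (y[core.ICASS] + cfg.ep.K_buf_ss) ** 2)
    d[core.ICASS] = bufss * (-i_xfer * vc / vss + i_rel * vsr / vss
                             - cur[core.CUR_CAL] * cap_uf / (2 * vss * F))
    bufsr = 1.0 / (1.0 + cfg.ep.buf_sr * cfg.ep.K_buf_sr
                   / (y[core.ICASR] + cfg.ep.K_buf_sr) ** 2)
    d[core.ICASR] = bufsr * (i_up - i_leak - i_rel)
    d[core.INAI] = -(cur[core.CUR_NA] + cur[core.CUR_BNA]
                     + 3 * cur[core.CUR_NAK] + 3 * cur[core.CUR_NACA]) \
        * cap_uf / (vc * F)
    d[core.IKI] = -(cur[core.CUR_K1] + cur[core.CUR_TO] + cur[core.CUR_KR]
                    + cur[core.CUR_KS] + cur[core.CUR_PK]
                    - 2 * cur[core.CUR_NAK] + i_stim) * cap_uf / (vc * F)
    d[core.ICATNC] = d_catnc
    d[core.INXB] = core.xb_derivative(y[core.INXB], y[core.ICATNC],
                                      s_frac, v1, p)
    d[core.IL1] = v1
    d[core.IL2] = v2

    ell = cfg.initial_length + (y[core.IL2] - p[P["l2_init"]])
    dl = y[core.IL2] - p[P["l2_init"]]
    fcur = np.empty(4)
    for i in range(n_fb):
        base = core.NMYO + 3 * i
        vf = y[base]
        icf = core.fb_current_sum(vf, y[base + 1], y[base + 2], p, fcur)
        extra = cfg.g_gap * (vf - y[core.IV])
        if cfg.mode == "model2":
            extra += core.msc_current(vf, ell, dl, p)
        d[base] = -(icf + extra / cfg.fb.C_mf)
        r_inf, tau_r, s_inf, tau_s = core.fb_gate_inf_tau(vf)
        d[base + 1] = (r_inf - y[base + 1]) / tau_r
        d[base + 2] = (s_inf - y[base + 2]) / tau_s
    return d


# ---------------------------------------------------------------------------
# per-beat metrics and steady-state pacing
# ---------------------------------------------------------------------------

def beat_metrics(time: np.ndarray, v: np.ndarray, ca: np.ndarray,
                 force: np.ndarray, period: float) -> dict:
    """Scalar measures of one pacing cycle sampled on a uniform grid."""
    rp_mask = (time >= time[0] + period - 15.0) & (time <= time[0] + period - 5.0)
    rp = float(np.mean(v[rp_mask])) if rp_mask.any() else float(v[-1])
    v_peak = float(np.max(v))
    v90 = rp + 0.1 * (v_peak - rp)
    above = v > v90
    apd90 = float(np.count_nonzero(above)) * (time[1] - time[0]) \
        if time.size > 1 else 0.0
    return {
        "rp": rp,
        "v_peak": v_peak,
        "apd90": apd90,
        "ca_peak": float(np.max(ca)),
        "ca_diast": float(np.min(ca)),
        "force_peak": float(np.max(force)),
        # active (developed) force: the preparation force minus its passive
        # diastolic offset, which grows with every parallel fibroblast spring
        "force_active": float(np.max(force) - np.min(force)),
    }


def run_to_steady_state(cfg: EnsembleConfig, tol: float = 1e-3,
                        max_beats: int = 100, keep_beats: int = 2):
    """Pace until beat-to-beat convergence of (APD90, Ca peak, force peak, RP).

    Returns ``(trace, info)`` where ``trace`` spans the final ``keep_beats``
    cycles and ``info`` carries ``beats``, ``converged`` and ``alternans``
    (period-2 flag: beats k and k+2 agree while k and k+1 do not).
    """
    cfg.validate()
    period = cfg.pacing.period
    y = initial_state(cfg)
    beat_cfg = replace(cfg, duration=period)
    history: list[dict] = []
    traces: list[SimulationTrace] = []
    converged = False
    alternans = False
    beats = 0
    keys = ("apd90", "ca_peak", "force_peak")
    for beat in range(max_beats):
        trace, y = simulate(beat_cfg, y0=y, return_state=True)
        trace = SimulationTrace(trace.time + beat * period, trace.channels,
                                cfg, trace.schema_version)
        traces.append(trace)
        if len(traces) > max(keep_beats, 4):
            traces.pop(0)
        m = beat_metrics(trace.time, trace["V_myo"], trace["Ca_i"],
                         trace["F_myo"], period)
        history.append(m)
        beats = beat + 1
        if len(history) >= 2:
            prev = history[-2]
            diff1 = max(_rel(m[k], prev[k]) for k in keys) \
                + abs(m["rp"] - prev["rp"]) / 100.0
            if diff1 < tol and beats >= 2:
                converged = True
                break
            if len(history) >= 3:
                prev2 = history[-3]
                diff2 = max(_rel(m[k], prev2[k]) for k in keys)
                if diff2 < tol and diff1 > 10 * tol:
                    converged = True
                    alternans = True
                    break
    tail = traces[-keep_beats:]
    time = np.concatenate([t.time for t in tail])
    channels = {k: np.concatenate([t.channels[k] for t in tail])
                for k in tail[0].channels}
    out = SimulationTrace(time, channels, cfg)
    info = {"beats": beats, "converged": converged, "alternans": alternans,
            "metrics": history[-1], "final_state": y}
    return out, info


def _rel(a: float, b: float) -> float:
    scale = max(abs(a), abs(b), 1e-12)
    return abs(a - b) / scale
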