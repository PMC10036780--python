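"""Electrophysiology of the human ventricular myocyte.

TP06-style sarcolemmal currents, a four-state (R/O/I/RI) ryanodine-receptor
ring with luminal-load regulation, SR/cytosol Ca2+ translocation and the
pacing stimulus.  These are thin, validated wrappers over the compiled core;
the same code paths drive the full ensemble integrator.

State is the flat myocyte vector documented in :mod:`myofib._core`; the
:class:`MyocyteElectricalState` dataclass offers a named view of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core as core
from .params import EnsembleConfig, MyocyteEPParams, PacingProtocol, pack_params

__all__ = [
    "MyocyteElectricalState",
    "CurrentSet",
    "ep_currents",
    "gating_derivatives",
    "ryr_release",
    "sr_cytosol_fluxes",
    "apply_stimulus",
    "GATE_NAMES",
    "CURRENT_NAMES",
]

GATE_NAMES = ("m", "h", "j", "d", "f", "f2", "fcass", "r", "s",
              "xr1", "xr2", "xs")
CURRENT_NAMES = ("i_CaL", "i_bCa", "i_K1", "i_to", "i_Kr", "i_Ks", "i_pK",
                 "i_Na", "i_bNa", "i_pCa", "i_NaK", "i_NaCa")

_STATE_FIELDS = {
    "V_myo": core.IV, "Na_i": core.INAI, "K_i": core.IKI, "Ca_i": core.ICAI,
    "Ca_SS": core.ICASS, "Ca_SR": core.ICASR, "CaTnC": core.ICATNC,
}


@dataclass
class MyocyteElectricalState:
    """Named view of the electrical part of the myocyte state vector."""

    V_myo: float
    gates: np.ndarray            # 12 HH gates, order of GATE_NAMES
    ryr_occupancies: np.ndarray  # R, O, I, RI
    Na_i: float
    K_i: float
    Ca_i: float
    Ca_SS: float
    Ca_SR: float
    CaTnC: float
    buffer2: float = 0.0         # residual instantaneous buffer occupancy

    @classmethod
    def from_vector(cls, y: np.ndarray) -> "MyocyteElectricalState":
        return cls(V_myo=float(y[core.IV]),
                   gates=np.array(y[1:13]),
                   ryr_occupancies=np.array(y[13:17]),
                   Na_i=float(y[core.INAI]), K_i=float(y[core.IKI]),
                   Ca_i=float(y[core.ICAI]), Ca_SS=float(y[core.ICASS]),
                   Ca_SR=float(y[core.ICASR]), CaTnC=float(y[core.ICATNC]))

    def to_vector(self) -> np.ndarray:
        y = np.zeros(core.NMYO)
        y[core.IV] = self.V_myo
        y[1:13] = self.gates
        y[13:17] = self.ryr_occupancies
        y[core.INAI], y[core.IKI] = self.Na_i, self.K_i
        y[core.ICAI], y[core.ICASS] = self.Ca_i, self.Ca_SS
        y[core.ICASR], y[core.ICATNC] = self.Ca_SR, self.CaTnC
        y[core.IKOFF] = -1.0
        return y

    def validate(self) -> None:
        for name, idx in _STATE_FIELDS.items():
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"non-finite state variable: {name}")
        if not np.all(np.isfinite(self.gates)):
            bad = GATE_NAMES[int(np.flatnonzero(~np.isfinite(self.gates))[0])]
            raise ValueError(f"non-finite state variable: gate {bad}")
        if np.any(self.gates < -1e-9) or np.any(self.gates > 1 + 1e-9):
            raise ValueError("gates must lie in [0, 1]")
        occ = self.ryr_occupancies
        if np.any(occ < -1e-9):
            raise ValueError("RyR occupancies must be non-negative")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"RyR occupancies must sum to 1 (got {occ.sum():.12f})")
        for name in ("Na_i", "K_i", "Ca_i", "Ca_SS", "Ca_SR", "CaTnC"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CurrentSet:
    """All sarcolemmal currents (pA/pF) and Ca2+ translocation fluxes (mM/ms)
    of the myocyte at one instant."""

    i_CaL: float
    i_bCa: float
    i_K1: float
    i_to: float
    i_Kr: float
    i_Ks: float
    i_pK: float
    i_Na: float
    i_bNa: float
    i_pCa: float
    i_NaK: float
    i_NaCa: float
    I_rel: float
    I_xfer: float
    I_leak: float
    I_up: float

    @property
    def i_myo_total(self) -> float:
        """Sum of the sarcolemmal currents (pA/pF)."""
        return (self.i_CaL + self.i_bCa + self.i_K1 + self.i_to + self.i_Kr
                + self.i_Ks + self.i_pK + self.i_Na + self.i_bNa + self.i_pCa
                + self.i_NaK + self.i_NaCa)

    def as_dict(self) -> dict:
        d = {n: getattr(self, n) for n in CURRENT_NAMES}
        d.update(I_rel=self.I_rel, I_xfer=self.I_xfer,
                 I_leak=self.I_leak, I_up=self.I_up)
        return d


def _as_vector(state) -> np.ndarray:
    if isinstance(state, MyocyteElectricalState):
        state.validate()
        return state.to_vector()
    y = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(y[:core.NMYO])):
        idx = int(np.flatnonzero(~np.isfinite(y[:core.NMYO]))[0])
        raise ValueError(f"non-finite state entry at index {idx}")
    return y


def _pack(params: MyocyteEPParams | None) -> np.ndarray:
    cfg = EnsembleConfig(mode="single")
    if params is not None:
        cfg.ep = params
    return pack_params(cfg)


def ep_currents(state, params: MyocyteEPParams | None = None) -> CurrentSet:
    """All membrane currents and Ca2+ fluxes at the instantaneous state.

    The L-type current scales linearly with ``params.ical_mult``; ``i_Kr``,
    ``i_Ks`` and the SERCA uptake scale with their respective multipliers.
    """
    y = _as_vector(state)
    p = _pack(params)
    cur = np.empty(core.N_CURRENTS)
    core.tp06_currents(y, p, cur)
    i_up, i_leak, i_xfer = core.sr_fluxes(y, p)
    i_rel = p[core.P_k_rel] * y[core.IRYR_O] * (y[core.ICASR] - y[core.ICASS])
    return CurrentSet(*[float(c) for c in cur],
                      I_rel=float(i_rel), I_xfer=float(i_xfer),
                      I_leak=float(i_leak), I_up=float(i_up))


def gating_derivatives(state) -> np.ndarray:
    """HH gate rates d(gate)/dt = (gate_inf(V) - gate) / tau(V), in 1/ms."""
    y = _as_vector(state)
    inf = np.empty(core.N_GATES)
    tau = np.empty(core.N_GATES)
    core.tp06_gate_inf_tau(y[core.IV], y[core.ICASS], inf, tau)
    return (inf - y[1:13]) / tau


def ryr_release(state, params: MyocyteEPParams | None = None):
    """RyR release flux and ring-occupancy derivatives.

    Returns ``(I_rel, d_occupancies)`` with ``I_rel`` in mM/ms (SR volume)
    and the four occupancy derivatives summing to zero.
    """
    y = _as_vector(state)
    occ = y[13:17]
    if abs(occ.sum() - 1.0) > 1e-6:
        raise ValueError(
            f"RyR occupancy sum violated: {occ.sum():.9f} (must be 1)")
    p = _pack(params)
    d4 = np.empty(4)
    i_rel = core.ryr_derivs(y, p, d4)
    return float(i_rel), d4


def sr_cytosol_fluxes(state, params: MyocyteEPParams | None = None):
    """(I_up, I_leak, I_xfer) in mM/ms; I_up scales with the SERCA multiplier."""
    y = _as_vector(state)
    p = _pack(params)
    return tuple(float(f) for f in core.sr_fluxes(y, p))


def apply_stimulus(t: float, protocol: PacingProtocol | None = None) -> float:
    """Stimulus current (pA/pF, negative = inward) at time ``t``.

    Rectangular pulses of the configured amplitude/duration with onsets at
    t = 0, period, 2*period, ...
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    protocol = protocol or PacingProtocol()
    protocol.validate()
    cfg = EnsembleConfig(mode="single", pacing=protocol)
    p = pack_params(cfg)
    return float(core.stimulus(t, p))
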