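"""Active fibroblast membrane model and the mechanosensitive current.

Four MacCannell-style membrane currents (delayed-rectifier K+, inward
rectifier K+, Na/K pump, background Na+ leak) plus the length-dependent
mechanosensitive current

    i_MS(dl, V_cf) = g_max * a(dl) * (V_cf - V_rev(l)),

with an affine deformation factor ``a`` (``a(0) = 1``) and an affine
reversal potential spanning [-38, -30] mV over the 80-90 % L_max working
range.  A negative i_MS depolarises the fibroblast.  The current carries
unspecified positive charge: it moves V_cf only and never touches the
(fixed) fibroblast ion concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _core as core
from .params import EnsembleConfig, FibroblastParams, pack_params

__all__ = [
    "FibroblastState",
    "fb_ionic_currents",
    "msc_current",
    "msc_calibration",
    "fb_membrane_derivative",
    "fb_resting_potential",
]

FB_CURRENT_NAMES = ("i_Kv", "i_K1", "i_NaK", "i_bNa")


@dataclass
class FibroblastState:
    """Membrane potential and delayed-rectifier gates of one fibroblast."""

    V_cf: float = -49.6
    r_Kv: float = 0.0
    s_Kv: float = 1.0

    def validate(self) -> None:
        if not (-1e-9 <= self.r_Kv <= 1 + 1e-9) or \
                not (-1e-9 <= self.s_Kv <= 1 + 1e-9):
            raise ValueError("Kv gates must lie in [0, 1]")


def _pack(params: FibroblastParams | None, mode="model2",
          initial_length=0.90) -> np.ndarray:
    cfg = EnsembleConfig(mode=mode, n=1, g_gap=0.5,
                         initial_length=initial_length)
    if params is not None:
        cfg.fb = params
    return pack_params(cfg)


def fb_ionic_currents(state: FibroblastState,
                      params: FibroblastParams | None = None):
    """Total ionic current i_cf (pA/pF) and the per-current breakdown.

    i_MS is *not* part of this sum; it enters the membrane equation
    separately (and only in model-2 mode).
    """
    state.validate()
    p = _pack(params)
    cur4 = np.empty(4)
    total = core.fb_current_sum(state.V_cf, state.r_Kv, state.s_Kv, p, cur4)
    return float(total), dict(zip(FB_CURRENT_NAMES, (float(c) for c in cur4)))


def msc_current(dl: float, V_cf: float,
                params: FibroblastParams | None = None,
                length: float | None = None,
                initial_length: float = 0.90) -> float:
    """Mechanosensitive current i_MS in pA.

    ``dl`` is the deformation relative to the run's initial length (in
    L_max units); ``length`` defaults to ``initial_length + dl``.  Negative
    values depolarise the fibroblast, positive values repolarise it.
    """
    p = _pack(params, initial_length=initial_length)
    ell = initial_length + dl if length is None else length
    return float(core.msc_current(V_cf, ell, dl, p))


def msc_calibration(params: FibroblastParams | None = None):
    """The calibrated affine pieces of i_MS.

    Returns ``(a, v_rev)``: ``a(dl)`` with ``a(0) = 1``, and ``v_rev(l)``
    mapping a length fraction in the working range onto the reversal
    potential, hitting the two configured endpoints exactly.
    """
    params = params or FibroblastParams()
    params.validate()
    if not params.length_lo < params.length_hi:
        raise ValueError("degenerate working length range")
    p = _pack(params)

    def a(dl: float) -> float:
        return max(1.0 + params.a_slope * dl, 0.05)

    def v_rev(length: float) -> float:
        return float(core.msc_vrev(length, p))

    return a, v_rev


def fb_membrane_derivative(state: FibroblastState, V_myo: float,
                           g_gap: float, dl: float,
                           params: FibroblastParams | None = None,
                           mode: str = "model2",
                           initial_length: float = 0.90) -> float:
    """dV_cf/dt (mV/ms) of one coupled fibroblast.

    ``model1`` omits i_MS; ``model2`` includes it.  The gap-junction term
    is ``g_gap * (V_cf - V_myo)`` in pA.
    """
    if g_gap < 0:
        raise ValueError("g_gap must be non-negative")
    if mode not in ("model1", "model2"):
        raise ValueError("mode must be 'model1' or 'model2'")
    state.validate()
    params = params or FibroblastParams()
    p = _pack(params, initial_length=initial_length)
    cur4 = np.empty(4)
    icf = core.fb_current_sum(state.V_cf, state.r_Kv, state.s_Kv, p, cur4)
    extra = g_gap * (state.V_cf - V_myo)
    if mode == "model2":
        extra += core.msc_current(state.V_cf, initial_length + dl, dl, p)
    return float(-(icf + extra / params.C_mf))


def fb_resting_potential(params: FibroblastParams | None = None,
                         with_ms: bool = False,
                         initial_length: float = 0.90) -> float:
    """Resting potential of an isolated fibroblast (bisection on the total
    membrane current in [-90, 0] mV), with or without i_MS."""
    from .ensemble import fb_rest_state
    cfg = EnsembleConfig(mode="model2" if with_ms else "model1", n=1,
                         g_gap=0.5, initial_length=initial_length)
    if params is not None:
        cfg.fb = params
    return float(fb_rest_state(cfg, with_ms=with_ms)[0])
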