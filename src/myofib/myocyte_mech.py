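"""Mechanics of the myocyte and the force balance of the preparation.

Cooperative Ca-TnC kinetics, mean-field cross-bridge kinetics with
length-dependent activation, and the rheological scheme: external series
element XSE in series with a parallel block of {passive element PE, the n
fibroblast elastic elements PEfb, and the contractile chain CE+VS1 in
series with SE+VS2}.  The accepted force balance is

    F_myo = F_XSE = F_PE + n * F_PEfb + F_CE + F_VS1

with the whole-preparation length held fixed (isometric mode); internal
compliance still lets the sarcomeres shorten during a twitch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _core as core
from .params import EnsembleConfig, MechParams, pack_params, P

__all__ = [
    "MechanicalState",
    "ForceSet",
    "catnc_rate",
    "xb_kinetics",
    "element_forces",
    "solve_isometric_balance",
    "sarcomere_fraction",
]


@dataclass
class MechanicalState:
    """Mechanical coordinates of the preparation.

    Strains are in units of ``L_max`` above the slack length of the
    respective element; ``L_prep`` is the whole-preparation length as a
    fraction of ``L_max``.
    """

    L_prep: float = 0.90
    l1: float = 0.0     # contractile-element (sarcomere) strain
    l2: float = 0.0     # parallel-block strain (shared by PE and each PEfb)
    l3: float = 0.0     # series-element strain; kinematics: l3 = l2 - l1
    N_xb: float = 0.0   # attached force-generating cross-bridge fraction
    v1: float = 0.0     # CE strain rate (L_max/ms, shortening negative)

    def validate(self) -> None:
        if not (0.0 <= self.N_xb <= 1.0):
            raise ValueError("N_xb must lie in [0, 1]")
        for name in ("L_prep", "l1", "l2", "l3", "N_xb", "v1"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite mechanical state: {name}")


@dataclass
class ForceSet:
    """Forces of the rheological elements, normalised to the peak
    steady-state isometric force of the uncoupled myocyte at 90 % L_max."""

    F_CE: float
    F_PE: float
    F_PEfb: float     # per fibroblast
    F_SE: float
    F_XSE: float
    F_VS1: float
    F_VS2: float
    n: int

    @property
    def F_myo(self) -> float:
        return self.F_XSE

    @property
    def balance_residual(self) -> float:
        """Residual of F_XSE - (F_PE + n*F_PEfb + F_CE + F_VS1)."""
        return self.F_XSE - (self.F_PE + self.n * self.F_PEfb
                             + self.F_CE + self.F_VS1)


def _pack(params: MechParams | None, n: int = 0, L_prep: float = 0.90):
    cfg = EnsembleConfig(mode="model2" if n > 0 else "single", n=n,
                         initial_length=L_prep)
    if params is not None:
        cfg.mech = params
    return pack_params(cfg)


def sarcomere_fraction(l1: float, params: MechParams | None = None) -> float:
    """Instantaneous sarcomere length as a fraction of L_max."""
    params = params or MechParams()
    return params.block_slack + l1


def catnc_rate(CaTnC: float, Ca_i: float, N_xb: float,
               params: MechParams | None = None,
               clamp: float | None = None) -> float:
    """dCaTnC/dt in uM/ms.

    ``k_off(N_xb, CaTnC)`` is strictly decreasing in the attached
    cross-bridge fraction (the cooperativity that feeds mechano-calcium
    feedback); passing ``clamp`` freezes the off-rate at that value, which
    is the ablation used by the cooperativity-clamp experiment.
    """
    params = params or MechParams()
    if CaTnC > params.A_tot * (1 + 1e-9):
        raise ValueError(f"CaTnC = {CaTnC} exceeds A_tot = {params.A_tot}")
    p = _pack(params)
    frozen = -1.0 if clamp is None else float(clamp)
    return float(core.catnc_derivative(CaTnC, Ca_i, N_xb, p, frozen))


def catnc_off_rate(CaTnC: float, N_xb: float,
                   params: MechParams | None = None) -> float:
    """The cooperative CaTnC off-rate (1/ms) itself."""
    p = _pack(params or MechParams())
    return float(core.catnc_off_rate(CaTnC, N_xb, p))


def xb_kinetics(state: MechanicalState, CaTnC: float,
                params: MechParams | None = None) -> float:
    """dN_xb/dt in 1/ms.

    Attachment grows with CaTnC and sarcomere length (length-dependent
    activation, the origin of mechano-electric feedback); detachment grows
    with |velocity|.  The rate keeps N_xb inside [0, 1].
    """
    state.validate()
    params = params or MechParams()
    p = _pack(params)
    s = sarcomere_fraction(state.l1, params)
    return float(core.xb_derivative(state.N_xb, CaTnC, s, state.v1, p))


def element_forces(state: MechanicalState, params: MechParams | None = None,
                   n: int = 0) -> ForceSet:
    """Forces of every rheological element at the given configuration."""
    state.validate()
    params = params or MechParams()
    p = _pack(params, n=n, L_prep=state.L_prep)
    l3 = state.l2 - state.l1
    lx = state.L_prep - params.block_slack - state.l2
    f_norm = params.F_norm
    f_ce = core.f_ce(state.N_xb, state.v1, p) / f_norm
    f_pe = core.elastic_force(params.alpha_PE, params.beta_PE, state.l2) / f_norm
    f_fb = core.elastic_force(params.alpha2fb, params.beta2fb, state.l2) / f_norm
    f_se = core.elastic_force(params.alpha_SE, params.beta_SE, l3) / f_norm
    f_xse = core.elastic_force(params.alpha_XSE, params.beta_XSE, lx) / f_norm
    # viscous forces require both internal strain rates; v2 follows from the
    # VS2 branch when the balance is solved, here report the VS1 part only
    f_vs1 = params.mu_VS1 * state.v1 / f_norm
    f_vs2 = 0.0
    return ForceSet(F_CE=f_ce, F_PE=f_pe, F_PEfb=f_fb, F_SE=f_se,
                    F_XSE=f_xse, F_VS1=f_vs1, F_VS2=f_vs2, n=n)


def solve_isometric_balance(state: MechanicalState, CaTnC: float,
                            params: MechParams | None = None,
                            n: int = 0):
    """Internal strain rates under the isometric whole-preparation constraint.

    Returns ``(dl1, dl2, dl3)`` in L_max/ms such that the accepted force
    balance holds to the solver tolerance; each attached fibroblast adds one
    ``F_PEfb`` term to the parallel block.  Raises :class:`RuntimeError`
    when no root lies in the velocity bracket.
    """
    state.validate()
    params = params or MechParams()
    p = _pack(params, n=n, L_prep=state.L_prep)
    y = np.zeros(core.NMYO)
    y[core.IL1] = state.l1
    y[core.IL2] = state.l2
    y[core.INXB] = state.N_xb
    y[core.ICATNC] = CaTnC
    v1, v2, f_xse, ok = core.solve_balance(y, p)
    if not ok:
        raise RuntimeError(
            "no force-balance root in the velocity bracket "
            f"(state l1={state.l1:.4f}, l2={state.l2:.4f}, N_xb={state.N_xb:.4f})")
    return float(v1), float(v2), float(v2 - v1)


def balance_residual(state: MechanicalState, CaTnC: float,
                     params: MechParams | None = None, n: int = 0) -> float:
    """Residual of the accepted force balance after solving for velocities."""
    params = params or MechParams()
    v1, v2, _ = solve_isometric_balance(state, CaTnC, params, n)
    solved = MechanicalState(L_prep=state.L_prep, l1=state.l1, l2=state.l2,
                             l3=state.l2 - state.l1, N_xb=state.N_xb, v1=v1)
    fs = element_forces(solved, params, n)
    return fs.balance_residual
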