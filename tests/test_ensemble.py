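"""Coupled-system assembly, integration, determinism, steady-state pacing."""

from dataclasses import replace

import numpy as np
import pytest

from myofib import (EnsembleConfig, ensemble_rhs, initial_state,
                    run_to_steady_state, simulate)
from myofib import _core as core
from myofib.params import FibroblastParams, MechParams, MyocyteEPParams


def test_config_invariants():
    with pytest.raises(ValueError):
        EnsembleConfig(mode="single", n=2).validate()
    with pytest.raises(ValueError):
        EnsembleConfig(n=-1).validate()
    with pytest.raises(ValueError):
        EnsembleConfig(g_gap=-0.5).validate()
    with pytest.raises(ValueError):
        EnsembleConfig(initial_length=0.5).validate()


def test_rhs_dimension_mismatch_rejected():
    cfg = EnsembleConfig(mode="model2", n=2, g_gap=1.0)
    with pytest.raises(ValueError, match="dimension"):
        ensemble_rhs(0.0, np.zeros(core.NMYO), cfg)


def test_rhs_n_zero_identical_to_single(rest_state):
    cfg1 = EnsembleConfig(mode="model1", n=0, g_gap=0.0)
    cfg0 = EnsembleConfig(mode="single")
    d1 = ensemble_rhs(500.0, rest_state, cfg1)
    d0 = ensemble_rhs(500.0, rest_state, cfg0)
    np.testing.assert_array_equal(d0, d1)


def test_gap_charge_antisymmetry():
    """The gap charge leaving the myocyte equals the total gap charge
    entering the fibroblasts (same g*(dV) terms, opposite signs)."""
    cfg = EnsembleConfig(mode="model1", n=3, g_gap=2.0)
    y = initial_state(cfg)
    y[core.NMYO::3] = [-45.0, -50.0, -55.0][:3]  # spread the fibroblasts
    d_on = ensemble_rhs(500.0, y, cfg)
    d_off = ensemble_rhs(500.0, y, replace(cfg, g_gap=0.0))
    c_myo = cfg.ep.C_myo
    c_mf = cfg.fb.C_mf
    myo_gap_charge = -(d_on[core.IV] - d_off[core.IV]) * c_myo
    fb_gap_charge = sum(-(d_on[core.NMYO + 3 * i] - d_off[core.NMYO + 3 * i]) * c_mf
                        for i in range(3))
    assert myo_gap_charge == pytest.approx(-fb_gap_charge, rel=1e-9)


def test_model_delta_is_exactly_msc_and_fibroblast_elasticity():
    """At an identical state, the model1/model2 derivative difference sits
    only in the i_MS terms of the fibroblasts and the PEfb terms of the
    mechanics; the myocyte membrane-potential derivative is untouched."""
    cfg2 = EnsembleConfig(mode="model2", n=2, g_gap=2.0)
    y = initial_state(cfg2)
    cfg1 = replace(cfg2, mode="model1")
    d2 = ensemble_rhs(100.0, y, cfg2)
    d1 = ensemble_rhs(100.0, y, cfg1)
    # myocyte voltage and EP states identical
    np.testing.assert_allclose(d1[:core.ICATNC], d2[:core.ICATNC], rtol=0, atol=1e-15)
    # fibroblast delta equals -i_MS / C_mf
    from myofib.fibroblast import msc_current
    for i in range(2):
        base = core.NMYO + 3 * i
        ims = msc_current(0.0, y[base], cfg2.fb, length=cfg2.initial_length)
        assert d2[base] - d1[base] == pytest.approx(-ims / cfg2.fb.C_mf, rel=1e-9)


def test_deterministic_bitwise():
    cfg = EnsembleConfig(mode="model2", n=2, g_gap=1.0, duration=500.0)
    a = simulate(cfg)
    b = simulate(cfg)
    np.testing.assert_array_equal(a["V_myo"], b["V_myo"])
    np.testing.assert_array_equal(a["Ca_i"], b["Ca_i"])


def test_halving_dt_changes_voltage_little():
    """Time-step convergence: halving dt moves V_myo by < 0.5 mV sup-norm
    over the final beat."""
    base = EnsembleConfig(mode="single", duration=2000.0)
    fine = replace(base, solver=replace(base.solver, dt=0.01))
    v1 = simulate(base)["V_myo"]
    v2 = simulate(fine)["V_myo"]
    # skip the 10-ms upstroke, where a sub-sample phase shift of the
    # near-vertical AP front dominates the pointwise difference
    last = slice(-990, None)
    assert np.max(np.abs(v1[last] - v2[last])) < 0.5


def test_trace_grid_uniform():
    cfg = EnsembleConfig(mode="single", duration=300.0)
    tr = simulate(cfg)
    dt = np.diff(tr.time)
    assert np.allclose(dt, dt[0])
    n = len(tr.time)
    assert all(len(v) == n for v in tr.channels.values())


def test_run_to_steady_state_fast_from_fixed_point():
    tr, info = run_to_steady_state(EnsembleConfig(mode="single", duration=1000.0),
                                   max_beats=20)
    assert info["converged"] and not info["alternans"]
    assert info["beats"] <= 5


def test_calcium_overload_produces_sr_alternans():
    """Doubling the L-type conductance drives the SR into a period-2
    regime: the Ca_SR (and Ca-transient) amplitudes alternate beat to
    beat, unlike at normal conductance."""
    cfg = EnsembleConfig(mode="single", duration=1000.0,
                         ep=MyocyteEPParams(ical_mult=2.0))
    tr, info = run_to_steady_state(cfg, tol=0.002, max_beats=100)
    assert info["alternans"]


def test_solver_failure_raises_with_time():
    from myofib.ensemble import SolverError
    bad = EnsembleConfig(mode="single", duration=100.0,
                         ep=MyocyteEPParams(g_Na=1e6))
    with pytest.raises(SolverError):
        simulate(bad)


def test_active_force_decreases_with_coupling():
    """Developed (active) force falls as fibroblasts and junctional
    conductance are added, and the fully electromechanical coupling costs
    more force than the purely electrotonic one."""
    def active(mode, n, g):
        cfg = EnsembleConfig(mode=mode, n=n, g_gap=g, duration=15000.0)
        tr = simulate(cfg)
        m = tr.time >= 14000.0
        f = tr["F_myo"][m]
        return f.max() - f.min()

    single = active("single", 0, 0.0)
    mild = active("model2", 2, 0.5)
    strong = active("model2", 4, 3.0)
    electrotonic = active("model1", 4, 3.0)
    assert single > mild > strong
    assert strong < electrotonic
    assert single - mild < 0.05 * single   # 0.5 nS is nearly free
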