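"""Myocyte electrophysiology: currents, gating, RyR ring, SR fluxes, pacing."""

import math

import numpy as np
import pytest

from myofib import EnsembleConfig, initial_state
from myofib.myocyte_ep import (MyocyteElectricalState, ep_currents,
                               gating_derivatives, ryr_release,
                               sr_cytosol_fluxes, apply_stimulus, GATE_NAMES)
from myofib.params import MyocyteEPParams, PacingProtocol
from myofib import _core as core

RTONF = 8314.472 * 310.0 / 96485.3415


def test_ik1_vanishes_at_potassium_reversal(rest_state):
    """Zero driving force: at V = E_K both K1 and the other pure-K+
    currents with (V - E_K) driving vanish."""
    y = rest_state.copy()
    ek = RTONF * math.log(5.4 / y[core.IKI])
    y[core.IV] = ek
    cs = ep_currents(y)
    assert cs.i_K1 == pytest.approx(0.0, abs=1e-12)
    assert cs.i_to == pytest.approx(0.0, abs=1e-12)


def test_ical_multiplier_scales_linearly(rest_state):
    base = ep_currents(rest_state, MyocyteEPParams())
    doubled = ep_currents(rest_state, MyocyteEPParams(ical_mult=2.0))
    assert doubled.i_CaL == pytest.approx(2.0 * base.i_CaL, rel=1e-12)
    for name in ("i_K1", "i_Na", "i_NaCa", "i_NaK", "i_Kr", "i_Ks"):
        assert getattr(doubled, name) == getattr(base, name)


def test_current_sum_matches_components(rest_state):
    cs = ep_currents(rest_state)
    total = sum(getattr(cs, n) for n in
                ("i_CaL", "i_bCa", "i_K1", "i_to", "i_Kr", "i_Ks", "i_pK",
                 "i_Na", "i_bNa", "i_pCa", "i_NaK", "i_NaCa"))
    assert cs.i_myo_total == pytest.approx(total, rel=1e-12)


def test_resting_state_zero_total_current_vs_bisection_oracle(rest_state):
    """The model's quiescent membrane potential agrees with an independent
    bisection root of the total-current curve (gates at steady state)."""
    y = rest_state.copy()

    def total(v):
        yy = y.copy()
        yy[core.IV] = v
        inf = np.empty(12)
        tau = np.empty(12)
        core.tp06_gate_inf_tau(v, yy[core.ICASS], inf, tau)
        yy[1:13] = inf
        return ep_currents(yy).i_myo_total

    lo, hi = -95.0, -60.0
    assert total(lo) < 0 < total(hi)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if total(mid) < 0:
            lo = mid
        else:
            hi = mid
    v_root = 0.5 * (lo + hi)
    assert abs(v_root - y[core.IV]) < 1.5   # mV
    assert abs(ep_currents(y).i_myo_total) < 0.05  # pA/pF at the paced RP


def test_non_finite_state_rejected_with_name(rest_state):
    st = MyocyteElectricalState.from_vector(rest_state)
    st.Ca_i = float("nan")
    with pytest.raises(ValueError, match="Ca_i"):
        st.validate()


@pytest.mark.parametrize("gate", [0, 3, 9])
def test_gate_fixed_point_and_sign(rest_state, gate):
    """A gate at its steady state has zero rate; below it, positive rate."""
    y = rest_state.copy()
    inf = np.empty(12)
    tau = np.empty(12)
    core.tp06_gate_inf_tau(y[core.IV], y[core.ICASS], inf, tau)
    y[1 + gate] = inf[gate]
    assert gating_derivatives(y)[gate] == pytest.approx(0.0, abs=1e-14)
    y[1 + gate] = max(inf[gate] - 0.1, 0.0)
    assert gating_derivatives(y)[gate] > 0


def test_gate_relaxation_matches_closed_form(rest_state):
    """Under voltage clamp each gate follows the scalar exponential
    g(t) = g_inf + (g0 - g_inf) exp(-t/tau) — checked by explicitly
    integrating the reported derivative."""
    y = rest_state.copy()
    y[core.IV] = -20.0  # clamp far from rest
    inf = np.empty(12)
    tau = np.empty(12)
    core.tp06_gate_inf_tau(y[core.IV], y[core.ICASS], inf, tau)
    g0 = y[1:13].copy()
    t_end = 5.0
    dt = 1e-3
    g = g0.copy()
    for _ in range(int(t_end / dt)):
        yy = y.copy()
        yy[1:13] = g
        g = g + dt * gating_derivatives(yy)
    expected = inf + (g0 - inf) * np.exp(-t_end / tau)
    np.testing.assert_allclose(g, expected, atol=5e-4)


def test_ryr_closed_means_no_release(rest_state):
    y = rest_state.copy()
    y[13:17] = [1.0, 0.0, 0.0, 0.0]
    i_rel, _ = ryr_release(y)
    assert i_rel == 0.0


def test_ryr_occupancy_derivatives_conserve(rest_state):
    y = rest_state.copy()
    y[core.ICASS] = 0.01
    _, d4 = ryr_release(y)
    assert abs(d4.sum()) < 1e-12


def test_ryr_occupancy_sum_violation_rejected(rest_state):
    y = rest_state.copy()
    y[13:17] = [0.5, 0.0, 0.0, 0.0]
    with pytest.raises(ValueError, match="occupancy sum"):
        ryr_release(y)


def test_ryr_refractoriness_second_pulse_smaller(rest_state):
    """Two identical subspace-Ca pulses 300 ms apart under clamped SR load:
    the second opens fewer channels (post-release refractoriness),
    by direct integration of the gating scheme."""
    y = rest_state.copy()
    y[core.ICASR] = 3.5

    def run_pulse_train(gaps):
        y[13:17] = [1.0, 0.0, 0.0, 0.0]
        peaks = []
        t = 0.0
        dt = 0.05
        for gap in gaps:
            # diastolic interval
            y[core.ICASS] = 2.5e-4
            for _ in range(int(gap / dt)):
                core.ryr_implicit_step(y, _pack_default(), dt)
            # 10-ms Ca_ss pulse
            y[core.ICASS] = 0.5
            peak = 0.0
            for _ in range(int(10.0 / dt)):
                core.ryr_implicit_step(y, _pack_default(), dt)
                peak = max(peak, y[core.IRYR_O])
            peaks.append(peak)
        return peaks

    p1, p2 = run_pulse_train([5.0, 300.0])
    assert p2 < p1


def _pack_default():
    from myofib.params import pack_params
    return pack_params(EnsembleConfig(mode="single"))


def test_sr_fluxes_trivial_zeros_and_serca_scaling(rest_state):
    y = rest_state.copy()
    y[core.ICAI] = 0.0
    i_up, _, _ = sr_cytosol_fluxes(y)
    assert i_up == 0.0
    y = rest_state.copy()
    y[core.ICASR] = y[core.ICAI]
    _, i_leak, _ = sr_cytosol_fluxes(y)
    assert i_leak == 0.0
    y = rest_state.copy()
    full = sr_cytosol_fluxes(y, MyocyteEPParams())[0]
    half = sr_cytosol_fluxes(y, MyocyteEPParams(serca_mult=0.5))[0]
    assert half == pytest.approx(0.5 * full, rel=1e-12)


def test_stimulus_pulse_train():
    proto = PacingProtocol(frequency_hz=1.0, amplitude=52.0, duration=1.0)
    for onset in (0.0, 1000.0, 2000.0):
        assert apply_stimulus(onset + 0.5, proto) == -52.0
    assert apply_stimulus(500.0, proto) == 0.0
    # pulse integral is amplitude * duration regardless of the period
    for period_hz in (1.0, 2.0):
        p = PacingProtocol(frequency_hz=period_hz)
        ts = np.arange(0.0, 1000.0 / period_hz, 0.01)
        integral = -sum(apply_stimulus(t, p) for t in ts) * 0.01
        assert integral == pytest.approx(p.amplitude * p.duration, rel=1e-2)


def test_stimulus_invalid_period_rejected():
    with pytest.raises(ValueError):
        PacingProtocol(frequency_hz=0.0).validate()
    with pytest.raises(ValueError):
        apply_stimulus(-1.0)


def test_ryr_conservation_along_trajectory(steady_single_trace):
    """Occupancies stay non-negative; the recorded open fraction is sane."""
    o = steady_single_trace["ryr_open"]
    assert np.all(o >= 0) and o.max() < 1.0


def test_paced_steady_state_is_period_one(steady_single_trace):
    """At 1 Hz, default parameters, consecutive beats are indistinguishable
    (no alternans at norm)."""
    tr = steady_single_trace
    b0 = (tr.time >= 1000) & (tr.time < 2000)
    b1 = (tr.time >= 2000) & (tr.time < 3000)
    for ch in ("Ca_i", "F_myo", "Ca_SR"):
        a, b = tr[ch][b0], tr[ch][b1]
        assert abs(a.max() - b.max()) / max(abs(a.max()), 1e-12) < 1e-3
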