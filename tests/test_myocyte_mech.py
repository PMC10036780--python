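"""Mechanics: cooperative CaTnC kinetics, cross-bridges, rheology, balance."""

import numpy as np
import pytest

from myofib import EnsembleConfig, simulate
from myofib.myocyte_mech import (MechanicalState, balance_residual,
                                 catnc_off_rate, catnc_rate, element_forces,
                                 sarcomere_fraction, solve_isometric_balance,
                                 xb_kinetics)
from myofib.params import MechParams


def test_catnc_rate_zero_at_origin():
    assert catnc_rate(0.0, 0.0, 0.0) == 0.0


def test_catnc_above_capacity_rejected():
    with pytest.raises(ValueError, match="A_tot"):
        catnc_rate(100.0, 1e-3, 0.2)


def test_off_rate_decreases_with_attached_crossbridges():
    """Cooperativity: more force-generating cross-bridges slow CaTnC decay."""
    k_lo = catnc_off_rate(30.0, 0.1)
    k_hi = catnc_off_rate(30.0, 0.5)
    assert k_hi < k_lo
    # strictly decreasing along a fine grid
    ks = [catnc_off_rate(30.0, n) for n in np.linspace(0, 1, 21)]
    assert all(b < a for a, b in zip(ks, ks[1:]))


def test_clamped_off_rate_is_frozen():
    frozen = catnc_off_rate(30.0, 0.5)
    # after cross-bridges detach, the unclamped rate rises but the clamped
    # flux keeps the frozen (smaller) rate
    unclamped = catnc_rate(30.0, 0.0, 0.05)
    clamped = catnc_rate(30.0, 0.0, 0.05, clamp=frozen)
    assert clamped > unclamped  # less negative: slower dissociation


def test_xb_relaxes_to_zero_without_catnc():
    st = MechanicalState(l1=0.13, l2=0.13, N_xb=0.3)
    assert xb_kinetics(st, 0.0) < 0
    st.N_xb = 0.0
    assert xb_kinetics(st, 0.0) == 0.0


def test_xb_rate_bounded():
    st = MechanicalState(l1=0.13, l2=0.13, N_xb=1.0)
    assert xb_kinetics(st, 70.0) <= 0
    st.N_xb = 0.0
    assert xb_kinetics(st, 50.0) >= 0


def test_length_dependent_activation_fixed_point():
    """Steady-state N_xb (root of the attachment/detachment balance) is
    larger at 90 % than at 80 % L_max for equal CaTnC."""
    me = MechParams()

    def n_ss(l1):
        st = MechanicalState(l1=l1, l2=l1, N_xb=0.0, v1=0.0)
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            st.N_xb = mid
            if xb_kinetics(st, 40.0, me) > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    l1_90 = 0.90 - me.block_slack
    l1_80 = 0.80 - me.block_slack
    assert n_ss(l1_90) > n_ss(l1_80)


def test_fibroblast_elastic_force_properties():
    me = MechParams()
    st0 = MechanicalState(l1=0.0, l2=0.0)
    assert element_forces(st0, me, n=1).F_PEfb == 0.0   # slack length
    l2s = np.linspace(0.0, 0.2, 30)
    f = [element_forces(MechanicalState(l1=l, l2=l), me, n=1).F_PEfb
         for l in l2s]
    d = np.diff(f)
    assert np.all(d > 0)            # strictly increasing
    assert np.all(np.diff(d) > 0)   # convex


def test_pe_and_fibroblast_share_coefficients():
    """With default coefficients the PE and PEfb curves coincide."""
    me = MechParams()
    for l2 in (0.02, 0.1, 0.18):
        fs = element_forces(MechanicalState(l1=l2, l2=l2), me, n=1)
        assert fs.F_PE == pytest.approx(fs.F_PEfb, rel=1e-12)


def test_balance_residual_below_tolerance():
    st = MechanicalState(L_prep=0.90, l1=0.12, l2=0.135, N_xb=0.3)
    res = balance_residual(st, 40.0, n=0)
    assert abs(res) < 1e-8
    res = balance_residual(st, 40.0, n=4)
    assert abs(res) < 1e-8


def test_passive_static_balance():
    """At rest (no cross-bridges) the solved velocities satisfy the passive
    balance F_XSE = F_PE + n F_PEfb and are small."""
    from myofib.ensemble import _passive_l2
    from myofib.params import pack_params
    cfg = EnsembleConfig(mode="single")
    l2 = _passive_l2(pack_params(cfg))
    st = MechanicalState(L_prep=0.90, l1=l2, l2=l2, N_xb=0.0)
    v1, v2, v3 = solve_isometric_balance(st, 0.0, n=0)
    assert abs(v1) < 1e-12 and abs(v2) < 1e-12


def test_n_zero_reduces_to_uncoupled_balance():
    st = MechanicalState(L_prep=0.90, l1=0.12, l2=0.135, N_xb=0.3)
    v_unc = solve_isometric_balance(st, 40.0, n=0)
    me0 = MechParams(beta2fb=0.0)
    v_zero_fb = solve_isometric_balance(st, 40.0, me0, n=5)
    np.testing.assert_allclose(v_unc, v_zero_fb, atol=1e-12)


def test_sarcomere_excursion_stays_above_80_percent(steady_single_trace):
    """Isometric twitches started at 90 % L_max shorten the sarcomeres (the
    preparation has internal compliance) but never below 80 % L_max."""
    s = sarcomere_fraction(0.0) + steady_single_trace["l1"]
    assert s.max() <= 0.90 + 1e-6
    assert s.min() > 0.80
    assert s.max() - s.min() > 0.01   # the sarcomeres really do shorten


def test_force_normalisation_is_unity(steady_single_trace):
    """Peak steady-state isometric force of the uncoupled myocyte at 90 %
    L_max is 1 by construction."""
    assert steady_single_trace["F_myo"].max() == pytest.approx(1.0, abs=0.02)


@pytest.mark.parametrize("pair", [(0.90, 0.85), (0.85, 0.80)])
def test_length_force_ascending_limb(pair):
    """Peak steady isometric force is ordered 90 % > 85 % > 80 % L_max."""
    peaks = []
    for L in pair:
        cfg = EnsembleConfig(mode="single", duration=2000.0, initial_length=L)
        tr = simulate(cfg)
        peaks.append(tr["F_myo"].max())
    assert peaks[0] > peaks[1]
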