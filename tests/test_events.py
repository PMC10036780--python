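"""Event detection, classification, diagrams and the i_MS I-V lines."""

import numpy as np
import pytest

from myofib import EnsembleConfig, simulate
from myofib.events import (EventConfig, detect_action_potentials,
                           detect_triggered_activity,
                           measure_resting_potentials, msc_iv_curves,
                           threshold_scan, vulnerability_sweep,
                           OUTCOME_EAD, OUTCOME_EXTRA, OUTCOME_NONE)
from myofib.io import make_fixtures
from myofib.params import FibroblastParams


# --- classifier sanity on constructed templates -----------------------------

def test_flat_trace_has_zero_events():
    rep = detect_triggered_activity(make_fixtures("flat"))
    assert rep.eads == [] and rep.extrasystoles == []
    on, _, _ = detect_action_potentials(make_fixtures("flat"))
    assert len(on) == 0


@pytest.mark.parametrize("kind,outcome", [
    ("plain-AP", OUTCOME_NONE),
    ("EAD-template", OUTCOME_EAD),
    ("extrasystole-template", OUTCOME_EXTRA),
])
def test_template_outcomes(kind, outcome):
    rep = detect_triggered_activity(make_fixtures(kind))
    assert rep.outcome == outcome


def test_ead_template_has_exactly_one_ead():
    rep = detect_triggered_activity(make_fixtures("EAD-template"))
    assert len(rep.eads) == 1
    t, take_off, amp = rep.eads[0]
    assert amp >= 5.0


def test_extrasystole_has_force_peak_and_avoids_stimulus():
    rep = detect_triggered_activity(make_fixtures("extrasystole-template"))
    assert len(rep.extrasystoles) == 1
    te = rep.extrasystoles[0]
    period = 1000.0
    assert (te % period) > 10.0          # never stimulus-attributed
    assert rep.first_extrasystole_time == te


def test_pulse_train_counts_aps():
    tr = make_fixtures("plain-AP", beats=5)
    on, peaks, apd = detect_action_potentials(tr)
    assert len(on) == 5
    assert np.all(peaks > 0)
    assert np.all((apd > 200) & (apd < 400))


def test_constant_trace_rp():
    tr = make_fixtures("flat")
    rp, rp_fb = measure_resting_potentials(tr)
    assert np.allclose(rp, -86.0)
    assert rp_fb is None


# --- simulated behaviour -----------------------------------------------------

def test_one_ap_per_stimulus_at_default_pacing(steady_single_trace):
    on, _, _ = detect_action_potentials(steady_single_trace)
    assert len(on) == 4


def test_resting_potential_ordering_model2_vs_uncoupled():
    """Electromechanical coupling with fibroblasts depolarises the myocyte
    resting potential (n = 4, g_gap = 3 nS vs uncoupled)."""
    rp = {}
    for mode, n, g in (("single", 0, 0.0), ("model2", 4, 3.0)):
        cfg = EnsembleConfig(mode=mode, n=n, g_gap=g, duration=8000.0)
        rp[mode], _ = measure_resting_potentials(simulate(cfg))
    assert rp["model2"][-1] > rp["single"][-1] + 2.0


def test_sweep_grid_and_reproducibility():
    cfg = EnsembleConfig(mode="model2", duration=1.0)
    kw = dict(n_values=[0, 2], g_gap_values=[0.5], ical_mult=1.0,
              duration=4000.0)
    d1 = vulnerability_sweep(cfg, **kw)
    d2 = vulnerability_sweep(cfg, **kw)
    assert d1.outcomes == d2.outcomes
    assert set(d1.outcomes) == {(0, 0.5), (2, 0.5)}
    assert d1.as_matrix().shape == (2, 1)


def test_sweep_rejects_empty_grid():
    cfg = EnsembleConfig(mode="model2", duration=1.0)
    with pytest.raises(ValueError):
        vulnerability_sweep(cfg, [], [0.5], 2.0)


def test_threshold_scan_validates_inputs():
    cfg = EnsembleConfig(mode="model2", n=2, g_gap=3.0, duration=1.0)
    with pytest.raises(ValueError, match="ascending"):
        threshold_scan(cfg, [1.0, 0.9])
    with pytest.raises(ValueError, match="modifier"):
        threshold_scan(cfg, [1.0, 1.1], modifier={"nope": 0.5})


# --- mechanosensitive I-V diagrams -------------------------------------------

def test_iv_lines_cross_zero_at_reversal():
    for c in msc_iv_curves([0.80, 0.85, 0.90]):
        i_at_vrev = c["slope_nS"] * (c["V_rev"] - c["V_rev"])
        assert i_at_vrev == 0.0
        k = np.argmin(np.abs(c["V"] - c["V_rev"]))
        assert abs(c["i_MS"][k]) <= c["slope_nS"] * 1.0 + 1e-9


def test_iv_band_confined_to_minus38_minus30():
    curves = msc_iv_curves(list(np.linspace(0.80, 0.90, 6)))
    lo, hi = curves[0]["band"]
    assert lo == pytest.approx(-38.0)
    assert hi == pytest.approx(-30.0)
    for c in curves:
        assert -38.0 - 1e-9 <= c["V_rev"] <= -30.0 + 1e-9


def test_iv_endpoints_reproduce_calibration():
    from myofib.fibroblast import msc_calibration
    fb = FibroblastParams()
    a, v_rev = msc_calibration(fb)
    for c in msc_iv_curves([0.80, 0.90], params=fb):
        assert c["V_rev"] == pytest.approx(v_rev(c["length"]))
        assert c["slope_nS"] == pytest.approx(fb.g_max * a(c["length"] - 0.90))


def test_iv_rejects_out_of_range_length():
    with pytest.raises(ValueError):
        msc_iv_curves([0.70])
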