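"""Measurement and in-silico experiment layer.

Resting potentials, action-potential detection, classification of
calcium-overload triggered activity (early afterdepolarisations and
extrasystoles), (n, g_gap) vulnerability diagrams, i_CaL threshold scans,
mechanosensitive I-V diagrams, and the cross-bridge/Ca-TnC
cooperativity-clamp experiment.

Detection thresholds (deflection size, AP onset criteria, the stimulus
attribution window) are not physiological constants; they live in
:class:`EventConfig` and default to values robust on the synthetic
fixtures in :mod:`myofib.io`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .ensemble import SimulationTrace, simulate, initial_state, beat_metrics
from .fibroblast import msc_calibration
from .params import EnsembleConfig, FibroblastParams, PacingProtocol

__all__ = [
    "EventConfig",
    "EventReport",
    "VulnerabilityDiagram",
    "measure_resting_potentials",
    "detect_action_potentials",
    "detect_triggered_activity",
    "vulnerability_sweep",
    "threshold_scan",
    "msc_iv_curves",
    "cooperativity_clamp_experiment",
    "OUTCOME_NONE", "OUTCOME_EAD", "OUTCOME_EXTRA", "OUTCOME_FAILURE",
]

OUTCOME_NONE = "none"
OUTCOME_EAD = "EAD"            # "0" cells of the vulnerability diagram
OUTCOME_EXTRA = "extrasystole" # "1" cells
OUTCOME_FAILURE = "failure"

_SEVERITY = {OUTCOME_NONE: 0, OUTCOME_EAD: 1, OUTCOME_EXTRA: 2,
             OUTCOME_FAILURE: 3}


@dataclass
class EventConfig:
    """Tunable thresholds of the event classifiers."""

    ap_threshold: float = -40.0     # mV, AP onset crossing
    # Minimal upstroke slope at the onset crossing.  Extra APs launched from
    # a depolarised resting potential are L-type-driven (the fast Na+
    # current is largely inactivated) and rise at only a few mV/ms, so the
    # default admits slow upstrokes; EAD humps never reach the crossing.
    ap_dvdt: float = 1.0            # mV/ms at the onset crossing
    ead_min_amp: float = 5.0        # mV, minimal upward deflection
    stim_window: float = 10.0       # ms, stimulus attribution half-window
    settle_time: float = 2000.0     # ms ignored at the start of a run
    failure_force_frac: float = 0.05  # of the uncoupled normalised peak
    force_peak_min: float = 0.02    # minimal extra force peak (normalised)
    # optional phase cut: only deflections before V first falls below this
    # potential count as EADs (None = classify deflections up to the next
    # stimulus; with strongly depolarised diastolic potentials the
    # plateau/diastole boundary is not sharp)
    v_phase_floor: Optional[float] = None


@dataclass
class EventReport:
    """Per-run summary of pacing behaviour and triggered activity."""

    rp_myo: np.ndarray              # per-beat resting potential (mV)
    rp_fb: Optional[np.ndarray]     # per-beat fibroblast RP (mean over cells)
    apd90: np.ndarray               # per detected stimulus-attributed AP (ms)
    eads: list                      # (time ms, take-off mV, amplitude mV)
    extrasystoles: list             # times (ms)
    outcome: str
    first_extrasystole_time: Optional[float]
    n_aps: int
    config_note: str = ""

    def as_dict(self) -> dict:
        return {
            "rp_myo": [float(v) for v in self.rp_myo],
            "rp_fb": None if self.rp_fb is None else [float(v) for v in self.rp_fb],
            "apd90": [float(v) for v in self.apd90],
            "eads": [[float(a) for a in e] for e in self.eads],
            "extrasystoles": [float(t) for t in self.extrasystoles],
            "outcome": self.outcome,
            "first_extrasystole_time": self.first_extrasystole_time,
            "n_aps": self.n_aps,
            "config_note": self.config_note,
        }


@dataclass
class VulnerabilityDiagram:
    """(n, g_gap) grid of outcome codes at a fixed i_CaL multiplier."""

    n_values: list
    g_gap_values: list
    outcomes: dict                  # (n, g_gap) -> outcome code
    ical_mult: float = 1.0
    initial_length: float = 0.90

    def cell(self, n: int, g_gap: float) -> str:
        return self.outcomes[(n, g_gap)]

    def as_matrix(self) -> np.ndarray:
        return np.array([[self.outcomes[(n, g)] for g in self.g_gap_values]
                         for n in self.n_values], dtype=object)

    def as_dict(self) -> dict:
        return {
            "n_values": list(self.n_values),
            "g_gap_values": [float(g) for g in self.g_gap_values],
            "ical_mult": self.ical_mult,
            "initial_length": self.initial_length,
            "cells": [{"n": n, "g_gap": float(g), "outcome": self.outcomes[(n, g)]}
                      for n in self.n_values for g in self.g_gap_values],
        }


# ---------------------------------------------------------------------------
# basic measurements
# ---------------------------------------------------------------------------

def measure_resting_potentials(trace: SimulationTrace,
                               pacing: Optional[PacingProtocol] = None):
    """Per-beat resting potentials: V averaged over the 10 ms window ending
    5 ms before each stimulus onset.  Returns ``(rp_myo, rp_fb)`` where
    ``rp_fb`` is the mean over fibroblasts (None when there are none)."""
    pacing = pacing or trace.config.pacing
    period = pacing.period
    t = trace.time
    v = trace["V_myo"]
    n_fb = trace.n_fb
    fb = [trace[f"V_cf_{i + 1}"] for i in range(n_fb)]
    rps, rps_fb = [], []
    onset = period  # first measurable window precedes the second stimulus
    while onset <= t[-1] + 1e-9:
        m = (t >= onset - 15.0) & (t <= onset - 5.0)
        if not m.any():
            warnings.warn(f"RP window before t = {onset:.0f} ms outside trace; "
                          "beat skipped")
        else:
            rps.append(float(np.mean(v[m])))
            if n_fb:
                rps_fb.append(float(np.mean([np.mean(f[m]) for f in fb])))
        onset += period
    return np.array(rps), (np.array(rps_fb) if n_fb else None)


def detect_action_potentials(trace: SimulationTrace,
                             events: Optional[EventConfig] = None):
    """AP onsets, peaks and APD90 from the myocyte voltage channel.

    Onset = upward crossing of the threshold with dV/dt above the slope
    criterion; APD90 runs from onset to 90 % repolarisation towards the
    pre-onset baseline.  Returns ``(onsets, peaks, apd90)`` arrays.
    """
    ec = events or EventConfig()
    t = trace.time
    v = trace["V_myo"]
    dt = trace.output_dt or 1.0
    dv = np.diff(v) / dt
    crossing = (v[:-1] <= ec.ap_threshold) & (v[1:] > ec.ap_threshold) \
        & (dv > ec.ap_dvdt)
    onset_idx = np.flatnonzero(crossing) + 1
    onsets, peaks, apd90 = [], [], []
    for k, i0 in enumerate(onset_idx):
        i1 = onset_idx[k + 1] if k + 1 < len(onset_idx) else len(v)
        seg = v[i0:i1]
        ipk = i0 + int(np.argmax(seg))
        peak = v[ipk]
        base = float(np.min(v[max(0, i0 - 50):i0 + 1]))
        v90 = peak - 0.9 * (peak - base)
        below = np.flatnonzero(v[ipk:i1] <= v90)
        end = t[ipk + below[0]] if below.size else t[min(i1, len(v) - 1) - 1]
        onsets.append(t[i0])
        peaks.append(float(peak))
        apd90.append(float(end - t[i0]))
    return np.array(onsets), np.array(peaks), np.array(apd90)


def _upward_deflections(t, v, min_amp):
    """(time, take-off V, amplitude) of upward deflections measured from the
    running minimum of the segment."""
    out = []
    if len(v) < 3:
        return out
    run_min = np.minimum.accumulate(v)
    excess = v - run_min
    i = 0
    while i < len(v):
        if excess[i] >= min_amp:
            j = i
            while j + 1 < len(v) and v[j + 1] >= v[j]:
                j += 1
            take_off_idx = int(np.argmin(v[:i + 1][::-1])) # nearest min
            take_off = float(run_min[i])
            out.append((float(t[np.argmax(v[: j + 1] == v[j])]), take_off,
                        float(v[j] - take_off)))
            # skip to after this hump returns near its take-off
            k = j
            while k + 1 < len(v) and v[k + 1] > take_off + 0.5 * min_amp:
                k += 1
            i = k + 1
        else:
            i += 1
    return out


def detect_triggered_activity(trace: SimulationTrace,
                              pacing: Optional[PacingProtocol] = None,
                              events: Optional[EventConfig] = None
                              ) -> EventReport:
    """Classify EADs and extrasystoles in a paced run.

    An EAD is an upward membrane deflection of at least ``ead_min_amp``
    after an AP peak that does not itself meet the AP-onset criteria; an
    extrasystole is an AP onset outside the stimulus attribution window
    that is accompanied by an extra force peak.  The outcome code is the
    worst event observed; a preparation whose steady peak force falls below
    ``failure_force_frac`` of the uncoupled norm is classified as failure.
    """
    ec = events or EventConfig()
    pacing = pacing or trace.config.pacing
    period = pacing.period
    t = trace.time
    v = trace["V_myo"]
    have_force = "F_myo" in trace.channels
    if not have_force:
        warnings.warn("force channel missing: extrasystole confirmation "
                      "downgraded to voltage-only")
    force = trace["F_myo"] if have_force else None

    onsets, peaks_v, apd90 = detect_action_potentials(trace, ec)
    stim_onsets = np.arange(0.0, t[-1] + 1e-9, period)

    def is_stim_attributed(time):
        return np.any(np.abs(stim_onsets - time) <= ec.stim_window) or \
            np.any((time - stim_onsets > 0) & (time - stim_onsets <= ec.stim_window))

    extras = []
    stim_aps = []
    for k, on in enumerate(onsets):
        if on <= ec.settle_time:
            stim_aps.append(k)
            continue
        if is_stim_attributed(on):
            stim_aps.append(k)
            continue
        confirmed = True
        if have_force:
            m = (t >= on) & (t <= on + 400.0)
            if m.any():
                fseg = force[m]
                base = float(fseg[0])
                confirmed = (np.max(fseg) - base) >= ec.force_peak_min
        if confirmed:
            extras.append(float(on))
        else:
            stim_aps.append(k)

    # EADs: deflections between an AP peak and the next stimulus onset
    eads = []
    for k, on in enumerate(onsets):
        if on <= ec.settle_time or k not in stim_aps:
            continue
        nxt = stim_onsets[np.searchsorted(stim_onsets, on + 1.0)] \
            if np.searchsorted(stim_onsets, on + 1.0) < len(stim_onsets) else t[-1]
        i_pk = np.searchsorted(t, on) + int(np.argmax(
            v[np.searchsorted(t, on):np.searchsorted(t, min(nxt, t[-1]))]))
        m = (t > t[i_pk] + 20.0) & (t < nxt - 2.0)
        if ec.v_phase_floor is not None:
            below = np.flatnonzero((t > t[i_pk]) & (v < ec.v_phase_floor))
            if below.size:
                m &= t < t[below[0]]
        if not m.any():
            continue
        for (te, take_off, amp) in _upward_deflections(t[m], v[m], ec.ead_min_amp):
            if any(x - 10.0 <= te <= x + 400.0 for x in extras) \
                    or take_off + amp > ec.ap_threshold:
                continue  # that deflection is (part of) a full extra AP
            eads.append((te, take_off, amp))

    rp_myo, rp_fb = measure_resting_potentials(trace, pacing)

    outcome = OUTCOME_NONE
    if eads:
        outcome = OUTCOME_EAD
    if extras:
        outcome = OUTCOME_EXTRA
    if have_force and t[-1] > ec.settle_time + 2 * period:
        tail = t >= t[-1] - 5 * period
        if np.max(force[tail]) < ec.failure_force_frac:
            outcome = OUTCOME_FAILURE

    stim_apd = apd90[[k for k in stim_aps if k < len(apd90)]] \
        if len(apd90) else np.array([])
    return EventReport(
        rp_myo=rp_myo, rp_fb=rp_fb, apd90=stim_apd,
        eads=eads, extrasystoles=extras, outcome=outcome,
        first_extrasystole_time=extras[0] if extras else None,
        n_aps=len(onsets))


# ---------------------------------------------------------------------------
# experiments
# ---------------------------------------------------------------------------

def _overload_config(base: EnsembleConfig, n: int, g_gap: float,
                     ical_mult: float, duration: float) -> EnsembleConfig:
    mode = "single" if n == 0 else base.mode
    if mode == "single":
        g_gap = 0.0
    cfg = replace(base, mode=mode, n=n, g_gap=g_gap, duration=duration,
                  ep=replace(base.ep, ical_mult=ical_mult))
    return cfg


def run_outcome(cfg: EnsembleConfig,
                events: Optional[EventConfig] = None) -> EventReport:
    """Simulate one configuration and classify its triggered activity."""
    trace = simulate(cfg)
    return detect_triggered_activity(trace, cfg.pacing, events)


def vulnerability_sweep(base: EnsembleConfig, n_values: Sequence[int],
                        g_gap_values: Sequence[float], ical_mult: float,
                        duration: float = 200000.0,
                        events: Optional[EventConfig] = None
                        ) -> VulnerabilityDiagram:
    """Outcome code for every (n, g_gap) cell at a fixed i_CaL multiplier.

    One full paced run per cell; a failed integration marks the cell
    ``failure`` and the sweep continues.
    """
    if not len(n_values) or not len(g_gap_values):
        raise ValueError("empty sweep grid")
    outcomes = {}
    for n in n_values:
        for g in g_gap_values:
            cfg = _overload_config(base, n, g, ical_mult, duration)
            try:
                rep = run_outcome(cfg, events)
                outcomes[(n, g)] = rep.outcome
            except Exception:
                outcomes[(n, g)] = OUTCOME_FAILURE
    return VulnerabilityDiagram(list(n_values), list(g_gap_values), outcomes,
                                ical_mult, base.initial_length)


def threshold_scan(base: EnsembleConfig, grid: Sequence[float],
                   duration: float = 200000.0,
                   events: Optional[EventConfig] = None,
                   modifier: Optional[dict] = None) -> dict:
    """Smallest grid multiplier whose run exhibits each outcome class.

    ``grid`` is an ascending i_CaL-multiplier grid (typically step 0.1);
    ``modifier`` optionally rescales other currents first, e.g.
    ``{"serca": 0.5}`` or ``{"ikr": 0.5, "iks": 0.5}``.  Bisection on the
    grid assumes outcome severity is non-decreasing in the multiplier; the
    result is reported on the grid.  Classes that never occur map to None.
    """
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be ascending")
    ep_kw = {}
    if modifier:
        key_map = {"serca": "serca_mult", "ikr": "ikr_mult", "iks": "iks_mult"}
        for k, val in modifier.items():
            if k not in key_map:
                raise ValueError(f"unknown modifier {k!r}; valid: {sorted(key_map)}")
            ep_kw[key_map[k]] = val
    base = replace(base, ep=replace(base.ep, **ep_kw)) if ep_kw else base

    cache: dict = {}

    def severity(mult: float) -> int:
        if mult not in cache:
            cfg = replace(base, duration=duration,
                          ep=replace(base.ep, ical_mult=mult))
            cache[mult] = _SEVERITY[run_outcome(cfg, events).outcome]
        return cache[mult]

    def smallest_with(sev: int):
        lo, hi = 0, len(grid) - 1
        if severity(grid[hi]) < sev:
            return None
        if severity(grid[lo]) >= sev:
            return grid[lo]
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if severity(grid[mid]) >= sev:
                hi = mid
            else:
                lo = mid
        return grid[hi]

    return {
        "triggered": smallest_with(_SEVERITY[OUTCOME_EAD]),
        "EAD": smallest_with(_SEVERITY[OUTCOME_EAD]),
        "extrasystole": smallest_with(_SEVERITY[OUTCOME_EXTRA]),
        "runs": len(cache),
    }


def msc_iv_curves(lengths: Sequence[float],
                  v_grid: Optional[np.ndarray] = None,
                  params: Optional[FibroblastParams] = None,
                  reference_length: float = 0.90) -> list:
    """Instantaneous i_MS current-voltage lines at the given lengths.

    Deformation is taken relative to ``reference_length`` (the standard
    initial length of the runs).  Each entry carries the slope (nS), the
    reversal potential, and the sampled line; the band boundaries (extreme
    reversal potentials over the requested lengths) are attached to the
    first entry for convenience.
    """
    params = params or FibroblastParams()
    a, v_rev = msc_calibration(params)
    if v_grid is None:
        v_grid = np.linspace(-100.0, 20.0, 121)
    out = []
    for ell in lengths:
        if not (params.length_lo - 1e-9 <= ell <= params.length_hi + 1e-9):
            raise ValueError(
                f"length {ell} outside working range "
                f"[{params.length_lo}, {params.length_hi}]")
        dl = ell - reference_length
        slope = params.g_max * params.gmax_mult * a(dl)
        vr = v_rev(ell)
        out.append({
            "length": float(ell),
            "slope_nS": float(slope),
            "V_rev": float(vr),
            "V": np.asarray(v_grid, dtype=float),
            "i_MS": slope * (np.asarray(v_grid, dtype=float) - vr),
        })
    vrevs = [c["V_rev"] for c in out]
    if out:
        out[0]["band"] = (float(min(vrevs)), float(max(vrevs)))
    return out


@dataclass
class ClampExperimentResult:
    """Paired baseline/clamped runs of the cooperativity-clamp experiment."""

    baseline: SimulationTrace
    clamped: SimulationTrace
    clamp_time: float
    window: np.ndarray              # times of the post-clamp window (ms)
    off_flux_baseline: np.ndarray   # CaTnC dissociation flux (uM/ms)
    off_flux_clamped: np.ndarray
    baseline_report: EventReport = None
    clamped_report: EventReport = None


def cooperativity_clamp_experiment(base: EnsembleConfig, clamp_time: float,
                                   window_ms: float = 30.0,
                                   events: Optional[EventConfig] = None
                                   ) -> ClampExperimentResult:
    """Freeze the CaTnC off-rate at ``clamp_time`` and compare with baseline.

    The clamped run is identical to the baseline up to ``clamp_time``;
    thereafter the cooperative dependence of the CaTnC off-rate on the
    attached cross-bridges is eliminated (the rate is held at the value it
    had at the switch).  Returns both traces plus the instantaneous
    dissociation-flux curves ``k_off * [CaTnC]`` over the post-switch
    window.
    """
    base.validate()
    if not (0 <= clamp_time <= base.duration):
        raise ValueError("clamp_time outside the run")
    y0 = initial_state(base)
    baseline = simulate(base, y0=y0)
    clamped_cfg = replace(base, clamp_time=clamp_time)
    clamped = simulate(clamped_cfg, y0=y0)
    m = (baseline.time >= clamp_time) & (baseline.time <= clamp_time + window_ms)
    res = ClampExperimentResult(
        baseline=baseline, clamped=clamped, clamp_time=clamp_time,
        window=baseline.time[m] - clamp_time,
        off_flux_baseline=baseline["catnc_off_flux"][m],
        off_flux_clamped=clamped["catnc_off_flux"][m],
    )
    res.baseline_report = detect_triggered_activity(baseline, base.pacing, events)
    res.clamped_report = detect_triggered_activity(clamped, base.pacing, events)
    return res
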