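"""Configuration files, trace/report serialisation and synthetic fixtures.

Run configurations are JSON documents with a flat, fully-validated schema;
traces are CSV with a units row; reports and manifests are JSON.  The
synthetic fixtures exercise the event classifiers without integrating the
ODE system.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, replace, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .ensemble import SimulationTrace, channel_units, TRACE_SCHEMA_VERSION
from .events import EventReport
from .params import (EnsembleConfig, PacingProtocol, SolverOptions,
                     PARAM_FILE_VERSION)

__all__ = [
    "RunManifest", "load_config", "dump_config", "config_hash",
    "write_outputs", "read_trace_csv", "read_report", "make_fixtures",
]

_TOP_KEYS = {"mode", "n", "g_gap", "initial_length", "duration_ms",
             "pacing", "solver", "multipliers", "clamp_time_ms"}
_PACING_KEYS = {"frequency_hz", "amplitude", "duration"}
_SOLVER_KEYS = {"dt", "output_dt", "balance_tol"}
_MULT_KEYS = {"i_CaL", "i_Kr", "i_Ks", "SERCA", "g_max", "V_rev"}


def load_config(source) -> EnsembleConfig:
    """Build a fully-resolved :class:`EnsembleConfig` from a JSON document.

    ``source`` may be a path, a JSON string or a dict.  Unknown keys are
    rejected by name; out-of-range values raise with the valid range.
    Defaults: 1 Hz pacing, 90 % L_max, 200 s, packaged parameter values.
    """
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if Path(str(source)).exists() \
            else str(source)
        doc = json.loads(text)
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    for sub, valid in (("pacing", _PACING_KEYS), ("solver", _SOLVER_KEYS),
                       ("multipliers", _MULT_KEYS)):
        bad = set(doc.get(sub, {})) - valid
        if bad:
            raise ValueError(f"unknown {sub} key(s): {sorted(bad)}")

    cfg = EnsembleConfig(
        mode=doc.get("mode", "model2"),
        n=int(doc.get("n", 0)),
        g_gap=float(doc.get("g_gap", 0.0)),
        initial_length=float(doc.get("initial_length", 0.90)),
        duration=float(doc.get("duration_ms", 200000.0)),
        pacing=PacingProtocol(**doc.get("pacing", {})),
        solver=SolverOptions(**doc.get("solver", {})),
        clamp_time=doc.get("clamp_time_ms"),
    )
    mult = doc.get("multipliers", {})
    cfg.ep = replace(cfg.ep,
                     ical_mult=float(mult.get("i_CaL", 1.0)),
                     ikr_mult=float(mult.get("i_Kr", 1.0)),
                     iks_mult=float(mult.get("i_Ks", 1.0)),
                     serca_mult=float(mult.get("SERCA", 1.0)))
    cfg.fb = replace(cfg.fb,
                     gmax_mult=float(mult.get("g_max", 1.0)),
                     vrev_mult=float(mult.get("V_rev", 1.0)))
    cfg.validate()
    return cfg


def dump_config(cfg: EnsembleConfig) -> dict:
    """Canonical JSON-compatible form of a run configuration."""
    cfg.validate()
    return {
        "mode": cfg.mode, "n": cfg.n, "g_gap": cfg.g_gap,
        "initial_length": cfg.initial_length, "duration_ms": cfg.duration,
        "pacing": asdict(cfg.pacing), "solver": asdict(cfg.solver),
        "multipliers": {"i_CaL": cfg.ep.ical_mult, "i_Kr": cfg.ep.ikr_mult,
                        "i_Ks": cfg.ep.iks_mult, "SERCA": cfg.ep.serca_mult,
                        "g_max": cfg.fb.gmax_mult, "V_rev": cfg.fb.vrev_mult},
        "clamp_time_ms": cfg.clamp_time,
    }


def config_hash(cfg: EnsembleConfig) -> str:
    text = json.dumps(dump_config(cfg), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record written next to every output file set."""

    config_hash: str
    param_file_version: str
    trace_schema_version: str
    solver: dict
    wall_time_s: float
    outcome_summary: str

    @classmethod
    def for_run(cls, cfg: EnsembleConfig, wall_time_s: float,
                outcome: str = "") -> "RunManifest":
        return cls(config_hash=config_hash(cfg),
                   param_file_version=PARAM_FILE_VERSION,
                   trace_schema_version=TRACE_SCHEMA_VERSION,
                   solver=asdict(cfg.solver),
                   wall_time_s=wall_time_s,
                   outcome_summary=outcome)

    def as_dict(self) -> dict:
        return asdict(self)


def write_outputs(trace: Optional[SimulationTrace],
                  report: Optional[EventReport],
                  manifest: RunManifest, out_dir) -> dict:
    """Write trace.csv (header with units), report.json and manifest.json.

    Returns the mapping of artefact name to path.  Reports round-trip
    bit-exactly through JSON; traces round-trip to full float precision
    (repr-format floats).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    man = manifest.as_dict()
    if trace is not None:
        names = ["time"] + list(trace.channels)
        units = [channel_units(n) for n in names]
        cols = [trace.time] + [trace.channels[n] for n in trace.channels]
        path = out / "trace.csv"
        with open(path, "w") as fh:
            fh.write("# manifest: " + man["config_hash"] + "\n")
            fh.write(",".join(f"{n} [{u}]" for n, u in zip(names, units)) + "\n")
            for row in zip(*cols):
                fh.write(",".join(repr(float(x)) for x in row) + "\n")
        paths["trace"] = path
    if report is not None:
        path = out / "report.json"
        doc = {"manifest": man["config_hash"], **report.as_dict()}
        path.write_text(json.dumps(doc, indent=1))
        paths["report"] = path
    path = out / "manifest.json"
    path.write_text(json.dumps(man, indent=1))
    paths["manifest"] = path
    return paths


def read_trace_csv(path) -> dict:
    """Read a trace.csv back into {channel: array} (units stripped)."""
    with open(path) as fh:
        line = fh.readline()
        if line.startswith("#"):
            line = fh.readline()
        names = [c.split(" [")[0] for c in line.strip().split(",")]
        data = np.loadtxt(fh, delimiter=",")
    if data.ndim == 1:
        data = data[None, :]
    return {n: data[:, i] for i, n in enumerate(names)}


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


# ---------------------------------------------------------------------------
# synthetic fixtures for the event classifiers
# ---------------------------------------------------------------------------

FIXTURE_KINDS = ("flat", "plain-AP", "EAD-template", "extrasystole-template")


def _ap_shape(t_rel, peak=32.0, rp=-86.0, apd=300.0):
    """Piecewise AP: 2-ms upstroke, plateau decay, 40-ms repolarisation."""
    v = np.full_like(t_rel, rp)
    up = (t_rel >= 0) & (t_rel < 2)
    v[up] = rp + (peak - rp) * t_rel[up] / 2.0
    plat = (t_rel >= 2) & (t_rel < apd - 40)
    v[plat] = peak - (peak - (-20.0)) * (t_rel[plat] - 2) / (apd - 42)
    rep = (t_rel >= apd - 40) & (t_rel < apd)
    v[rep] = -20.0 + (rp - (-20.0)) * (t_rel[rep] - (apd - 40)) / 40.0
    return v


def _force_bump(t_rel, peak=0.8, t_peak=160.0, width=90.0):
    return peak * np.exp(-((t_rel - t_peak) / width) ** 2)


def make_fixtures(kind: str, beats: int = 6, period: float = 1000.0
                  ) -> SimulationTrace:
    """Deterministic synthetic traces for the classifiers.

    ``flat`` has no events; ``plain-AP`` one AP per stimulus;
    ``EAD-template`` adds exactly one sub-threshold hump; the extrasystole
    template adds one full off-stimulus AP with an extra force peak.
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; valid: {FIXTURE_KINDS}")
    cfg = EnsembleConfig(mode="single", duration=beats * period,
                         pacing=PacingProtocol(frequency_hz=1000.0 / period))
    t = np.arange(0.0, beats * period + 0.5, 1.0)
    rp = -86.0
    v = np.full_like(t, rp)
    f = np.full_like(t, 0.02)
    if kind != "flat":
        for b in range(beats):
            rel = t - b * period - 2.0
            m = (rel >= 0) & (rel < period - 10)
            v[m] = np.maximum(v[m], _ap_shape(rel[m]))
            f[m] += _force_bump(rel[m])
    # the templated event goes into the fourth beat (well past settling)
    b_ev = min(3, beats - 1)
    if kind == "EAD-template":
        rel = t - b_ev * period - 2.0
        hump = (rel >= 420) & (rel < 520)
        v[hump] += 14.0 * np.exp(-((rel[hump] - 470) / 25.0) ** 2)
    elif kind == "extrasystole-template":
        rel = t - b_ev * period - 520.0
        m = (rel >= 0) & (rel < 420)
        v[m] = np.maximum(v[m], _ap_shape(rel[m], apd=250.0))
        f[m] += _force_bump(rel[m], peak=0.5)
    channels = {"V_myo": v, "Ca_i": np.full_like(t, 1e-4),
                "Ca_SR": np.full_like(t, 3.0), "Ca_ss": np.full_like(t, 2.5e-4),
                "CaTnC": np.full_like(t, 3.0), "N_xb": np.zeros_like(t),
                "F_myo": f, "l1": np.full_like(t, 0.13),
                "l2": np.full_like(t, 0.13), "k_off": np.full_like(t, 0.05),
                "catnc_off_flux": np.full_like(t, 0.15),
                "ryr_open": np.zeros_like(t)}
    return SimulationTrace(t, channels, cfg)
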