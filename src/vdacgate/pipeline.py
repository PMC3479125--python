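"""Validated run configuration and the end-to-end analysis pipeline.

``run_pipeline`` composes the stages in recording order: simulate (or
ingest) -> decimate -> baseline -> segment -> classify -> Ohm fits ->
closed-state mixture decomposition -> dwell/asymmetry statistics ->
comparisons against the native reference values.  Everything is
deterministic given the configuration (all randomness flows from the
single seed), so two runs of the same config produce byte-identical
reports.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .conductance_analysis import (ClosedStateDecomposition, OhmFit,
                                   decompose_closed_states, ohm_fit,
                                   percent_of_open)
from .dwell_time_analysis import (AsymmetryReport, DwellSummary,
                                  detect_asymmetry, dwell_summary)
from .gating_model import (REFERENCE_CONDUCTANCES, CurrentTrace,
                           VoltageProtocol, build_preset, decimate,
                           simulate_trace)
from .idealization import (BASELINE, Idealization, SegmentationParams,
                           estimate_baseline, segment_trace)
from .stats_core import SampleSummary, welch_t
from .trace_io import events_to_dataframe

logger = logging.getLogger("vdacgate")


class IdealizationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window: float = 0.05
    min_duration_s: float = 0.025
    jump_threshold_pa: float | None = None
    edge_exclude_s: float = 0.0


class AnalysisConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bin_width_ns: float = 0.05
    s2_window_ns: tuple[float, float] = (0.80, 2.20)


class RunConfig(BaseModel):
    """Full configuration of a simulate-and-analyze run.

    Unknown keys are rejected so configuration typos fail loudly; the JSON
    schema is available via ``RunConfig.model_json_schema()``.
    """

    model_config = ConfigDict(extra="forbid")
    preset: str
    protocol: list[tuple[float, float]]  # (duration_s, voltage_mV)
    n_traces: int = Field(default=1, ge=1)
    fs_hz: float = 5000.0
    analysis_fs_hz: float = 200.0
    n_channels: int = Field(default=1, ge=1, le=5)
    insertion_s: float = 1.0
    seed: int = 0
    idealization: IdealizationConfig = Field(default_factory=IdealizationConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)


@dataclass
class PipelineResult:
    config: RunConfig
    idealizations: list[Idealization]
    ohm_fits: dict[str, OhmFit]
    decomposition: ClosedStateDecomposition | None
    dwell: DwellSummary | None
    asymmetry: AsymmetryReport | None
    report: dict
    dwell_report: dict


class PipelineError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc
    return wrap


def _round(x, nd=6):
    if x is None:
        return None
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return None
    return round(float(x), nd)


def _summary_dict(s: SampleSummary, unit: str) -> dict:
    return {f"mean_{unit}": _round(s.mean), f"sem_{unit}": _round(s.sem), "n": s.n}


def analyze_traces(traces: list[CurrentTrace], config: RunConfig) -> PipelineResult:
    """Run the analysis stages on already-acquired traces."""
    preset = _stage("preset")(build_preset, config.preset)
    refs = preset.reference_conductances
    params = SegmentationParams(
        jump_threshold_pA=config.idealization.jump_threshold_pa,
        min_duration_s=config.idealization.min_duration_s,
        window=config.idealization.window,
        edge_exclude_s=config.idealization.edge_exclude_s)

    idealizations: list[Idealization] = []
    for tr in traces:
        if tr.fs_Hz > config.analysis_fs_hz:
            tr = _stage("decimate")(decimate, tr, config.analysis_fs_hz)
        base = _stage("baseline")(estimate_baseline, tr)
        ideal = _stage("segment")(segment_trace, tr, params,
                                  base.baseline_pA, refs)
        idealizations.append(ideal)

    events = [s for ideal in idealizations for s in ideal.segments]
    ohm_fits: dict[str, OhmFit] = {}
    for state in preset.labels:
        if any(e.state == state for e in events):
            ohm_fits[state] = _stage("ohm_fit")(ohm_fit, events, state)

    closed = [e for e in events if e.state not in ("S0", BASELINE)]
    decomposition = None
    if len(closed) >= 30:
        decomposition = _stage("decompose")(
            decompose_closed_states, closed,
            config.analysis.s2_window_ns, config.analysis.bin_width_ns)
    else:
        logger.warning("only %d closed events; skipping mixture decomposition",
                       len(closed))

    dwell = None
    try:
        dwell = _stage("dwell")(dwell_summary, idealizations,
                                config.analysis.s2_window_ns)
    except PipelineError as exc:
        logger.warning("%s", exc)

    asymmetry = None
    volts = {np.sign(s.voltage_mV) for i in idealizations for s in i.segments
             if s.voltage_mV != 0}
    if {1.0, -1.0} <= volts:
        asymmetry = _stage("asymmetry")(detect_asymmetry, idealizations)

    report = _build_report(config, idealizations, ohm_fits, decomposition, asymmetry)
    dwell_report = _build_dwell_report(dwell, asymmetry)
    return PipelineResult(config=config, idealizations=idealizations,
                          ohm_fits=ohm_fits, decomposition=decomposition,
                          dwell=dwell, asymmetry=asymmetry,
                          report=report, dwell_report=dwell_report)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None,
                 traces: list[CurrentTrace] | None = None) -> PipelineResult:
    """Simulate (unless ``traces`` are supplied) and analyze end to end."""
    if traces is None:
        preset = _stage("preset")(build_preset, config.preset)
        protocol = VoltageProtocol(tuple(config.protocol))
        seed_rng = np.random.default_rng(config.seed)
        trace_seeds = seed_rng.integers(0, 2**31 - 1, size=config.n_traces)
        traces = [
            _stage("simulate")(simulate_trace, preset, protocol,
                               fs_Hz=config.fs_hz, seed=int(s),
                               n_channels=config.n_channels,
                               insertion_s=config.insertion_s)
            for s in trace_seeds
        ]
    result = analyze_traces(traces, config)
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def _component_dict(c) -> dict:
    return {"mean_nS": _round(c.mean_nS), "sd_nS": _round(c.sd_nS),
            "weight": _round(c.weight)}


def _mixture_dict(m) -> dict:
    return {"components": [_component_dict(c) for c in m.components],
            "r_squared": _round(m.r_squared, 4),
            "bin_width_nS": m.bin_width_nS,
            "fit_range_nS": [_round(m.fit_range_nS[0]), _round(m.fit_range_nS[1])],
            "n": m.n}


def _build_report(config: RunConfig, idealizations, ohm_fits, decomposition,
                  asymmetry) -> dict:
    report: dict = {
        "vdacgate_version": __version__,
        "preset": config.preset,
        "seed": config.seed,
        "n_traces": len(idealizations),
        "baseline_pA": [_round(i.baseline_pA) for i in idealizations],
        "ohm_fits": {
            st: {"conductance_nS": _round(f.conductance_nS),
                 "sem_nS": _round(f.sem_nS), "n": f.n, "fallback": f.fallback,
                 "per_voltage_mean_pA": {str(v): _round(m)
                                         for v, m in sorted(f.per_voltage_mean_pA.items())}}
            for st, f in ohm_fits.items()},
    }
    if "S0" in ohm_fits:
        g0 = ohm_fits["S0"].conductance_nS
        report["percent_of_open"] = {
            st: percent_of_open(f.conductance_nS, g0)
            for st, f in ohm_fits.items() if st != "S0"}
    if decomposition is not None:
        d = decomposition
        report["closed_state_decomposition"] = {
            "sample_mean_nS": _round(d.sample_mean_nS),
            "single_gaussian": _mixture_dict(d.single_gaussian),
            "stage1": _mixture_dict(d.stage1),
            "stage2": None if d.stage2 is None else _mixture_dict(d.stage2),
            "counts": d.counts,
            "s2_window_nS": list(d.s2_window_nS),
        }
    native_refs = REFERENCE_CONDUCTANCES["native"]
    comparisons = {}
    for st, f in ohm_fits.items():
        if st in native_refs and f.n >= 2 and np.isfinite(f.sem_nS) and f.sem_nS > 0:
            ref = SampleSummary(*native_refs[st])
            res = welch_t(SampleSummary(f.conductance_nS, f.sem_nS, f.n), ref)
            comparisons[st] = {"t": _round(res.t_statistic, 3),
                               "df": _round(res.degrees_of_freedom, 1),
                               "p": _round(res.p_value, 4)}
    report["comparisons_vs_native"] = comparisons
    if asymmetry is not None:
        report["asymmetry"] = _asymmetry_dict(asymmetry)
    return report


def _asymmetry_dict(a: AsymmetryReport) -> dict:
    return {"closed_fraction_pos": _round(a.closed_fraction_pos),
            "closed_fraction_neg": _round(a.closed_fraction_neg),
            "asymmetric": a.asymmetric,
            "inferred_orientation": a.inferred_orientation}


def _build_dwell_report(dwell: DwellSummary | None,
                        asymmetry: AsymmetryReport | None) -> dict:
    out: dict = {}
    if dwell is not None:
        out["per_state"] = {st: _summary_dict(s, "s")
                            for st, s in dwell.per_state.items()}
        out["overall"] = _summary_dict(dwell.overall, "s")
        if dwell.s2_union is not None:
            out["s2_union"] = _summary_dict(dwell.s2_union, "s")
    if asymmetry is not None:
        out["asymmetry"] = _asymmetry_dict(asymmetry)
    return out


def _histogram_table(decomposition: ClosedStateDecomposition) -> list[dict]:
    m1, m2 = decomposition.single_gaussian, decomposition.stage1
    bw = m2.bin_width_nS
    lo, hi = m2.fit_range_nS
    edges = lo + bw * np.arange(int(round((hi - lo) / bw)) + 1)
    centers = (edges[:-1] + edges[1:]) / 2

    def fitted(m):
        y = np.zeros_like(centers)
        for c in m.components:
            amp = c.weight * m.n * bw / (c.sd_nS * math.sqrt(2 * math.pi))
            y += amp * np.exp(-0.5 * ((centers - c.mean_nS) / c.sd_nS) ** 2)
        return y

    y1, y2 = fitted(m1), fitted(m2)
    return [{"bin_left": _round(edges[i]), "bin_right": _round(edges[i + 1]),
             "fitted_k1": _round(y1[i], 4), "fitted_k2": _round(y2[i], 4)}
            for i in range(len(centers))]


def write_outputs(result: PipelineResult, out_dir: str | Path) -> None:
    """Write events.csv, report.json, dwell.json, histogram.csv and run.log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events_to_dataframe(result.idealizations).to_csv(out / "events.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "dwell.json", "w") as fh:
        json.dump(result.dwell_report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if result.decomposition is not None:
        import pandas as pd

        closed = [s for i in result.idealizations for s in i.segments
                  if s.state not in ("S0", BASELINE)]
        table = _histogram_table(result.decomposition)
        vals = np.array([s.conductance_nS for s in closed])
        hist_counts = [int(((vals >= row["bin_left"]) & (vals < row["bin_right"])).sum())
                       for row in table]
        for row, c in zip(table, hist_counts):
            row["count"] = c
        pd.DataFrame(table, columns=["bin_left", "bin_right", "count",
                                     "fitted_k1", "fitted_k2"]).to_csv(
            out / "histogram.csv", index=False)
    with open(out / "run.log", "w") as fh:
        fh.write(f"vdacgate {__version__}\n")
        fh.write(f"seed: {result.config.seed}\n")
        fh.write("config:\n")
        fh.write(result.config.model_dump_json(indent=2))
        fh.write("\n")
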