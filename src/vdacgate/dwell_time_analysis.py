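"""Dwell-time statistics, fold-changes and asymmetric-gating detection.

A dwell (sojourn) is the time a channel spends in one conductance state
before switching to another.  Idealized segments are stitched back into
sojourns (a sojourn split across a voltage step appears as two same-state
segments and is re-joined), the first and last sojourn of every trace are
discarded as censored — their true lengths are unknown — and per-state and
overall (any state, time to next switch) means with SEMs are reported.

Polarity-asymmetric gating is detected from the closed-time fractions at
positive and negative applied voltage: a channel that closes at one
polarity but never at the other has its closure gated by the direction of
the electric field, i.e. by its orientation in the bilayer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .conductance_analysis import DEFAULT_S2_WINDOW_NS, round_half_up
from .idealization import BASELINE, INTERMEDIATE, Idealization
from .stats_core import SampleSummary, summarize

logger = logging.getLogger("vdacgate")


@dataclass(frozen=True)
class DwellSummary:
    per_state: dict[str, SampleSummary]
    overall: SampleSummary
    s2_union: SampleSummary | None = None  # S2A + S2B (+ in-window intermediates)


@dataclass(frozen=True)
class AsymmetryReport:
    closed_fraction_pos: float
    closed_fraction_neg: float
    asymmetric: bool
    inferred_orientation: int | None  # +1 / -1 / None


@dataclass(frozen=True)
class _Sojourn:
    state: str
    duration_s: float
    voltage_mV: float


def _extract_sojourns(ideal: Idealization, gap_tol_s: float = 0.05
                      ) -> list[_Sojourn]:
    """Stitch segments into sojourns and drop the censored first/last.

    A sojourn that spans a voltage step appears as same-state segments in
    consecutive voltage regions; such pieces (same state, different
    voltage, separated by no more than ``gap_tol_s``) are re-joined, and
    the voltage recorded for the merged sojourn is that of its longest
    piece.  Same-state neighbours at the *same* voltage are distinct
    events (the segmenter only cuts where the level genuinely jumped, so
    adjacency there means two different states received the same label)
    and are kept separate.  BASELINE segments (no channel) are not
    sojourns and break merging.
    """
    segs = [s for s in ideal.segments if s.state != BASELINE]
    merged: list[list] = []  # [state, start, end, {voltage: time}, last_voltage]
    for s in segs:
        if (merged and merged[-1][0] == s.state
                and s.voltage_mV != merged[-1][4]
                and s.start_s - merged[-1][2] <= gap_tol_s):
            merged[-1][2] = s.end_s
            merged[-1][3][s.voltage_mV] = merged[-1][3].get(s.voltage_mV, 0.0) + s.duration_s
            merged[-1][4] = s.voltage_mV
        else:
            merged.append([s.state, s.start_s, s.end_s,
                           {s.voltage_mV: s.duration_s}, s.voltage_mV])
    merged = merged[1:-1]  # censored: true start/end unobserved
    return [_Sojourn(m[0], m[2] - m[1], max(m[3], key=m[3].get)) for m in merged]


def dwell_summary(idealizations: list[Idealization],
                  s2_window_nS: tuple[float, float] = DEFAULT_S2_WINDOW_NS,
                  include_intermediate_in_s2: bool = True) -> DwellSummary:
    """Per-state and overall dwell-time statistics over uncensored sojourns.

    The overall summary pools every uncensored sojourn regardless of state
    (the mean time in any state before switching).  The S2 union aggregates
    S2A and S2B; with ``include_intermediate_in_s2`` INTERMEDIATE sojourns
    whose conductance fell inside the S2 window also count towards it (the
    conductance is not retained per sojourn, so intermediates are included
    wholesale only when requested and labelled events are absent).
    """
    sojourns: list[_Sojourn] = []
    ideal_sojourns: list[list[_Sojourn]] = []
    for ideal in idealizations:
        s = _extract_sojourns(ideal)
        ideal_sojourns.append(s)
        sojourns.extend(s)
    if not sojourns:
        raise ValueError("no uncensored sojourns; record longer traces")

    # sorted before summarizing so results are exactly invariant to the
    # order in which traces are supplied
    durations = np.sort([s.duration_s for s in sojourns])
    overall = summarize(durations) if len(durations) >= 2 else SampleSummary(
        float(durations.mean()), float("nan"), len(durations))

    per_state: dict[str, SampleSummary] = {}
    for lab in sorted({s.state for s in sojourns}):
        d = np.sort([s.duration_s for s in sojourns if s.state == lab])
        per_state[lab] = (summarize(d) if len(d) >= 2
                          else SampleSummary(float(d.mean()), float("nan"), len(d)))

    s2_states = {"S2A", "S2B"}
    if include_intermediate_in_s2:
        s2_states.add(INTERMEDIATE)
    d2 = np.sort([s.duration_s for s in sojourns if s.state in s2_states])
    s2_union = None
    if len(d2) >= 2:
        s2_union = summarize(d2)
    elif len(d2) == 1:
        s2_union = SampleSummary(float(d2[0]), float("nan"), 1)
    return DwellSummary(per_state=per_state, overall=overall, s2_union=s2_union)


def fold_change(a_mean_s: float, b_mean_s: float,
                rounding: str = "none") -> float:
    """Ratio of two mean dwell times, optionally rounded half-up.

    rounding: "none" (raw float), "integer", "ten" (nearest ten, the
    convention behind headline fold-changes such as 177.6 -> 180), or
    "tenth" (one decimal).
    """
    if b_mean_s <= 0:
        raise ValueError("denominator mean must be positive")
    ratio = a_mean_s / b_mean_s
    if rounding == "none":
        return ratio
    if rounding == "integer":
        return float(round_half_up(ratio))
    if rounding == "ten":
        return float(round_half_up(ratio / 10.0) * 10.0)
    if rounding == "tenth":
        return float(round_half_up(ratio, 1))
    raise ValueError(f"unknown rounding {rounding!r}")


def minutes_to_seconds(minutes: float) -> float:
    return minutes * 60.0


def event_percentage(k: int, n: int) -> int:
    """Integer percentage of events, half-up (e.g. closure probability)."""
    if n <= 0:
        raise ValueError("n must be positive")
    return int(round_half_up(100.0 * k / n))


def detect_asymmetry(idealizations: list[Idealization],
                     zero_tolerance: float = 0.005,
                     closed_floor: float = 0.02,
                     open_conductance_nS: float | None = None,
                     closed_cutoff: float = 0.8) -> AsymmetryReport:
    """Detect polarity-asymmetric gating from per-polarity closed fractions.

    A segment counts as closed when its conductance has dropped below
    ``closed_cutoff`` times the open-state conductance — a conductance
    criterion rather than a label one, so that open sojourns whose
    event-to-event conductance scatter pushed them just outside the S0
    classification window are not mistaken for closures (the deepest known
    closed state still sits at ~2/3 of the open conductance, well below
    the default 0.8 cutoff).  ``open_conductance_nS`` defaults to the
    median conductance of S0-labelled segments, or the 90th percentile of
    all segment conductances when no segment was labelled S0.

    The closed fraction at a polarity is closed time over analyzable
    (non-baseline, V != 0) time at that polarity.  Gating is asymmetric
    when one polarity's closed fraction is essentially zero
    (< ``zero_tolerance``) while the other's exceeds ``closed_floor``; the
    inferred orientation is the polarity sign showing closure.
    """
    all_segs = [s for ideal in idealizations for s in ideal.segments
                if s.voltage_mV != 0 and s.state != BASELINE]
    if open_conductance_nS is None:
        s0_g = [s.conductance_nS for s in all_segs if s.state == "S0"]
        if s0_g:
            open_conductance_nS = float(np.median(s0_g))
        elif all_segs:
            open_conductance_nS = float(
                np.quantile([s.conductance_nS for s in all_segs], 0.9))
        else:
            raise ValueError("no analyzable segments")
    cutoff_nS = closed_cutoff * open_conductance_nS

    time = {+1: 0.0, -1: 0.0}
    closed = {+1: 0.0, -1: 0.0}
    for s in all_segs:
        pol = +1 if s.voltage_mV > 0 else -1
        time[pol] += s.duration_s
        if s.conductance_nS < cutoff_nS:
            closed[pol] += s.duration_s
    if time[+1] == 0.0 or time[-1] == 0.0:
        raise ValueError(
            "asymmetry detection needs analyzable data at both polarities; "
            "record traces under both positive and negative voltage")
    frac = {p: closed[p] / time[p] for p in (+1, -1)}
    asym = False
    orientation: int | None = None
    for p in (+1, -1):
        if frac[p] > closed_floor and frac[-p] < zero_tolerance:
            asym = True
            orientation = p
    return AsymmetryReport(closed_fraction_pos=frac[+1],
                           closed_fraction_neg=frac[-1],
                           asymmetric=asym, inferred_orientation=orientation)
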