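"""Channel-variant presets and synthetic single-channel BLM current traces.

The voltage-dependent anion channel (VDAC) in a planar lipid bilayer sits in
one of a small number of discrete conductance states: an open state S0
(~3.9 nS in 1 M KCl) and low-conductance "closed" states S1, S2A and S2B.
Gating is modelled as a semi-Markov process: the channel sojourns in a state
for an exponentially distributed time with a state-specific mean, then jumps
to a successor drawn from a per-state categorical distribution.  Current is
Ohmic per state, I(t) = g(state) * V(t) + noise, with g in nS and V in mV so
that I is in pA.

Disulfide cross-linking at the pore base (the V3C-K119C variant, oxidized)
produces polarity-asymmetric gating: the channel closes under only one sign
of applied voltage, set by its insertion orientation.  The simulator
reproduces this by suppressing transitions out of S0 — and forcing a return
to S0 — whenever the applied polarity does not match the preset's
orientation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

logger = logging.getLogger("vdacgate")

STATE_LABELS = ("S0", "S1", "S2A", "S2B")

# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GatingState:
    """A discrete conductance state of one channel."""

    label: str
    conductance_nS: float

    def __post_init__(self) -> None:
        if self.conductance_nS <= 0:
            raise ValueError(f"conductance must be positive, got {self.conductance_nS}")
        if self.label not in STATE_LABELS:
            raise ValueError(f"unknown state label {self.label!r}; expected one of {STATE_LABELS}")


@dataclass(frozen=True)
class ChannelPreset:
    """A channel variant's gating model.

    ``transition_weights`` maps each state label to a categorical
    distribution over successor labels; an empty row marks an absorbing
    state (the channel never leaves it once entered).  ``asymmetric``
    presets close under one voltage polarity only: transitions into non-S0
    states are permitted only while ``sign(V) == orientation``, and a
    polarity flip while closed forces an immediate return to S0.

    ``conductance_jitter_sd_nS`` is a per-sojourn Gaussian perturbation of
    the state conductance emulating membrane-to-membrane and insertion-to-
    insertion variability; it is what gives the closed-state amplitude
    histogram its finite component widths (~0.12 nS in 1 M KCl recordings).
    """

    name: str
    states: tuple[GatingState, ...]
    mean_dwell_s: Mapping[str, float]
    transition_weights: Mapping[str, Mapping[str, float]]
    asymmetric: bool = False
    orientation: int = 0
    noise_sd_pA: float = 2.0
    conductance_jitter_sd_nS: float = 0.12

    def __post_init__(self) -> None:
        labels = [s.label for s in self.states]
        if len(set(labels)) != len(labels):
            raise ValueError("state labels must be unique within a preset")
        for lab in labels:
            if self.mean_dwell_s.get(lab, 0.0) <= 0:
                raise ValueError(f"mean_dwell_s must be positive for state {lab}")
            row = self.transition_weights.get(lab, {})
            if lab in row:
                raise ValueError(f"self-transition not allowed (state {lab})")
            for succ in row:
                if succ not in labels:
                    raise ValueError(f"transition {lab}->{succ}: unknown successor")
            total = sum(row.values())
            if row and not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError(f"transition weights from {lab} sum to {total}, expected 1")
        if self.asymmetric and self.orientation not in (+1, -1):
            raise ValueError("asymmetric presets need orientation +1 or -1")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def conductance(self, label: str) -> float:
        for s in self.states:
            if s.label == label:
                return s.conductance_nS
        raise KeyError(f"preset {self.name!r} has no state {label!r}")

    @property
    def reference_conductances(self) -> dict[str, float]:
        """Per-state nominal conductances (nS), e.g. for classification."""
        return {s.label: s.conductance_nS for s in self.states}

    def with_(self, **kwargs) -> "ChannelPreset":
        """Return a copy with some fields replaced (e.g. noise turned off)."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class VoltageProtocol:
    """Ordered voltage steps applied across the bilayer."""

    steps: tuple[tuple[float, float], ...]  # (duration_s, voltage_mV)

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("protocol must contain at least one step")
        for dur, _ in self.steps:
            if dur <= 0:
                raise ValueError("step durations must be positive")

    @property
    def total_duration_s(self) -> float:
        return float(sum(d for d, _ in self.steps))

    @property
    def edges_s(self) -> np.ndarray:
        """Cumulative step boundaries, length len(steps)+1, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.steps])])

    def voltage_at(self, t: float) -> float:
        edges = self.edges_s
        if t >= edges[-1]:
            return self.steps[-1][1]
        i = int(np.searchsorted(edges, t, side="right")) - 1
        return self.steps[max(i, 0)][1]

    def sample_voltages(self, fs_Hz: float) -> np.ndarray:
        n = int(round(fs_Hz * self.total_duration_s))
        t = np.arange(n) / fs_Hz
        idx = np.clip(np.searchsorted(self.edges_s, t, side="right") - 1, 0, len(self.steps) - 1)
        volts = np.array([v for _, v in self.steps])
        return volts[idx]

    @staticmethod
    def constant(voltage_mV: float, duration_s: float) -> "VoltageProtocol":
        return VoltageProtocol(((duration_s, voltage_mV),))

    @staticmethod
    def alternating(voltage_mV: float, half_period_s: float, n_cycles: int) -> "VoltageProtocol":
        steps = []
        for _ in range(n_cycles):
            steps.append((half_period_s, +abs(voltage_mV)))
            steps.append((half_period_s, -abs(voltage_mV)))
        return VoltageProtocol(tuple(steps))


@dataclass(frozen=True)
class Sojourn:
    state: str
    start_s: float
    end_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class StatePath:
    """One realization of the gating process: contiguous labelled sojourns."""

    sojourns: tuple[Sojourn, ...]

    def __post_init__(self) -> None:
        for a, b in zip(self.sojourns, self.sojourns[1:]):
            if not math.isclose(a.end_s, b.start_s, rel_tol=0, abs_tol=1e-9):
                raise ValueError("sojourns must be contiguous")
            if a.state == b.state:
                raise ValueError("consecutive sojourns must have different states")

    @property
    def start_s(self) -> float:
        return self.sojourns[0].start_s

    @property
    def end_s(self) -> float:
        return self.sojourns[-1].end_s

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def state_at(self, t: float) -> str:
        ends = [s.end_s for s in self.sojourns]
        i = int(np.searchsorted(ends, t, side="right"))
        return self.sojourns[min(i, len(self.sojourns) - 1)].state

    def sample_states(self, fs_Hz: float, n: int) -> np.ndarray:
        """Per-sample sojourn index for sample times k/fs, k=0..n-1."""
        t = np.arange(n) / fs_Hz
        ends = np.array([s.end_s for s in self.sojourns])
        return np.clip(np.searchsorted(ends, t, side="right"), 0, len(self.sojourns) - 1)


@dataclass
class CurrentTrace:
    """A uniformly sampled current record with per-sample applied voltage."""

    fs_Hz: float
    current_pA: np.ndarray
    voltage_mV: np.ndarray
    meta: dict = field(default_factory=dict)
    paths: tuple[StatePath, ...] | None = None  # ground truth when simulated

    def __post_init__(self) -> None:
        if len(self.current_pA) != len(self.voltage_mV):
            raise ValueError("current and voltage vectors must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.current_pA)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_Hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_Hz


# ---------------------------------------------------------------------------
# Preset registry
# ---------------------------------------------------------------------------

# Per-variant state conductances as (mean_nS, sem_nS, n) measured in 1 M KCl,
# 5 mM CaCl2.  Used both to parameterize the presets and as the reference
# summaries the comparison stage tests new estimates against.
REFERENCE_CONDUCTANCES: dict[str, dict[str, tuple[float, float, int]]] = {
    "native": {"S0": (3.94, 0.04, 680), "S1": (2.61, 0.01, 386),
               "S2A": (2.03, 0.01, 224), "S2B": (1.48, 0.02, 70)},
    "cysteinless": {"S0": (3.78, 0.09, 28), "S1": (2.55, 0.12, 24), "S2A": (1.78, 0.09, 12)},
    "delta21": {"S0": (4.00, 0.04, 20)},
    "A14C-S193C_ox": {"S0": (3.74, 0.09, 30), "S2A": (1.85, 0.07, 14)},
    "A14C-S193C_red": {"S0": (3.75, 0.12, 30), "S1": (2.55, 0.12, 30), "S2A": (1.67, 0.09, 30)},
    "V3C-K119C_ox": {"S0": (3.76, 0.10, 77), "S2A": (1.77, 0.09, 30)},
    "V3C-K119C_red": {"S0": (3.98, 0.04, 30), "S1": (2.70, 0.13, 20), "S2A": (2.05, 0.13, 20)},
}

# Overall (any state, time to next switch) dwell summaries, seconds.
REFERENCE_OVERALL_DWELL: dict[str, tuple[float, float, int]] = {
    "native": (10.34, 1.65, 310),
    "cysteinless": (10.45, 5.06, 37),
    "A14C-S193C_ox": (1836.60, 372.91, 14),
    "V3C-K119C_ox": (78.58, 3.99, 8),
}

# Closed-state event counts of the native channel's amplitude histogram,
# used to regenerate the closed-conductance sample at the recorded sizes.
NATIVE_CLOSED_EVENT_COUNTS: dict[str, int] = {"S1": 386, "S2A": 224, "S2B": 70}

# Width (sd, nS) of the per-sub-state conductance scatter across events.
DEFAULT_CONDUCTANCE_JITTER_SD_NS = 0.12

# Native successor weights.  The S0 row splits closures 0.50/0.35/0.15 over
# S1/S2A/S2B; each closed state returns to S0 with weight 0.4503 and
# otherwise moves to another closed state (weights proportional to the S0
# row, excluding itself).  The return weight is chosen so that the embedded
# chain's stationary sojourn mix, combined with the per-state mean dwells
# below, gives an overall mean sojourn of 10.34 s — closed counts exceeding
# open counts in the recordings imply such closed<->closed transitions.
_NATIVE_RETURN_W = 0.4503


def _closed_rows(labels: Sequence[str], s0_row: Mapping[str, float],
                 return_w: float) -> dict[str, dict[str, float]]:
    rows: dict[str, dict[str, float]] = {}
    closed = [l for l in labels if l != "S0"]
    for lab in closed:
        others = {k: v for k, v in s0_row.items() if k != lab}
        tot = sum(others.values())
        row = {"S0": return_w}
        if tot > 0 and len(closed) > 1:
            row.update({k: (1 - return_w) * v / tot for k, v in others.items()})
        else:
            row = {"S0": 1.0}
        rows[lab] = row
    return rows


def _make_preset(name: str, dwell: Mapping[str, float],
                 s0_row: Mapping[str, float], return_w: float,
                 asymmetric: bool = False, orientation: int = 0,
                 absorbing: Sequence[str] = ()) -> ChannelPreset:
    conds = REFERENCE_CONDUCTANCES[name]
    states = tuple(GatingState(lab, conds[lab][0]) for lab in STATE_LABELS if lab in conds)
    labels = [s.label for s in states]
    weights: dict[str, dict[str, float]] = {}
    if len(labels) > 1:
        weights["S0"] = dict(s0_row)
        weights.update(_closed_rows(labels, s0_row, return_w))
    for lab in labels:
        weights.setdefault(lab, {})
    for lab in absorbing:
        weights[lab] = {}
    return ChannelPreset(name=name, states=states, mean_dwell_s=dict(dwell),
                         transition_weights=weights, asymmetric=asymmetric,
                         orientation=orientation)


def _registry() -> dict[str, ChannelPreset]:
    presets = {
        # Native: printed per-state mean dwells; S2A/S2B share the S2 dwell.
        "native": _make_preset(
            "native",
            {"S0": 27.40, "S1": 2.92, "S2A": 2.45, "S2B": 2.45},
            {"S1": 0.50, "S2A": 0.35, "S2B": 0.15}, _NATIVE_RETURN_W),
        "cysteinless": _make_preset(
            "cysteinless",
            {"S0": 36.70, "S1": 3.61, "S2A": 3.10},
            {"S1": 0.588235, "S2A": 0.411765}, 0.2700),
        # N-terminal truncation: a single constitutively open state.
        "delta21": _make_preset("delta21", {"S0": 1.0e6}, {}, 1.0),
        # Mid-pore cross-link, oxidized: locked open for ~30 min on average;
        # rare relaxation into S2 is permanent (absorbing).
        "A14C-S193C_ox": _make_preset(
            "A14C-S193C_ox", {"S0": 1836.60, "S2A": 1.0e6},
            {"S2A": 1.0}, 1.0, absorbing=("S2A",)),
        "A14C-S193C_red": _make_preset(
            "A14C-S193C_red", {"S0": 27.40, "S1": 2.92, "S2A": 2.45},
            {"S1": 0.588235, "S2A": 0.411765}, _NATIVE_RETURN_W),
        # Pore-base cross-link, oxidized: closes under one polarity only.
        # The 5.74 s S0 dwell is the open linger under the closing polarity;
        # under the opposite polarity closure is suppressed entirely.
        "V3C-K119C_ox": _make_preset(
            "V3C-K119C_ox", {"S0": 5.74, "S2A": 2.55},
            {"S2A": 1.0}, 1.0, asymmetric=True, orientation=+1),
        "V3C-K119C_red": _make_preset(
            "V3C-K119C_red", {"S0": 27.40, "S1": 2.92, "S2A": 2.45},
            {"S1": 0.588235, "S2A": 0.411765}, _NATIVE_RETURN_W),
    }
    return presets


_PRESETS = _registry()
PRESET_NAMES = tuple(_PRESETS)


def build_preset(name: str) -> ChannelPreset:
    """Return the registered gating model for a channel variant.

    Raises ``KeyError`` listing the registered names if ``name`` is unknown.
    """
    try:
        return _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; registered presets: {', '.join(PRESET_NAMES)}"
        ) from None


def preset_registry_json() -> dict:
    """The preset registry as a JSON-serializable mapping."""
    out = {}
    for name, p in _PRESETS.items():
        out[name] = {
            "states": {s.label: s.conductance_nS for s in p.states},
            "mean_dwell_s": dict(p.mean_dwell_s),
            "transition_weights": {k: dict(v) for k, v in p.transition_weights.items()},
            "asymmetric": p.asymmetric,
            "orientation": p.orientation,
            "noise_sd_pA": p.noise_sd_pA,
            "conductance_jitter_sd_nS": p.conductance_jitter_sd_nS,
        }
    return out


# ---------------------------------------------------------------------------
# Semi-Markov realization
# ---------------------------------------------------------------------------


def _polarity_ok(preset: ChannelPreset, voltage_mV: float) -> bool:
    """May the channel occupy a non-S0 state at this voltage?"""
    if not preset.asymmetric:
        return True
    return int(np.sign(voltage_mV)) == preset.orientation


def _next_nonclosing_edge(preset: ChannelPreset, protocol: VoltageProtocol,
                          t: float) -> float:
    """First protocol edge after t at which closure becomes forbidden."""
    edges = protocol.edges_s
    for e, (_, v) in zip(edges[:-1], protocol.steps):
        if e > t and not _polarity_ok(preset, v):
            return float(e)
    return math.inf


def simulate_state_path(preset: ChannelPreset, protocol: VoltageProtocol,
                        seed: int | np.random.Generator,
                        start_s: float = 0.0) -> StatePath:
    """Realize the semi-Markov gating process over the protocol's duration.

    Sojourn lengths are exponential with the preset's per-state means;
    successors follow ``transition_weights``.  For asymmetric presets,
    closures attempted while ``sign(V) != orientation`` are suppressed (the
    S0 sojourn simply continues) and an ongoing closed sojourn is cut short
    the moment the polarity flips away from the closing sign.  The path
    starts in S0 (channels insert open) and is truncated at the protocol
    end.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    T = protocol.total_duration_s
    if start_s >= T:
        raise ValueError("start_s must lie before the protocol end")
    labels = list(preset.labels)
    succ = {lab: (list(row), np.array([row[k] for k in row]))
            for lab, row in ((l, preset.transition_weights.get(l, {})) for l in labels)}

    sojourns: list[Sojourn] = []
    state = "S0"
    t0 = start_s
    t = start_s
    while t < T:
        names, probs = succ[state]
        if not names:  # absorbing (or single-state) — occupy to the end
            t = T
            break
        dwell = rng.exponential(preset.mean_dwell_s[state])
        t_end = t + dwell
        if preset.asymmetric and state != "S0":
            # a polarity flip away from the closing sign forces reopening
            flip = _next_nonclosing_edge(preset, protocol, t)
            if flip < t_end:
                t_end = flip
                if t_end >= T:
                    t = T
                    break
                sojourns.append(Sojourn(state, t0, t_end))
                state, t0, t = "S0", t_end, t_end
                continue
        if t_end >= T:
            t = T
            break
        nxt = names[rng.choice(len(names), p=probs)]
        if nxt != "S0" and not _polarity_ok(preset, protocol.voltage_at(t_end)):
            t = t_end  # closure suppressed: remain in S0, keep waiting
            continue
        sojourns.append(Sojourn(state, t0, t_end))
        state, t0, t = nxt, t_end, t_end
    sojourns.append(Sojourn(state, t0, T))
    return StatePath(tuple(sojourns))


def render_current(path: StatePath, preset: ChannelPreset,
                   protocol: VoltageProtocol, fs_Hz: float,
                   seed: int | np.random.SeedSequence,
                   insertion_s: float = 0.0) -> CurrentTrace:
    """Render one channel's Ohmic current for a state path.

    I(t) = g(state(t)) * V(t) + noise, in pA (nS x mV).  Samples before
    ``insertion_s`` carry no channel current (pre-insertion baseline).
    Per-sojourn conductance jitter and per-sample Gaussian noise come from
    independent streams derived from ``seed``, so the same path can be
    re-rendered with different noise.
    """
    if fs_Hz <= 0:
        raise ValueError("fs_Hz must be positive")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    jitter_rng, noise_rng = (np.random.default_rng(c) for c in ss.spawn(2))

    volts = protocol.sample_voltages(fs_Hz)
    n = len(volts)
    t = np.arange(n) / fs_Hz

    g_states = np.array([preset.conductance(s.state) for s in path.sojourns])
    if preset.conductance_jitter_sd_nS > 0:
        g_states = g_states + jitter_rng.normal(
            0.0, preset.conductance_jitter_sd_nS, size=len(g_states))
    idx = path.sample_states(fs_Hz, n)
    g = g_states[idx]
    g = np.where(t < max(insertion_s, path.start_s), 0.0, g)

    current = g * volts
    if preset.noise_sd_pA > 0:
        current = current + noise_rng.normal(0.0, preset.noise_sd_pA, size=n)
    meta = {"preset": preset.name, "noise_sd_pa": preset.noise_sd_pA,
            "n_channels": 1, "insertion_s": insertion_s}
    return CurrentTrace(fs_Hz=fs_Hz, current_pA=current, voltage_mV=volts,
                        meta=meta, paths=(path,))


MAX_CHANNELS = 5  # recordings with more simultaneous insertions are discarded


def simulate_trace(preset: ChannelPreset, protocol: VoltageProtocol,
                   fs_Hz: float = 5000.0, seed: int = 0,
                   n_channels: int = 1, insertion_s: float = 0.0,
                   decimate_to_Hz: float | None = None) -> CurrentTrace:
    """Simulate a complete BLM recording: path(s) + Ohmic rendering + noise.

    Multi-channel membranes sum up to ``MAX_CHANNELS`` independent channels
    of the same preset (and hence the same orientation — insertion is
    auto-directed); a single noise term is applied to the summed current.
    """
    if not 1 <= n_channels <= MAX_CHANNELS:
        raise ValueError(f"n_channels must be in 1..{MAX_CHANNELS}")
    master = np.random.SeedSequence(seed)
    path_ss, render_ss, noise_ss = master.spawn(3)
    path_seeds = path_ss.spawn(n_channels)
    render_seeds = render_ss.spawn(n_channels)

    quiet = preset.with_(noise_sd_pA=0.0)
    total = None
    paths = []
    for ps, rs in zip(path_seeds, render_seeds):
        path = simulate_state_path(preset, protocol, np.random.default_rng(ps),
                                   start_s=insertion_s)
        tr = render_current(path, quiet, protocol, fs_Hz, rs, insertion_s=insertion_s)
        total = tr.current_pA if total is None else total + tr.current_pA
        paths.append(path)
    volts = protocol.sample_voltages(fs_Hz)
    if preset.noise_sd_pA > 0:
        total = total + np.random.default_rng(noise_ss).normal(
            0.0, preset.noise_sd_pA, size=len(total))
    meta = {"preset": preset.name, "seed": seed, "noise_sd_pa": preset.noise_sd_pA,
            "n_channels": n_channels, "insertion_s": insertion_s}
    trace = CurrentTrace(fs_Hz=fs_Hz, current_pA=total, voltage_mV=volts,
                         meta=meta, paths=tuple(paths))
    if decimate_to_Hz is not None:
        trace = decimate(trace, decimate_to_Hz)
    return trace


def decimate(trace: CurrentTrace, target_fs_Hz: float) -> CurrentTrace:
    """Downsample by non-overlapping block averaging (e.g. 5 kHz -> 200 Hz)."""
    ratio = trace.fs_Hz / target_fs_Hz
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"fs ({trace.fs_Hz} Hz) must be an integer multiple of the target "
            f"({target_fs_Hz} Hz)")
    r = int(round(ratio))
    if r == 1:
        return trace
    n_blocks = trace.n_samples // r
    cur = trace.current_pA[: n_blocks * r].reshape(n_blocks, r).mean(axis=1)
    vol = trace.voltage_mV[: n_blocks * r].reshape(n_blocks, r).mean(axis=1)
    meta = dict(trace.meta)
    meta["decimated_from_hz"] = trace.fs_Hz
    return CurrentTrace(fs_Hz=target_fs_Hz, current_pA=cur, voltage_mV=vol,
                        meta=meta, paths=trace.paths)


def sample_state_conductances(preset: ChannelPreset,
                              counts: Mapping[str, int],
                              sd_nS: float = DEFAULT_CONDUCTANCE_JITTER_SD_NS,
                              seed: int = 0) -> np.ndarray:
    """Draw per-event conductances around the preset's state means.

    Emulates the per-event scatter of an amplitude histogram: for each state
    label, ``counts[label]`` values are drawn from
    N(conductance(label), sd_nS**2).  Returns the concatenated sample in
    label order (S0, S1, S2A, S2B as present in ``counts``).
    """
    rng = np.random.default_rng(seed)
    parts = []
    for lab in STATE_LABELS:
        if lab in counts:
            parts.append(rng.normal(preset.conductance(lab), sd_nS, size=counts[lab]))
    if not parts:
        raise ValueError("counts is empty")
    return np.concatenate(parts)
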