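"""Current-trace idealization: baseline, change-point segmentation, labels.

A recording is reduced to a sequence of piecewise-constant segments
(events).  Each event's amplitude is measured relative to the zero-channel
baseline and converted to a conductance g = (I - baseline) / V, which is
then matched against the variant's reference state conductances within a
relative window (default +-5%): events matching no reference are labelled
INTERMEDIATE, events at the baseline level BASELINE.

Segmentation uses deterministic binary change-point splitting on running
means within each constant-voltage region, with a jump threshold expressed
in units of the estimated noise standard deviation and minimum-duration
merging.  It is parameter-light and exactly recovers the generating change
points on noise-free traces, which is what makes the simulator an oracle
for it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .gating_model import CurrentTrace

logger = logging.getLogger("vdacgate")

INTERMEDIATE = "INTERMEDIATE"
BASELINE = "BASELINE"


@dataclass(frozen=True)
class Segment:
    """One piecewise-constant stretch of a recording."""

    start_s: float
    end_s: float
    mean_current_pA: float
    voltage_mV: float
    conductance_nS: float
    state: str

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables for segmentation and classification.

    jump_threshold_pA: minimum mean-current difference between adjacent
        segments; ``None`` uses 4x the robust noise-sd estimate.
    min_duration_s: events shorter than this are merged into the
        neighbouring segment with the nearer mean (25 ms = 5 samples at the
        200 Hz analysis rate).
    window: half-width of the relative classification window (0.05 = +-5%).
    edge_exclude_s: stretch dropped after each voltage step (capacitive
        artifacts in real recordings; 0 for the artifact-free simulator).
    """

    jump_threshold_pA: float | None = None
    min_duration_s: float = 0.025
    window: float = 0.05
    edge_exclude_s: float = 0.0


@dataclass(frozen=True)
class BaselineEstimate:
    baseline_pA: float
    method: str  # "cluster" | "lowest_cluster" | "median_fallback"


@dataclass
class Idealization:
    segments: list[Segment]
    baseline_pA: float
    params: SegmentationParams = field(default_factory=SegmentationParams)


# ---------------------------------------------------------------------------
# Baseline
# ---------------------------------------------------------------------------


def estimate_baseline(trace: CurrentTrace, min_voltage_mV: float = 5.0,
                      bin_width_nS: float = 0.1,
                      cluster_halfwidth_nS: float = 0.3) -> BaselineEstimate:
    """Estimate the zero-channel current level.

    Builds a histogram of the per-sample apparent conductance I/V (over
    samples with |V| >= ``min_voltage_mV``), locates its lowest peak, and
    returns the mean raw current of the samples in that cluster — for true
    baseline samples the current is voltage-independent, so the cluster
    mean converts cleanly back to pA.  If the lowest cluster does not sit
    near zero conductance the trace contains no baseline-level samples; the
    lowest-conductance cluster is used anyway and a warning is logged.
    Traces with no usable voltage fall back to the median current.
    """
    if trace.duration_s < 1.0:
        raise ValueError("need at least 1 s of data to estimate a baseline")
    mask = np.abs(trace.voltage_mV) >= min_voltage_mV
    if not mask.any():
        logger.warning("baseline: no samples with |V| >= %g mV; "
                       "falling back to median current", min_voltage_mV)
        return BaselineEstimate(float(np.median(trace.current_pA)), "median_fallback")

    g = trace.current_pA[mask] / trace.voltage_mV[mask]

    # A cluster at zero conductance is the baseline whenever it holds a
    # usable amount of data (>= 0.25 s), however small a fraction of a long
    # recording that is.
    near_zero = np.abs(g) <= cluster_halfwidth_nS
    if near_zero.sum() >= max(10, int(0.25 * trace.fs_Hz)):
        cluster = mask.copy()
        cluster[mask] = near_zero
        return BaselineEstimate(float(trace.current_pA[cluster].mean()), "cluster")

    lo = math.floor(g.min() / bin_width_nS) * bin_width_nS
    hi = math.ceil(g.max() / bin_width_nS) * bin_width_nS + bin_width_nS
    edges = np.arange(lo, hi + bin_width_nS / 2, bin_width_nS)
    counts, _ = np.histogram(g, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2

    min_count = max(5, int(0.005 * len(g)))
    padded = np.concatenate([[-1], counts, [-1]])
    is_peak = (counts >= padded[:-2]) & (counts >= padded[2:]) & (counts >= min_count)
    if not is_peak.any():
        is_peak = counts == counts.max()
    peak_center = float(centers[np.argmax(is_peak)])

    cluster = mask.copy()
    cluster[mask] = np.abs(g - peak_center) <= cluster_halfwidth_nS
    baseline = float(trace.current_pA[cluster].mean())
    if abs(peak_center) > 0.6:
        logger.warning(
            "baseline: lowest conductance cluster at %.2f nS is not near 0; "
            "trace appears to contain no baseline-level samples", peak_center)
        return BaselineEstimate(baseline, "lowest_cluster")
    return BaselineEstimate(baseline, "cluster")


# ---------------------------------------------------------------------------
# Change-point segmentation
# ---------------------------------------------------------------------------


def estimate_noise_sd(current_pA: np.ndarray) -> float:
    """Robust per-sample noise sd from first differences (MAD-based)."""
    d = np.diff(current_pA)
    if len(d) == 0:
        return 0.0
    mad = np.median(np.abs(d - np.median(d)))
    return float(mad * 1.4826 / math.sqrt(2.0))


def _best_split(x: np.ndarray) -> tuple[int, float]:
    """Best binary split of x: (index k, |mean(x[:k]) - mean(x[k:])|).

    k maximizes the CUSUM statistic sqrt(k(n-k)/n) * |mean difference|;
    the returned jump is the plain mean difference at that k.
    """
    n = len(x)
    cs = np.cumsum(x)
    k = np.arange(1, n)
    mean_l = cs[:-1] / k
    mean_r = (cs[-1] - cs[:-1]) / (n - k)
    stat = np.sqrt(k * (n - k) / n) * np.abs(mean_l - mean_r)
    i = int(np.argmax(stat))
    return i + 1, float(abs(mean_l[i] - mean_r[i]))


def _split_recursive(x: np.ndarray, offset: int, threshold: float,
                     out: list[int]) -> None:
    if len(x) < 2:
        return
    k, jump = _best_split(x)
    if jump <= threshold:
        return
    out.append(offset + k)
    _split_recursive(x[:k], offset, threshold, out)
    _split_recursive(x[k:], offset + k, threshold, out)


def _merge_short_runs(bounds: list[int], x: np.ndarray, min_len: int) -> list[int]:
    """Drop boundaries so every run has >= min_len samples, merging short
    runs into the neighbour with the nearer mean."""
    bounds = list(bounds)
    while True:
        runs = list(zip(bounds[:-1], bounds[1:]))
        lens = [b - a for a, b in runs]
        if not runs or min(lens) >= min_len or len(runs) == 1:
            return bounds
        i = int(np.argmin(lens))
        a, b = runs[i]
        m = x[a:b].mean()
        if i == 0:
            drop = i + 1
        elif i == len(runs) - 1:
            drop = i
        else:
            left = x[runs[i - 1][0]:runs[i - 1][1]].mean()
            right = x[runs[i + 1][0]:runs[i + 1][1]].mean()
            drop = i if abs(m - left) <= abs(m - right) else i + 1
        del bounds[drop]


def _merge_similar_runs(bounds: list[int], x: np.ndarray, threshold: float) -> list[int]:
    """Remove boundaries between adjacent runs whose means differ <= threshold."""
    changed = True
    while changed and len(bounds) > 2:
        changed = False
        for i in range(1, len(bounds) - 1):
            left = x[bounds[i - 1]:bounds[i]].mean()
            right = x[bounds[i]:bounds[i + 1]].mean()
            if abs(left - right) <= threshold:
                del bounds[i]
                changed = True
                break
    return bounds


def segment_trace(trace: CurrentTrace, params: SegmentationParams | None = None,
                  baseline_pA: float | None = None,
                  preset_refs: dict[str, float] | None = None) -> Idealization:
    """Partition a (decimated) trace into piecewise-constant events.

    Each constant-voltage region is split independently by recursive binary
    change-point detection; runs shorter than ``params.min_duration_s`` are
    merged into the nearer-mean neighbour, and adjacent runs whose means
    differ by no more than the jump threshold are re-joined.  Zero-voltage
    regions are skipped (conductance undefined).  If ``preset_refs`` is
    given each segment is classified; otherwise states are left as
    INTERMEDIATE placeholders.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot segment an empty trace")
    params = params or SegmentationParams()
    if baseline_pA is None:
        baseline_pA = estimate_baseline(trace).baseline_pA

    threshold = params.jump_threshold_pA
    if threshold is None:
        sd = estimate_noise_sd(trace.current_pA)
        threshold = max(4.0 * sd, 1e-9)

    min_len = max(1, int(round(params.min_duration_s * trace.fs_Hz)))
    edge_skip = int(round(params.edge_exclude_s * trace.fs_Hz))

    # constant-voltage regions
    v = trace.voltage_mV
    change = np.flatnonzero(np.diff(v) != 0) + 1
    region_bounds = np.concatenate([[0], change, [trace.n_samples]])

    segments: list[Segment] = []
    for r0, r1 in zip(region_bounds[:-1], region_bounds[1:]):
        a = r0 + (edge_skip if r0 > 0 else 0)
        if r1 - a < 1:
            continue
        voltage = float(v[a])
        if voltage == 0.0:
            continue  # not analyzable
        x = trace.current_pA[a:r1]
        cuts: list[int] = []
        _split_recursive(x, 0, threshold, cuts)
        bounds = [0] + sorted(cuts) + [len(x)]
        bounds = _merge_short_runs(bounds, x, min_len)
        bounds = _merge_similar_runs(bounds, x, threshold)
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            mean_i = float(x[b0:b1].mean())
            g = (mean_i - baseline_pA) / voltage
            state = INTERMEDIATE
            if preset_refs is not None:
                state = classify_state(g, preset_refs, params.window)
            segments.append(Segment(
                start_s=(a + b0) / trace.fs_Hz, end_s=(a + b1) / trace.fs_Hz,
                mean_current_pA=mean_i, voltage_mV=voltage,
                conductance_nS=g, state=state))
    return Idealization(segments=segments, baseline_pA=baseline_pA, params=params)


# ---------------------------------------------------------------------------
# State classification
# ---------------------------------------------------------------------------


def classify_state(conductance_nS: float, preset_refs: dict[str, float],
                   window: float = 0.05) -> str:
    """Assign a conductance to a reference state within a relative window.

    A state with reference conductance r matches when
    |g - r| <= window * r (boundaries inclusive); among several matches the
    one with the smallest relative distance wins.  Values matching nothing
    are INTERMEDIATE; values lying more than two windows below the smallest
    reference are BASELINE.
    """
    if not 0 < window < 0.5:
        raise ValueError("window must lie in (0, 0.5)")
    if not preset_refs or any(r <= 0 for r in preset_refs.values()):
        raise ValueError("preset_refs must be non-empty with positive values")
    g = conductance_nS
    best = None
    for label, r in preset_refs.items():
        rel = abs(g - r) / r
        if rel <= window * (1 + 1e-12) + 1e-15 and (best is None or rel < best[1]):
            best = (label, rel)
    if best is not None:
        return best[0]
    r_min = min(preset_refs.values())
    if g < r_min * (1 - 2 * window):
        return BASELINE
    return INTERMEDIATE
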