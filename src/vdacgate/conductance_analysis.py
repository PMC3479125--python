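"""Per-state conductance estimation and closed-state mixture decomposition.

Two complementary estimates come out of an idealized recording:

* **Ohm fits** — for each state, the mean event amplitude DeltaI at each
  applied voltage is regressed on V through the origin; the slope is the
  state conductance in nS.  A through-origin fit encodes the channel's
  Ohmic behaviour (the I-V relation passes through zero at both
  polarities).

* **Amplitude-histogram decomposition** — the closed-state (non-S0) event
  conductances are binned and fitted by sums of Gaussians, least-squares on
  the binned histogram.  Stage 1 fits two components over all closed events,
  separating S1 (upper) from S2 (lower).  Stage 2 restricts to the S2
  window (0.80-2.20 nS by default) and fits two components again, splitting
  S2 into the S2A (upper) and S2B (lower) sub-states.  Goodness of fit is
  the R-squared of the binned fit.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .idealization import BASELINE, Segment

logger = logging.getLogger("vdacgate")

DEFAULT_BIN_WIDTH_NS = 0.05
DEFAULT_S2_WINDOW_NS = (0.80, 2.20)
MIN_OHM_MEASUREMENTS = 15  # minimum replicate count behind a reported conductance


@dataclass(frozen=True)
class OhmFit:
    state: str
    conductance_nS: float
    sem_nS: float
    n: int
    per_voltage_mean_pA: dict[float, float]
    fallback: bool = False  # single voltage: mean conductance, no regression


@dataclass(frozen=True)
class GaussianComponent:
    mean_nS: float
    sd_nS: float
    weight: float  # relative area, components of a fit sum to 1


@dataclass(frozen=True)
class MixtureFit:
    components: tuple[GaussianComponent, ...]  # sorted by descending mean
    r_squared: float
    bin_width_nS: float
    fit_range_nS: tuple[float, float]
    n: int


@dataclass(frozen=True)
class ClosedStateDecomposition:
    """Result of the nested two-stage closed-state decomposition."""

    stage1: MixtureFit                 # S1 (upper) + S2 (lower) over all closed events
    stage2: MixtureFit | None          # S2A (upper) + S2B (lower) within the S2 window
    single_gaussian: MixtureFit        # one-component fit ("mean closed state")
    sample_mean_nS: float              # plain mean of the closed conductances
    counts: dict[str, int]             # events per component, nearest-mean assignment
    s2_window_nS: tuple[float, float]

    @property
    def s1(self) -> GaussianComponent:
        return self.stage1.components[0]

    @property
    def s2(self) -> GaussianComponent:
        return self.stage1.components[-1]

    @property
    def s2a(self) -> GaussianComponent | None:
        return None if self.stage2 is None else self.stage2.components[0]

    @property
    def s2b(self) -> GaussianComponent | None:
        if self.stage2 is None or len(self.stage2.components) < 2:
            return None
        return self.stage2.components[-1]


# ---------------------------------------------------------------------------
# Ohm fits
# ---------------------------------------------------------------------------


def ohm_fit(events: list[Segment], state: str) -> OhmFit:
    """Through-origin weighted regression of mean event amplitude on voltage.

    Per-voltage mean amplitudes are weighted by their event counts, which
    makes the slope identical to the per-event through-origin least-squares
    slope sum(V_i * dI_i) / sum(V_i^2).  The quoted SEM is the standard
    error of the per-event conductances.  With events at a single voltage
    no regression is possible; the mean per-event conductance is returned
    with ``fallback=True``.
    """
    evs = [e for e in events if e.state == state]
    if not evs:
        raise ValueError(f"no events with state {state!r}")
    # Event amplitudes are already baseline-relative (conductance * V).
    di = np.array([e.conductance_nS * e.voltage_mV for e in evs])
    v = np.array([e.voltage_mV for e in evs])
    g = np.array([e.conductance_nS for e in evs])
    n = len(evs)
    if n < MIN_OHM_MEASUREMENTS:
        logger.warning("ohm_fit(%s): only %d measurements (fewer than %d)",
                       state, n, MIN_OHM_MEASUREMENTS)
    per_v = {float(vv): float(di[v == vv].mean()) for vv in np.unique(v)}
    sem = float(g.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    if len(per_v) < 2:
        logger.warning("ohm_fit(%s): single voltage; falling back to mean "
                       "per-event conductance", state)
        return OhmFit(state, float(g.mean()), sem, n, per_v, fallback=True)
    slope = float(np.sum(v * di) / np.sum(v * v))
    return OhmFit(state, slope, sem, n, per_v, fallback=False)


# ---------------------------------------------------------------------------
# Histogram + mixture fitting
# ---------------------------------------------------------------------------


def closed_state_histogram(events: list[Segment],
                           bin_width_nS: float = DEFAULT_BIN_WIDTH_NS
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of closed-event conductances on a grid aligned to 0.

    Returns (counts, bin_edges).  ``events`` must already exclude S0 and
    BASELINE; passing an empty list is an error.
    """
    if not events:
        raise ValueError("no closed events to histogram")
    bad = [e for e in events if e.state in ("S0", BASELINE)]
    if bad:
        raise ValueError("closed_state_histogram received S0/BASELINE events")
    values = np.array([e.conductance_nS for e in events])
    return _histogram(values, bin_width_nS)


def _histogram(values: np.ndarray, bin_width: float,
               fit_range: tuple[float, float] | None = None
               ) -> tuple[np.ndarray, np.ndarray]:
    if fit_range is not None:
        values = values[(values >= fit_range[0]) & (values <= fit_range[1])]
        lo = math.floor(fit_range[0] / bin_width) * bin_width
        hi = math.ceil(fit_range[1] / bin_width) * bin_width
    else:
        lo = math.floor(values.min() / bin_width) * bin_width
        hi = math.ceil(values.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return counts, edges


def _gauss_sum(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x, dtype=float)
    for i in range(0, len(params), 3):
        a, mu, sd = params[i:i + 3]
        y = y + a * np.exp(-0.5 * ((x - mu) / sd) ** 2)
    return y


def _peak_inits(centers: np.ndarray, counts: np.ndarray, k: int) -> list[float]:
    """Initial (amplitude, mean, sd) triplets from the k tallest separated bins."""
    order = np.argsort(counts)[::-1]
    chosen: list[int] = []
    min_sep = max(2, len(centers) // (3 * k)) if k > 1 else 0
    for i in order:
        if counts[i] <= 0:
            break
        if all(abs(i - j) >= min_sep for j in chosen):
            chosen.append(int(i))
        if len(chosen) == k:
            break
    while len(chosen) < k:  # fall back to quantile positions
        q = (len(chosen) + 0.5) / k
        chosen.append(int(np.clip(round(q * (len(centers) - 1)), 0, len(centers) - 1)))
    span = centers[-1] - centers[0] + 1e-12
    sd0 = max(span / (4 * k), (centers[1] - centers[0]) if len(centers) > 1 else span)
    p0 = []
    for i in sorted(chosen):
        p0 += [max(counts[i], 1.0), centers[i], sd0]
    return p0


def _fit_once(centers: np.ndarray, counts: np.ndarray, p0: list[float],
              bounds: tuple) -> tuple[np.ndarray, float] | None:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss_sum, centers, counts, p0=p0,
                                bounds=bounds, maxfev=20000)
        sse = float(np.sum((counts - _gauss_sum(centers, *popt)) ** 2))
        return popt, sse
    except (RuntimeError, ValueError):
        return None


class MixtureFitError(RuntimeError):
    """Raised when no Gaussian-sum fit converges; carries the last iterate."""

    def __init__(self, message: str, last_p0: list[float] | None = None):
        super().__init__(message)
        self.last_p0 = last_p0


def fit_mixture(values: np.ndarray, k: int,
                fit_range_nS: tuple[float, float] | None = None,
                bin_width_nS: float = DEFAULT_BIN_WIDTH_NS) -> MixtureFit:
    """Least-squares fit of a k-component Gaussian sum to a binned histogram.

    The histogram (fixed ``bin_width_nS``, optionally restricted to
    ``fit_range_nS``) is fitted by sum_i A_i exp(-(x-mu_i)^2 / 2 sd_i^2)
    with several deterministic initializations (histogram peaks, quantiles
    and, for k=2, a split of the single-Gaussian solution, which makes the
    two-component fit at least as good as the one-component fit).  Weights
    are normalized component areas; components are sorted by descending
    mean.  R-squared is computed on the binned counts.
    """
    values = np.asarray(values, dtype=float)
    if fit_range_nS is not None:
        values = values[(values >= fit_range_nS[0]) & (values <= fit_range_nS[1])]
    if len(values) < 30:
        raise ValueError(f"need at least 30 values to fit a mixture, got {len(values)}")
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")

    counts, edges = _histogram(values, bin_width_nS, fit_range_nS)
    centers = (edges[:-1] + edges[1:]) / 2
    rng_lo, rng_hi = float(edges[0]), float(edges[-1])
    span = rng_hi - rng_lo

    sd_min = bin_width_nS / 4
    one = (np.array([0.0, rng_lo - span, sd_min]), np.array([np.inf, rng_hi + span, 2 * span]))
    bounds = (np.tile(one[0], k), np.tile(one[1], k))

    inits = [_peak_inits(centers, counts, k)]
    if k == 2:
        q = np.quantile(values, [0.3, 0.7])
        a0 = max(counts.max(), 1.0)
        inits.append([a0, q[0], span / 6 + sd_min, a0, q[1], span / 6 + sd_min])
        # grid of second-component positions: a small, well-separated
        # component is easy to miss from peak heights alone
        main = float(centers[np.argmax(counts)])
        sd0 = max(span / 10, 2 * bin_width_nS)
        for frac in (0.1, 0.25, 0.4, 0.6, 0.75, 0.9):
            pos = rng_lo + frac * span
            if abs(pos - main) < 2 * sd0:
                continue
            inits.append([a0, main, sd0, 0.2 * a0, pos, sd0])
        try:  # nest the single-Gaussian solution so R2(k=2) >= R2(k=1)
            f1 = fit_mixture(values, 1, fit_range_nS, bin_width_nS)
            c = f1.components[0]
            a1 = c.weight * len(values) * bin_width_nS / (c.sd_nS * math.sqrt(2 * math.pi))
            eps = bin_width_nS / 2
            inits.append([a1, c.mean_nS - eps, c.sd_nS, 1e-3, c.mean_nS + eps, c.sd_nS])
        except (ValueError, MixtureFitError):
            pass

    best = None
    for p0 in inits:
        res = _fit_once(centers, counts, p0, bounds)
        if res is not None and (best is None or res[1] < best[1]):
            best = res
    if best is None:
        raise MixtureFitError(
            f"no {k}-component fit converged on {len(values)} values", inits[-1])
    popt, sse = best

    comps = []
    areas = []
    for i in range(0, 3 * k, 3):
        a, mu, sd = popt[i:i + 3]
        areas.append(a * sd * math.sqrt(2 * math.pi))
        comps.append((float(mu), float(sd)))
    total = sum(areas) or 1.0
    components = tuple(
        GaussianComponent(mu, sd, float(area / total))
        for (mu, sd), area in sorted(zip(comps, areas), key=lambda t: -t[0][0]))

    sst = float(np.sum((counts - counts.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else 0.0)
    return MixtureFit(components=components, r_squared=float(np.clip(r2, 0.0, 1.0)),
                      bin_width_nS=bin_width_nS, fit_range_nS=(rng_lo, rng_hi),
                      n=len(values))


def _assign_counts(values: np.ndarray, comps: tuple[GaussianComponent, ...],
                   labels: tuple[str, ...]) -> dict[str, int]:
    """Assign each value to the component with the nearest mean in sd units."""
    dist = np.stack([np.abs(values - c.mean_nS) / max(c.sd_nS, 1e-12) for c in comps])
    idx = np.argmin(dist, axis=0)
    return {lab: int(np.sum(idx == i)) for i, lab in enumerate(labels)}


def decompose_closed_states(closed_events: list[Segment] | np.ndarray,
                            s2_window_nS: tuple[float, float] = DEFAULT_S2_WINDOW_NS,
                            bin_width_nS: float = DEFAULT_BIN_WIDTH_NS
                            ) -> ClosedStateDecomposition:
    """Nested two-stage decomposition of the closed-state conductances.

    Stage 1 fits two Gaussians to all closed-event conductances: the upper
    component is S1, the lower S2.  Stage 2 restricts to the S2 window and
    fits two Gaussians again: upper = S2A, lower = S2B.  Also reports the
    single-Gaussian fit and the plain sample mean of the closed events (the
    two candidate readings of a "mean closed state"), and per-component
    event counts by nearest-mean assignment.

    Accepts either labelled closed events or a raw conductance array.  If
    the sample is (near-)degenerate a single component is reported with a
    warning; if the S2 window holds too few events stage 2 is skipped.
    """
    if isinstance(closed_events, np.ndarray):
        values = np.asarray(closed_events, dtype=float)
    else:
        if any(e.state in ("S0", BASELINE) for e in closed_events):
            raise ValueError("decompose_closed_states expects closed (non-S0) events")
        values = np.array([e.conductance_nS for e in closed_events])
    if len(values) < 30:
        raise ValueError("need at least 30 closed events")
    if len(values) < 100:
        logger.warning("decompose_closed_states: only %d closed events; "
                       ">= 100 recommended", len(values))

    sample_mean = float(values.mean())
    if float(np.ptp(values)) < bin_width_nS:  # all events at one level
        logger.warning("closed conductances are degenerate (range < bin width); "
                       "reporting a single component")
        comp = GaussianComponent(sample_mean, bin_width_nS, 1.0)
        degenerate = MixtureFit((comp,), 1.0, bin_width_nS,
                                (sample_mean - bin_width_nS, sample_mean + bin_width_nS),
                                len(values))
        return ClosedStateDecomposition(
            stage1=degenerate, stage2=None, single_gaussian=degenerate,
            sample_mean_nS=sample_mean, counts={"S1": len(values)},
            s2_window_nS=s2_window_nS)

    single = fit_mixture(values, 1, bin_width_nS=bin_width_nS)
    stage1 = fit_mixture(values, 2, bin_width_nS=bin_width_nS)
    counts = _assign_counts(values, stage1.components, ("S1", "S2"))

    in_window = values[(values >= s2_window_nS[0]) & (values <= s2_window_nS[1])]
    stage2 = None
    if len(in_window) >= 30:
        try:
            stage2 = fit_mixture(values, 2, fit_range_nS=s2_window_nS,
                                 bin_width_nS=bin_width_nS)
            counts.update(_assign_counts(in_window, stage2.components, ("S2A", "S2B")))
        except MixtureFitError as exc:
            logger.warning("stage-2 fit failed (%s); skipping", exc)
    else:
        logger.warning("S2 window %s holds only %d events; stage 2 skipped",
                       s2_window_nS, len(in_window))
    return ClosedStateDecomposition(
        stage1=stage1, stage2=stage2, single_gaussian=single,
        sample_mean_nS=sample_mean, counts=counts, s2_window_nS=s2_window_nS)


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal-style rounding: halves away from zero (2.5 -> 3)."""
    factor = 10.0 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def percent_of_open(g_state_nS: float, g_open_nS: float) -> int:
    """A state's conductance as an integer percentage of the open state."""
    if g_open_nS <= 0:
        raise ValueError("open-state conductance must be positive")
    return int(round_half_up(100.0 * g_state_nS / g_open_nS))
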