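# Methods

## Gating model

A channel is modelled as a semi-Markov jump process over a small set of
conductance states.  In state *s* the channel sojourns for an
Exponential(τ_s) time (τ_s the state's mean dwell, seconds), then jumps to
a successor drawn from a per-state categorical distribution (no
self-transitions; an empty successor row marks an absorbing state).
Conduction is Ohmic per state: the baseline-subtracted current is
I(t) = g(state) · V(t), with g in nS and V in mV so I is in pA.  Simulated
paths always start open (channels insert in the open state).

Each variant is a `ChannelPreset` holding per-state conductances, mean
dwells, successor weights, an asymmetry flag/orientation, the recording
noise level, and the per-sojourn conductance scatter:

| preset          | states (nS)                               | mean dwells (s)            |
|-----------------|-------------------------------------------|----------------------------|
| `native`        | S0 3.94, S1 2.61, S2A 2.03, S2B 1.48      | 27.40 / 2.92 / 2.45 / 2.45 |
| `cysteinless`   | S0 3.78, S1 2.55, S2 1.78                 | 36.70 / 3.61 / 3.10        |
| `delta21`       | S0 4.00 (single, constitutively open)     | —                          |
| `A14C-S193C_ox` | S0 3.74, S2 1.85 (absorbing)              | 1836.60 / —                |
| `A14C-S193C_red`| S0 3.75, S1 2.55, S2 1.67                 | native-like                |
| `V3C-K119C_ox`  | S0 3.76, S2 1.77 (asymmetric)             | 5.74 / 2.55                |
| `V3C-K119C_red` | S0 3.98, S1 2.70, S2 2.05                 | native-like                |

S2A and S2B share one mean dwell because only a pooled S2 dwell is
measurable.  Variants whose closed state is a single population are given
the `S2A` label internally.

**Native successor weights.**  The open state closes into S1/S2A/S2B with
weights 0.50/0.35/0.15.  Each closed state returns to S0 with weight
0.4503 and otherwise moves to another closed state (weights proportional
to the S0 row, renormalized without the current state).  The return weight
is calibrated (1-D root find, frozen into the registry) so that the
embedded chain's stationary sojourn mix, combined with the per-state mean
dwells, gives a theoretical overall mean sojourn of 10.34 s.  Closed↔closed
transitions are required by the data: recordings show more closed sojourns
than open ones, which a strictly alternating open↔closed chain cannot
produce.  The cysteinless return weight (0.27) is calibrated the same way
to its 10.45 s overall mean.

**Polarity asymmetry.**  For asymmetric presets, closure is permitted only
while sign(V) equals the preset's orientation (+1 by convention: closure
at positive voltage; the physical sign is set by the insertion orientation
and is configurable).  Two rules implement this: a drawn transition into a
non-S0 state is suppressed (the S0 sojourn simply continues) whenever the
polarity is wrong, and an ongoing closed sojourn is terminated at the step
edge where the polarity flips away from the closing sign.  Consequently
the time spent closed under the non-closing polarity is exactly zero.  At
0 mV closure is likewise suppressed (no driving field; closed conductance
would be unobservable anyway).

**Noise and conductance scatter.**  Recording noise is white Gaussian,
default sd 2 pA at the 5 kHz acquisition rate; after 25-sample block
averaging to 200 Hz the effective sd is 0.4 pA, so the smallest state
separation (~0.4 nS ≡ 16 pA at 40 mV, 5.5 pA at 10 mV) stays many sd above
the noise.  In addition, each sojourn's conductance is drawn
N(g_state, σ_j²) with σ_j = 0.12 nS by default.  This per-sojourn scatter
emulates membrane-to-membrane and insertion-to-insertion variability and
is what gives the closed-state amplitude histogram its observed component
widths; without it, simulated events would cluster orders of magnitude
more tightly than real ones.  Both noise sources come from independent
streams derived from the master seed, so a path can be re-rendered with
different noise; all simulator functions are bit-reproducible given
(preset, protocol, seed).

Multi-channel membranes sum up to 5 independent channels of the same
preset and orientation (auto-directed insertion); a single noise term
applies to the summed current.  `simulate_trace` can prepend a
pre-insertion baseline stretch (`insertion_s`) during which the trace
carries noise only — this is what anchors baseline estimation.

The simulator does **not** model capacitive transients at voltage steps,
1/f or flicker noise, filter roll-off, lipid/salt dependence, antiparallel
insertion, or voltage-dependent dwell times (dwell means are treated as
voltage-independent; no voltage dependence is documented for them).
Passing tests therefore demonstrate correct recovery under idealized
recording statistics, not robustness to every artifact of real rigs.

## Idealization

**Baseline.**  The zero-channel current level is found from the per-sample
apparent conductance I/V over samples with |V| ≥ 5 mV.  A cluster at zero
conductance (|g| ≤ 0.3 nS) holding at least 0.25 s of data is taken as the
baseline and its mean raw current returned (baseline current is
voltage-independent, so the cluster mean converts cleanly to pA).  With no
near-zero cluster, the lowest peak of a 0.1 nS-binned conductance
histogram is used instead and a warning logged; with no usable voltage at
all, the median current is returned, flagged.

**Segmentation.**  Within each constant-voltage region, recursive binary
change-point splitting on means: the candidate split maximizes the CUSUM
statistic √(k(n−k)/n)·|Δmean| and is accepted while the plain mean
difference exceeds a jump threshold (default 4× a robust noise-sd estimate
from median absolute first differences; an epsilon floor makes noise-free
traces split at exact change points).  Runs shorter than the minimum event
duration (default 25 ms = 5 samples at 200 Hz, the shortest run with a
stable mean) are merged into the neighbour with the nearer mean, and
adjacent runs whose means differ by no more than the threshold are
re-joined.  On noise-free traces this recovers the generating change
points to one sample; events shorter than the minimum duration are
missed by construction (~1% of closed sojourns at the native 2.45 s mean;
no missed-event correction is applied).  An `edge_exclude_s` parameter can
drop samples after each voltage step (capacitive artifacts in real
recordings); it defaults to 0 because the simulator produces none.

**Classification.**  An event conductance g matches reference state r when
|g − r| ≤ w·r with w = 0.05 (±5%), boundaries inclusive; among several
matches the smallest relative distance wins (overlap windows need a
deterministic tie-break).  Values matching nothing are INTERMEDIATE;
values more than two windows below the smallest reference are BASELINE.
Classification operates on conductance, not current amplitude — identical
at fixed voltage, and polarity-symmetric via g = ΔI/V.

## Conductance analysis

**Ohm fits.**  Per state, mean event amplitude per voltage is regressed on
V through the origin, weighted by event counts (equivalently, the
per-event through-origin least-squares slope Σ V·ΔI / Σ V²).  The
through-origin form encodes the channel's Ohmic I–V symmetry; a
free-intercept fit is a diagnostic, not the reported number.  The quoted
SEM is the standard error of per-event conductances; events from one
sojourn share a conductance draw, so pooling many insertions is what makes
the estimate converge.  Events at a single voltage fall back to the mean
per-event conductance, flagged.  Fits on fewer than 15 measurements are
reported with a warning.

**Closed-state decomposition.**  Closed (non-S0, non-baseline) event
conductances are binned at 0.05 nS and fitted by sums of Gaussians with
least squares on the binned histogram — the R² quoted is that of the
binned fit.  Stage 1 fits k = 2 over all closed events (upper component
S1, lower S2); stage 2 refits k = 2 inside the 0.80–2.20 nS window (upper
S2A, lower S2B).  Initialization is deterministic and multi-start:
histogram peaks, quantiles, a split of the single-Gaussian solution
(which guarantees R²(k=2) ≥ R²(k=1)), and a grid of candidate positions
for a small second component that peak heights alone would miss; the
lowest-SSE solution wins.  Component weights are normalized areas;
components are reported sorted by descending mean; events are assigned to
the component with the nearest mean in sd units to give occupancy counts.
Both candidate readings of a "mean closed state" are reported: the
single-Gaussian fitted mean and the plain sample mean.  Degenerate samples
(range below one bin) yield a single component with a warning; an
under-populated stage-2 window (< 30 events) skips stage 2 with a warning.
No AIC/BIC model selection is applied — the R² comparison plus a
summary-statistics t-test is the decision apparatus.

Percentages of the open conductance are rounded half-up to integers.

## Dwell-time analysis

Idealized segments are stitched back into sojourns: same-state pieces
separated by a voltage step (different voltage, contiguous in time) are
re-joined; same-state neighbours at the same voltage are kept separate —
the segmenter only cuts where the level genuinely jumped, so such
adjacency means two different states happened to receive the same label.
The first and last sojourn of every trace are censored (true lengths
unknown) and excluded.  Per-state and overall (any state, time to next
switch) means with SEMs are reported; an S2 union aggregates S2A, S2B and
(configurably) INTERMEDIATE sojourns.  Dwells are pooled across voltages
by default.  Durations are sorted before summarizing so results are
exactly invariant to trace order.

Because a sojourn is only observed complete if it fits inside the record,
short recordings bias dwell estimates downward; records several times the
longest mean dwell (hundreds of seconds for the native S0 at 27.4 s) keep
this bias negligible, which is why the dwell analyses here use long
constant-voltage recordings.  Fold-changes between variants are reported
raw and under half-up rounding conventions (integer, nearest ten, one
decimal).  The oxidized V3C-K119C "initial-potential" dwell conflates
waiting-for-reversal with intrinsic kinetics; the simulator reproduces it
only under a protocol that actually reverses the potential.

**Asymmetry detection.**  Closure is judged on conductance, not label: a
segment counts as closed when g < 0.8 × g_open (g_open defaulting to the
median of S0-labelled segments).  The 0.8 cutoff sits between the open
band (per-sojourn scatter keeps open events above ~0.9 g_open) and the
deepest closed state (~0.66 g_open), so open events pushed just outside
the ±5% classification window are not mistaken for closures.  Gating is
asymmetric when one polarity's closed-time fraction is < 0.5% while the
other's exceeds 2% (both configurable; chosen so the presets classify
correctly from ≥ 60 s per polarity); the inferred orientation is the
closing polarity's sign.  Single-polarity data are rejected with an
instruction to record both signs.

## Statistics

All quantities are mean ± SEM with n (SEM = sd/√n, sd with the n−1
denominator).  Two-sample comparisons are computed from summary triplets:
t = (m_a − m_b)/√(sem_a² + sem_b²) with Welch–Satterthwaite degrees of
freedom and a two-sided p from the t distribution.  Welch's form is the
defensible default for the very unequal group sizes and variances these
datasets produce; the pooled-variance Student form is available via a
flag.  Zero-variance degenerate inputs return t = 0, p = 1 for equal
means and p = 0 (flagged) otherwise.  Under the null the test's empirical
type-I error at α = 0.05 calibrates to [0.04, 0.06] over 10⁴ replicates.
No multiple-testing correction is applied (none is part of this analysis).

## Pipeline, formats, determinism

`run_pipeline` composes simulate/ingest → decimate → baseline → segment →
classify → Ohm fits → mixture decomposition → dwell/asymmetry →
comparisons against the native reference summaries, writing `events.csv`,
`report.json`, `dwell.json`, `histogram.csv` and a `run.log`.  All
randomness flows from the single config seed (per-trace seeds are spawned
from it); reports are timestamp-free and serialized with sorted keys, so
identical configs give byte-identical reports.  Report keys carry unit
suffixes (`…_nS`, `…_s`) to prevent unit drift.  Traces are CSV with
`# key=value` headers and full-precision values (bit-exact round trips);
the configuration is a pydantic model that rejects unknown keys and
publishes a JSON schema.

## Problem sizes used in tests and the acceptance script

Simulated recovery runs use 5 kHz acquisition decimated to 200 Hz
throughout.  The conductance target uses 50 traces × 60 s over a
±10…±40 mV step protocol (~300 S0 measurements); the mixture target draws
the closed-state sample at the recorded event counts (386/224/70, σ 0.12
nS); the dwell target uses 20 traces × 1000 s at +40 mV (~1,800 uncensored
sojourns).  The replicated recovery test runs 20 seeded replicates of a
smaller combined design (15 × 60 s steps + 4 × 400 s constant) and asks
for success in ≥ 19 of them; at one of those seeds the sparse S2B
population makes the stage-2 fit collapse onto the dominant component,
which is the expected failure mode at that sample size.

## Known limitations

- Multi-channel records are simulated but the idealizer assigns states as
  if one channel were present; summed conductance levels of k > 1 open
  channels classify as INTERMEDIATE.
- No sub-sample interpolation of transition times and no fast-flicker
  (missed event) correction.
- The amplitude decomposition assumes Gaussian components of a binned
  histogram (matching the original least-squares workflow), not a
  maximum-likelihood mixture; with very tight or very sparse components
  the binned fit's component sd is poorly identified even when the mean is
  recovered.
- Dwell estimates inherit the finite-window selection bias described
  above; use recordings long relative to the slowest state.
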