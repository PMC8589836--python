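# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the package, in the order the pipeline runs.

## Synthetic single-molecule data

No public raw recordings exist for this system, so all inputs are
synthetic, generated with exact ground truth by `motorlab.synth`.  The
generators are first-class, tested code: their defaults define the study
conditions every downstream stage is validated against.

**Photobleaching traces.**  A motor carries `m` dye labels, binomially
drawn from its labelable subunits with the per-subunit labelling
probability (default 1.0 for stoichiometry experiments on active-subunit
labels; 0.66 reproduces the study-condition fit).  Each label bleaches at
an independent exponential time (mean 20 s — a typical cyanine-dye
photobleaching lifetime under TIRF excitation; the donor lifetime is not
a published quantity, so this is the package's choice, fixed once).
Intensity is `m(t) × step amplitude` over a zero baseline with i.i.d.
Gaussian noise per 100-ms frame.  Default trace length 150 s leaves the
probability that a label survives the whole recording below 10⁻³.

**Engagement trajectories.**  Gaps between DNA engagements are drawn
directly from the two-exponential mixture the dwell-time analysis fits
(default 0.8 × 5 s + 0.2 × 40 s, amplitude-weighted mean 12 s, matching an
unimpaired motor).  The mixture components are reported as ground-truth
metadata tagged with their state interpretation (short = engaging-state
burst, long = quiescent state); no explicit hidden two-state process is
simulated, which keeps ground truth exact.  Each engagement's intrinsic
lifetime comes from a three-exponential mixture; since the published
analysis reports only the class thresholds, not fitted lifetimes, the
defaults (weights 0.75/0.15/0.10, lifetimes 0.8/4/25 s) were chosen so
that transient events dominate (~80% of engagements fail) and long-lived
events are terminated mainly by acceptor photobleaching.  The observed
event end is min(intrinsic lifetime, photobleach time ~ Exp(40 s)); events
clipped by the trace end are marked censored.  Generated gaps run from the
previous event's end to the next start, which keeps ground-truth events
exactly non-overlapping; the analysis measures dwell times between
successive event starts, as the experimental analysis does.

**Extension traces.**  Packaging proceeds at the pause-free velocity
(default 960 bp/s, the measured all-active mean), interrupted by pauses
placed as a homogeneous Poisson process in packaged length (default 1.2
per kb) with exponential durations (mean 0.8 s).  A pause is a plateau or,
with probability 0.2, a gradual release of DNA at the unpackaging velocity
(default −300 bp/s, the middle of the observed −100..−500 bp/s range).
Base pairs are converted to nm through the worm-like chain at the trace
force (5 pN) and Gaussian noise (2 nm per sample) is added.  The trap
generator samples at 1 kHz — optical-trap instruments record much faster
than the 100-ms camera; at 100 Hz a 0.1-s velocity window would hold only
two samples.  If an unpackaging pause would release the whole substrate,
the trace is flagged as a failure and generation stops, mirroring tethers
whose DNA slips out.

What the generators deliberately do not emulate: camera/EMCCD noise
statistics beyond additive Gaussian, spectral crosstalk, drift, bead
Brownian-noise spectra, or spatial (image) structure.  Passing tests
therefore demonstrate correctness of the analysis chain under idealised
noise, not robustness to every instrumental artifact of real recordings.

## Photobleaching step counting

Traces can be smoothed with a nonlinear forward–backward filter: banks of
forward (past) and backward (future) running-mean predictors with window
sizes `n·2^i` (defaults n = 4 frames, M = 3 windows), mixed with weights
equal to each predictor's mean squared prediction error over its own
window raised to the power −P (default 20).  In flat regions all
predictors agree; at a step the predictors straddling the edge acquire
large errors and drop out, so edges stay sharp.  The exact predictor/
weight construction is this package's own (the literature describes a
family of such filters); it is documented here and in the code.

Step *counting* operates on the raw trace by default.  Penalized binary
changepoint segmentation (L2 cost; BIC-style penalty `2σ̂² ln N` with σ̂
from the median absolute frame-to-frame difference) is followed by a
coordinate-descent polish of boundary positions and by merging of any
transition that is upward or smaller than `min_amplitude`, leaving a
monotone-decreasing staircase.  Counting on the filter output was tried
and rejected: the filter's residual noise is correlated between frames,
which produces short half-amplitude "shelf" segments at step edges and
systematically corrupts counts.  The filter remains available (and
tested) for visualization and threshold-based idealization.

Two labels bleaching within the same frame window merge into a single
transition of twice the unit amplitude.  Segment levels are therefore
snapped to an integer ladder `baseline + m·a`: the rung count of the top
level is scanned, the unit amplitude `a` refitted by length-weighted least
squares, and a finer ladder is accepted only if it improves the weighted
residual decisively (factor ≈ 3), because a finer ladder always fits at
least as well as a coarser one whose rungs it contains.  The ladder is
anchored on the last long-lived level, since a short terminal segment can
be a noise dip rather than the bleached baseline.  For pooled datasets,
`count_steps_dataset` runs a second pass with the dataset-median unit
amplitude: all traces share one dye, and the global unit resolves ladders
that a single noisy level would otherwise alias (this is the standard
practice of calibrating the single-fluorophore intensity across a field
of view).  Defaults (`min_amplitude` = 0.6 × step amplitude, penalty
factor, minimum segment length 2 frames) were calibrated against the
synthetic ground truth to the ≥95% exact-recovery target at an
amplitude-to-noise ratio of 3.

The binomial stoichiometry fit is zero-truncated by default: motors with
zero labels produce no spot and are unobservable.  The untruncated
likelihood is retained for experiments where unlabelled motors are still
detected through a second channel.  Candidate ring sizes default to
{3..8}; candidates smaller than any observed count get zero likelihood;
ties break toward the smaller ring.  Whether the original distribution
fit was zero-truncated is not recorded; both routes are implemented and
reported.  The known discrepancy between biochemically measured labelling
(~88%) and the fitted efficiency (~66%) is a property of the data, not of
the fit, and is simply reported.

## Coordination model

`composition_pmf`, `predicted_activity` and `fit_kmin` implement the
binomial hetero-pentamer model exactly as stated in the README.  Observed
activities are assumed pre-normalised to the undoped condition, and equal
assembly affinity of active and inactive monomers is assumed (the mutant
binds heads with wild-type affinity).  `predicted_activity` is verified in
the tests against brute-force enumeration over all 2⁵ subunit
configurations to 10⁻¹².  `fit_kmin` breaks ties toward larger `k_min`
(the more coordinated model), needs at least two distinct doping
fractions, and reports the residual sum for every candidate.

## Engagement kinetics

Idealization is threshold-based: baseline and noise are estimated
robustly (seeded on the lowest 30% of frames so that heavily engaged
traces cannot pull the baseline onto the spike level), events are frames
exceeding baseline + 2.5σ for ≥ 2 frames, and single-frame sub-threshold
dips inside events are closed.  The published analysis used an external
statistical idealization model; the threshold procedure here is
deliberately simple, fully documented, and validated against synthetic
ground truth (≥ 90% of events of ≥ 2 frames recovered with ≤ 1-frame
boundary error at the default signal-to-noise of 5).  Events shorter than
two frames (0.2 s) are below the detection resolution by construction.

Lifetime classes partition [0, ∞) as [0, 2) s transient, [2, 10] s
semi-transient, (10, ∞) s long-lived; the published wording ("<2 s",
"between 2 and 10 s", ">10 s") leaves the boundary values ambiguous, and
both are assigned to the middle class here.

Exponential mixtures are fitted by maximum likelihood with right
censoring handled through survival terms, L-BFGS-B over log-lifetimes and
weight logits from deterministic quantile-scaled starts, and BIC model
order selection (2m − 1 parameters for m components).  τ_avg is the
amplitude-weighted mean over the fitted components, weights normalized
over those components only.  A least-squares fit to the empirical
survival curve is provided as an independent cross-check of the
likelihood route; the two agree within 10% on single-exponential data in
the tests.  Gap times are measured start-to-start; events censored by the
trace end are excluded from lifetime fits but enter gap fits up to the
censoring point.

## Optical-trap analysis

The extensible worm-like chain uses the high-force interpolation
x/L₀ = 1 − ½√(k_BT/(F·L_p)) + F/K with L_p = 50 nm, K = 1000 pN,
0.34 nm/bp and k_BT = 4.11 pN·nm (≈23 °C; configurable).  The published
contour length "1156 bp" is read as 1156 nm = 3400 bp × 0.34 nm/bp — the
printed unit is taken as a typo.  `bp_from_extension` is the exact
algebraic inverse of the forward map at fixed force.  Tether screening
fits a constant extension offset by least squares and rejects offsets
outside [−100, 50] nm or residuals whose extremum/variance exceed global
thresholds (defaults 15 nm and 25 nm², about 5σ of the 2-nm measurement
noise).

Velocity is the OLS slope over a centred running 0.1-s window, packaging
positive.  The variance-based pause threshold is made concrete as
max(v_floor, min(median(v) − c·MAD(v), 0.4·median(v))) with defaults
c = 5 and v_floor = 50 bp/s.  The 0.4-band cap keeps the threshold well
below the packaging band on quiet traces: the running window can depress
a sub-0.1-s interruption only to about half speed, and such interruptions
must not be flagged under the > 0.1-s pause rule.  Maximal runs below
threshold and longer than 0.1 s are pauses; runs separated by less than
0.1 s (window-smeared crossings of an unpackaging excursion) are merged
first.  Pauses classify as plateau (|v| within 50 bp/s) or unpackaging
(clearly negative mean velocity).

Per-trace metrics follow the excise-and-catenate convention: the pause
intervals are removed and the remaining packaging intervals catenated.
The pause-free velocity is summed displacement over summed time of the
catenated intervals, with a half-window guard margin trimmed around each
pause — those frames mix paused and packaging motion through the rolling
window and would bias the estimate low by ~5%.  Pause frequency divides
the pause count by the total packaged length (no margin, so transition
displacement is not lost).  The start time is the first sustained
(> 0.1 s) above-threshold run, minus the supplied buffer-entry time.
Residual bias of the velocity estimate on synthetic traces is about −1%,
from genuine sub-0.1-s interruptions that the > 0.1-s rule deliberately
leaves inside packaging intervals.

## Kinetic Monte Carlo packaging model

Each event is either a 2-bp packaging step or a pause&slip: a uniform
random number against p_pause&slip decides, the slip length is
exponential with mean 0.5 bp, and the waiting time is exponential with
mean 10 (packaging) or 2 (pause&slip) arbitrary units.  Success is
unpackaged length ≤ 0; failure is unpackaged length ≥ 3400 bp (the
30–40 bp pre-packaged prevent immediate slip-out).  Mean velocities are
computed over successful trajectories as initial unpackaged length over
completion time — the convention implied by defining success through
complete encapsidation — and only velocity *ratios* are meaningful, since
time units are arbitrary.

Two representations of inactive subunits exist, and the distinction
matters:

* `grip_model="aggregate"` (used for the headline condition table): the
  per-event probabilities encode the composition — p_pause&slip = 0.65
  for an all-active motor and 0.75 for motors with 1 or 2 inactive
  subunits, the published tuning.  Per-event drift is then +0.375 bp
  (0 inactive) vs +0.125 bp (1–2 inactive), mean event times 4.8 vs 4.0,
  and the asymptotic velocity ratio is 2.5, at the upper edge of the
  published "~2-fold" comparison.
* `grip_model="per_subunit"`: an explicit grip pointer rotates around the
  ring (by default after every event; advancing only on packaging events
  is available) and an inactive subunit at the strongest-grip position
  forces a pause&slip.  Applying this rule *on top of* the elevated
  p_pause&slip double-counts inactivity: the drift is exactly 0 at one
  inactive subunit and negative at two, so completed trajectories arise
  only as rare fluctuations.  This regime is real and tested (the drift
  closed form covers it), but it cannot reproduce the published ~2-fold
  velocity ratio, which is why the aggregate rule backs the condition
  table while the per-subunit rule backs the structural contracts: a
  fully inactive motor never packages, and the strict-arrest scheme
  (permanent arrest at the first inactive grip, the behaviour expected of
  a strictly coordinated motor) never succeeds with any inactive subunit.

Slip lengths are continuous-exponential by default; the source material
describes them both as "Poisson-distributed" and as "chosen from the
exponential distribution", and the exponential reading is implemented,
with rounding to integer base pairs as an option.  Inactive subunits are
placed randomly on the ring per motor (adjacency is not specified
anywhere; it matters only for two inactive subunits under the pointer
rule).  The event cap (10⁶ per trajectory) bounds runtime in the
zero-drift regime; capped trajectories are reported as censored, never as
successes.  The batch simulator draws events in vectorized chunks and is
exact in distribution for the every-event pointer policy, whose pointer
sequence is deterministic given its random start.

## Problem sizes and numerical conventions

Test and acceptance runs use the study-scale sizes: 486 traces per
stoichiometry dataset and 100 replicate datasets, 1000 traces for step
counting, 2000 dwell times for mixture fits, 100–200 trap traces spanning
100–2000 bp/s, and ≥500 (4000 in the acceptance script) successful
trajectories per kinetic Monte Carlo condition.  Optimizer tolerances are
scipy defaults; mixture fits use three deterministic starts; ties in
model selection break toward the simpler model except for k_min (toward
more coordination) as noted.  All generators and simulators are
bit-reproducible for a fixed seed.

## Known limitations

* Step counting assumes a common unit step amplitude per trace (one dye
  species) and a fully bleached baseline by the end of the recording;
  two labels bleaching within a single frame on a two-label motor are
  fundamentally unresolvable and are counted as one.
* The engagement idealizer cannot distinguish a permanently engaged
  (saturated) trace from a quiet trace at a shifted baseline without an
  externally supplied baseline level.
* The dwell-time convention (start-to-start) folds the previous event's
  lifetime into the gap; with the default kinetics this inflates the
  mean gap by ~20% relative to the end-to-start generation convention,
  and matters only when comparing against the generator's gap mixture
  directly.
* The kinetic Monte Carlo model has no force or ATP dependence and no
  mapping from arbitrary time units to seconds; only ratios between
  conditions are interpretable.
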