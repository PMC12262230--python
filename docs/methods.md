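# Methods

`scvigor` re-implements, as a tested pipeline, an analysis of how reward
value modulates the neuronal subtypes of the superior colliculus (SC)
and, through them, saccadic vigor. Because the primate recordings the
analysis was designed for are not publicly deposited, the package ships
a synthetic-session generator that emulates their statistical structure;
every downstream stage is validated by recovering the generator's ground
truth. This note documents the models, the estimators, the numerical
choices, and what the synthetic validation does and does not establish.

## Task and data model

A session consists of ~99 completed visually guided saccade trials (56
to high-value "good" fractal objects, 43 to low-value "bad" objects, the
observed session averages), a 1 kHz binocular-average eye-position
trace, and spike trains from units recorded simultaneously on one
penetration. Trials present a fixation point for 300 ms, then a target
at the session's receptive-field eccentricity (4–25 deg); the saccade
follows at the reaction time (RT), with gaze held 500 ms after landing.

On disk a session is plain text: `manifest.json`, `trials.csv`,
`spikes.csv`, `eye.csv`, plus `truth.json` for synthetic sessions
(ground-truth subtype labels, per-unit couplings, behavioral draws, and
the full generator configuration — the template shapes are generator
constructs, not measurements, and the file says so).

## Saccade kinematics

Saccade onset/offset are the up/down crossings of the radial eye speed
through 30 deg/s; events whose peak speed exceeds 700 deg/s are flagged
as blink artifacts; a landing farther than 8 deg from the target center
invalidates the trial; the trial saccade is the first event with RT in
[50, 600] ms.

Differentiating a 1 kHz video-oculography trace is the precision
bottleneck. We estimate velocity with a Savitzky–Golay filter (window
25 ms, polynomial order 5) applied per component. Order 5 reproduces
the quintic minimum-jerk displacement exactly — so the estimator has
zero systematic bias on ideal saccades of any amplitude — while the
25 ms window suppresses differentiation noise enough for
millisecond-scale onsets. Peak velocity (PV) is read from a parabola
fitted around the speed maximum (window ±18% of the event duration),
which removes the upward bias that a raw max over noisy samples incurs.
Above-threshold runs shorter than 8 ms are discarded as noise. A
numerical calibration against analytic minimum-jerk saccades fixed
these constants: with 0.01 deg positional noise (high-end tracker
precision, the generator default), onset is recovered within ±2 ms and
PV within 1% on ≥99% of trials over the 4–25 deg amplitude range. With
noise of 0.05 deg no local polynomial differentiator reaches 1% PV
accuracy at 1 kHz for 20 ms saccades — the information is simply not in
the trace — which is why the generator's noise default sits at the
tracker-precision end of the realistic range.

Duration-normalized profiles re-estimate the radial displacement by
cubic-spline interpolation at 20 equally spaced fractions (5%…100%) of
the saccade duration and differentiate the same spline for the velocity
profile, so velocities and displacements stay mutually consistent.

## Spike tools

Spike-density functions (SDFs) convolve each spike with a unit-mass
Gaussian kernel of SD 10 ms ("bandwidth" read as the SD, the common
convention in this literature). Kernels are evaluated to ±6 SD on a
span padded by the same amount and cropped, so a trial's SDF integral
equals its interior spike count to better than 1e-6. Window firing
rates use half-open windows [start, end) on a 0-based millisecond grid
to avoid double counting at shared edges. A unit enters the analysis
only with ≥5 valid trials per condition and strictly more than 20
spikes in the −300…+400 ms target-aligned span (the span is our
operationalization; the rule itself follows the recorded study).

## Functional classification

Per-trial rates in five canonical windows — baseline (−200…0 ms),
phasic #1 (0…80 ms), phasic #2 (80…160 ms) target-aligned; pre-saccadic
(−100…−50 ms) and peri-saccadic (−50…+20 ms) saccade-aligned — feed a
Kruskal–Wallis omnibus screen (p ≥ 0.05 ⇒ no task response) followed by
directional Mann–Whitney contrasts, all at α = 0.05 without multiplicity
correction (single-α criteria throughout, as in the source study):

* **visual** — both phasic windows above baseline, no pre/peri contrast;
* **visuomotor** — both phasic windows above baseline *and* a pre/peri
  contrast;
* **motor** — pre/peri contrast and phasic #1 below phasic #2;
* **tonic** — phasic #1 or #2 significantly *below* baseline.

Two resolution rules make the overlapping definitions deterministic.
A unit meeting the visual criteria is visuomotor iff its pre/peri
contrast is significant. And the excitatory gates run before the tonic
gate: rank tests on short low-count windows carry a small
distribution-shape bias toward "reduction" even at equal means (an
80 ms Poisson-count window and a 200 ms one with the same mean rate
have different discreteness), and a unit with a genuine phasic increase
should never land in the suppressed class. The motor and tonic gates
cannot both fire in practice, since motor requires phasic #1 < #2 and
suppression implies the opposite.

On 200 synthetic units at default gains the labels agree with ground
truth for ≥90% (typically 93–97%); the residual confusions are
visual→visuomotor (the value gain engages at 95 ms, inside the
pre-saccadic window of short-RT trials, creating a genuine small
pre/peri contrast in pure visual units) and tonic→unclassified at low
suppression power.

## Value modulation

Three per-unit statistics quantify good-vs-bad firing:

* **Signed-rank comparison** of per-trial rates in the 80–240 ms
  window. The comparison is paired at the trial level: the longer
  condition is subsampled deterministically (evenly spaced in trial
  order) to the shorter one. An object-level pairing (4 good vs 4 bad
  object means) cannot reach significance — the exact two-sided
  signed-rank floor at n = 4 is 0.125 — so trial-level pairing is the
  only version of the test that can express the effect; object
  identities are still carried in the data.
* **Value index** — mean good minus mean bad rate, 80–160 ms.
* **AUROC** of good vs bad rates (80–160 ms), computed from ranks
  (exactly U/(n₁n₂), ties half-credit), with a label-permutation test
  (default 1000 shuffles) for significance. Internally good is the
  positive class; the published plotting convention is mirrored
  (values below 0.5 = positive modulation), so reporting layers emit
  1 − AUROC behind a flag.

**Modulation onset** is the first time the good−bad SDF difference
exceeds its baseline (−300…0 ms) mean + 3 SD continuously for 20 ms,
searched within 80–250 ms post-target; negative-sign onsets apply the
same rule to the negated difference. Two properties of this detector
shaped the search window. First, the threshold is estimated from the
*baseline*, where rates are low; during the response, Poisson
variability scales with the rate, so the effective threshold shrinks in
σ units wherever the trace is elevated — at the early visual transient
(the highest-rate epoch, and value-agnostic anyway) false crossings
concentrate. Second, beyond ~250 ms the difference trace picks up
movement-locked lobes because the two conditions have different RT
distributions; those are saccade-timing effects, not value signals.
With the 80–250 ms window, false-onset rates on value-free synthetic
units are ~5–10%, and the median detected onset on default units is
~98 ms against an engagement latency of 95 ms.

## Pseudo-population bootstrap

Trials are split into RT tertiles (stable sort, earlier tertiles take
the remainder; per session). One pseudo-trial of a tertile is the mean
of single-trial SDFs from 25 units drawn uniformly with replacement,
one uniformly drawn trial of that tertile per unit; 25 pseudo-trials
are averaged; per-epoch extrema (argmax, or argmin for tonic units;
first sample on exact ties) are taken from the average; the whole
procedure repeats (10000 by default; 1000 in tests and the acceptance
script — the CIs stabilize well before that) and the summary reports
the mean and the 2.5/97.5 percentile interval of extremum time and rate
per (tertile, epoch, alignment), optionally per value condition.

Epochs: early visual E_VIS 30–80 ms and late visual L_VIS 80–130 ms
target-aligned; pre-saccadic PRE_SAC beyond 130 ms target-aligned (its
upper bound is 130 ms plus the long tertile's median RT, to keep
post-saccadic activity out of an otherwise open-ended window) and
−40…0 ms saccade-aligned. Extrema are extracted per repeat, not from
the grand mean — that is what gives the percentile intervals their
meaning.

The logic the bootstrap tests: target-locked components have
tertile-invariant peak times under target alignment; saccade-locked
components have tertile-invariant peaks only under saccade alignment.
On synthetic populations the recovered pattern matches construction:
E_VIS peaks at ~42 ms in all tertiles; target-aligned PRE_SAC peaks
order short < medium < long; saccade-aligned PRE_SAC peaks sit at
−11 ± 3 ms; tonic troughs lock to −33 ms saccade-aligned while ordering
with RT target-aligned; and the value gain separates good/bad rate CIs
in L_VIS and PRE_SAC but not E_VIS.

## Neuron–behavior indices

Per unit, the RT index and PV index are Pearson correlations between
the 80–160 ms target-aligned rate and the trial's RT or PV, over trials
with ≥5 spikes in the window and requiring ≥15 surviving trials (good
and bad trials pooled). Constant inputs raise an explicit
undefined-correlation error rather than returning 0. Across units of a
subtype, the value index correlates negatively with the RT index and
positively with the PV index — more value-modulated neurons push
behavior harder — and the eight-cell overlap table (reward/RT/PV
significance) partitions each subtype exactly.

## The synthetic generator

Each trial draws RT from a condition-specific truncated normal
(good 186 ± 25 ms, bad 211 ± 36 ms, floor 140 ms — the floor plays the
role of the anticipatory-saccade bound). The drawn RT is defined as the
30 deg/s threshold-crossing time; the minimum-jerk movement starts
earlier by the analytic crossing lag, so detector and generator agree
on what "RT" means. Amplitude is the session eccentricity with 3%
motor jitter; PV follows a saturating main sequence
`PV = vmax (1 − exp(−A/9 deg))` with a 5% good-trial bonus and 3%
noise. The main sequence saturates at 620 deg/s so that no clean
saccade crosses the 700 deg/s blink-artifact threshold — with the
published artifact rule, a generator whose PVs matched the published
~740 deg/s means would reject its own large saccades, so the synthetic
PV scale sits below the recorded one by design. The eye trace is the
minimum-jerk displacement plus 0.01 deg Gaussian noise, with a return
saccade in each inter-trial interval.

Firing rates are additive templates per subtype (all shapes generator
constructs): a Gaussian visual transient (peak 42 ms, SD 12 ms); a late
visual bump-plateau (peak 106 ms — 110 ms for motor units — settling to
a plateau fraction that holds until 50 ms after saccade onset, then
decays); a saccade-locked Gaussian burst peaking 11 ms before onset
(SD 10 ms); and for tonic units a suppression that deepens from ~50 ms
post-target to a trough exactly 33 ms before saccade onset and recovers
with SD 25 ms. Defaults: visual 17 Hz baseline + 35 transient +
10 late; visuomotor 15 + 40 + 28 late + 50 burst; motor 15 baseline +
20 late + 55 burst and *no* transient; tonic 22 Hz suppressed by 10.
Spikes are drawn by exact thinning against the per-trial rate envelope
on a 1 ms grid.

Value and behavior couple through three mechanisms:

* **Value gain** (default 3.0) multiplies the late and motor components
  of good trials after a smooth engagement step at 95 ms (8 ms rise).
  Per-unit susceptibility c_u ~ U(0.25, 1.75) scales the effective gain
  (1 + c_u (g_v − 1)), giving the across-unit heterogeneity that the
  index correlations need. Tonic units split half/half into positively
  and negatively modulated (suppression divided or multiplied by the
  gain).
* **A shared per-trial latent gain** g ~ N(1, 0.5) multiplies the motor
  component (scaled by c_u) and shifts RT by −0.8 (g−1) SD_RT and PV by
  +0.08 (g−1) — a premotor-excitability fluctuation that makes strong
  bursts fast, vigorous saccades. Restricting the latent to the motor
  component keeps pure visual units free of shared condition-mean
  offsets, which would otherwise corrupt the onset detector's
  false-positive behavior; the cost is that synthetic visual units
  carry no rate–RT correlation (the recorded study reports a modest
  one), so the behavior-link result is carried by the visuomotor and
  motor populations.
* **Per-trial, per-unit excitability** (lognormal, CV 0.15) multiplies
  the whole rate, giving realistic super-Poisson count variability.

Defaults were fixed by measuring the pipeline's own recovery invariants
(classification agreement, onset detection and false-positive rates,
epoch timing, index-correlation signs) across candidate settings; the
gains are deliberately at the "clearly modulated exemplar" end —
population-mean effect sizes as small as the published ones (e.g. 27
vs 22 Hz sustained) are undetectable per unit at 56 + 43 trials with a
mean + 3 SD rule, so a generator meant to exercise per-unit statistics
must be louder than the published population averages.

## What the synthetic validation shows — and what it cannot

Passing tests establish that every estimator does what it claims on
data whose ground truth is known, at realistic rates, trial counts and
noise levels, and that the full pipeline is deterministic under a seed.
They do not establish that real SC data satisfy the generator's
assumptions: real units are not Poisson, templates are not shared
within a subtype, value effects are weaker and more heterogeneous,
eye-tracker artifacts (blinks, dropouts) are richer than a speed
threshold, and the motor template's lack of a visual transient means
the generator cannot reproduce the recorded motor-population E_VIS/
L_VIS peak invariance (short-RT trials push the burst's rising edge
into the 80–130 ms window, pinning its argmax to the window edge).
Those epoch checks are therefore asserted on the subtypes whose
templates genuinely carry the relevant component.

## Numerical and degenerate-input conventions

Exact ties in epoch extrema resolve to the first sample. Zero-variance
baselines in the onset detector yield "absent", never a division
error. Rank tests on fully degenerate (zero-range) inputs count as no
evidence (p = 1). The permutation p-value uses the add-one estimator
(k+1)/(n+1). All randomness flows from `numpy.random.default_rng`
seeds carried in the configuration objects; reruns are byte-identical,
including CSV formatting (fixed float formats, 0.1 ms time precision).
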