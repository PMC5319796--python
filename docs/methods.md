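# Methods

This note documents the models implemented in `oriturn`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that pin down otherwise ambiguous
behaviour.

## FRAP

**Model.** Recovery of a bleached region is fitted with the single-state
exchange model `f(t) = A(1 − e^(−k_r t))` on post-bleach points only, with
t = 0 at the first post-bleach frame.  The half-time is `t½ = ln2/k_r`
(enforced exactly in the result record).  This form assumes
binding-dominated exchange with one effective rate; pure-diffusion and
two-state reaction–diffusion recovery models are out of scope.

**Normalization.** *Single* normalization divides the background-subtracted
ROI by a background-subtracted unbleached control cell (removing
acquisition bleaching) and then by the trace's own pre-bleach mean.
Whether the control channel should also be background-subtracted is
ambiguous in common practice; the symmetric choice (subtract from both) is
the default and is configurable.  *Double* normalization divides by the
whole-cell intensity of the bleached cell instead, which also cancels the
bleach pulse; the recovery level A of a double-normalized fit is then the
mobile fraction and 1 − A (clamped to [0, 1]) the fraction of molecules
that do not exchange on the experiment's timescale.  The immobile fraction
is only reported from double-normalized fits.

**Clustering.** Traces are sorted by pre-bleach intensity and grouped into
consecutive clusters of three ("similar intensities" operationalized as
adjacency after sorting — the natural deterministic reading).  A remainder
group of ≥ 2 traces is kept, a singleton is dropped with a log entry.
Each trace is full-scale normalized, `(v − min_post)/(pre_mean − min_post)`,
before pointwise averaging, so different bleach depths map onto a common
[0, 1] recovery scale.  Under noise the post-bleach *minimum* sits a few
noise sd below the true bleach floor; this biases fitted half-times
downward by ~5% at noise sd 0.03 — visible in the parameter-recovery suite
and accepted as the price of the pinned-down formula.

**Fitting.** Nonlinear least squares (lmfit/Levenberg–Marquardt) with
data-driven initialization: A₀ = mean of the last quartile of post-bleach
values, k_r⁰ = ln2 / (time of first crossing of A₀/2 by linear
interpolation).  A ≥ 0 and k_r > 0 are enforced as bounds; hitting a bound
logs a warning.  Group comparison uses the pooled-variance Student's
t-test (two-sided) to match the conventional naming; Welch's form is
available behind a flag.  Half-time means and SEMs are computed over
clusters (the unit that is fitted), not over cells.

**Bleach-frame detection.** The first post-bleach frame is the one after
the largest single-frame fractional drop of the ROI channel, overridable
(`--bleach-index`, metadata line, or function argument).

## Single-molecule tracking

**Step-size mixture.** Per-axis frame-to-frame displacements (x and y
pooled as independent draws; pairs spanning a frame gap excluded) are
fitted by maximum likelihood with a mixture of zero-mean normal densities,
variance σᵢ² = 2 dᵢ Δt per component.  The zero-mean constraint reflects
unbiased Brownian steps; because no stock mixture implementation fixes the
means at zero with free variances, the EM iteration is implemented here
directly (log-space responsibilities, variance floor 1e-12, 10 seeded
restarts, best likelihood kept — so permuting initializations cannot
change the result).  Components are always reported ascending in d;
weights are the population fractions ("areas under the curves").  The fit
uses raw step values, not binned histograms: binning would add a bin-width
parameter that affects nothing but plots (plots use 50 nm bins).  Model
order is assessed with BIC (free parameters 2k − 1 for order k);
on two-population data a third component adds no BIC improvement.
Per-dataset fits are the default; the variance-sharing joint fit across
datasets is intentionally not implemented until a use case pins down its
weighting.

**MSD.** Per-track time-averaged MSD uses all ordered pairs at exact frame
spacing (gap-aware).  The ensemble curve is the pair-count-weighted mean
over tracks, and a straight line through the origin is fitted to the first
4 lags, each lag weighted by its total pair count; D* = slope/4.  Four
lags is all that photobleaching-limited tracks (mean ~6 frames) can
support.  The origin constraint assumes no localization-error offset; an
intercept can be added when localization error is significant.  SEM is a
200-resample bootstrap over tracks.  Note that D* from the whole data set
is a population average and deliberately not reconciled with the
mobile-component d of the mixture fit; with a 20/80 static/mobile mixture
D* lands between the components.

**Static intervals (residence times).**  A trapping event is a maximal run
of consecutive frames (gaps break runs — a gap hides unobserved motion)
whose points all lie within radius r = 0.23 µm of an anchor, where the
anchor is a trajectory point, not a centroid.  Every point is a candidate
anchor; maximal runs shorter than 3 frames are discarded; the final
decomposition picks non-overlapping intervals greedily by decreasing
length (ties: earlier start, then earlier anchor index) — a deterministic,
order-independent rule that reproduces hand-traceable cases.  Durations
are (frames × Δt), reported in ms.  The ≥ 3-frame threshold truncates the
dwell distribution; for memoryless (geometric) dwells the truncation
shifts the mean by exactly (min_frames − 1) frames, and
`truncation_corrected_mean_ms` undoes that shift.  Track-end censoring and
photobleaching are *not* corrected: reported residence times underestimate
true dwell times.

**KS comparison.** Dwell CDFs are compared with the two-sample
Kolmogorov–Smirnov test.  Because durations are frame-quantized the
samples are heavily tied and the continuous-null p-values are
conservative: null rejection at α = 0.05 runs at ~2%, never above
nominal.  Below n = 5 per group a warning flags the asymptotic p as
unreliable.

**False-positive model.** A free molecule with diffusion coefficient D
stays within r_max in one frame with probability
p = 1 − e^(−r_max²/(4DΔt)) (p = 1 at D = 0).  The probability that a track
of n frames contains ≥ 3 consecutive static frames is evaluated as the
combinatorial sum Σ_{r≥3} C(n−2, n−r) pʳ(1−p)ⁿ⁻ʳ (log-space terms, stable
to n = 10⁴; generalized min_run replaces n−2 by n−min_run+1).  The sum has
the closed form p^(m−1)(1 − (1−p)^(n−m+1)), used as an independent oracle
in the tests.  Against exhaustive enumeration of Bernoulli strings the
grouping is exact for n ≤ 4 and an undercount for n ≥ 5 (overlapping runs
are merged); it also saturates at p^(m−1) for long tracks while the true
run probability tends to 1 — so the model is only meaningful for the short
tracks photobleaching actually produces.  The expected false-positive rate
is the mean of this probability over the empirical track-length
distribution, with the dataset's mobile-component d as the natural choice
of D; both inputs are exposed rather than fixed.  A Monte-Carlo mode
cross-checks the analytic value: the default `moving` detector classifies
each simulated jump as static when its radial displacement is below r_max
(the moving-circle relaxation the analytic model assumes) and agrees with
the analytic rate to within ~2 percentage points on short fixed-length
tracks, sitting slightly *below* it (the grouping spends one more trial
than the track has jumps).  The `anchored` detector applies the real
fixed-anchor interval finder; because it unions over every candidate
anchor it flags several-fold more free tracks — a genuine property of the
detector that the analytic model does not capture, worth knowing when
quoting analytic false-positive rates.

**Heat maps.** Each time point deposits a unit-amplitude Gaussian bell
(sd 80 nm) on a damped copy (factor 0.8) of the previous temperature
field; the map is the pointwise maximum over time, so a molecule resting k
frames reaches (1 − 0.8ᵏ)/0.2 while a fast crossing stays near 1.  Grid
spacing 20 nm, field padded by 3 bell sd and aligned so the first track
point falls on a node (which makes the geometric-series peak exact).  All
three parameters are invented defaults exposed on the CLI.

## Oscillation

Region intensities are divided framewise by the whole-cell channel — this
cancels any multiplicative decay common to all channels (acquisition
bleaching) exactly — and compared by Pearson correlation (Spearman behind
a flag).  No detrending beyond that normalization is applied.  Exchanging
the two regions leaves r unchanged; complementary noiseless signals give
r = −1 exactly.  A period estimate (twice the lag of the first
autocorrelation minimum) is provided as an exploratory extra only.

## Synthetic-data generators

All simulators draw from a private `numpy` generator seeded through
`SimulationConfig`; identical configuration and seed give bit-identical
output files.  Defaults mirror the acquisition they emulate: Δt = 41 ms
(24.5 Hz streams; 4 ms for the fast regime), track lengths geometric with
configurable mean (photobleaching gives constant per-frame survival, hence
geometric lifetimes) and minimum 2 frames, localization error 0 by default
since no value is pinned down experimentally.

*Tracks*: per-axis displacements N(0, 2DΔt) with the component assigned
per molecule by weight, or, with switching enabled, a two-state
(static/mobile) chain whose per-frame switch probability Δt/mean gives
geometric dwells with exactly the configured mean dwell time; state
occupancy then follows the dwell ratio and the component weights are
ignored.  No cell-boundary confinement is applied: confinement distorts
the MSD only at lags longer than the ≤ 4 used here, and adding it would
entangle the generator with geometry parameters the analyses never see.

*FRAP traces*: pre-bleach plateau 1, instantaneous drop by `bleach_depth`
at the bleach frame (diffusion during the bleach pulse ignored), recovery
of the mobile share as `mobile_level(1 − e^(−k_r t))`, multiplicative
acquisition-bleach decay on all channels, conserved whole-cell channel,
additive Gaussian noise per measured channel.  Noise magnitudes are
placeholders (no reference values exist) and fully configurable.

*Oscillation traces*: complementary sinusoids of configurable period
(default 2 s, the seconds-scale regime of interest) and amplitude around a
conserved total, with independent noise on each region channel.  The
whole-cell channel is generated noiseless: it integrates over many more
pixels than either region, and a noisy shared denominator would induce a
spurious positive correlation (~+0.2 at the default noise) between the
normalized series that the analysis cannot distinguish from biology.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: localization error is off by default; there is
no detection/linking noise (misconnections, missed frames other than
explicit gaps), no cell geometry or confinement, no intensity-dependent
(shot) noise, no photophysics beyond geometric track lengths (no blinking)
and no photobleaching of *bound* molecules during a dwell.  Parameter
recovery on these synthetic data validates the estimators' correctness,
not their robustness to every instrumental artifact.

## Problem sizes

The recovery suites use 30–32 FRAP traces of ~500 frames, 1,000–2,400
tracks (≥ 20,000 pooled steps) for the mixture and MSD checks, ~1,500
two-state tracks for the residence check, and 10⁵ Monte-Carlo tracks for
the false-positive cross-check — sizes chosen to hold the sampling error
of each recovered quantity comfortably inside the tolerance being
asserted while keeping the full suite at a few CPU-minutes.
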