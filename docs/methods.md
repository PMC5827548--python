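# Methods

## The experiment being modelled

A backward-masked visual detection task under continuous 10-Hz electrical
stimulation of the parieto-occipital cortex. Defaults throughout encode
this design: three blocks of 128 trials per condition, two conditions
(sham, otCS) performed in counterbalanced order by 36 participants, 20%
target-absent catch trials, eight fixation-to-target SOAs
{200, 225, 266.66, 283.33, 300, 341.66, 374.99, 408.33} ms, an 8.33-ms
target with a 41.7-ms target-to-mask SOA, a 1000-ms response window, and
2.5-ms stimulation pulses every 100 ms. The analysis variable is the
pulse-to-target SOA, `(target_onset − pulse_phase0) mod 100` on the
half-open interval `[0, 100)` ms — a target coincident with a pulse has
SOA 0.

Two scheduling details are under-determined by the design description and
fixed here as package conventions: the pulse train is phase-locked to
block onset (the alternative — re-alignment per trial — would make the SOA
distribution degenerate), and catch-trial counts are fixed per block at
`round(0.2 × 128) = 26` rather than drawn per trial, which stabilises
detection-rate denominators. Fixation-to-target SOAs are sampled uniformly
with replacement. Under these conventions the accumulated trial durations
spread the pulse-to-target SOAs over all ten phase bins (a scheduler
property the test suite asserts).

## Staircase

The luminance staircase is a transformed up-down rule: one hit lowers
luminance by `step_down`, three *consecutive* misses raise it by
`step_up`; catch and no-response trials never touch it. The
consecutive-miss counter is a three-state Markov chain, giving an up-step
rate of q³/(1+q+q²) per trial at miss probability q. Balancing expected
drift at p = 0.5 yields `step_up/step_down = 7` exactly; that ratio ships
as the default, and `equilibrium_hit_rate()` exposes the analytic map from
any ratio to its stationary hit rate (assuming steps small relative to the
psychometric spread — the regime the defaults sit in).
`examples/staircase_calibration.py` verifies the analysis by simulation.
No fixed-step equal-step rule targets 0.5, so the step sizes and ratio are
explicit configuration, not hidden constants. Converged luminance is read
out either as the mean of the last *k* reversal levels or as the mean
level over a trailing trial window (the rule used by the cohort
simulator: the mean over the final staircased block).

## Generative observers

A participant is a lapse-scaled logistic in luminance on the log-odds
scale:

logit(p_hit) = slope·(L − threshold) + A·sin(2π·SOA/100 + φ) +
fatigue_slope·trial + offset·1[second condition],  p_hit scaled by (1 − lapse)

* `threshold` ~ N(0.5, 0.05) per participant (luminance in arbitrary
  units on [0, 1]), `slope` 10 per unit, `lapse` 0.02.
* Entrainment enters on log-odds, so probabilities stay in (0, 1) for any
  amplitude A; sham always has A = 0. The entrainment phase φ is drawn
  uniformly per participant — no mechanism makes participants share one.
* `fatigue_slope` −0.004 log-odds/trial loses roughly ten percentage
  points across a 128-trial block, matching the size of within-block
  declines such tasks show.
* `condition_offset` 0.2 log-odds (~5 points) in the second-performed
  condition reproduces a realistic practice/sequence effect.
* Catch trials produce false alarms at `guess_fa` = 0.05; 2% of trials
  carry no valid response, independent of the stimulus.
* Luminance is fixed per participant at the level a simulated
  pre-session staircase (two blocks) settles on, so cohorts sit near 50%
  detection like the staircased task they emulate.

What the simulator does *not* emulate: serial dependence between trials,
criterion shifts, non-stationary lapse, real EEG physiology, or any
coupling between stimulation and the observer other than the imposed
sinusoid. Passing operating-characteristic tests therefore certify the
*analysis pipeline* — its calibration and sensitivity under a faithful
generative null and alternative — not claims about real cortical
entrainment.

## Binning and normalization

Detection rate per bin is hits/(hits+misses) over included trials (no
catch, valid response), separately per participant × condition; empty bins
propagate as missing. "Normalization" is implemented as the z-score
across the ten bins within participant × condition (sample SD); a
mean-centering mode is provided since plain centering is the other common
reading. Z-scoring removes all participant × condition mean differences,
which is exactly why it eliminates sequence effects from the mixed ANOVA
while leaving phase structure intact. Time-course bins group 32
consecutive presentation positions (12 bins across three blocks);
exclusions reduce a bin's numerator and denominator but never shift later
trials between bins.

## Sinusoidal model

x(t) = α₀ + α₁ sin(ωt + φ) is fit to the ten standardized rates at the bin
centers t = 5, 15, …, 95 ms with ω fixed. The printed frequency
specification in the source design ("0.06 bins/cycle (100 Hz)") is
internally inconsistent; this package fixes ω = 2π/100 rad·ms⁻¹ ≈ 0.0628 —
one cycle per 100-ms stimulation period, i.e. the 10-Hz pulse rate, which
matches both the printed 0.06 and the logic of the experiment. ω is a
parameter, not a constant, for anyone who wants the other reading.

The estimator of record is bounded nonlinear least squares (α₁ ≥ 0, φ ∈
[−π, π], wrapped to (−π, π] afterwards) from 50 random starts (α₀ near the
data mean, α₁ ~ U(0, 2·SD), φ ~ U(−π, π), seed-controlled). Because ω is
fixed the problem is linear in (α₀, a, b) with a·sin + b·cos, so the exact
global optimum is also available in closed form (`method="analytic"`); the
suite asserts the two agree to 1e-8 and that both beat a 51³ brute-force
grid. The bulk simulation paths use the analytic solver. Conventions: the
amplitude bound is closed at 0 (the flat solution is admissible); constant
input returns α₁ = 0, φ = 0, R² = adjusted R² = 0; adjusted R² counts
p = 3 free parameters (ω is not estimated); fits require ≥ 5 non-missing
bins.

One property worth knowing: because the profile is z-scored before
fitting, the *noise-free* recoverable amplitude saturates near √(2·9/10) ≈
1.34 for any nonzero generative amplitude — the standardization strips the
scale. Detection power therefore comes from the otCS − sham amplitude
*contrast* (noise pushes fitted amplitudes toward a common floor ≈ 0.57
under the null; entrainment pushes the otCS fit toward the ceiling), not
from the absolute fitted value.

## ANOVA machinery

All designs are balanced and complete (validated, with the offending cell
named otherwise); sums of squares are the classical marginal-mean
decompositions, which are mutually orthogonal in balanced layouts and sum
to the total SS (asserted to 1e-8).

The condition × bin × order analysis supports two error modes.
`stratified` is the textbook split-plot analysis: each within effect
against its own subject-interaction stratum — condition × order on
df (1, 34) for 36 subjects in two order groups. `pooled` enters the
participant as a single additive 35-df block and pools all remaining
subject-by-within variation into one 646-df residual; this reproduces a
df structure that appears in published reports of this design and exists
here as a replication mode. The order main effect lies in the
between-subject stratum and is tested there in both modes. Mauchly's W
uses the pooled within-group covariance of orthonormal (Helmert) contrast
scores, the standard chi-square approximation with Box's second-order
term (the ezANOVA/SPSS convention, cross-checked against pingouin), and
Greenhouse-Geisser ε = (Σλ)²/(d·Σλ²) from the contrast-covariance
eigenvalues, clipped to [1/d, 1]; corrected tests scale both df by ε.
Two-level factors report W = ε = 1 (sphericity is vacuous).

## Inference suite

* **Paired t**: scipy's `ttest_rel` behind a thin validation layer
  (zero-variance differences are an error unless identically zero).
* **JZS Bayes factor**: Cauchy(0, r) prior on the standardized effect
  (default r = 0.707) via its inverse-gamma(1/2, r²/2) scale mixture;
  BF₁₀ computed by adaptive quadrature in log space with relative error
  held below 1e-6, cross-checked in tests against a 200k-point trapezoid
  oracle and against pingouin. At the benchmark point t = 0.65, n = 36 it
  evaluates to 0.218 → 0.22 at two decimals.
* **Wilcoxon signed-rank**: zeros dropped, midranks for ties,
  tie-corrected variance n(n+1)(2n+1)/24 − Σ(t³−t)/48, no continuity
  correction, so Z is reproducible bit for bit. Z is signed by W⁺ relative
  to its mean (software that reports Z from the smaller rank sum, always
  negative, will agree in |Z| and p). For n ≤ 12 the exact two-sided p
  over all 2ⁿ sign assignments is computed alongside.
* **Holm**: step-down adjustment with monotonicity enforcement, clipped
  at 1; used for the time-course post-hocs (first 32-trial bin against
  each later bin).
* **DP signed-rank**: the Bayesian analogue targets the signed-rank
  functional θ = P((X+X′)/2 > 0). The posterior over difference
  distributions is a Dirichlet process centred at a point mass at zero
  with concentration s (default s = 0, the Bayesian-bootstrap limit);
  each draw samples Dirichlet weights over the observed differences and
  evaluates θ = Σᵢⱼ wᵢwⱼ 1[dᵢ+dⱼ > 0] (half-mass at exact ties).
  `posterior_p_h0` is the posterior mass of θ ∈ 0.5 ± 0.05 — an explicit
  practical-equivalence reading, since the underlying method yields
  posterior probabilities of dominance rather than of a point null. The
  equivalence half-width and s are configuration. Note the posterior for
  θ has sampling spread ~ n^(−1/2), so with small n even perfectly
  symmetric data place modest mass in the equivalence region; statements
  like "symmetric data support H₀" hold at realistic n (the tests use
  n = 300).

## EEG cleaning

The chain runs: baseline subtraction (−300..0 ms), rejection of trials
with any |V| > 1000 μV, epoching (−800..1000 ms around target onset),
regression ocular correction, re-baselining over the same window, and
rejection at 500 μV. The narrative order it reproduces describes baseline
and coarse rejection *before* epoching; since the baseline window lies
inside the epoch window, both orderings operate on the same samples, and
the implementation works on extracted windows (`order="conventional"` is
accepted as an alias documenting the equivalence). Events too close to the
recording edge are flagged, not raised. The ocular correction is the
regression variant: event-related averages are removed from EEG and EOG
before estimating one propagation factor per (channel, EOG-channel) pair
by least squares on the concatenated residuals, and the scaled raw EOG is
subtracted trial by trial. No separate blink/saccade partition is
attempted — the single-factor variant is the documented simplification,
and a partitioned variant would slot in at the same interface. The
synthetic-recording generator (alpha-band sinusoid + 1/f noise +
raised-cosine blink templates with known propagation) provides ground
truth for all of this; recovery of an injected 0.35 propagation factor to
±0.02 and sub-5% post-correction RMS error are asserted in the suite.

## Operating characteristics

`operating_characteristics` sweeps the generative amplitude A over
{0, 0.1, 0.25, 0.5, 1.0} by default (null through saturating, on
log-odds) and, per value, simulates cohorts and records rejection of the
two-sided amplitude t-test at α = 0.05 with Monte-Carlo standard errors,
plus bias/RMSE of the fitted otCS amplitude against the noise-free
expectation (`expected_alpha1`). The sweep uses the analytic fitter and a
lean path (binning → z-scoring → fits → t-test) — the quantities the
characteristics are defined on. Problem sizes in the shipped tests (1000
replicates for type-I calibration at the full 36 × 2 × 384 design, 40
replicates per amplitude for the power curve) were chosen so the whole
suite runs on a laptop-class single core in minutes; at those sizes the
measured type-I error is 0.047 with uniform p-values.

## Known limitations

* The pooled-error ANOVA mode treats repeated measures as exchangeable
  within participant; it exists for replication, and the stratified mode
  is the statistically defensible default.
* The DP signed-rank "P(H₀)" depends on the equivalence half-width; there
  is no canonical value, only an explicit one.
* Amplitude recovery on the standardized scale is attenuated by binomial
  noise and saturated by z-scoring (see above); `alpha1_bias` should be
  read with that in mind.
* EDF reading requires the optional `mne` dependency; everything else is
  plain delimited text.
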