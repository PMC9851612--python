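# Methods

`mvextrap` re-implements, as a tested pipeline over synthetic data, a
time-resolved EEG decoding analysis that measures how early the visual system
represents the position of a smoothly moving object relative to an
unpredictable flash in the same location. This note documents the model the
package implements, the synthetic data it is validated on, the numerical
choices, and what the tests do and do not establish.

## The analysis

**Stimulus geometry.** Thirty-seven positions form a centred hexagonal grid
(three rings). The grid spacing is not an independent quantity: the disc moves
at 10.36 dva/s and takes 400 ms between adjacent positions, fixing the spacing
at 4.144 dva. Straight trajectories run along the three lattice axes in both
senses (six directions), one per parallel row of positions (seven rows on the
3-ring grid), giving 42 trajectories crossing between 4 and 7 positions each.
Paths begin and end 7 dva plus one grid spacing beyond the outermost crossed
position; this reconstruction reproduces motion durations of ~3351–4551 ms
(the printed range is 3350–4550 ms) and is the only reading of the lead
distance we found that does. Sessions repeat every position 42 times and every
trajectory 18 times, shuffled, with ISIs uniform on [350, 450] ms; six
sessions give 252 static trials per position and 108 per trajectory.

**Preprocessing** (in order): re-reference to the two mastoid channels;
baseline-correct each epoch by its mean over the 100 ms before onset; reject
static trials whose gaze leaves a strict 2.1 dva radius while the stimulus is
on screen (motion trials are never rejected on this basis — they are only ever
test data); reject epochs whose per-channel amplitude SD exceeds the mean of
that channel's per-epoch SDs by more than 4 (static) or 5 (motion) SDs of
those SDs, ties kept; demean by condition — static trials lose the mean
channel-by-time ERP over all positions, motion trials the mean over
trajectories crossing the same number of positions. No filtering anywhere, so
event timing is never distorted.

**Decoding.** For every pair of positions (666 pairs) and every training time
(each sample in 0–350 ms), a linear discriminant is trained on static trials
with the pooled within-class covariance shrunk towards a scaled identity,
`S_reg = (1-γ)S + γ(tr S/d)I`, γ = 0.05. Classes are balanced per pair by
subsampling the majority class without replacement (seeded). Static
evaluation is 5-fold cross-validated over the full training-time × test-time
grid; motion evaluation applies classifiers trained on all static trials to
epochs re-cut from −500 to +500 ms around each position crossing, with each
trajectory's first crossing dropped (onset-response confound). The decoding
features are instantaneous channel vectors. Scores are class-conditional vote
fractions r_ij — the fraction of true-class trials the (i, j) classifier
labels i — so r_ji = 1 − r_ij by construction; a posterior-based variant is
available behind `DecoderSpec.score_mode`.

**Likelihoods.** Vote fractions combine into a likelihood over positions,

    p_s(i) = ( Σ_{j≠i} 1/r_ij − (k−2) )⁻¹ ,  normalised to Σ_i p_s(i) = 1,

with r clipped to [1e−6, 1−1e−6] so perfect classifiers stay finite. With all
r = 0.5 the result is uniform, 1/37 ≈ 0.027027. The likelihood at the true
position, p_s(s), averaged over positions (and crossings/directions, which are
pooled at the vote-fraction stage) and indexed by training × test time, is
the temporal generalisation matrix (TGM) the latency analysis consumes.
Chance (1/k) is subtracted for display only; statistics always operate on
unsubtracted values against the permutation null.

**Latency extraction.** Static peak times are the argmax over test time per
training time (earliest sample on ties). Motion time courses are noisier, so
each training time's course is fitted with a four-parameter Gaussian
`b1·exp(−(t−b2)²/2b3²) + b4` (nonlinear least squares, five restarts with the
peak initialised at the smoothed argmax and ±100/±200 ms, b2 bounded to the
test window, b3 to [8, 500] ms). Fits are kept when the adjusted R² is at
least 0.5 *and* the width did not land on its upper bound (a width at the
bound means the curve degenerated into a window-wide trend with no
localisable peak). Piecewise-linear regression with free interior knots
(candidate totals 4–7, endpoints fixed, selection by adjusted R² with ties to
fewer knots) locates the inflections of the motion peak-time series; the
feedforward window runs from the start of the fitted range to the first
interior knot at which the fitted slope drops materially (by ≥ 0.5): the
point where peak latency stops rising with training time is the end of the
feedforward sweep. Free-knot fits regularly park a surplus knot inside a
straight noisy segment; such a knot changes the slope by next to nothing,
marks no inflection, and is skipped (if no knot qualifies, the first interior
knot is used). Within the window, ordinary least squares lines relate peak time to
training time separately for static and motion; the slope difference and
intercept difference are tested with a dummy-coded interaction regression,
and the mean vertical distance between the lines is evaluated analytically at
the window midpoint (the mean of a linear function, hence independent of
sampling density). The *reported* intercept difference — the recovered shift —
is estimated under the parallel-lines (common slope) model: slope equality is
established first and only then is the intercept difference interpreted, and
the separate-fit difference extrapolates both lines to t = 0, which amplifies
slope noise by roughly the window midpoint (~100 ms); the separate-fit value
is retained alongside. Bootstrap CIs of the Gaussian peak come from resampling
participants with replacement and refitting on each resampled mean
(percentile interval).

**Statistics.** Nulls come from shuffling position labels at the aggregation
step — classifiers are never retrained — 1000 times by default, recomputing
the diagonal stimulus-position likelihood from the stored per-trial votes
each time; the identity permutation reproduces the observed value exactly.
Group inference uses a one-sample Yuen's t (20% trimming, winsorized
variance, one-tailed) of participants' observed likelihoods against their own
null means, per timepoint; with zero trimming this reduces exactly to
Welch's t. Cluster-based correction thresholds the t series at the one-tailed
critical value for the trimmed df, scores contiguous runs by summed t, and
compares against the distribution of the maximal cluster mass across
permutations with the +1 correction, so p ≥ 1/(n_perm+1).

## The synthetic forward model

Synthetic data exist to give the pipeline a ground truth it can be asked to
recover. One participant's recording is generated as

    x(t) = Σ_c g_c · env_c(t) · topo_c(position) + noise ,

a cascade of stimulus-evoked components with Gaussian temporal envelopes
(width 15 ms) at latencies 50, 60, …, 170 ms and equal gains (nominally
4 µV). The cascade is quasi-continuous deliberately: with only two or three
discrete stages the preferred latency of the evoked pattern is a staircase of
the stage latencies, the peak-time series inherits the steps, and the
piecewise regression spends its knots on them; overlapping stages every 10 ms
make the dominant representation drift smoothly, which is also the premise of
reading training time as a proxy for processing stage. Equal gains and narrow
envelopes matter for the same reason: motion responses have broad position
tuning, so a gain taper (or wide envelopes truncated at the cascade edges)
skews the multi-stage mixture towards the stronger stages and biases fitted
peak latencies away from the injected shift.

After the feedforward sweep the same stage patterns reactivate in reverse
order — stage topographies reappear at `360 ms − latency` with half the gain —
modelling information flowing back down the hierarchy. The reactivations are
flagged flash-evoked only: they ride on the static response but are not
re-expressed by the moving stimulus, which is also why static-trained
classifiers at late training times still generalise to the feedforward motion
response (the late flash-evoked signal reflects reactivation of earlier
patterns, common to both stimulus types). This feedback branch is what gives
the peak-latency series its rise-then-fall shape, and hence the feedforward
window a structurally identifiable end; carrying the reactivations in the
motion response as well would make every motion likelihood time course
bimodal (each pattern would be expressed twice) and destroy the Gaussian peak
estimates.

Each component has its own channel topography per position: an independent
zero-mean Gaussian-process draw over the 2-D layout (squared-exponential
kernel, length scale 5 dva) for fine position tuning, plus two smooth global
gradient patterns — random orthonormal channel loadings multiplied by the
stimulus x and y coordinates, amplitude 1.5× the GP at the field edge —
emulating coarse retinotopic organisation (hemifield and eccentricity).
Together they give the retinotopy premise that makes pairwise decodability
grow with position separation: the gradients keep pattern separation growing
linearly out to the largest separations (any stationary kernel saturates
after a few length scales), while the local GP keeps motion likelihood bumps
narrow enough for unbiased peak estimation; and because the gradients are
linear in position they flip each pairwise discriminant exactly at the pair
midline, adding no asymmetry to those bumps. Rows are unit norm. The GP field is drawn over the grid extended by three lattice rings so
that a disc travelling its lead-in/lead-out segments expresses its own
smoothly continued topography rather than a frozen copy of the nearest edge
position; evoked amplitude additionally rolls off (Gaussian profile) with
distance beyond the grid hull, reflecting the weak sensor-level response to
far-peripheral stimulation. Both choices are load-bearing: with a hard edge,
exit crossings keep voting for the last position for the full ~1.1 s
lead-out (no neighbouring position exists beyond the hull to flip the
pairwise votes), which biases motion peak latencies late by tens of
milliseconds.

**The extrapolation shift Δ** is the generative analogue of the latency
advantage under study: during motion, component c expresses the topography of
the stimulus position at `t − λ_c + Δ`, i.e. every stage's represented
position is advanced along the trajectory by the same Δ. `Δ = 0` means each
stage carries its fully accumulated lag; `Δ = λ_1` aligns the first stage
with the real-time position. Static trials are unaffected, so the pipeline's
static–motion intercept difference should recover Δ.

**Noise** is spatially mixed AR(1): per-channel AR(1) processes (coefficient
0.3, stationary SD `white_sd`) mixed to a common inter-channel correlation of
0.2. There is no 1/f component, no eye-blink or muscle artefact, and no bad
channels — deliberate simplifications, documented here. Gaze traces are white
fixational jitter (SD 0.4 dva) plus an optional smooth-pursuit term
proportional to stimulus displacement; with `pursuit_gain = 0` they carry no
position information, which is the premise of the eye-movement control.

**Calibration.** The free amplitude parameters were fixed once against the
qualitative behaviour of the real recordings: `white_sd` (4 µV against gain
4 µV unit-norm topographies) is set so that matched-time pairwise accuracy
spans roughly 0.60–0.76 from adjacent to maximally separated pairs (the range
of the published group curves) while a desk-scale dataset still supports
Gaussian latency fits, and the gradient amplitude is set so binned accuracy
rises over the whole range of available separations rather than saturating.
Defaults: see `synthgen.SimConfig`.

## Problem sizes

Full-scale defaults reproduce the study conditions (6 sessions, 42/18
repetitions, 64 channels + 2 reference channels, 128 Hz). The test suite and
worked examples run reduced profiles chosen as the package's own desk-scale
conditions: `RunConfig.desk_scale()` (one session, 15/5 repetitions, 32
channels, 200 permutations and bootstrap resamples), and the
parameter-recovery profile (three participants of one session each with 12
static and 6 motion repetitions, 32 channels, classifiers trained over
40–300 ms — the range covering the synthetic feedforward cascade and its
feedback reversal). Recovery is group-level by design, exactly like the
analysis it validates: component topographies are random draws, and the
O(1/√channels) overlap between independent component fields gives every
single draw a fixed coherent distortion of the broad motion likelihood
bumps; averaging likelihoods over participants cancels it, which is also why
the original analysis fits latencies on the participant-averaged time
course. The reduced training window changes nothing conceptually: the
feedforward-window logic operates within it exactly as it would within
0–350 ms.

## Numerical and design choices

- Grid spacing, lead distance: see geometry above; both are reconstructions,
  flagged as such.
- Position ids are 0-based throughout.
- The SD-rejection rule reads "exceeds k standard deviations from the mean
  SD" as a z-score on per-epoch amplitude SDs over the full epoch window,
  strict inequality.
- Fixation rejection is strictly greater than 2.1 dva.
- Demeaning subtracts the full channel × time group ERP (not a per-channel
  scalar), matching the epoch-resolved reading of "average amplitude of each
  electrode".
- Cross-validated classifiers are reused across all test times (no refit per
  test time); fold assignment is seeded and stratified by position.
- r-clipping at 1e−6 keeps the combination formula finite for perfect
  classifiers; configurable.
- Piecewise knot search is Nelder–Mead over sorted interior knots,
  multi-started from quantile configurations, with segments required to span
  at least 8% of the x-range and contain at least three points (soft
  penalty); without this the search spends knots absorbing single noisy
  points and the feedforward window degenerates.
- Argmax ties resolve to the earliest test time.
- Group-level test: one-sample Yuen of observed minus own-null-mean, the
  pairing that makes the observed value exchangeable with the permutations
  (it is their identity element); a two-sample mode is available.
- Reported millisecond values round to the nearest integer.

## What passing tests show — and what they do not

The suite establishes that the implementation is faithful to its own
definitions (hand-worked examples, independent textbook oracles for OLS,
Yuen's t and the likelihood combination, exactness on in-model data) and that
the full pipeline recovers a known extrapolation shift from data with the
assumed generative structure, at desk scale. It does not establish anything
about real EEG: the generator has no 1/f noise, no artefacts, a single clean
feedback sweep rather than ongoing oscillatory reactivation, no
trial-to-trial latency jitter, and position tuning that is exactly GP-smooth. Rejection percentages and
significance onsets in the original recordings are data-dependent quantities
that the synthetic data make no attempt to match.

## Known limitations

- The vote-fraction geometry is asymmetric at the grid boundary (inside the
  grid a passed position is actively voted *against*; beyond the hull votes
  merely decay to chance). The amplitude rolloff keeps the residual bias in
  recovered shifts small at desk scale, but edge positions remain the noisiest.
- At very low noise the vote fractions saturate at 0/1 and peak latencies
  become ill-defined plateaus; the pipeline is designed for realistic noise
  levels.
- Memory scales as (train times × test times × positions × pairs); the
  full-scale motion tensor is ~0.5 GB in float32.
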