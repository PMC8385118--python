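# Methods

This note documents the models, algorithms and numerical choices behind the
toolkit, the design decisions that were genuinely open, and the limits of
what the synthetic-data tests establish.

## Task engine

The stress scenario is simulated as a sequence of timed arithmetic trials in
a 3 × 5 grid of 1 m² floor tiles (x ∈ [0, 3), z ∈ [0, 5), row-major tile
index; the body position used for tile tests is the headset position shifted
0.10 m backward, with facing simplified to +z for simulated agents).

**Titration.** Display time starts at 2.5 s and moves in exact 60 ms steps
driven by the rolling accuracy of the last five recorded outcomes: above 60%
and display time > 1 s, subtract a step; below 40% and display time < 3 s,
add a step. Guards are evaluated on the current value with no post-hoc
clamping, so the reachable range is exactly [1.00, 3.04] s. All display-time
arithmetic is done in integer milliseconds so that steps are exact and the
grid is never blurred by accumulated floating error. With fewer than five
trials the rolling accuracy is computed over the trials available.

**Trial mechanics.** A trial ends at the button press (or display-time
expiry); a timeout is always recorded incorrect. There is a 5% chance that a
correct press is scored incorrect ("flipped"); a configuration switch
(`flip_basis`) can widen this to all pressed trials, but the default applies
it to correct presses only. Inter-trial intervals are 1.75 s exactly in
training and uniform on 1.75 ± 0.525 s in the test (the uniform law is a
declared choice; only the range and mean are prescribed). Recorded errors
explode one uniformly chosen remaining tile (1.0 s alarm + 0.75 s visual);
stepping over a gap triggers a fall, which suspends trial scheduling for a
configurable 2 s and lands the agent in a fresh 15-tile room. At the end of
the second test block everything — display time, performance counters, all
tiles — resets, so the third block starts from the same state as the first.
Voice messages after blocks 1–3 pause the task clock and consume no block
time. Control-scenario trials use one-digit operands at a fixed 5 s display
and 1 s interval, with no explosions or titration, and the final control
block has no arithmetic. Stress-scenario operands are 1–99 with non-negative
results; difficulty is carried by display time, not operand size.

**Agents.** A simulated participant has a logistic psychometric curve
P(correct | display time d) = 1/(1 + exp(−(d − c)/s)) with scale s = 0.35 s
and offset c set so that P(2.5 s) equals the agent's ability. The scale was
chosen once so that even the extreme abilities tested (0.30–0.95 at 2.5 s)
cross the 40%/60% band inside the reachable display-time range, which is the
regime where titration can equalize challenge. Response latency is a Beta-
shaped fraction of the display time; incorrect trials are timeouts with
probability 0.3. Movement is a reflected random walk (or a stationary
policy). With these defaults a session completes ≈ 160 test trials in the
10-minute test, consistent with an average near 149.

**Logs.** A session log holds tick-level positions at 10 Hz, trial records
(including the ±1 display-step adjustment applied after each trial, needed
for the increments/decrements behavioral variables), tile events, falls and
a numbered trigger stream. Serialization uses full-precision floats so that
read(write(log)) is the identity.

## Physiological features

Twenty-five variables are computed per 2.5-minute block; a Δ variant
subtracts the first baseline block. Blocks are half-open windows [start,
end); a beat interval belongs to the block containing the beat that ends it.

- **Time domain / Poincaré.** HR = 60000/mean(NN); RMSSD; SDNN (population
  std); pNN50 with strict > 50 ms. SD1 ≡ RMSSD/√2 and SD2 ≡
  √(2·SDNN² − SD1²), so the identities SD1 = RMSSD/√2 and SD1² + SD2² =
  2·SDNN² hold exactly by construction rather than approximately.
- **Geometric.** Histogram with 7.8125 ms (1/128 s) bins; TRI = total count /
  modal bin count; TINN is the base of the least-squares triangle with apex
  pinned at the mode, found by grid search over base endpoints.
- **PRSA.** Deceleration (ac: acceleration) anchors are intervals strictly
  longer (shorter) than their predecessor; capacity = (X₀ + X₁ − X₋₁ − X₋₂)/4
  averaged over anchors with a full two-interval window on each side.
- **Entropies.** SampEn and ApEn with m = 2, r = 0.2·SDNN floored at 1 ms,
  Chebyshev distance; SampEn counts pairs among the first N−m templates
  excluding self-matches, ApEn includes self-matches. Both are verified
  against a brute-force template-counting oracle.
- **Spectral.** Lomb–Scargle on the irregular beat-time series (no
  resampling), 4× oversampled frequency grid, bands 0.04–0.15 (lf),
  0.15–0.40 (hf), 0.003–0.40 Hz (total). The periodogram is scaled by 2T/n so
  its integral approximates the series variance (Parseval-type check within
  10% in tests).
- **rrHRV.** Relative interval changes rrᵢ = 2(RRᵢ−RRᵢ₋₁)/(RRᵢ+RRᵢ₋₁); the
  statistic is the median Euclidean distance of return-map points
  (rrᵢ, rrᵢ₊₁) from their componentwise median — scale-free by construction.
  The cited toolbox's exact scaling constant is not published; this package
  fixes the unscaled median-distance definition.
- **Respiration.** Zero-phase 1 Hz low-pass; peaks must rise ≥ 1.4826·MAD of
  the filtered trace, be ≥ 0.8 s apart and ≥ 0.4 s wide; rate is the median
  of 60/inter-peak-interval, depth/width the median prominence/width.
- **EDA.** Trough-to-peak: smoothed conductance, a peak counts if it rises ≥
  0.05 µS above the minimum of the preceding 10 s (the lookback prevents slow
  tonic drift from accumulating into spurious responses). Continuous
  decomposition: the Bateman kernel b(t) = e^(−t/τ₂) − e^(−t/τ₁) with τ =
  (1.0, 3.75) s has a rational transfer function, so deconvolution is the
  exact differential operator (y″ + (a+b)y′ + aby)/(b−a) evaluated with
  Savitzky–Golay derivatives (0.75 s window); the driver splits into a 10-s
  rolling-median tonic part and non-negative phasic impulses. SCRs are
  counted on the sharp phasic driver (peaks whose local driver area times the
  kernel maximum exceeds the 0.05 µS criterion), because two responses a few
  seconds apart merge into one extremum in reconstructed conductance but stay
  distinct in the driver. Tonic level is the mean of conductance minus the
  reconstructed phasic component. Counts are normalized to per-minute rates
  (count × 60 / block duration).
- **Preprocessing.** Decimation uses a zero-phase windowed-sinc FIR with
  cutoff at 80% of the post-decimation Nyquist (30·factor + 1 taps) — a
  deliberately conservative anti-alias choice. R-peak detection is a light
  Pan–Tompkins variant (5–25 Hz zero-phase band-pass, squared energy,
  adaptive robust threshold, 0.3 s refractory period, local refinement);
  NN cleaning rejects intervals outside 300–2000 ms or changing > 20% from
  the previous accepted interval, and flags a block unusable above 20%
  rejection. These cleaning thresholds are declared defaults (the original
  acquisition-specific thresholds are not public) and are configurable.

## Cortisol

Samples s1–s4 (arrival; immediately, +20 and +40 min after the test) are
corrected by subtracting the chord through (t1, s1) and (t4, s4), which
forces c1 = c4 = 0 and removes any linear-in-time trend exactly. Total
release between the two post-task samples is AUCi = (c3 − c2)(t3 − t2)/2
(nmol/L·min, negative when levels fall); with only two post-task values the
increase term anchors on c2. Missing sampling times fall back to cohort
means with a warning.

## Screening statistics

Outliers are values more than 3 scaled MADs (1.4826 × median absolute
deviation) from the median, replaced in a single pass by the median of the
non-flagged values; with a degenerate zero MAD nothing is replaced (the
literal rule would flag every non-median value) and a warning is issued.
Group screening applies a pooled-variance t-test per variable per block,
switching to Welch when Levene's test rejects homogeneity at 5%;
Benjamini–Hochberg adjustment is applied within each block's 50-variable
family. Variable display order comes from average-linkage Euclidean
clustering of the t-statistic profiles (deterministic leaf order).
Between-subject associations use Spearman correlations of participant means
across the test blocks; within-subject associations use the repeated-measures
correlation (common within-subject slope, computed via pingouin), with BH
adjustment within each correlation modality. Quartile grouping of the
difficulty-adjustment balance (decrement% − increment%) assigns boundary
ties to the lower quartile. The power computation evaluates the noncentral-t
power function exactly (ncp = d√(n/2), df = 2n − 2) and returns the smallest
total N over two equal groups; at d = 0.5, 80% power, one-sided α = 0.05 it
gives 102.

## Stress classifier

PLS1 is implemented by NIPALS deflation; for a univariate response each
component is a closed-form step (weight ∝ deflated X'y), so there is no
iterative convergence concern. Features are z-scored on the training fold
(test rows transformed with training parameters); the response is the
centered 0/1 dummy. In the full-component limit and on univariate problems
PLS predictions coincide with ordinary least squares, which the test suite
uses as an oracle alongside scikit-learn's implementation.

The leave-one-out procedure treats each participant's test blocks (T1, T3,
T4 by default; the middle block T2 is excluded from training because group
differences habituate there) as independent labeled samples. For each
held-out participant: (i) the component count (grid 1–10, ties to fewer) is
chosen by inner cross-validation minimizing squared prediction error;
(ii) the inner CV predictions build an ROC curve whose Youden-J-maximizing
threshold (candidates = unique scores, classification rule score ≥
threshold, ties to the lowest) becomes the decision point; (iii) the four
test blocks of the held-out participant are scored and blocks at or above
threshold count toward the 0–4 stress count. The inner CV is
participant-grouped: all blocks of an inner held-out participant leave
together. This matters — with row-level inner LOO, sibling blocks let the
model memorize participant identity, and null-cohort AUC inflates well above
chance (≈ 0.73 at 30 + 30 in our measurements) even with no group effect.
Zero-variance features are dropped with a warning; residual missing values
are imputed with training-column means.

The permutation test shuffles labels at the participant level and compares
participant-grouped 5-fold CV AUCs, with the add-one estimator
p = (1 + #{null ≥ observed})/(n_perm + 1). Using in-sample AUC for the
permutation statistic would center the null above 0.5 (overfitting); the
grouped-CV statistic keeps the null centered at chance and makes the p-value
uniform under the null, which the acceptance suite verifies by a KS test
over 50 replicated null cohorts. Coefficient importance is the element-wise
mean of standardized-space regression coefficients across the leave-one-out
models (positive = toward the stress label).

## Synthetic data

The generators are phenomenological stand-ins, not physiological models.
Beat intervals are AR(1) mean-reverting noise (φ = 0.9) around a
block-specific mean plus 0.1 Hz and 0.3 Hz sinusoids that give the spectrum
lf/hf structure; programmed variance splits evenly between the broadband and
modulated parts, with the hf fraction lowered under stress. EDA is a slowly
drifting tonic level plus Poisson-timed Bateman impulses (lognormal
amplitudes around 0.3 µS, a 4 s refractory gap so that trough-to-peak
counting can resolve every programmed event). Respiration is a
rate-modulated oscillation. Cortisol declines linearly (−0.03 nmol/L/min
from a ≈12 nmol/L baseline) with a stress bump weighted (0, 0.7, 1, 0)
across the four samples and lognormal noise. An optional ECG renderer places
Gaussian QRS complexes (σ = 12 ms) at the programmed beat times for detector
tests.

Default group effects follow the directional pattern such a task elicits:
heart rate (+10–12 bpm), respiration (+3–4 cpm), SCR rate (+4–5/min) and
tonic EDA elevated across all four test blocks, HRV suppressed (SDNN × 0.70)
and hf fraction reduced mainly in the second half, a dip in all effects in
the second block (habituation before the forced restart), and a 4 nmol/L
cortisol bump. One multiplier θ scales every group difference continuously;
θ = 0 makes the groups exchangeable. Between-participant offsets (HR sd
4 bpm, respiration sd 1.2 cpm, SCR sd 0.8/min, tonic sd 0.3 µS) are drawn
once per participant and shared across blocks, which is what gives the inner
cross-validation its leakage structure and the Δ features their power.

**What passing tests show — and don't.** Recovery tests demonstrate that the
extraction pipeline returns the programmed ground truth at zero/low noise
and degrades gracefully; classifier tests demonstrate correct machinery
(holdout integrity, calibrated permutation p, chance-level null AUC). They
do not establish performance on real recordings: real ECG has ectopy,
artifacts and non-stationarity the AR(1) generator lacks; real EDA has
overlapping compound SCRs; real group effects are far smaller and more
heterogeneous than the default θ = 1 profile, so the near-perfect synthetic
AUC is a property of the generator, not a claim about human data.

## Problem sizes and determinism

The test and acceptance workloads use 30 + 30 participant cohorts for the
classifier checks, 10 + 10 cohorts for the 50 permutation-calibration
replicates (n_perm = 200), ≈ 100 simulated sessions for the titration grid,
and 1000 random series for the HRV identities. All generators and the
engine take explicit seeds; identical seeds give bit-identical outputs.
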