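# Methods

## The analysis in one paragraph

Each subject contributes three sessions on different days; a session is 36
alternating 25-s trials (18 wash-off, 18 stimulation) with six channels —
PPG, GSR, four EOG electrodes — at a common raw rate, plus a 1–5 craving
self-report per trial. Trials are preprocessed, reduced to 14 features,
and labeled by trial kind (stimulation = high craving). Per training set a
Fisher score ranks the features; a classifier fit on the top one or two
features predicts the day-3 trials under four conditions (within-day
cross-validation, train-on-day-1, train-on-day-2, train-on-both). ICC(A,1)
of per-session feature means quantifies each feature's test-retest
reliability. Because real recordings of this kind are not publicly
available, a simulator generates study-shaped data with known ground truth;
every claim the package makes is tested against that truth or against an
independent oracle.

## Preprocessing

* **PPG**: 5-sample median filter (impulse suppression), then 4th-order
  Butterworth band-pass 0.1–10 Hz, applied forward–backward so peak timing
  is unbiased. Kept at the raw rate.
* **GSR**: anti-aliased decimation to 16 Hz, 4th-order Butterworth low-pass
  at 0.2 Hz (order is a package choice; only the cutoff is conventional),
  least-squares linear detrend.
* **EOG**: vertical component = above − below the right eye, horizontal =
  right − left outer canthus; each decimated to 16 Hz, median-filtered with
  a 7-sample window, and re-based by subtracting the component's median
  (one global median per trial — the natural reading of per-trial baseline
  correction).

Edge handling matters for 25-s trials with sub-hertz filters: decimation
uses line-extension padding, median filters replicate the edge value, and
the forward–backward filters are padded to several time constants of the
lowest cutoff. With scipy's shorter defaults, a constant or a slow trend
bends visibly at the trial edges and the last beat's amplitude is inflated;
with these settings a pure ramp passes the GSR chain to ~1e-6 of its span.

## Features

HR and RR are computed on the 10–25 s window of each trial, insulating them
from any residual start-up transient.

* **stdHR, mHR**: pulse peaks via prominence-thresholded peak picking
  (minimum spacing 60/180 bpm); instantaneous HR = 60/IBI per beat pair in
  the window; at least 5 beats required, otherwise the trial's HR features
  are NaN.
* **stdRR, mRR**: the respiratory rate is recovered from the respiratory
  amplitude modulation of the pulse train. Beat amplitude is measured
  baseline-corrected (peak height above the mean of the two adjacent
  inter-beat troughs) — raw peak heights pick up heart-rate wander through
  the 0.1 Hz high-pass, which competes with the ~10 % respiratory AM. The
  envelope is interpolated to 4 Hz, detrended, and the dominant frequency
  in 0.1–0.7 Hz is tracked over sliding 10-s windows (Hann taper,
  zero-padded FFT, parabolic peak refinement). Modulation below 1 % of the
  pulse amplitude is flagged undetectable (NaN). The estimator sits behind
  a plain function interface so another RR-from-PPG algorithm can be
  substituted.
* **mNSC, minNSC**: z-score the 16 Hz GSR trace; peaks are maxima at
  rising-to-falling zero crossings of the first difference; mNSC averages
  the normalized peak amplitudes (a whole-trace-mean mode exists behind a
  config flag; note the whole-trace mean of a z-scored trace is 0 by
  construction, which is why the peak reading is the default). A
  zero-variance trace yields NaN.
* **NE** (blink count): samples with |veog| above `blink_k` (default 3)
  robust SDs form candidate intervals; gaps ≤ 2 samples merge; intervals
  shorter than 2 samples or whose peak stays below `blink_min_height`
  (default 25 a.u.) are discarded. The amplitude floor separates blinks
  (hundreds of a.u. on the vertical component) from saccadic gaze levels
  (tens of a.u.) that occasionally exceed a purely relative threshold.
  Detected intervals, padded by 3 samples per side to swallow the
  sub-threshold flanks, are replaced by linear interpolation before saccade
  analysis.
* **DHSM, DVSM, mDHV, DSM**: a Haar-family continuous wavelet transform
  (mean-after minus mean-before at scales 3–8 samples, with a 3-sample gap
  around the candidate edge so filter-smoothed transitions do not bias the
  estimate) marks steps on each component; the degree of movement per
  component is the sum of absolute detected step amplitudes;
  mDHV = (DHSM + DVSM)/2 exactly; DSM sums √(h² + v²) over events, pairing
  H and V detections within 2 samples and counting an absent component as
  0. Step amplitudes on controlled inputs are recovered within a few
  percent; on fully random simulated saccades the sum is biased low by
  ~5 % because sub-threshold micro-saccades are invisible.
* **CHV, CHP, CVP**: sample covariances (ddof = 1) of the two EOG
  components and the PPG decimated to the same 16 Hz timeline.

Missing features (NaN) propagate to the model stage, which imputes them
with training-set means; the pipeline never aborts on a degenerate trial.

## Classification protocol

Labels are the trial kinds. For every training set independently: Fisher
scores are computed NaN-aware with an ε-guard for zero-variance features
(a perfectly separating degenerate feature ranks first; ties break toward
the lower feature number); the SVM takes the top two features, all other
classifiers the single best. Selected columns are mean-imputed and z-scored
with training-set statistics — distance- and kernel-based classifiers need
commensurate scales across features in different units; a raw-scale mode
exists for sensitivity checks. Nothing derived from test trials reaches the
fitted model.

Classifier settings: SVM (RBF, C = 1, γ = 1/#input-features), kNN (k = 17;
odd, so binary votes cannot tie), CDNN (k = n_train; the query joins each
class's neighbourhood and the class whose centroid moves least wins; ties
resolve by neighbourhood majority, then lower label), LDA, random forest
(100 trees, seeded). CDNN is implemented here; the others are standard
library estimators behind this module's interface.

Condition 1 uses stratified 6-fold CV within day 3 (3 wash-off + 3
stimulation per test fold, shuffled with a seed), refitting selection and
standardization inside each fold. Conditions 2–4 train on the named earlier
day(s) and test on all 36 day-3 trials. Cohort summaries are across-subject
medians and IQRs per classifier × condition.

## Reliability and statistics

ICC(A,1) is computed from the two-way ANOVA mean squares; the significance
test is F = MSR/MSE on (n−1, (n−1)(k−1)) df for H0: ICC ≤ 0 (the
conventional choice when no test is otherwise specified). The feature
reliability table uses subjects as rows and the subject's session mean over
the 18 same-kind trials as cells, for each feature × trial kind; a
per-trial-position variant (rows = 18 trial slots, cells averaged over
subjects) is available behind the `unit` flag for sensitivity analysis —
the sentence defining the aggregation is ambiguous in the source paradigm,
so both readings are provided and neither is asserted as canonical.

The estimator's small-sample bias is real and measurable: at n = 9, k = 3
the mean estimate is low by ≈0.02–0.04 over the 0.25–0.75 range (largest
mid-range). The recovery test therefore uses enough replicates (2000) that
Monte-Carlo error does not mask the bias, and checks it stays within 0.05.

Rank-sum and signed-rank tests use exact null distributions for small
tie-free samples (n ≤ 20 / ≤ 25) and tie-corrected normal approximations
otherwise; all-zero paired differences return p = 1 with a warning. The
Friedman test is the tie-corrected chi-square on ranks. Bonferroni
adjustment caps at 1. Type-I error of all three is Monte-Carlo checked at
α = 0.05.

## The simulator: what it emulates, and what it does not

Per trial: PPG is a Gaussian pulse train (σ = 60 ms) whose beat rate is an
AR(1) process (pole 0.7) around the subject's mean HR, amplitude-modulated
at the respiratory frequency with 10 % depth — respiration is embedded in
the PPG because that is where the analysis reads it from. GSR is a tonic
level with slow drift plus Poisson SCRs (0.7 s rise, 3 s decay). EOG gaze
components carry Poisson saccades (gaze jumps between positions drawn
around straight-ahead, σ_h = 10, σ_v = 5 a.u.) and raised-cosine blinks
(half-amplitude duration 0.2–0.4 s, i.e. base width 0.4–0.8 s — the
half-amplitude reading is what survives 16 Hz decimation plus a 7-point
median filter the way real blinks do; amplitude ~200 a.u., positive above /
negative below the eye at gains ±½ so the derived components reconstruct
the drawn amplitudes at unit gain).

Defaults: HR 70 bpm (sd 3), RR 15 breaths/min, 15 blinks/min, 40
saccades/min, 4 SCRs/min. Stimulation shifts: −1.5 bpm HR-sd, −6
blinks/min, +3 breaths/min — directions from the reported physiology of
craving stimulation; magnitudes are free parameters chosen once to be
comfortably recoverable at trial level. Craving scores are drawn in
disjoint bands (wash-off 1–2, stimulation 3–5), so the manipulation check
passes by construction, mirroring a cohort in which the stimulation worked
for every retained subject.

Two variance knobs shape the reliability questions: `subject_sd` (default
0.10) multiplies each process parameter once per subject — the trait
variance that makes features reliable across days — and `session_drift_sd`
(default 0) does the same once per session, eroding cross-day transfer
while leaving within-day separability intact. Both are fractional
perturbations, one interpretable knob across parameters with different
units. Everything is driven by `numpy.random.Generator` streams spawned
from a single seed; (config, seed) determines every sample bit for bit.

Not emulated: real pulse morphology and baroreflex coupling, respiratory
sinus arrhythmia, motion and electrode-pop artifacts, smooth-pursuit eye
movements, non-stationary tonic EDA, and any genuine physiological response
to video content. Passing tests therefore demonstrate that the *analysis*
recovers what it assumes from data of this structure — not that the
features behave this way in human recordings.

## Problem sizes and numerical choices

The raw rate is configurable; the default is 2048 Hz. Single-trial and
single-subject checks run at the full rate; cohort-scale Monte-Carlo runs
(20 subjects × 3 drift levels; the nine-subject acceptance cohort) use
256 Hz, still a 16× decimation to the 16 Hz working rate, which changes none
of the analysis logic. One pipeline seed is expanded via
`numpy.random.SeedSequence` spawn keys into fixed child streams
(simulation, CV shuffling, forest seeding), so adding a consumer does not
shift existing streams. Report CSVs are written with fixed float formatting;
identical config + seed reproduces a bundle byte for byte.

## Known limitations

* The saccade "degree of movement" convention (summed absolute step
  heights; Euclidean pairing for DSM) is one defensible reading of a
  quantity whose original definition is not fully public.
* The RR estimator assumes the respiratory AM is the dominant in-band
  envelope component; strong low-frequency HR wander narrows its margin.
* ICC p-values assume the normal-theory F distribution; with n = 9 subjects
  they are approximate at best.
* CDNN with k = n_train makes the neighbourhood the whole training set;
  its behaviour then differs from published CDNN variants with local k.
* The craving-score generator guarantees the manipulation check; it cannot
  probe what happens when a subject feels no craving (such subjects were
  excluded in the motivating paradigm).
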