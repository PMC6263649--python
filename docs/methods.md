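# Methods

stridekit implements a suite of accelerometer walk-detection (WD) and
step-counting (SC) algorithms, a strict per-gait-cycle evaluation
methodology, a context-impact benchmarking protocol, and a synthetic
gait simulator that stands in for an instrumented data collection. This
note records the models, the parameters that matter, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Problem setting

A body-worn tri-axial accelerometer produces x = {x_1, …, x_T} (units g;
a static sensor reads magnitude ≈ 1). Two tasks are addressed:

* **Walk detection** — classify each analysis frame as walking vs. any
  other activity (stairs, running, riding, brushing teeth, sedentary).
* **Step counting** — within a walking bout, emit one event per gait
  cycle of the instrumented side. A "step" throughout this package is
  one annotated gait cycle (heel strike to heel strike of the same
  foot); bilateral step totals are out of scope.

Five context variables modulate performance and are treated explicitly:
orientation knowledge IO, personalization IP, sampling rate R ∈ [5, 200]
Hz, frame size W ∈ [1.5, 6] s, and wearing location L (Foot,
FrontPocket, BackPocket, UpPocket, Hand, HandU).

## Preprocessing

* **Magnitude** d_t = √(x_t² + y_t² + z_t²) removes orientation
  dependence; all detectors and counters consume it unless IO is known.
  Gravity is kept in (no Earth-frame reconstruction): the magnitude of a
  static sensor is ~1 g and every downstream statistic either ignores DC
  (spectral band energies, detail coefficients) or removes the mean
  (variance, normalization).
* **WD filtering**: 15 Hz low-pass before framing. The filter family is
  a 4th-order Butterworth applied forward–backward (zero phase), chosen
  because it preserves peak timing; when a requested cutoff reaches
  Nyquist (e.g. the Pan–Tompkins 50 Hz cutoff at R ≤ 100 Hz) it is
  clipped to 0.45·R with a logged warning.
* **Framing**: W = 3 s frames with 0.5 s overlap by default; in
  window-size sweeps the overlap is always W/6. A frame's label is the
  majority activity of its samples; exact ties resolve to non-walk.
  The trailing partial frame is discarded.
* **SC normalization**: mean removed and scaled to unit variance, so the
  finite-state machine's four thresholds are comparable across subjects,
  placements and intensities. Mean removal is a package choice (the
  normalization could in principle scale only); it makes peak/valley
  gates symmetric about zero. Constant signals are rejected as
  degenerate.
* **Resampling**: polyphase anti-aliased decimation
  (`scipy.signal.resample_poly`); sessions are always synthesized at the
  200 Hz reference rate and downsampled for low-rate evaluation.

## Walk detectors

Three signal detectors threshold one scalar statistic per frame:

| detector | statistic |
|---|---|
| THR | variance of the low-passed magnitude frame |
| STFT | one-sided spectral energy in the closed walk band [0.66, 1.66] Hz |
| DWT | mean over the frame of the smoothed (1 s moving average) squared db10 detail coefficients of levels 7–8, mapped back to sample positions |

All three share the same fitting rule: an exhaustive scan over every
midpoint between consecutive distinct statistic values (plus the
extremes), maximizing training accuracy. Because walking variance sits
*between* sedentary and vigorous activities, the scan also fits a
polarity bit (walk-above vs. walk-below); threshold ties resolve to the
smallest threshold, polarity ties to walk-above. Detail levels are
indexed with level 1 finest; at rates other than 200 Hz the levels are
shifted by log2(200/R) rounded to nearest so the passband stays at the
same physical frequencies.

Two machine-learning detectors consume the full feature vector: k-NN
(k = 5) and an SVM with RBF kernel, evaluated by stratified 10-fold
cross-validation with per-training-fold standardization. The SVM's C is
chosen from {1, 10, 100} by an inner 3-fold grid search (gamma =
"scale"); both hyperparameter sets are deliberately small — the package
benchmarks representative algorithms, it does not chase a ceiling.

**Features** (per frame, on the magnitude; on all three axes
concatenated when IO is known): mean, population variance, min, max,
energy (mean square, so rms² = energy), population skewness, excess
kurtosis (both 0 by convention for constant frames), mean-crossing rate
(sign changes of x − mean, zeros dropped so plateaus count once), RMS,
and the first K = 32 one-sided FFT amplitude bins of a Hann-windowed
frame. With a 3 s frame the bin width is 1/3 Hz at any sampling rate,
which is what makes the ML detectors nearly rate-invariant above the
walk band.

## Step counters

Every counter reduces to *scored peak detection* on a transformed
signal, which gives all five a common ROC sweep variable:

* **FSM** — five-state machine on the normalized magnitude with
  thresholds t1 > t2 ≥ 0 ≥ t3 > t4: IDLE →(x>t2) RISING →(x>t1) PEAK
  →(x<t3) FALLING →(x<t4) VALLEY, emitting one event at the PEAK-phase
  maximum and returning to IDLE; incomplete traversals emit nothing. The
  four thresholds are grid-searched on an annotated training bout,
  maximizing strict TPR subject to FPR ≤ 5%; ties prefer larger t1
  (stricter peak gate), then larger t4. The t4 tie-break is a margin
  argument: among equally perfect configs, the valley gate furthest from
  the observed valley floor generalizes best to unseen bouts (a gate
  that training valleys barely clear is a knife edge).
* **PTM** (Pan–Tompkins chain) — FIR low-pass of order 200 with 50 Hz
  cutoff, first-difference differentiator, squaring, 0.5 s moving-window
  integrator; one integrator maximum per step. The FIR is applied as an
  edge-padded linear-phase convolution, so there is no group delay and a
  constant input stays exactly constant (no boundary transients).
* **STFT** — mean removed, FFT, keep the largest-magnitude coefficients
  (conjugate pairs counted jointly) until cumulative energy reaches 20%
  of the total, inverse transform, differentiate. Mean removal is
  required for the energy budget to be meaningful: on raw magnitude the
  gravity DC bin would absorb the entire 20%. An alternative reading of
  the 20% rule — accumulate from the low-frequency end — is available
  behind `mode="lowfreq"`; magnitude order is the default.
* **DWT / DWT2** — db10 decomposition to 8 levels; zero everything
  except detail levels {6, 7, 8} (gait band, ~0.4–3 Hz at 200 Hz) or
  {2, 3} (impact band, ~12–50 Hz); reconstruct. Level indices shift with
  rate as in the WD detector.

**Peak pruning.** Candidates are strict local maxima (plateau middles).
After optional minimum-height and minimum-prominence filters (defaults:
no height floor, prominence ≥ 0.1 × IQR of the transformed signal),
candidates are greedily pruned by a minimum distance of 0.25 s in
decreasing-height order, ties to the earlier peak. The decision
threshold is applied **last**, so raising it always selects a subset of
the events — this ordering is what makes every ROC monotone by
construction: thresholding a fixed event stream can only merge points
upward along the curve.

**Group II.** At UpPocket (and optionally Hand) the magnitude shows two
periods per gait cycle, so counters emit two events per step;
`fold_group2_events` pairs consecutive events and keeps the
higher-scored member of each pair before strict matching. Hand placement
is printed ambiguously in the source material's grouping; it defaults to
Group I with an override flag.

## Evaluation

* **WD error**: per-frame absolute disagreement Σ|s_t − f_t|; accuracy
  is 1 − error/T, reported after 1:1 class balancing by seeded
  subsampling of the majority class.
* **Loose SC error**: (Cest − Cgt)/Cgt × 100% (signed). It hides false
  positives that cancel misses, which motivates the strict rule.
* **Strict SC matching**: cycles are half-open [start, end); a cycle
  holding n > 0 events contributes 1 to Ctp and n − 1 to Cfp; empty
  cycles are misses; events outside every cycle count as Cfp (the strict
  definition exists to penalize spurious detections, so orphan events
  must not be free). TPR = Ctp/Cgt, FPR = Cfp/Cgt; FPR may exceed 1.
  Conservation holds exactly: Ctp + misses = Cgt, and Cest = Ctp + Cfp
  when all events fall inside cycles.
* **ROC**: sweep the score threshold from above the maximum score down
  through every distinct score; thresholds strictly decreasing, both
  rates non-decreasing. Operating points are picked as the grid point
  with FPR nearest the target (3% for context tables, 5% for
  error-source decomposition), ties to lower FPR.
* **Context reports**: the baseline is pooled data at R = 200 Hz,
  W = 3 s, IO/IP unknown. IO known → three-axis features for ML, best
  single axis for signal detectors/counters (chosen by training
  accuracy/TPR, exact ties to the gravity axis); IP known → fit and
  score per subject, then average (fold counts shrink to the subject's
  class sizes when needed); L known → restrict to that placement.
  Reports show per-setting deltas and the [min Δ, max Δ] range per
  context axis.

## The synthetic benchmark

The simulator emulates the kind of multi-subject, multi-placement
collection such studies use, with exact ground truth. The walking model
in the body frame is: gravity on z, plus 0.8× (vertical) and 0.3×
(forward) of a harmonic burst — ≥3 coherent harmonics of the observed
fundamental (stride frequency × periods-per-cycle, drawn U[0.8, 1.2] Hz
per subject, inside the [0.66, 1.66] Hz walk band) — plus one negative
Gaussian heel-strike impulse per observed period (amplitude 0.4 g ×
subject scale, σ = 50 ms), a small lateral sway at the stride frequency,
an arbitrary proper rotation (free orientation; identity when IO is
known), and white Gaussian noise (0.05 g default; no published noise
model exists for this setting, so a mid-grade MEMS figure was chosen).
Cycles are annotated heel strike to heel strike, so the harmonic peak
falls mid-cycle; annotation boundaries never coincide with the waveform
peak (an early design placed them together, which makes strict matching
ill-posed — any event jitter flips a detection into the neighboring
cycle).

Periodic non-walk activities are harmonic bursts with *coherent*
harmonics and a random global time offset (independent random phases
would randomize the waveform shape itself and hand the ML detectors a
phase-coherence artifact instead of a real discriminant). Stair
climbing — the hard confuser — is generated from a *different* cohort
member's walking signature, slowed 5–10%, with foot-fall impulses:
pooled across subjects the walk and stairs distributions then overlap
irreducibly, while each subject's own walk remains separable from their
own stairs. This construction is what gives personalization (IP) its
headroom. Per-subject variation: one amplitude scale U[0.6, 1.6], one
preferred cadence, and lognormal(σ = 0.25) harmonic jitter drawn once
per subject per activity. The default cohort is 6 subjects × 2 sessions
(~160 s each: walk, stairs, run, ride, stand, walk, sit), giving ~770
frames — sized so the full context sweep runs on a laptop in seconds.

What passing on this benchmark shows: the algorithms, metrics, and
context protocol are implemented coherently, and the qualitative
structure of real evaluations is reproduced (ML > spectral > threshold
ordering, personalization gains, rate robustness above the walk band,
near-perfect Foot counting, monotone strict ROCs). What it does not
show: absolute accuracies on real gait, robustness to cadence drift,
turning, irregular gait, device displacement, or hand-motion diversity
(extra hand jitter is exposed as a parameter without any fidelity
claim). Published table values from human-subject datasets cannot be
and are not reproduced here.

## Determinism and numerics

All randomness flows through one seeded `numpy` generator per run. CSV
writers use `%.17g` (exact double round-trip) and readers parse with
`float_precision="round_trip"`; identical configuration + seed yields
byte-identical output files. Wavelet decompositions reduce depth with a
logged warning when the signal is too short and reject depth < 2.
Zero spectra, constant signals, single-class training sets and empty
session plans raise informative errors rather than degenerate results.
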