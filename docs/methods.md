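# Methods

`mrcpkit` re-implements, on synthetic data with known ground truth, an
analysis chain for decoding attempted arm/hand movements from low-frequency
EEG in people with cervical spinal cord injury: a cue-based offline
five-class decoding study, its group statistics, and a self-paced online
detection proof-of-concept. This note documents the models, the defaults
and why, the numerical choices, and what the synthetic experiments do and
do not show.

## Signal model

The movement-related cortical potential (MRCP) is modelled as two
raised-cosine (Hann) lobes on the vertex electrode Cz: an early positive
lobe (cue processing) and a later negative lobe (the movement attempt).
Per-trial peak amplitudes and latencies are drawn from per-class Gaussian
distributions whose means and standard deviations are the published
group-level descriptive statistics of the two peaks (e.g. pronation:
+8.01 ± 2.97 µV at 0.44 ± 0.14 s, −5.48 ± 2.38 µV at 1.10 ± 0.09 s after
the class cue). Lobe half-widths are fixed constants (0.2 s positive,
0.3 s negative); the lobe coefficients are solved so the waveform passes
exactly through the drawn amplitudes at the drawn latencies, so with the
default widths the waveform extrema *are* the drawn peaks. Latency draws
are clipped to (0.1–1.2 s positive, positive + 0.2 s … 2.6 s negative) to
keep the two-peak morphology well defined; the clip is inactive for all but
extreme draws.

Treating across-participant summary statistics as per-trial generative
distributions is a stand-in, not a claim of fidelity: it reproduces the
*published peak statistics* in trial averages, but real single-trial MRCP
variability is not independent across trials, and real class information is
not confined to two peak parameters. One consequence is deliberate and
worth stating: because the two grasp classes differ by under 1 µV in mean
peak amplitude against ~2 µV amplitude spread and share one spatial
pattern, the achievable (Bayes) two-class accuracy of the synthetic online
task is modest (~60 %) — and at the detection moment it degenerates
further, since a partially-covered large MRCP is indistinguishable from a
fully-covered small one when classes differ only by scale. Property tests
that need clear class separation ("strong MRCP" conditions) therefore
scale amplitudes up, shrink spreads, and separate the negative-peak
latencies between the classes, and say so.

The scalp spread is a radial Gaussian gain around Cz in
azimuthal-equidistant coordinates (σ = 0.42 rad), ≈ 1 at Cz and ≈ 10⁻³ at
temporal sites, consistent with discriminative activity over central motor
areas. Background activity per channel is 1/f-amplitude ("pink") Gaussian
noise, default 5 µV RMS — a realistic low-frequency EEG floor. Optional
nuisances: 50 Hz line interference (2 µV, random phase per channel),
biphasic ocular blinks (default 2/min, 120 µV on EOG) projected with a
frontal gain that still reaches ~15 % of the frontopolar amplitude at the
vertex (as real blinks do — this is what makes ICA cleaning measurable),
short single-channel transients, and "bad" channels swamped with broadband
noise. All draws flow through one PCG64 generator seeded from the config,
so sessions are byte-identical across platforms for a given seed.

## Paradigm schedules

* **Offline**: 9 runs × 40 trials (72 per class, balanced within session),
  5 s trials, class cue 2 s after trial start, breaks uniform 1–3 s.
* **Online training**: class cue at trial start, ready cue at 2 s, go cue
  after U(0.5, 1) s + U(2, 4) s (the shrinking circle); MRCP time-locked to
  the go cue with the positive lobe scaled to 0.3 (the cue-related
  positivity is strongly reduced in this design); 5 × 30 movement trials
  and 4 × 70 s rest runs by default. A config toggle adds a second negative
  lobe 0.5 s after the main one, emulating the short-attempt session
  morphology.
* **Online test**: 5 s class cue then a 60 s self-paced period; attempts at
  least 3 s apart; each attempt is "reported" 2 s later with ± 0.3 s jitter
  (the jitter makes the true-positive-offset search non-trivial).

## Preprocessing

Four steps, as in the deployed pipeline: (1) drop noisy channels — AFz
always (blink-dominated), plus channels whose log median-absolute-deviation
departs from the population median by > 5 robust SDs (an automated stand-in
for visual screening; threshold config-exposed); (2) extended-infomax ICA
(mne implementation) on 0.3–70 Hz data, PCA-reduced to 99 % variance,
fitted only on samples within 10.4 MADs (≈ 7 Gaussian SDs) on every
channel; components are flagged as ocular when |r| ≥ 0.7 against any EOG
channel, or muscle-like when ≥ 30 Hz Welch power exceeds twice the
0.5–15 Hz power; (3) trial rejection: |x| > 100 µV, or joint-probability /
kurtosis statistics beyond 5 SDs across trials. The joint-probability
statistic is the classic single-trial log-improbability: per-channel
histogram densities (100 bins) pooled over trials, statistic = mean −log p̂;
cross-channel joint modelling is out of scope. (4) the cached ICA weights
are applied to the narrow-band (0.3–3 Hz) data, flagged components removed,
and back-projected.

Filtering: 4th-order Butterworth, zero-phase (forward–backward, squared
magnitude, zero group delay) offline; single-pass with steady-state initial
conditions online, so a constant input produces no onset transient — the
online path depends on this. Notch: zero-phase IIR at 50 Hz, Q = 30.
Re-referencing: common average over good EEG channels only.

## Decoding

Features are raw µV samples of all good EEG channels on a 200 ms lag grid
inside a feature window (default 1.4 s → 8 lags/channel), centred on the
evaluation time offline (non-causal) or trailing it online (causal);
ordering is channel-major. The classifier is multiclass LDA with the
shrunk pooled covariance Σ̃ = (1−λ)Σ̂ + λνI, ν = mean diagonal, λ estimated
by the analytic Ledoit–Wolf formula on within-class-centred data (λ can be
forced for the λ=0 / λ=1 oracle checks); scores pass through a softmax.
Ties in argmax resolve to the lowest class index. Accuracy curves: the
window slides in 1/16 s steps; at each position a repeated stratified
trial-based k-fold CV (10 × 10 by default; folds partition trials, never
samples) yields the mean per-trial correct-classification percentage.
Per-repeat fold shuffles derive from one seed stream, so curves are
deterministic given the seed. The 3-class subset analysis is the same
machinery with a restricted class list — configuration, not code.

## Group statistics

Difference topoplots: per participant, the mean over all C(k,2) pairwise
absolute differences of trial-averaged potentials, averaged within twelve
250 ms segments over 0–3 s post-cue, then averaged over participants.
(The published description contains a "250 s" segment length; 250 ms is the
only reading consistent with twelve panels over 3 s, and is what is
implemented.) Bad channels are interpolated before grid assembly with a
thin-plate-spline RBF — the 2-D biharmonic spline.

Significance: one-tailed max-statistic permutation test. Labels are
shuffled within each participant, the grand grid recomputed, and the null
distribution formed from the maximum of each shuffled grid over channels ×
segments; a cell is significant when the observed grid exceeds the (1−α)
null quantile. A single threshold for the whole family controls the
family-wise error by construction; the calibration (FWER ≤ α on null data
over 200 independent runs) is machine-checked. Default 1000 permutations
(not stated in the source study).

Cz peaks: positive peak = maximum in 0.2–0.9 s, negative peak = minimum in
0.7–2.5 s (fixed documented windows; the peaks are defined only
descriptively in the source). Waveforms violating the two-peak morphology
are measured anyway and flagged degenerate. Class effects on peak features
are tested with the Friedman rank test (scipy, mid-ranks for ties; the
all-identical table returns χ² = 0 by convention). Confidence intervals
are t-based: mean ± t₁₋α/2,n₋₁·sd/√n. Better-than-chance accuracy
thresholds use the upper bound of the adjusted Wald (add-z²/2) interval
around chance at α/m, two-sided, with m the number of tested time points;
all inputs are exposed because the published 22.3 %/38.1 %/62.4 %/65.3 %
values depend on post-rejection trial counts and an m that are not
printed. For the grand-average curve the pipeline uses the pooled
(summed) kept-trial count across participants as n, which reproduces the
magnitude of the published grand-average threshold. The cohort pipeline
reports the confusion matrix as the mean of per-participant confusions at
each participant's own accuracy peak, which avoids retaining all epochs in
memory and is equivalent in expectation for synthetic cohorts.

## Online detection

The 5-class training set anchors at t_train, the 1/16-s grid point in
[1, 2] s post-go with maximal 10-fold CV accuracy (ties → earliest). Pre
and post classes take the causal feature window shifted −500/+500 ms,
pooled over both movement classes; rest epochs are cut evenly from the
70 s rest runs so the rest count equals the movement-trial count.

The replay evaluates the classifier at every sample (256 Hz) of the
causally filtered stream — the deployed classifier was "constantly active"
without a stated cadence, and per-sample is the faithful limit. A movement
is detected at decision time t (t₀ = t − 650 ms) when: pre-class
probability > 0.7 for a cumulative 150 ms within [t₀−650, t₀−350] ms;
either movement probability > 0.9 within [t₀−50, t₀+50] ms; post-class
probability > 0.7 for 150 ms within [t₀+350, t₀+650] ms. Dwell is counted
in whole samples (⌈0.150·rate⌉), cumulative by default with a consecutive
variant behind a config switch. The detected class is the movement class
with the higher within-window maximum; detections are suppressed for 2 s
(refractory). The decision at t uses samples ≤ t only — causality is a
tested property. The deployed channel policy (bad channels, CAR) is fixed
at training time and reused at test time.

Delay accounting: the average maximum detection delay is t_train + 500 ms
(post-window centre) + 75 ms (half the dwell). Evaluation: the
true-positive window is 2 s wide, centred at reported attempt + offset,
with the offset chosen on a 0–5 s grid (0.1 s step) to maximise the TP/FP
detection ratio; zero-FP offsets dominate all finite ratios and compare by
TP count; ties take the smallest offset. TPR = TP/P·100 over reported
attempts; FP/min counts detections within the 60 s rest periods only
(excluding the 5 s cue); accuracy is computed over TPs only, each TP
matched to the nearest covering window.

## Problem sizes and what the tests show

The test and acceptance runs use desk-scale problem sizes chosen as the
smallest that make each property statistically decidable: cohorts of 2–4
synthetic participants, sessions of 1–9 runs, 199-permutation tests with
200 calibration repetitions, 10-seed paired comparisons, and reduced
(30 s) self-paced periods in the multi-seed replay. Parameter recovery is
tested with latency SDs set to zero: latency jitter attenuates trial
averages by design (exactly as in real ERP averaging), so the published
peak means are recovered in averages only when the latency is held at its
class mean; with jitter on, the attenuation is expected and not an error.

Passing tests show that the pipeline is correct and calibrated *under this
generative model*. They do not show that real SCI EEG reaches any
particular accuracy: the published human decoding numbers (45.3 % 5-class
peak, 53.0 % 3-class, the per-participant table, the online session table)
are measurements on the deposited human recordings and are intentionally
not reproduction targets of the synthetic study.

## Known limitations

* No biophysical head model; the spatial patterns are one-parameter radial
  gains, so spatial-filter behaviour (CAR, ICA mixing) is simpler than on
  real data.
* The ocular/muscle component screening is heuristic and unvalidated
  against expert labels; thresholds are config-exposed.
* The online generator plants go-locked MRCPs for self-paced attempts;
  anticipatory activity before self-paced movement is not modelled.
* Class discriminability of the synthetic online task is Bayes-limited to
  ~60 % under the published peak statistics (see Signal model).
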