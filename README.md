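# mrcpkit

Decoding attempted arm and hand movements from low-frequency EEG, end to
end, on synthetic ground truth.

People with cervical spinal cord injury retain cortical correlates of
movements they can no longer execute. Movement-related cortical potentials
(MRCPs) — slow deflections over sensorimotor cortex in the 0.3–3 Hz band,
an early positive peak followed by a negative peak near 1 s — carry
information about *which* movement was attempted (hand open, palmar grasp,
lateral grasp, pronation, supination), which a brain–computer interface can
turn into neuroprosthesis commands. `mrcpkit` implements the complete
analysis chain for this problem as a tested Python package, driven by a
paradigm-faithful synthetic EEG generator so every stage is verifiable
without human recordings:

* **Synthetic sessions** (`mrcpkit.synth`) — 61-channel 10-5 EEG + 3 EOG at
  256 Hz; cue-based offline trials, shrinking-circle online training
  trials, 60 s self-paced test periods; class-dependent two-peak MRCP
  waveforms with published group-level peak statistics as generative
  defaults; 1/f noise, 50 Hz line, blinks, transients, bad channels.
* **Artifact pipeline** (`mrcpkit.preprocessing`) — bad-channel screening,
  extended-infomax ICA on MAD-masked broadband data with cached weights,
  ocular/muscle component rules, amplitude / joint-probability / kurtosis
  trial rejection, zero-phase and causal Butterworth filtering, CAR.
* **Decoding** (`mrcpkit.decoding`) — lagged-sample features (200 ms grid),
  shrinkage LDA

  Σ̃ = (1−λ)·Σ̂ + λ·ν·I,  ν = tr(Σ̂)/d,

  with analytic (Ledoit–Wolf) λ and softmax probabilities; sliding-window
  10 × 10 trial-based cross-validation; confusion matrices.
* **Group statistics** (`mrcpkit.group_stats`) — difference topoplots
  (mean absolute pairwise class differences, 250 ms segments), one-tailed
  max-statistic permutation test with family-wise error control, biharmonic
  bad-channel interpolation, Cz peak features, Friedman tests, t-based
  CIs, adjusted-Wald significance thresholds.
* **Online detection** (`mrcpkit.online`) — the self-paced proof-of-concept:
  5-class training (movement classes + rest + pre/post gates around
  t_train), a causal three-window detection state machine (pre > 0.7 for
  150 ms, movement > 0.9, post > 0.7 for 150 ms, 2 s refractory), TPR =
  TP/P·100, FP/min from rest, detection-delay accounting
  (t_train + 575 ms), TP-window offset search.
* **Pipelines** (`mrcpkit.pipelines`) — both experiments end to end,
  deterministic from config + seed.

The numbered drivers under `analysis/` run the study: `01_simulate_sessions.py`,
`02_offline_analysis.py`, `03_online_experiment.py`; each writes plain
tables under `results/`.

## Worked example

A synthetic five-participant offline cohort (9 runs × 20 trials each,
default noise, 10 × 2 cross-validation on a five-point time grid):

```bash
$ python analysis/02_offline_analysis.py --seed 1
classes: 5 (chance 20.0 %)
grand-average peak accuracy: 27.9 % at 0.70 s post-cue
95 % CI over participants: [21.5, 34.4] %
significance threshold (adjusted Wald, Bonferroni): 23.7 %
trials kept per participant: [180, 180, 180, 180, 180]
...
Friedman neg_amp: chi2(4) = 15.7, p = 0.0035
Friedman pos_lat: chi2(4) = 13.9, p = 0.0075
```

Reading: the decoder peaks between the two MRCP peaks at 27.9 % against a
20 % chance level, clearing the multiple-comparison-corrected significance
threshold of 23.7 % computed from the pooled kept-trial count; the
per-participant spread gives the confidence interval, and the Friedman
tests find significant class effects on the Cz peak features. The
synthetic effect sizes come from group-level peak statistics, so the
absolute accuracy is not meant to match the human study; clearing the
threshold with central-channel difference topoplots is the designed
outcome.

The self-paced online experiment (train, pick t_train, replay, score):

```bash
$ python analysis/03_online_experiment.py --seed 1
t_train = 1.625 s (3-class CV accuracy 46.7 %)
detection delay = 2.20 s
TP-window offset = 0.0 s
movement attempts P = 307
TP = 79, TPR = 25.7 %
FP/min (rest trials) = 6.7
accuracy on TPs = 58.2 % (chance 50 %)
```

Reading: t_train is the post-go-cue time where the 3-class (open/grasp/
rest) training accuracy peaks; every detection is gated by the pre- and
post-class probability windows and suppressed for 2 s afterwards; TPR
counts detections inside the 2 s true-positive window around reported
attempts, FP/min comes from rest trials only, and the class accuracy is
computed over true positives only. Under the published group-level peak
statistics the two grasps are nearly indistinguishable at the detection
moment (see `docs/methods.md`), so the TP accuracy sits close to chance
here by construction.

## Real data

The optional `read_recording(path, format="gdf_or_edf")` reads deposited
biosignal recordings through mne; nothing in the package or its tests
requires them.
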