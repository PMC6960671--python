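# Methods

## Problem and model

`pepdetect` implements single-trial detection of postural-perturbation
("falling-risk") events from multichannel EEG. An unexpected withdrawal of
postural support elicits a perturbation-evoked potential (PEP): a large
fronto-central negativity within ~100 ms (N1), followed by a smaller frontal
positivity (P2). Because these components are time-locked, large, and only
elicited by *unpredicted* perturbations, they are a usable biomarker for
online detection of dangerous balance events.

The detector is a linear pipeline:

1. **Conditioning.** Zero-phase Butterworth bandpass 0.1–10 Hz (order 4,
   forward–backward), then decimation to 50 Hz. The band suppresses EMG and
   most sensorimotor rhythms while keeping the slow evoked components;
   zero-phase filtering is used so component latencies are not shifted.
2. **Epoching.** −2 s to +4 s around each perturbation onset; onsets come
   either from ground truth (simulation) or from the handle force (argmax of
   the magnitude of the smoothed second difference of the perturbed-side
   force — the point of sharpest curvature).
3. **Augmentation.** Per training trial, 20 "rest" windows of 500 ms with
   random starts on [−2000, −500] ms and 20 "instability" windows sliding
   from −300 ms to +80 ms in 20 ms steps (half-open at +100 ms).
4. **xDAWN.** The evoked response is estimated by least squares through the
   0/1 Toeplitz design of the onsets; spatial filters are the leading
   generalized eigenvectors of the (evoked, total) covariance pair. One
   component is kept, signed so its evoked time course has a negative
   extremum (N1 polarity). Rank-deficient total covariance is ridged with
   εI, ε = 1e−8 · trace/channels.
5. **Normalization.** Per-feature z-scoring; parameters estimated on the
   training windows only and reused verbatim on test windows.
6. **BLDA.** Bayesian linear regression onto class-balanced targets
   (+N/N₊, −N/N₋), prior precision α on the weights (bias unpenalized),
   noise precision β, both learned by MacKay evidence updates
   (effective-parameters form) until the relative change is < 1e−4 or 100
   iterations (non-convergence is flagged, not fatal). The decision
   threshold is the median of the pooled training scores; with the balanced
   20/20 augmentation this equilibrates sensitivity and specificity.
7. **Evaluation.** 500 ms test windows slide from −500 to +500 ms in 20 ms
   steps over held-out trials. Per offset, the detection rate is the
   fraction of windows above threshold. Scalars: false-alarm rate (fully
   pre-onset windows), maximum detection rate and its peak timing (post-onset
   offsets), and detection latency — the earliest post-onset window start
   whose rate reaches the criterion (default 90 %). Cross-validation uses
   ten independent random 45/5 trial subsamples (a disjoint 10-fold
   partition is impossible at 45/5 of 50); train/test trial sets are
   disjoint within every fold. Cross-task evaluation trains on one
   perturbation side only and tests on the other.

Window coordinates are 0-based, half-open `[start, start+500) ms` relative
to onset, and all window starts land on the 50 Hz grid. Test windows that
straddle the onset are scored in the curve but excluded from the scalar
false-alarm/detection aggregates.

## Synthetic sessions

No public recordings exist for this paradigm, so the package ships a
generator that emulates the study conditions and makes every stage testable:

* **Protocol**: 50 events per session, rest intervals uniform on 5–15 s,
  perturbation side random (or prescribed), 60-channel 10-10 montage at
  1000 Hz.
* **Evoked model** (all time-locked to onset, zero at t = 0):
  N1 — Hann lobe, −14.75 μV peak at 62 ms, half-width 60 ms, Gaussian scalp
  gain centred at FCZ with σ calibrated so C3/C4 retain 40 % of the peak;
  P2 — Hann lobe, +5 μV at 167 ms, half-width 100 ms, centred at FZ;
  sustained negativity — 30 % of the N1 amplitude, FCZ topography, cosine
  ramp over 0.28–0.42 s, plateau to 1.2 s, resolved by 1.8 s. The sustained
  part models the ongoing instability state (the subject is destabilised and
  recovering for over a second); without it, test windows starting late
  after onset would contain no signal at all, which contradicts how such
  detectors behave on recorded data. It begins after P2 resolves and scales
  with the N1 amplitude, so the calibrated peak values and the all-zero
  degenerate case are exactly preserved.
* **Background noise**: 12 latent 1/f^γ sources (γ = 1) with smooth random
  Gaussian scalp maps, mixed into the channels, plus 10 % (variance)
  independent per-channel 1/f noise; every channel scaled to exactly
  `noise_rms`. Default `noise_rms` = 12 μV — a realistic resting-EEG RMS in
  the 0.1–10 Hz band, and the one free calibration knob: it places the
  synthetic benchmark near the method's reported operating regime (~4 %
  false alarms, ~100 % peak detection) without being fitted to any reported
  number.
* **Handle force**: baseline 180 N per handle; at onset the perturbed side
  follows a fast saturating decline losing 130 N within 300 ms (> 80 N in
  the first 100 ms), the contralateral side rises ~60 N (compensation), and
  both recover to baseline within 4 s. The abrupt start of the decline is
  what the second-difference onset marker keys on.
* Optional knobs, off by default: per-trial N1 amplitude jitter (Normal,
  truncated to keep N1 negative) honouring the ±5.99 μV inter-subject
  spread, and a left/right template asymmetry for robustness experiments.

What the generator does **not** emulate: eye blinks, line noise, electrode
drift, sEMG crosstalk, auditory confounds, or any nonstationarity of the
background statistics. Passing tests therefore demonstrate the pipeline's
correctness and its behaviour under the stated signal/noise model — not
performance on recorded EEG, where artifact structure and inter-subject
variability dominate.

## Numerical choices

* Decimation is plain sample picking; the 0.1–10 Hz bandpass is the
  anti-alias stage (50 Hz = 5× the upper band edge). Event indices map by
  integer division.
* Onset marking smooths with an 11-sample moving average (at 1000 Hz)
  before the second difference; the marker lands within a few ms of the
  true onset, well inside the 20 ms window step.
* The generalized eigenproblem is solved on covariance matrices
  (`scipy.linalg.eigh`), not via the QR-of-data route; at these sizes the
  two are equivalent and the covariance route is directly testable against
  dense oracles and random-search scans.
* BLDA with frozen (α, β) reduces exactly to ridge regression, which is the
  closed-form oracle used in tests. The bias is excluded from the prior by
  default (`penalize_bias=True` restores the plain isotropic prior).
* Degenerate inputs: constant features get unit sd (map to 0); a flat force
  trace raises "no onset detected"; events too close to a recording edge are
  dropped with a warning; a failing CV fold is excluded and warned about.
* EDF+ export quantizes to 16 bits over a per-channel symmetric range
  (error ≤ 1 step ≈ 0.003 μV at ±100 μV) and pads to whole 1 s records;
  events travel as EDF+ annotations and return sample-exact.
* All randomness flows from explicit integer seeds (`numpy.random.default_rng`);
  per-fold seeds are derived via `SeedSequence([seed, fold])`. Identical
  seeds give bit-identical sessions and reports.

## Known limitations

* Epoch-wise filtering does not commute with continuous filtering to high
  precision: the 0.1 Hz band edge has a multi-second impulse response, so
  the pipeline always filters the continuous recording before epoching.
* With few training trials (< ~15 at 60 channels) the xDAWN covariances are
  poorly estimated and the filter can overfit; the detection-rate curves
  then become unstable. The study-scale 45-trial training set is comfortably
  above this.
* The detection curve shows a reproducible dip for windows starting just
  past the training slide range (+100…+160 ms): those alignments were never
  seen during training (half-open slide at +100 ms) and the ERP is partly
  outside the window. This is a property of the protocol, not a bug.
* Detection latencies on the synthetic benchmark are short (tens of ms),
  since windows starting at 0 already contain the full N1 at the calibrated
  SNR; latencies of ~300 ms arise only at lower SNR, as the per-offset rates
  cross 90 % later.
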