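# Methods

`eeghotspot` estimates the location of the motor hotspot — the scalp site
whose stimulation most effectively drives a hand muscle (FDI), normally
found with TMS-evoked MEPs — from movement-related EEG alone. A per-subject
2D convolutional network regresses the hotspot's 3D coordinates (mm,
vertex-origin frame) from single-trial EEG tensors; accuracy is scored as
the Euclidean distance to the ground-truth location. Because clinical
EEG/TMS data of this kind are not publicly available, the package ships a
synthetic movement-EEG generator with known planted hotspots, and all
quantitative results here are parameter recovery on that generator — not
clinical accuracy claims.

## Head frame and montages

Electrode positions are computed on an idealized spherical head
(radius 90 mm): the 10-20/10-10 placement arcs are divided in 18° steps and
intermediate rows are placed by great-circle interpolation between their
midline and outer-ring anchors. Coordinates are reported in a vertex-origin
frame — Cz at (0,0,0), +x right, +y nasion, +z up — matching the digitizer
convention in which hotspot coordinates are recorded relative to the vertex.
Two montages are shipped: `healthy63` (63 data channels at 1000 Hz;
Fpz/FCz are ground/reference and are not data channels) and `stroke29`
(29 channels at 500 Hz). Left/right electrode pairs are exact mirror images
in x by construction.

Channel sets mirror the ablation layouts: healthy Set1 (all 63) ⊃ Set2
(fronto-central-parietal rows, 48) ⊃ Set3 (FC/C/CP rows, 30) ⊃ Set4
(contralateral motor rows, 14 per hand) ⊃ Set5 (9 channels around the
contralateral C3/C4); stroke Set1 (29) ⊃ Set2 (14) ⊃ Set3 (5 around
contralateral C3/C4). Only the smallest sets' memberships are published
explicitly; the intermediate sets are reasonable reconstructions and every
set is overridable via `select_channel_set(..., overrides=...)`.

## Synthetic movement-EEG generator

The generator defines the study conditions and is first-class, tested code.
Per subject and hand it draws a hotspot on the scalp sphere near the
contralateral hand-knob electrode (C3 for right-hand movement, C4 for
left), displaced anterior-laterally along the scalp and jittered
isotropically in the tangent plane (SD 7 mm healthy, 14 mm stroke), then
reprojected onto the sphere. The fixed displacement magnitudes (24.07 mm
healthy, 34.79 mm stroke) were calibrated once by Monte Carlo so the mean
3D distance to C3/C4 equals the clinically reported offsets (24.31 mm and
34.96 mm respectively); the calibration is re-verified by a seeded test and
recomputed by `scripts/acceptance.py`.

Signal model, per continuous recording (30 trials per hand, inter-trial
intervals uniform on 3–7 s, 2 s lead-in/out):

* **Background**: per-channel band-limited 1/f noise (1–55 Hz), 10 µV RMS,
  plus a rank-3 shared pink-noise component at 20 % RMS as a stand-in for
  volume conduction.
* **Movement-locked burst**: 30–50 Hz band-limited noise under a 0.4 s Hann
  envelope, centred on the key press (healthy) or 0.3 s after the cue
  (stroke, movement latency). Channel amplitudes follow a Gaussian
  scalp-distance kernel around the hotspot, gain_i = exp(−d_i²/2σ²) with
  σ = 20 mm, max-normalized. The burst is scaled so that at the best channel
  its RMS is `snr` × that channel's background RMS (defaults: 5.0 healthy,
  3.5 stroke — the stroke preset lowers SNR by 30 % and doubles jitter to
  echo the noisier clinical setting).
* **Artifacts**: frontal-dominant blinks (300 ms biphasic template, 80 µV
  at the most anterior site, weight ∝ clipped anterior y², Poisson at
  10/min by default).

The kernel footprint is a forward-model surrogate, not a leadfield: it is
the simplest spatial model that makes the hotspot decodable from
channel-space gamma patterns. The generator does not emulate alpha/beta
ERD/ERS, cardiac/EMG artifacts, electrode impedance drift, or lesion
effects, so passing tests demonstrate method mechanics and parameter
recovery on this model, not clinical fidelity.

## Preprocessing ladder

Five cumulative input levels, all downsampled to 200 Hz first (polyphase
anti-aliased resampling; event indices rescaled): (1) raw channel × time
epochs; (2) + common average reference; (3) + zero-phase 3rd-order
Butterworth band-pass 1–55 Hz (forward-backward, so the realized magnitude
response is the squared one-pass response; edges padded by ~6 time
constants of the 1 Hz cutoff so transients settle); (4) + extended-Infomax
ICA with automatic artifact flagging — a component is removed when its time
course correlates with the frontal blink proxy (|r| > 0.7, mean of Fp1/Fp2)
or its excess kurtosis exceeds 8, both thresholds config-exposed; PCA
whitening with rank truncation handles the rank deficiency CAR introduces;
(5) + gamma-band PSD: magnitude-squared FFT (rectangular window) with the
epoch zero-padded to the next multiple of fs/resolution samples so integer
frequencies are exact bins; 21 bins at 30…50 Hz inclusive.

Epoch windows are (−0.5, 0.5) s around key presses (healthy; 200 samples at
200 Hz) and (−0.5, 1.0) s around cues (stroke; 300 samples). Trials whose
window leaves the recording are dropped with a warning, never zero-padded.
CAR and ICA always run on the full montage; channel-set restriction is
applied after epoching. The original analysis removed ICA components by
visual inspection, which is not testable; the correlation/kurtosis rule is
the automated stand-in.

## CNN coordinate regressor

`MotorHotspotCNN` (statsmodels-style: model object built from data,
`fit()` returns a results object) wraps a NumPy implementation of the
published architecture: four convolution blocks of (2, 2, 3, 3) stride-1
7×7 convolutions with 16/32/64/128 filters and shape-preserving padding,
each followed by a 2×2 stride-2 max-pool with ceil/zero-padding semantics —
10 convolutions + 4 pools + 3 dense layers = 17 layers, final width 3 with
linear activation, ReLU elsewhere. Convolution padding and the widths of
the first two dense layers are not published; defaults are shape-preserving
padding and 256/64, both config-exposed. Channels map to image height,
time/PSD bins to width, one single-channel "image" per trial.

Training follows the published recipe: Adam (lr 0.001), MSE loss, batch 10,
up to 1000 epochs with early stopping after 20 epochs without validation
improvement and best-weight restoration. Two numerical choices are ours:

* inputs are standardized per channel with training-set statistics only
  (zero-variance channels get unit scale with a warning), and
* targets are normalized by `coordinate_scale` (the 90 mm head radius)
  during optimization, with predictions and reported losses rescaled to mm.
  Without this, Adam's per-update output movement at lr 0.001 is
  O(0.05 mm), so reaching 60–80 mm coordinates needs on the order of a
  thousand epochs (consistent with the original 1000-epoch GPU budget);
  with it, per-subject fits converge in tens of epochs on one CPU. The
  history's `train_loss`/`val_loss` are reported in mm².

The engine (conv via im2col/GEMM, float32) is verified by finite-difference
gradient checks and is deterministic given the config seed.

## Evaluation protocol

Per subject × hand dataset (all 30 trials share that subject's ground-truth
coordinates): trial-wise nested cross-validation with a 5-fold outer loop
repeated 5 times (25 evaluations). Within each outer training set (80 %),
validation takes floor(n/5) trials (4:1) for early stopping, remainder to
training; a fresh model is trained per fold. The per-fold subject
prediction is the mean over outer-test trial predictions; fold errors are
averaged to a subject mean, subject means to a cohort mean ± SE. Fold
assignment is seeded per (dataset, repetition) and every fold's
train/val/test indices are retained in the result for leakage audits and
exact replay. Fold sizes differ by at most one when trials are not
divisible by 5; datasets down to max(k_outer, 3) trials are accepted so the
5-trial ablation condition can run.

Ablations: channel sets restrict tensors after epoching; trial-count
conditions subsample without replacement with nested subsets per seed
(the 5-trial subset ⊂ 10 ⊂ … ⊂ 30), so conditions differ only by data
volume. The chance-level reference is the mean predictor (predicts the mean
training-truth coordinate); its error approximates the spread of hotspots
around the cohort mean, ≈9 mm for the healthy prior within one hemisphere.

Statistics mirror the published comparisons: Friedman omnibus across ≥3
paired conditions, pairwise Wilcoxon signed-rank (paired) or rank-sum
(unpaired) post hoc, Bonferroni-multiplied p-values capped at 1,
significance at corrected p < 0.05. The signed-rank test uses the exact
null for n ≤ 25 without ties (verified in tests against full 2^n
enumeration for n ≤ 12) and the normal approximation above.

## Problem sizes in the shipped tests and acceptance script

The clinical headline errors (0.35–2.34 mm over 54 healthy datasets; 25
nested-CV evaluations per dataset at up to 1000 epochs) are not
reproducible without the clinical recordings; the package's own experiments
are sized for a single CPU:

* **Recovery** (tests and `scripts/acceptance.py`): healthy preset, 6–10
  subjects (right hand), 9-channel Set5, raw time-series input, full
  published architecture, one 80/20 outer split per subject, published
  optimizer settings with the epoch budget capped at 40. The published
  patience of 20 is kept deliberately: the validation loss oscillates
  strongly during the first ~10 epochs while predictions transit toward the
  target coordinates, and a shorter patience strands fits mid-transit.
  Success criterion: cohort mean error < 0.5 × mean-predictor baseline.
  Typical result ≈1–3 mm vs ≈9–10 mm baseline.
* **Trial-count trend**: 10 seeds × 1 subject, reduced network
  ((1,8),(1,16) conv blocks, one 32-unit hidden dense layer), nested CV
  with one repetition, max 100 epochs. The trend error(5) > error(10) >
  error(30) arises from under-training — fewer gradient updates and
  noisier early stopping at small trial counts — the same mechanism that
  produces the steep degradation reported clinically (≈57 mm at 5 trials).
  The architecture reduction is justified because the trend is a
  data-volume property, not an architecture-size property.
* **ICA tests** use a blink-heavy short stroke recording (120 blinks/min)
  so blink variance clearly dominates the frontopolar channels.

## Known limitations

* The spatial footprint is a Gaussian kernel, not a biophysical leadfield;
  absolute error magnitudes on synthetic data are not comparable to
  clinical numbers.
* Per-subject training with a constant target makes the task a
  regularized memorization problem; the evaluation therefore measures
  convergence and robustness of the training protocol rather than
  cross-subject generalization (which the clinical protocol also did not
  attempt).
* EDF files can be read (via MNE) but not written; the native interchange
  format is a `.npy` matrix with a JSON sidecar header.
* The montage geometry is an idealized sphere; no individual head geometry
  or MRI coregistration is supported.
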